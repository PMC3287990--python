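# Methods

## Fold validation

A query is scored against each globin template (GLB3F, GLB3S, GLB2 —
one per family) by pairwise alignment with BLOSUM62 and affine gaps
(open 11, extend 1). End gaps are free on both sequences (overlap
alignment), so a 150-residue globin template anchors inside a 400- or
1100-residue chimera without terminal penalties; this is the package's
deterministic stand-in for profile-based fold recognition, which is out
of scope. Helix-coordinate labels are transferred through the aligned
blocks; a label falling in a query gap maps to "unaligned".

The null for the Z score consists of `n_shuffles` (default 200)
Fisher–Yates permutations of the query — composition-preserving by
construction — each aligned to the template; Z = (S − mean)/sd with the
sample standard deviation (ddof = 1). A degenerate null (sd = 0, e.g. a
homopolymer query) makes Z undefined and the query is rejected. The
Monte-Carlo error of Z scales as Z/√(2n): a self-match (Z ≈ 95) moves
by a few units between seeds while a borderline query (Z ≈ 10–15)
moves by well under one, which is what matters at the Z > 6 acceptance
threshold.

Acceptance is conjunctive: Z > 6 (the conventional 99%-probability
threshold), His at F8, and hydrophobic fraction ≥ 2/3 over the mapped
checklist positions. The hydrophobic set is {A, V, L, I, M, F, W, Y, C};
neither the residue set nor the fraction cutoff is fixed by convention,
so both are configurable. Unmapped checklist positions count as
failures. For the truncated 2/2 fold the checklist drops all A- and
E-helix labels (vestigial helices) and keeps the rest. The family of a
query is the family of the accepted template with maximal Z; the Z is
computed on the anchored protein as a whole, not per trimmed domain.

Trimming follows the fixed rule: the domain runs from 11 residues
before B10 to 15 residues after H8, clamped to the sequence; if either
anchor is unaligned, trimming is refused explicitly rather than
guessed. All coordinates in the package are 1-based inclusive.

## Architecture classification

Non-globin domains are located by local alignment against the cqx2 and
cqx3 templates, accepted at ≥ 35% of the template self-score — a
threshold placed between the score distribution of random 400-residue
sequences (empirically ≤ 5% false positives) and that of true domains
diverged to 60% identity, with a wide margin on both sides. LRR blocks
are ≥ 3 tandem matches of `LxxLxLxxN/CxL` at 11-residue spacing, merged
into one hit. Overlapping hits are resolved greedily by score (an
overlap above half the shorter hit's length discards the lower-scoring
hit). The signal-peptide heuristic requires a K/R within the first five
residues followed by a hydrophobic run of ≥ 8, all within the first 20.

The rule table is applied in order (F: cqx2+cqx3 → FHb, cqx2 only →
FHb_incomplete, else Fgb; S: C-terminal extension ≥ 100 → SensorChimera
else Sgb; T: any co-occurring domain → T1Chimera else T1; no accepted
globin → NonGlobin). Two descriptive conventions keep the table total:
an S-globin of ≥ 260 residues with a short C-tail stays Sgb with an
`oversized-sgb` flag (the < 260 rule of thumb is "generally", not
absolute), and an F-globin with cqx3 but no cqx2 — never produced by
the generator — falls through to Fgb. Normal-length FHbs (380–420
residues) and N-terminal extensions > 25 residues led by a predicted
signal peptide are flags on the call, not classes. Proteins with more
than one globin hit are reported as unclassifiable rather than forced
into a class. Extensions are measured from the first/last domain hit,
so an unknown N-terminal domain counts into `n_term_ext`.

## Synthetic data

Templates are artificial packaged sequences, not database entries:
hydrophobic residues at every checklist position, His at F8,
polar-biased elsewhere. GLB3F and GLB3S share the annotation layout but
are otherwise unrelated (~14% identity), so family assignment has a
well-conditioned argmax; GLB2 (116 aa) carries no A/E-helix labels.
CQX2 (100 aa) and CQX3 (146 aa) are sized so GLB3F+CQX2+CQX3 = 396
residues, the length of the *E. coli* flavohemoglobin. The LRR block is
six 11-mer repeats whose consensus positions are annotated so the
mutation model conserves them, as real LRR consensus positions are
conserved.

The mutation model substitutes `round((1−identity)·L)` distinct
positions uniformly over the 19 non-identical residues, exempting
annotated labels when `conserve_checklist` is set, and applies
Poisson-many short indels (1–3 residues, expected `indel_rate` per 100
residues, default 1.0) that never fall within 5 residues of a label —
keeping the label remapping total and letting true alignments be
written straight from the edit scripts with no aligner. Default
per-protein identities are drawn from 0.4–0.8 in general use and
0.6–0.8 in the recovery experiments; divergence levels among real
fungal globins are not documented, so this range is a package choice
meant to span "comfortably detectable" to "near the discrimination
limit".

What the generator does *not* emulate: realistic proteome sizes and
background (globin-free) proteins beyond composition-shuffled controls,
site-rate heterogeneity, domain shuffling, and alignment error —
passing recovery tests therefore demonstrates the internal consistency
of detector + classifier under the stated divergence model, not
performance on real proteomes.

The packaged census configuration encodes the reference census's
marginal totals (165 genomes; 136 with globins; 117 Ascomycota with 110
carrying globins; 33 Basidiomycota with 20; 21 of 29 Saccharomycotina
genomes with incomplete FHbs; 2 genomes with T1 globins; Mucoromycotina
with two Fgbs per genome). Within-taxon detail below those margins
(which species carries which count) is synthetic; the
`genome_complete` flag alternates to emulate that about half the
surveyed assemblies are drafts.

## Phylogenetics

p-distances use pairwise deletion — gap and X sites are excluded per
pair, not per column — and the per-pair usable-site counts are kept.
The Poisson correction d = −ln(1−p) is computed with `log1p`; p = 1 is
flagged as saturated rather than mapped to infinity. NJ follows
Saitou–Nei with the Q criterion; ties are broken by the lowest index
pair in current matrix order, making the tree a pure function of the
input order. Negative branch lengths are clamped to zero by default
(presentation convention; a flag disables it). The final three nodes
join a trifurcating root, i.e. trees are unrooted. On additive
matrices the input path lengths are reproduced to machine precision,
and topologies agree with scikit-bio's independent NJ on generic
matrices.

Bootstrap resamples columns with replacement, rebuilds the NJ tree per
replicate, and reports for each bipartition of the original tree the
fraction of replicates containing it; replicates whose resampled
distances saturate are dropped (conservative: they count as
non-supporting). The convention of displaying only supports
> 50% is exposed as a constant, not enforced in serialization.
Bayesian and ML inference are explicitly out of scope; clade
conservation is instead asserted NJ-versus-generating-tree on clean
synthetic alignments.

Alignment-ensemble ranking uses the symmetric average-overlap score
normalized by the mean of the two pair-set sizes. Overlap comparison
requires the same sequence ids with the same ungapped lengths but does
not compare residue content, so column-permuted negative controls can
be scored.

## Problem sizes and determinism

The recovery experiment uses 200 proteins (the seven classes cycled) at
identity 0.6 with 100-shuffle nulls; the specificity experiment uses
100 composition-matched shuffles of the F-template with 200-shuffle
nulls; bootstrap checks use 10 taxa × 150 columns × 100 replicates.
These sizes give binomial standard errors comfortably below the 95%
acceptance margins. All randomness flows from explicit integer seeds
(one `numpy` generator per call; per-template null seeds are spawned
from a `SeedSequence`), and every pipeline run writes a manifest of
config, seed and SHA-256 input/output digests; reruns are
byte-identical.

## Known limitations

- Anchoring quality degrades below ~40% identity to the nearest
  template; the Z score stays discriminative longer than the label
  transfer does.
- The signal-peptide and LRR detectors are deliberately simple pattern
  heuristics, adequate for the generator's constructs but not
  substitutes for dedicated predictors on real sequences.
- Family assignment assumes one globin domain per protein, which holds
  for the fungal architectures modeled; multi-globin proteins are
  surfaced but not classified.
- The census fixture is synthetic below these margins and
  carries no per-species identity.
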