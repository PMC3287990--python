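"""Synthetic proteomes with planted ground truth.

Proteins are assembled from domain grammars over the packaged templates
(globin 3/3 and 2/2 folds, the cqx2/cqx3 reductase halves, LRR repeat
blocks, signal peptides and unannotated extensions) and mutated to a
target identity.  Every generated protein carries its true architecture
class, true domain spans and true helix-coordinate map, so the
downstream fold detector, architecture classifier and phylogenetics can
be scored against known answers without any external data.

Mutations are substitution-dominated (uniform over the 19 non-identical
residues) with short 1-3 residue indels kept away from annotated
coordinate labels, which keeps the label mapping total and lets true
multiple alignments be written directly from the edit scripts, with no
aligner involved.

A packaged census configuration reproduces the headline totals of the
fungal globin census (165 genomes, 136 with globins, 117 Ascomycota,
21/29 Saccharomycotina genomes with incomplete flavohemoglobins, 2
genomes with T1 globins).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import architecture as arch
from .templates import DEFAULT_TEMPLATES, DomainTemplate, get_template

#: Architecture class labels (shared with the classifier).
ARCH_LABELS = (
    "FHb", "FHb_incomplete", "Fgb", "Sgb", "SensorChimera",
    "T1", "T1Chimera", "NonGlobin",
)

#: Polar-biased pool for unannotated extension segments.
_EXT_POOL = np.array(list("ADEGKNPQRSTHSED"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Indels are never placed within this many residues of an annotated label.
_INDEL_EXCLUSION = 5


class UnknownTemplateError(KeyError):
    pass


@dataclass(frozen=True)
class MutationModel:
    """Divergence model applied to template segments.

    target_identity
        Fraction of template positions left unsubstituted, in (0, 1].
    indel_rate
        Expected indels per 100 residues (lengths 1-3, half insertions).
    seed
        Integer seed; all randomness in a call flows from one generator.
    conserve_checklist
        Exempt annotated coordinate labels (the fold checklist and F8)
        from substitution, emulating their conservation in real globins.
    """

    target_identity: float = 0.6
    indel_rate: float = 1.0
    seed: int = 0
    conserve_checklist: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError(f"target_identity must be in (0,1], got {self.target_identity}")
        if self.indel_rate < 0:
            raise ValueError(f"indel_rate must be >= 0, got {self.indel_rate}")


# Grammar segments are template names, optionally with a length for EXT.
Segment = Union[str, Tuple[str, int]]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered domain grammar for one protein.

    ``grammar`` is a sequence of segments: a template name (``"GLB3F"``,
    ``"CQX2"``, ``"SIG"``, ...) or ``("EXT", length)`` for an
    unannotated extension of the given length.  At most one globin
    template is allowed (fungal globin architectures carry a single
    globin domain).
    """

    grammar: Tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grammar", tuple(self.grammar))
        n_globin = 0
        for seg in self.grammar:
            kind = seg[0] if isinstance(seg, tuple) else seg
            if kind == "EXT":
                if not (isinstance(seg, tuple) and int(seg[1]) > 0):
                    raise ValueError("EXT segments need a positive length: ('EXT', n)")
                continue
            if kind not in DEFAULT_TEMPLATES:
                raise UnknownTemplateError(kind)
            if DEFAULT_TEMPLATES[kind].is_globin:
                n_globin += 1
        if n_globin > 1:
            raise ValueError("at most one globin template per architecture")


#: Default grammars realizing the fungal globin architectures.  The
#: three-domain flavohemoglobin totals 396 residues uninterrupted.
DEFAULT_GRAMMARS: Mapping[str, ArchitectureSpec] = {
    "FHb": ArchitectureSpec(("GLB3F", "CQX2", "CQX3")),
    # unknown N-terminal fused to a flavohemoglobin missing cqx3
    "FHb_incomplete": ArchitectureSpec((("EXT", 60), "GLB3F", "CQX2")),
    "Fgb": ArchitectureSpec(((("EXT", 10)), "GLB3F", ("EXT", 15))),
    "Sgb": ArchitectureSpec((("EXT", 20), "GLB3S", ("EXT", 30))),
    "SensorChimera": ArchitectureSpec((("EXT", 10), "GLB3S", ("EXT", 120))),
    "T1": ArchitectureSpec(("GLB2",)),
    "T1Chimera": ArchitectureSpec(
        (("EXT", 30), "LRR", ("EXT", 20), "GLB2", ("EXT", 30))
    ),
    # flavohemoglobin with a signal-peptide-led N-terminal extension
    "FHb_signal": ArchitectureSpec(("SIG", ("EXT", 10), "GLB3F", "CQX2", "CQX3")),
}


@dataclass
class MutatedDomain:
    """A mutated copy of a template plus its edit script.

    ``aligned[i]`` is the residue carried by template position ``i+1``
    (``None`` if deleted); ``insertions[k]`` is the string inserted after
    template position ``k`` (``0`` = before the first residue).
    """

    template_name: str
    sequence: str
    annotations: Dict[str, int]
    aligned: List[Optional[str]]
    insertions: Dict[int, str]


def _remap_annotations(
    template: DomainTemplate,
    aligned: List[Optional[str]],
    insertions: Dict[int, str],
) -> Dict[str, int]:
    L = len(template.sequence)
    kept = np.cumsum([r is not None for r in aligned])
    ins_before = np.zeros(L + 1, dtype=int)
    for k, s in insertions.items():
        ins_before[k] += len(s)
    ins_cum = np.cumsum(ins_before)  # ins_cum[p] = inserted residues at slots <= p
    out = {}
    for label, pos in template.annotations.items():
        if aligned[pos - 1] is None:  # pragma: no cover - labels are protected
            continue
        out[label] = int(kept[pos - 1] + ins_cum[pos - 1])
    return out


def _realize(aligned: List[Optional[str]], insertions: Dict[int, str]) -> str:
    parts = [insertions.get(0, "")]
    for i, r in enumerate(aligned, start=1):
        if r is not None:
            parts.append(r)
        parts.append(insertions.get(i, ""))
    return "".join(parts)


def mutate_template(
    template: DomainTemplate,
    model: MutationModel,
    rng: Optional[np.random.Generator] = None,
) -> MutatedDomain:
    """Mutate a template to the model's target identity.

    Substitutions are drawn uniformly from the 19 non-identical residues
    at ``round((1 - target_identity) * L)`` distinct positions; annotated
    labels are exempt when ``conserve_checklist`` is set.  Indels (length
    1-3) never fall within 5 residues of an annotated label, so the
    returned annotation map is always complete.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    seq = list(template.sequence)
    L = len(seq)
    ann_pos0 = {idx - 1 for idx in template.annotations.values()}
    protected = ann_pos0 if model.conserve_checklist else set()

    n_sub = round((1.0 - model.target_identity) * L)
    candidates = np.array(sorted(set(range(L)) - protected), dtype=int)
    n_sub = min(n_sub, len(candidates))
    if n_sub > 0:
        for i in rng.choice(candidates, size=n_sub, replace=False):
            current = seq[i]
            choices = [a for a in _AA if a != current]
            seq[i] = str(rng.choice(choices))

    aligned: List[Optional[str]] = list(seq)
    insertions: Dict[int, str] = {}
    near_label = {
        p for a in ann_pos0 for p in range(a - _INDEL_EXCLUSION, a + _INDEL_EXCLUSION + 1)
    }
    n_indels = int(rng.poisson(model.indel_rate * L / 100.0)) if model.indel_rate > 0 else 0
    for _ in range(n_indels):
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion after slot k
            slots = [k for k in range(L + 1) if k not in near_label and (k - 1) not in near_label]
            if not slots:
                continue
            k = int(rng.choice(slots))
            insertions[k] = insertions.get(k, "") + "".join(rng.choice(_AA, size=length))
        else:  # deletion of a clean window
            starts = [
                s for s in range(L - length + 1)
                if all(p not in near_label and aligned[p] is not None
                       for p in range(s, s + length))
            ]
            if not starts:
                continue
            s = int(rng.choice(starts))
            for p in range(s, s + length):
                aligned[p] = None

    annotations = _remap_annotations(template, aligned, insertions)
    return MutatedDomain(
        template_name=template.name,
        sequence=_realize(aligned, insertions),
        annotations=annotations,
        aligned=aligned,
        insertions=insertions,
    )


def identity_to_template(template: DomainTemplate, mutated: MutatedDomain) -> float:
    """Fraction of template positions carrying an identical residue."""
    matches = sum(
        1 for t, r in zip(template.sequence, mutated.aligned) if r == t
    )
    return matches / len(template.sequence)


@dataclass
class GroundTruthRow:
    """Planted truth for one synthetic protein."""

    protein_id: str
    true_class: str
    spans: List[Tuple[str, int, int]]  # (kind, start, end), 1-based inclusive
    globin_coords: Dict[str, int]  # label -> 1-based index in the protein
    species: str
    taxonomy: Tuple[str, str, str]  # (phylum, subphylum, class)

    def __post_init__(self) -> None:
        last_end = 0
        for kind, start, end in self.spans:
            if start <= last_end or end < start:
                raise ValueError(f"{self.protein_id}: bad span ({kind},{start},{end})")
            last_end = end


def _random_extension(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_EXT_POOL, size=length))


_GLOBIN_SCAN_KINDS = arch.GLOBIN_KINDS


def build_protein(
    spec: ArchitectureSpec,
    model: MutationModel,
    rng: Optional[np.random.Generator] = None,
    protein_id: str = "prot1",
    species: str = "synthetic_sp",
    taxonomy: Tuple[str, str, str] = ("", "", ""),
) -> Tuple[Tuple[str, str], GroundTruthRow, Dict[str, MutatedDomain]]:
    """Realize one protein from a grammar.

    Returns ``((protein_id, sequence), ground_truth, mutated_domains)``
    where ``mutated_domains`` maps template names to their edit scripts
    (used for true-alignment assembly).  The true class is derived from
    the realized segments by the same rule table the architecture
    classifier applies, so classifier recovery is well-defined.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    parts: List[str] = []
    spans: List[Tuple[str, int, int]] = []
    globin_coords: Dict[str, int] = {}
    mutated_domains: Dict[str, MutatedDomain] = {}
    ideal_hits: List[arch.DomainHit] = []
    family: Optional[str] = None
    offset = 0
    for seg in spec.grammar:
        kind = seg[0] if isinstance(seg, tuple) else seg
        if kind == "EXT":
            segment = _random_extension(int(seg[1]), rng)
        elif kind == "SIG":
            segment = get_template("SIG").sequence
        else:
            template = get_template(kind)
            md = mutate_template(template, model, rng=rng)
            segment = md.sequence
            mutated_domains[template.name] = md
            if template.is_globin:
                family = template.family_tag
                globin_coords = {l: offset + i for l, i in md.annotations.items()}
            ideal_hits.append(
                arch.DomainHit(template.name, offset + 1, offset + len(segment), float("inf"))
            )
        start, end = offset + 1, offset + len(segment)
        spans.append((kind, start, end))
        parts.append(segment)
        offset = end
    sequence = "".join(parts)
    call = arch.classify_architecture(ideal_hits, family, len(sequence), sequence=sequence)
    truth = GroundTruthRow(
        protein_id=protein_id,
        true_class=call.label,
        spans=spans,
        globin_coords=globin_coords,
        species=species,
        taxonomy=taxonomy,
    )
    return (protein_id, sequence), truth, mutated_domains


@dataclass(frozen=True)
class TaxonProfile:
    """Per-taxon presence probabilities for each architecture class."""

    name: str
    taxonomy: Tuple[str, str, str]
    presence: Mapping[str, float]  # class label -> probability

    def __post_init__(self) -> None:
        for label, p in self.presence.items():
            if label not in DEFAULT_GRAMMARS:
                raise KeyError(f"no grammar for class {label!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability {p} outside [0,1]")


@dataclass
class SyntheticProteome:
    """In-memory result of :func:`build_proteome`, writable to disk."""

    records: List[Tuple[str, str]]  # (protein_id, sequence)
    truth: List[GroundTruthRow]
    true_msas: Dict[str, Tuple[List[str], List[str]]]  # class -> (ids, rows)
    genomes: List[Tuple[str, Tuple[str, str, str]]]  # (species, taxonomy)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append({
                "protein_id": t.protein_id,
                "true_class": t.true_class,
                "spans": ";".join(f"{k}:{s}-{e}" for k, s, e in t.spans),
                "globin_coords": ";".join(
                    f"{l}:{i}" for l, i in sorted(t.globin_coords.items())
                ),
                "species": t.species,
                "phylum": t.taxonomy[0],
                "subphylum": t.taxonomy[1],
                "class": t.taxonomy[2],
            })
        return pd.DataFrame(rows)

    def taxonomy_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "phylum": tax[0], "subphylum": tax[1], "class": tax[2]}
            for sp, tax in self.genomes
        ]
        return pd.DataFrame(rows)

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        """Write FASTA (60-column wrap), ground truth and true MSAs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        fasta = outdir / "proteome.fasta"
        with fasta.open("w") as fh:
            for pid, seq in self.records:
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        paths["fasta"] = fasta
        truth_path = outdir / "ground_truth.tsv"
        self.truth_frame().to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        tax_path = outdir / "taxonomy.tsv"
        self.taxonomy_frame().to_csv(tax_path, sep="\t", index=False)
        paths["taxonomy"] = tax_path
        for label, (ids, rows) in sorted(self.true_msas.items()):
            p = outdir / f"true_msa_{label}.fasta"
            with p.open("w") as fh:
                for i, r in zip(ids, rows):
                    fh.write(f">{i}\n")
                    for k in range(0, len(r), 60):
                        fh.write(r[k:k + 60] + "\n")
            paths[f"msa_{label}"] = p
        return paths


def _merge_true_alignment(
    template: DomainTemplate,
    entries: Sequence[Tuple[str, MutatedDomain]],
) -> Tuple[List[str], List[str]]:
    """Assemble a true MSA from edit scripts against a common template."""
    L = len(template.sequence)
    width = {k: 0 for k in range(L + 1)}
    for _, md in entries:
        for k, s in md.insertions.items():
            width[k] = max(width[k], len(s))
    ids, rows = [], []
    for pid, md in entries:
        parts = [md.insertions.get(0, "").ljust(width[0], "-")]
        for p in range(1, L + 1):
            parts.append(md.aligned[p - 1] or "-")
            parts.append(md.insertions.get(p, "").ljust(width[p], "-"))
        ids.append(pid)
        rows.append("".join(parts))
    return ids, rows


def build_proteome(
    taxon_profile: Union[TaxonProfile, Sequence[TaxonProfile]],
    n_genomes: int,
    seed: int = 0,
    identity_range: Tuple[float, float] = (0.6, 0.8),
    indel_rate: float = 1.0,
) -> SyntheticProteome:
    """Generate ``n_genomes`` genomes with planted globin repertoires.

    Each genome is drawn from a taxon profile (round-robin when several
    are given): each architecture class is present with its configured
    probability, realized from its default grammar at an identity drawn
    uniformly from ``identity_range``.  Deterministic for a fixed seed.
    True per-class alignments of the globin-carrying proteins are
    assembled from the edit scripts (no aligner is run).
    """
    if n_genomes < 1:
        raise ValueError(f"n_genomes must be >= 1, got {n_genomes}")
    profiles = [taxon_profile] if isinstance(taxon_profile, TaxonProfile) else list(taxon_profile)
    rng = np.random.default_rng(seed)
    records: List[Tuple[str, str]] = []
    truth: List[GroundTruthRow] = []
    genomes: List[Tuple[str, Tuple[str, str, str]]] = []
    per_class: Dict[str, List[Tuple[str, MutatedDomain]]] = {}
    for g in range(n_genomes):
        profile = profiles[g % len(profiles)]
        species = f"{profile.name}_g{g + 1:03d}"
        genomes.append((species, profile.taxonomy))
        for label in sorted(profile.presence):
            if rng.random() >= profile.presence[label]:
                continue
            identity = float(rng.uniform(*identity_range))
            model = MutationModel(
                target_identity=identity, indel_rate=indel_rate, seed=0
            )
            pid = f"{species}|{label}"
            record, row, mutated = build_protein(
                DEFAULT_GRAMMARS[label], model, rng=rng,
                protein_id=pid, species=species, taxonomy=profile.taxonomy,
            )
            records.append(record)
            truth.append(row)
            for name, md in mutated.items():
                if DEFAULT_TEMPLATES[name].is_globin:
                    per_class.setdefault(row.true_class, []).append((pid, md))
    true_msas = {}
    for label, entries in per_class.items():
        template = get_template(entries[0][1].template_name)
        true_msas[label] = _merge_true_alignment(template, entries)
    return SyntheticProteome(records, truth, true_msas, genomes)


def evolve_sequence(
    sequence: str,
    identity: float,
    rng: np.random.Generator,
) -> str:
    """Substitute ``round((1 - identity) * L)`` distinct positions.

    Substitution-only divergence (no indels), so sets of sequences
    evolved from common ancestors stay trivially aligned column-for-
    column - the substrate for clean synthetic phylogenies.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0,1], got {identity}")
    seq = list(sequence)
    L = len(seq)
    n_sub = round((1.0 - identity) * L)
    for i in rng.choice(L, size=n_sub, replace=False):
        choices = [a for a in _AA if a != seq[i]]
        seq[i] = str(rng.choice(choices))
    return "".join(seq)


def two_clade_alignment(
    n_per_clade: int = 5,
    within_identity: float = 0.9,
    between_identity: float = 0.4,
    seed: int = 0,
    ancestor: Optional[str] = None,
) -> Tuple[List[str], List[str], "object"]:
    """Two well-separated clades evolved from divergent ancestors.

    Clade A descends from the 3/3 globin template (or ``ancestor``),
    clade B from a copy diverged to ``between_identity``; each leaf is
    evolved independently to ``within_identity`` of its clade ancestor.
    Returns ``(ids, rows, generating_tree)`` where the generating tree
    is the true two-star topology (a :class:`skbio.TreeNode`) whose only
    non-trivial bipartition is the central split.
    """
    from skbio import TreeNode  # local import: phylo stays optional here

    rng = np.random.default_rng(seed)
    anc_a = ancestor if ancestor is not None else get_template("GLB3F").sequence
    anc_b = evolve_sequence(anc_a, between_identity, rng)
    ids: List[str] = []
    rows: List[str] = []
    for tag, anc in (("A", anc_a), ("B", anc_b)):
        for i in range(n_per_clade):
            ids.append(f"{tag}{i + 1}")
            rows.append(evolve_sequence(anc, within_identity, rng))
    newick = "(({}),({}));".format(
        ",".join(ids[:n_per_clade]), ",".join(ids[n_per_clade:])
    )
    import io

    tree = TreeNode.read(io.StringIO(newick), format="newick")
    return ids, rows, tree


# --- census fixture ----------------------------------------------------

@dataclass(frozen=True)
class CensusBlock:
    """One taxon block of the census configuration.

    ``runs`` lists ``(count, payload)`` pairs for the globin-carrying
    genomes; the remaining genomes of the block carry no globins.
    """

    phylum: str
    subphylum: str
    klass: str
    n_genomes: int
    runs: Tuple[Tuple[int, Mapping[str, int]], ...] = ()

    def __post_init__(self) -> None:
        n_with = sum(c for c, _ in self.runs)
        if n_with > self.n_genomes:
            raise ValueError(
                f"{self.phylum}/{self.klass}: {n_with} globin-carrying genomes "
                f"exceed taxon total {self.n_genomes}"
            )
        for _, payload in self.runs:
            for label, count in payload.items():
                if label not in ARCH_LABELS:
                    raise ValueError(f"unknown architecture label {label!r}")
                if count < 0:
                    raise ValueError(f"negative count for {label}")


#: Packaged default census configuration.  Its totals reproduce the
#: headline counts of the reference fungal census: 165 genomes, 136 with
#: globins, 117 Ascomycota (110 with globins, >90%), 33 Basidiomycota,
#: 21 of 29 Saccharomycotina genomes with incomplete FHbs, and exactly 2
#: genomes carrying T1 globins.
DEFAULT_CENSUS_CONFIG: Tuple[CensusBlock, ...] = (
    CensusBlock("Ascomycota", "Saccharomycotina", "Saccharomycetes", 29,
                ((21, {"FHb": 2, "FHb_incomplete": 1}), (7, {"FHb": 1}))),
    CensusBlock("Ascomycota", "Pezizomycotina", "Sordariomycetes", 25,
                ((23, {"FHb": 2, "Sgb": 1}),)),
    CensusBlock("Ascomycota", "Pezizomycotina", "Eurotiomycetes", 30,
                ((22, {"FHb": 1, "Sgb": 1}), (8, {"Sgb": 2}))),
    CensusBlock("Ascomycota", "Pezizomycotina", "Dothideomycetes", 15,
                ((14, {"FHb": 1, "Sgb": 1}),)),
    CensusBlock("Ascomycota", "Pezizomycotina", "Leotiomycetes", 5,
                ((5, {"FHb": 1, "Sgb": 1}),)),
    CensusBlock("Ascomycota", "Pezizomycotina", "Pezizomycetes", 2,
                ((2, {"Sgb": 1}),)),
    CensusBlock("Ascomycota", "Pezizomycotina", "Xylonomycetes", 5,
                ((5, {"FHb": 1}),)),
    CensusBlock("Ascomycota", "Taphrinomycotina", "Schizosaccharomycetes", 3,
                ((3, {"FHb": 1}),)),
    CensusBlock("Ascomycota", "Taphrinomycotina", "Pneumocystidomycetes", 3, ()),
    CensusBlock("Basidiomycota", "Agaricomycotina", "Agaricomycetes", 20,
                ((15, {"FHb": 1, "Sgb": 1}),)),
    CensusBlock("Basidiomycota", "Pucciniomycotina", "Pucciniomycetes", 6,
                ((1, {"Sgb": 1}),)),
    CensusBlock("Basidiomycota", "Ustilaginomycotina", "Ustilaginomycetes", 7,
                ((4, {"FHb": 1}),)),
    CensusBlock("Microsporidia", "", "", 7, ()),
    CensusBlock("Glomeromycota", "", "", 1, ()),
    CensusBlock("Fungi incertae sedis", "Mucoromycotina", "Mucorales", 3,
                ((3, {"Fgb": 2}),)),
    CensusBlock("Blastocladiomycota", "", "Blastocladiomycetes", 1,
                ((1, {"T1Chimera": 1, "Sgb": 1}),)),
    CensusBlock("Chytridiomycota", "", "Chytridiomycetes", 3,
                ((1, {"T1": 1}), (1, {"Sgb": 1}))),
)


def build_census_fixture(
    config: Sequence[CensusBlock] = DEFAULT_CENSUS_CONFIG,
) -> pd.DataFrame:
    """Expand a census configuration into a per-genome census table.

    One row per genome with taxonomy columns, per-label globin counts
    and a genome_complete flag (alternating, emulating that about half
    of the surveyed assemblies are incomplete).
    """
    rows = []
    label_cols = [l for l in ARCH_LABELS if l != "NonGlobin"]
    i_global = 0
    for block in config:
        payloads: List[Mapping[str, int]] = []
        for count, payload in block.runs:
            payloads.extend([payload] * count)
        payloads.extend([{}] * (block.n_genomes - len(payloads)))
        slug = (block.klass or block.phylum).lower().replace(" ", "_")
        for j, payload in enumerate(payloads):
            row = {
                "species": f"{slug}_sp{j + 1:03d}",
                "phylum": block.phylum,
                "subphylum": block.subphylum,
                "class": block.klass,
                "genome_complete": i_global % 2 == 0,
            }
            for label in label_cols:
                row[label] = int(payload.get(label, 0))
            rows.append(row)
            i_global += 1
    columns = ["species", "phylum", "subphylum", "class"] + label_cols + ["genome_complete"]
    return pd.DataFrame(rows, columns=columns)


def digest(data: Union[str, bytes]) -> str:
    """SHA-256 hex digest of a string or bytes payload."""
    if isinstance(data, str):
        data = data.encode()
    return hashlib.sha256(data).hexdigest()
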