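"""Myoglobin-fold validation of candidate globins.

A candidate protein is accepted as a globin when (i) its best
template-anchored alignment scores more than ``z_threshold`` standard
deviations above the mean score of composition-preserving shuffles of
the query, (ii) the residue transferred to the proximal F8 coordinate is
histidine, and (iii) the residues transferred to the 36-position fold
checklist (33 intra-helical positions, the CD1 and FG4 corners, and F8)
are predominantly hydrophobic.

Anchoring uses a deterministic pairwise alignment (BLOSUM62, affine
gaps 11/1, free end gaps so a globin domain embedded in a chimera is
found without penalty) in place of profile methods.  The family of a
query (F, S or T) is the family of the best accepted template.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .templates import (
    DomainTemplate,
    GLOBIN_TEMPLATES,
    HYDROPHOBIC,
    LABEL_ORDER,
    STANDARD_AA,
)

#: Acceptance threshold on the shuffle-null Z score ("number of standard
#: deviations above the mean score obtained by chance").
DEFAULT_Z_THRESHOLD = 6.0
#: Default number of composition-preserving shuffles in the null.
DEFAULT_N_SHUFFLES = 200
#: Minimum fraction of checklist positions that must be hydrophobic.
DEFAULT_MIN_HYDROPHOBIC_FRACTION = 2.0 / 3.0

#: Marker for a checklist label that falls in a gap of the anchoring
#: alignment.  PositionMaps are plain dicts ``label -> 1-based index`` with
#: ``None`` for unaligned labels.
UNALIGNED = None

PositionMap = Dict[str, Optional[int]]


class SequenceAlphabetError(ValueError):
    """Query contains characters outside the amino-acid alphabet."""


class UndefinedZScoreError(ArithmeticError):
    """The shuffle null is degenerate (zero standard deviation)."""


class TrimmingError(ValueError):
    """B10 or H8 is unaligned, so the trimming rule cannot be applied."""


@dataclass(frozen=True)
class MbFoldChecklist:
    """The 36 conserved, solvent-inaccessible positions of the Mb fold.

    33 intra-helical positions across helices A-H, the two inter-helical
    corners CD1 and FG4, and the invariant proximal histidine F8 (which
    is tested for identity, not hydrophobicity).
    """

    intra_helical: Tuple[str, ...] = (
        "A8", "A11", "A12", "A15",
        "B6", "B9", "B10", "B13", "B14",
        "C4",
        "E4", "E7", "E8", "E11", "E12", "E15", "E18", "E19",
        "F1", "F4",
        "G5", "G8", "G11", "G12", "G13", "G15", "G16",
        "H7", "H8", "H11", "H12", "H15", "H19",
    )
    inter_helical: Tuple[str, ...] = ("CD1", "FG4")
    invariant: str = "F8"

    def __post_init__(self) -> None:
        assert self.invariant not in self.hydrophobic_positions

    @property
    def hydrophobic_positions(self) -> Tuple[str, ...]:
        """The positions scored for hydrophobicity (everything but F8)."""
        return self.intra_helical + self.inter_helical

    @property
    def size(self) -> int:
        """Total checklist cardinality including the invariant F8."""
        return len(self.intra_helical) + len(self.inter_helical) + 1

    def restricted_to(self, labels: Iterable[str]) -> "MbFoldChecklist":
        """Checklist restricted to labels a template actually carries.

        Used for the truncated 2/2 fold, whose vestigial A and E helices
        carry no annotations.
        """
        keep = set(labels)
        return MbFoldChecklist(
            intra_helical=tuple(l for l in self.intra_helical if l in keep),
            inter_helical=tuple(l for l in self.inter_helical if l in keep),
        )


FULL_CHECKLIST = MbFoldChecklist()


@dataclass(frozen=True)
class FoldAssessment:
    """Outcome of the Mb-fold test for one query against one template."""

    raw_score: float
    z: Optional[float]
    hydrophobic_fraction: float
    f8_residue: Optional[str]
    family: Optional[str]
    accepted: bool
    template_name: Optional[str] = None


@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # Free end gaps on both sequences (overlap alignment): a domain
    # embedded in a longer chimera anchors without terminal penalties.
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


def _check_alphabet(sequence: str, what: str = "sequence") -> None:
    if not sequence:
        raise SequenceAlphabetError(f"empty {what}")
    bad = set(sequence.upper()) - set(STANDARD_AA) - {"X"}
    if bad:
        raise SequenceAlphabetError(f"{what} contains non-amino-acid characters {sorted(bad)}")


def alignment_score(template_seq: str, query: str) -> float:
    """Deterministic alignment score of a query against a template."""
    return float(_aligner().score(template_seq, query))


def anchor_to_template(query: str, template: DomainTemplate) -> Tuple[PositionMap, float]:
    """Transfer the template's coordinate labels onto a query sequence.

    Returns the position map (label -> 1-based query index, ``None`` for
    labels falling in query gap columns) and the raw alignment score.
    """
    _check_alphabet(query, "query")
    query = query.upper()
    alignment = _aligner().align(template.sequence, query)[0]
    score = float(alignment.score)
    t_blocks, q_blocks = alignment.aligned
    pmap: PositionMap = {}
    for label, t_idx in template.annotations.items():
        t0 = t_idx - 1  # 0-based template position
        mapped = UNALIGNED
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            if ts <= t0 < te:
                mapped = qs + (t0 - ts) + 1  # back to 1-based
                break
        pmap[label] = mapped
    return pmap, score


def fold_zscore(
    query: str,
    template: DomainTemplate,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> float:
    """Standardized score against a composition-preserving shuffle null.

    z = (S - mean(null)) / sd(null), where the null scores come from
    aligning Fisher-Yates shuffles of the query to the template.

    Raises
    ------
    UndefinedZScoreError
        If the null has zero standard deviation (degenerate query, e.g.
        a homopolymer).
    """
    if n_shuffles < 30:
        raise ValueError(f"n_shuffles must be >= 30, got {n_shuffles}")
    _check_alphabet(query, "query")
    query = query.upper()
    s_obs = alignment_score(template.sequence, query)
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(query.encode(), dtype="S1")
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(letters).tobytes().decode()
        null[k] = alignment_score(template.sequence, shuffled)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise UndefinedZScoreError("shuffle null has zero standard deviation")
    return (s_obs - float(null.mean())) / sd


def mbfold_check(
    query: str,
    pmap: PositionMap,
    checklist: MbFoldChecklist = FULL_CHECKLIST,
) -> Tuple[float, Optional[str]]:
    """Hydrophobicity fraction over the checklist, and the F8 residue.

    Unmapped checklist positions count as failures.  Returns
    ``(hydrophobic_fraction, f8_residue)`` where ``f8_residue`` is
    ``None`` if F8 is unaligned.
    """
    query = query.upper()
    positions = checklist.hydrophobic_positions
    n_ok = 0
    for label in positions:
        idx = pmap.get(label)
        if idx is not None and query[idx - 1] in HYDROPHOBIC:
            n_ok += 1
    fraction = n_ok / len(positions) if positions else 0.0
    f8_idx = pmap.get(checklist.invariant)
    f8 = query[f8_idx - 1] if f8_idx is not None else None
    return fraction, f8


def checklist_for(template: DomainTemplate) -> MbFoldChecklist:
    """The checklist restricted to labels the template carries."""
    return FULL_CHECKLIST.restricted_to(template.annotations.keys())


def assess_fold(
    query: str,
    template: DomainTemplate,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_hydrophobic_fraction: float = DEFAULT_MIN_HYDROPHOBIC_FRACTION,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> FoldAssessment:
    """Full Mb-fold assessment of a query against one globin template.

    Acceptance is conjunctive: z above threshold AND His at F8 AND a
    predominantly hydrophobic checklist.
    """
    pmap, score = anchor_to_template(query, template)
    try:
        z: Optional[float] = fold_zscore(query, template, n_shuffles=n_shuffles, seed=seed)
    except UndefinedZScoreError:
        z = None
    fraction, f8 = mbfold_check(query, pmap, checklist_for(template))
    accepted = (
        z is not None
        and z > z_threshold
        and f8 == "H"
        and fraction >= min_hydrophobic_fraction
    )
    return FoldAssessment(
        raw_score=score,
        z=z,
        hydrophobic_fraction=fraction,
        f8_residue=f8,
        family=template.family_tag if accepted else None,
        accepted=accepted,
        template_name=template.name,
    )


def assign_family(
    query: str,
    template_set: Sequence[DomainTemplate] = GLOBIN_TEMPLATES,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_hydrophobic_fraction: float = DEFAULT_MIN_HYDROPHOBIC_FRACTION,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> Tuple[Optional[str], Optional[DomainTemplate], FoldAssessment]:
    """Assign a query to the globin family of its best accepted template.

    Every template is assessed; the family is that of the accepted
    assessment with maximal z.  If no template is accepted, the family
    is ``None`` and the best (rejected) assessment is returned for
    inspection.
    """
    if not template_set:
        raise ValueError("empty template set")
    child_seeds = np.random.SeedSequence(seed).spawn(len(template_set))
    assessments = []
    for template, ss in zip(template_set, child_seeds):
        a = assess_fold(
            query,
            template,
            z_threshold=z_threshold,
            min_hydrophobic_fraction=min_hydrophobic_fraction,
            n_shuffles=n_shuffles,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        assessments.append((template, a))

    def _zkey(item):
        _, a = item
        return a.z if a.z is not None else float("-inf")

    accepted = [item for item in assessments if item[1].accepted]
    if accepted:
        template, best = max(accepted, key=_zkey)
        return template.family_tag, template, best
    _, best = max(assessments, key=_zkey)
    return None, None, best


def trim_domain(query: str, pmap: PositionMap) -> Tuple[int, int]:
    """Trim a globin domain by the B10/H8 rule.

    The domain is taken to start 11 residues before the B10 position and
    to end 15 residues after the H8 position, clamped to the sequence.
    Returns a 1-based inclusive span.

    Raises
    ------
    TrimmingError
        If B10 or H8 is unaligned.
    """
    b10 = pmap.get("B10")
    h8 = pmap.get("H8")
    if b10 is None or h8 is None:
        missing = [l for l in ("B10", "H8") if pmap.get(l) is None]
        raise TrimmingError(f"cannot trim: unaligned anchor position(s) {missing}")
    start = max(1, b10 - 11)
    end = min(len(query), h8 + 15)
    return start, end
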