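"""Domain-architecture classification of globin-carrying proteins.

Fungal globins occur as single domains or in a small set of chimeric
architectures.  This module scans a protein for the non-globin building
blocks (the cqx2 FAD-binding and cqx3 NAD(P)-binding reductase halves,
leucine-rich-repeat blocks, signal peptides) and applies a fixed rule
table to the combination of globin family and domain content:

=================  ====================================================
label              rule (applied in order)
=================  ====================================================
FHb                F-family globin + cqx2 + cqx3
FHb_incomplete     F-family globin + cqx2, no cqx3 (the absence of
                   cqx3 is diagnostic)
Fgb                F-family globin alone
SensorChimera      S-family globin with a C-terminal extension of 100
                   residues or more
Sgb                any other S-family globin (generally < 260 residues;
                   longer ones keep the label but are flagged)
T1Chimera          T-family globin with any other domain hit
T1                 T-family globin alone
NonGlobin          no accepted globin
=================  ====================================================

Normal-length flavohemoglobins (380-420 residues) and >25-residue
N-terminal extensions led by a predicted signal peptide are flagged on
the call rather than given their own class.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .templates import DEFAULT_TEMPLATES, DomainTemplate, HYDROPHOBIC

#: Hit kinds treated as globin domains.
GLOBIN_KINDS = frozenset({"GLB3", "GLB3F", "GLB3S", "GLB2"})

#: LRR 11-mer consensus LxxLxLxxN/CxL, matched tandemly.
LRR_MOTIF = re.compile(r"(?=(L..L.L..[NC].L))")
#: Minimum number of tandem 11-mer repeats for an LRR hit.
LRR_MIN_REPEATS = 3

#: Local-alignment hits must score at least this fraction of the
#: profile's self-score (calibrated so random 400-residue sequences
#: produce <= 5% false positives).
DEFAULT_MIN_SCORE_FRACTION = 0.35


class MultiGlobinError(ValueError):
    """More than one globin domain: reported, not classified."""


class EmptyHitListError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """A located domain: kind, 1-based inclusive span, score."""

    kind: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad span {self.start}..{self.end} for {self.kind}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the architecture rule table.

    sgb_max_length
        Sensor globins are generally shorter than this; longer
        non-chimeric S-globins keep the Sgb label but are flagged.
    chimera_cterm_min
        C-terminal extension (residues) that turns an S-globin into a
        sensor chimera.
    n_term_ext_min
        N-terminal extension beyond which a signal peptide is looked for.
    normal_fhb_range
        Length window of normal flavohemoglobins.
    """

    sgb_max_length: int = 260
    chimera_cterm_min: int = 100
    n_term_ext_min: int = 25
    normal_fhb_range: Tuple[int, int] = (380, 420)


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class ArchitectureCall:
    """Classification of one protein's domain architecture."""

    label: str
    hits: Tuple[DomainHit, ...]
    n_term_ext: int
    c_term_ext: int
    signal_peptide: bool
    length: int
    flags: Tuple[str, ...] = ()


@functools.lru_cache(maxsize=1)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


@functools.lru_cache(maxsize=32)
def _self_score(sequence: str) -> float:
    return float(_local_aligner().score(sequence, sequence))


def _default_profiles() -> Mapping[str, DomainTemplate]:
    return {
        name: DEFAULT_TEMPLATES[name]
        for name in ("GLB3F", "GLB3S", "GLB2", "CQX2", "CQX3")
    }


def _scan_lrr(sequence: str) -> List[DomainHit]:
    """Merge >= LRR_MIN_REPEATS tandem 11-mer motif matches into hits."""
    starts = [m.start() for m in LRR_MOTIF.finditer(sequence)]
    hits: List[DomainHit] = []
    run: List[int] = []
    def _flush(run: List[int]) -> None:
        if len(run) >= LRR_MIN_REPEATS:
            hits.append(DomainHit("LRR", run[0] + 1, run[-1] + 11, float(len(run))))
    for s in starts:
        if run and s - run[-1] == 11:
            run.append(s)
        else:
            _flush(run)
            run = [s]
    _flush(run)
    return hits


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def scan_domains(
    sequence: str,
    profiles: Optional[Mapping[str, DomainTemplate]] = None,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
) -> List[DomainHit]:
    """Locate domain hits in a protein, ordered by position.

    Template profiles are matched by local alignment (BLOSUM62, affine
    11/1) and accepted above ``min_score_fraction`` of the profile's
    self-score; LRR blocks are matched by the tandem 11-mer motif.
    Overlapping hits are resolved greedily by score.
    """
    sequence = sequence.upper()
    if profiles is None:
        profiles = _default_profiles()
    aligner = _local_aligner()
    raw: List[DomainHit] = []
    for name, template in profiles.items():
        score = float(aligner.score(template.sequence, sequence))
        if score < min_score_fraction * _self_score(template.sequence):
            continue
        aln = aligner.align(template.sequence, sequence)[0]
        _, q_blocks = aln.aligned
        raw.append(DomainHit(name, int(q_blocks[0][0]) + 1, int(q_blocks[-1][1]), score))
    raw.extend(_scan_lrr(sequence))
    kept: List[DomainHit] = []
    for hit in sorted(raw, key=lambda h: (-h.score, h.start)):
        if all(_overlap(hit, k) <= 0.5 * min(hit.length, k.length) for k in kept):
            kept.append(hit)
    return sorted(kept, key=lambda h: h.start)


def detect_signal_peptide(sequence: str) -> Tuple[bool, Optional[Tuple[int, int]]]:
    """Heuristic signal-peptide call on the first ~20 residues.

    Requires a basic n-region (at least one K/R within the first five
    residues) followed by a hydrophobic stretch of at least eight
    residues, all within residues 1-20.  Returns ``(flag, span)`` with
    span ``(1, 20)`` when positive.
    """
    sequence = sequence.upper()
    if len(sequence) < 20:
        return False, None
    head = sequence[:20]
    if not any(c in "KR" for c in head[:5]):
        return False, None
    run = best = 0
    for c in head:
        run = run + 1 if c in HYDROPHOBIC else 0
        best = max(best, run)
    if best >= 8:
        return True, (1, 20)
    return False, None


def measure_extensions(hits: Sequence[DomainHit], length: int) -> Tuple[int, int]:
    """Residues before the first hit and after the last hit."""
    if not hits:
        raise EmptyHitListError("cannot measure extensions of an empty hit list")
    ordered = sorted(hits, key=lambda h: h.start)
    return ordered[0].start - 1, length - ordered[-1].end


def classify_architecture(
    hits: Sequence[DomainHit],
    family: Optional[str],
    length: int,
    sequence: Optional[str] = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ArchitectureCall:
    """Apply the architecture rule table to a protein's domain content.

    ``family`` is the globin family from fold validation (``None`` if no
    globin was accepted).  ``sequence`` is only needed for the
    signal-peptide flag on N-terminally extended proteins.

    Raises
    ------
    MultiGlobinError
        If more than one globin hit is present (such proteins are
        reported rather than classified).
    """
    hits = tuple(sorted(hits, key=lambda h: h.start))
    globin_hits = [h for h in hits if h.kind in GLOBIN_KINDS]
    if len(globin_hits) > 1:
        raise MultiGlobinError(f"{len(globin_hits)} globin hits")
    if hits:
        n_term, c_term = measure_extensions(hits, length)
    else:
        n_term, c_term = 0, 0
    kinds = {h.kind for h in hits if h.kind not in GLOBIN_KINDS}
    flags: List[str] = []
    signal = False

    if family is None or not globin_hits:
        label = "NonGlobin"
    elif family == "F":
        if "CQX2" in kinds and "CQX3" in kinds:
            label = "FHb"
            lo, hi = config.normal_fhb_range
            if lo <= length <= hi:
                flags.append("normal-length")
        elif "CQX2" in kinds:
            label = "FHb_incomplete"
        else:
            label = "Fgb"
    elif family == "S":
        if c_term >= config.chimera_cterm_min:
            label = "SensorChimera"
        else:
            label = "Sgb"
            if length >= config.sgb_max_length:
                flags.append("oversized-sgb")
    elif family == "T":
        label = "T1Chimera" if kinds else "T1"
    else:
        raise ValueError(f"unknown globin family {family!r}")

    if n_term > config.n_term_ext_min and sequence is not None:
        signal = detect_signal_peptide(sequence)[0]
        if n_term > 100:
            flags.append("long-n-ext")

    return ArchitectureCall(
        label=label,
        hits=hits,
        n_term_ext=n_term,
        c_term_ext=c_term,
        signal_peptide=signal,
        length=length,
        flags=tuple(flags),
    )
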