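"""Overlap scoring of alternative multiple alignments.

When the same sequences are aligned by several programs, the alignments
can be ranked without a reference: two alignments that place the same
residues in the same columns agree on those residue pairs.  The overlap
score between alignments A and B is

    overlap(A, B) = |P_A ∩ P_B| / ((|P_A| + |P_B|) / 2)

where P_X is the set of aligned residue pairs of alignment X (a
MUMSA-style average-overlap score: symmetric, in [0, 1], and 1 exactly
when the pair sets coincide).  The ensemble winner is the alignment with
the highest mean overlap against all the others.

The module also checks that the proximal F8 histidines of all sequences
share a single alignment column, the manual sanity check applied to
candidate globin alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import AlignIO

GAP_CHARS = ("-", ".")

#: An aligned residue pair: (id_s, residue index i, id_t, residue index j)
#: with id_s < id_t and 1-based ungapped residue indices.
ResiduePair = Tuple[str, int, str, int]


class RaggedAlignmentError(ValueError):
    pass


class SequenceSetMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment: ordered ids and equal-length rows.

    Residues are stored uppercase; ``.`` is accepted as an alternate gap
    character on input and normalized to ``-``.
    """

    ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        norm = tuple(r.upper().replace(".", "-") for r in self.rows)
        object.__setattr__(self, "rows", norm)
        if len({len(r) for r in norm}) > 1:
            raise RaggedAlignmentError("alignment rows have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def from_file(cls, path: Union[str, Path], fmt: Optional[str] = None) -> "MSA":
        """Read an aligned FASTA or Clustal file (format auto-detected)."""
        path = Path(path)
        if fmt is None:
            head = path.read_text()[:64].lstrip()
            fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls(tuple(r.id for r in aln), tuple(str(r.seq) for r in aln))

    def to_fasta(self) -> str:
        out = StringIO()
        for i, r in zip(self.ids, self.rows):
            out.write(f">{i}\n")
            for k in range(0, len(r), 60):
                out.write(r[k:k + 60] + "\n")
        return out.getvalue()


def residue_pairs(msa: MSA) -> FrozenSet[ResiduePair]:
    """The set of residue pairs sharing a column, keyed by sequence id.

    Gap positions contribute no pairs.  Pairs are canonicalized with
    ``id_s < id_t`` so alignments listing the sequences in different
    orders are comparable.
    """
    counters = {i: 0 for i in msa.ids}
    pairs: set = set()
    n = len(msa.ids)
    for col in range(msa.n_columns):
        present: List[Tuple[str, int]] = []
        for sid, row in zip(msa.ids, msa.rows):
            c = row[col]
            if c not in GAP_CHARS:
                counters[sid] += 1
                present.append((sid, counters[sid]))
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                (s, i), (t, j) = present[a], present[b]
                if s > t:
                    s, i, t, j = t, j, s, i
                pairs.add((s, i, t, j))
    return frozenset(pairs)


def pairwise_overlap(a: MSA, b: MSA) -> float:
    """Fraction of aligned residue pairs shared by two alignments."""
    if set(a.ids) != set(b.ids):
        raise SequenceSetMismatchError("alignments cover different sequence sets")
    for sid in a.ids:
        # ungapped lengths must agree for residue indices to be comparable;
        # residue content is not compared so that column-permuted variants
        # of an alignment can still be scored against it
        if len(a.ungapped(sid)) != len(b.ungapped(sid)):
            raise SequenceSetMismatchError(f"sequence {sid!r} differs in length")
    pa, pb = residue_pairs(a), residue_pairs(b)
    denom = (len(pa) + len(pb)) / 2.0
    if denom == 0:
        return 1.0
    return len(pa & pb) / denom


@dataclass(frozen=True)
class OverlapScores:
    """Pairwise overlap matrix and per-alignment mean scores."""

    names: Tuple[str, ...]
    matrix: np.ndarray  # symmetric, unit diagonal
    means: Tuple[float, ...]  # mean overlap against the other alignments


def score_ensemble(
    ensemble: Sequence[MSA],
    names: Optional[Sequence[str]] = None,
) -> OverlapScores:
    """All pairwise overlaps and per-alignment means for an ensemble."""
    k = len(ensemble)
    if k < 2:
        raise ValueError("need at least two alignments")
    if names is None:
        names = tuple(f"aln{i + 1}" for i in range(k))
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = pairwise_overlap(ensemble[i], ensemble[j])
    means = tuple(float((m[i].sum() - 1.0) / (k - 1)) for i in range(k))
    return OverlapScores(tuple(names), m, means)


def select_best(
    ensemble: Sequence[MSA],
    names: Optional[Sequence[str]] = None,
) -> Tuple[MSA, OverlapScores]:
    """Pick the alignment with the highest mean overlap (ties: first)."""
    scores = score_ensemble(ensemble, names)
    winner = int(np.argmax(scores.means))  # argmax takes the first maximum
    return ensemble[winner], scores


def check_f8_column(msa: MSA, f8_positions: Dict[str, int]) -> Dict[str, bool]:
    """Check conservation of the proximal F8 histidine across an alignment.

    ``f8_positions`` maps each sequence id to the 1-based ungapped index
    of its F8 residue.  A sequence passes iff its F8 residue is His and
    sits in the modal F8 column of the alignment.
    """
    missing = set(msa.ids) - set(f8_positions)
    if missing:
        raise KeyError(f"no F8 position for {sorted(missing)}")
    columns: Dict[str, int] = {}
    residues: Dict[str, str] = {}
    for sid in msa.ids:
        row = msa.row(sid)
        target = f8_positions[sid]
        count = 0
        for col, c in enumerate(row):
            if c not in GAP_CHARS:
                count += 1
                if count == target:
                    columns[sid] = col
                    residues[sid] = c
                    break
        else:
            raise KeyError(f"F8 index {target} beyond sequence {sid!r}")
    modal = max(set(columns.values()), key=lambda c: (list(columns.values()).count(c), -c))
    return {
        sid: residues[sid] == "H" and columns[sid] == modal
        for sid in msa.ids
    }
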