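"""Poisson-corrected neighbor-joining phylogenies with bootstrap.

Pairwise distances are observed proportions of differing sites with
*pairwise deletion* (columns with a gap or X in either member of the
pair are excluded for that pair only), corrected for superimposed
substitutions by the Poisson formula d = -ln(1 - p).  Trees are built by
the Saitou-Nei neighbor-joining algorithm with deterministic tie
breaking (lowest index pair), negative branch lengths clamped to zero by
default, and branch support estimated by bootstrap resampling of
alignment columns.

Trees are :class:`skbio.TreeNode` objects; Newick serialization stores
bootstrap supports as internal-node labels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
from skbio import TreeNode

from .msa import GAP_CHARS, MSA

#: Characters excluded by pairwise deletion (gaps and missing data).
MISSING = set(GAP_CHARS) | {"X"}

#: Bootstrap supports at or below this value are conventionally
#: suppressed in rendered trees.
SUPPORT_DISPLAY_CUTOFF = 0.5


class SaturatedDistanceError(ValueError):
    """p >= 1: the Poisson correction is undefined (saturated pair)."""


class NoUsableSitesError(ValueError):
    pass


def p_distance(a: str, b: str) -> Tuple[float, int]:
    """Observed proportion of differences under pairwise deletion.

    Sites where either row carries a gap or X are excluded for this pair
    only.  Returns ``(p, usable_sites)``.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    a, b = a.upper(), b.upper()
    usable = mismatch = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        usable += 1
        if x != y:
            mismatch += 1
    if usable == 0:
        raise NoUsableSitesError("no usable sites for this pair")
    return mismatch / usable, usable


def poisson_correct(p: float) -> float:
    """Poisson distance d = -ln(1 - p) for 0 <= p < 1."""
    if not 0.0 <= p:
        raise ValueError(f"p must be >= 0, got {p}")
    if p >= 1.0:
        raise SaturatedDistanceError(f"p = {p}: distance saturated")
    return -float(np.log1p(-p))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix with per-pair usable-site counts."""

    ids: Tuple[str, ...]
    distances: np.ndarray
    usable_sites: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(d < 0):
            raise ValueError("negative distances")

    @property
    def size(self) -> int:
        return len(self.ids)


def distance_matrix(msa: MSA, correction: str = "poisson") -> DistanceMatrix:
    """All pairwise distances of an alignment (pairwise deletion).

    ``correction`` is ``"poisson"`` (default) or ``"p"`` for the raw
    proportion of differences.
    """
    n = len(msa.ids)
    d = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            p, u = p_distance(msa.rows[i], msa.rows[j])
            d[i, j] = d[j, i] = poisson_correct(p) if correction == "poisson" else p
            usable[i, j] = usable[j, i] = u
    return DistanceMatrix(tuple(msa.ids), d, usable)


def nj(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the lowest
    (row, column) index pair in the current matrix order.  Negative
    branch lengths are clamped to zero unless ``clamp_negative`` is
    False.  Returns an unrooted tree represented with a trifurcating
    root (for 3+ taxa).
    """
    n = dm.size
    if n < 3:
        raise ValueError(f"need >= 3 taxa, got {n}")
    if not np.all(np.isfinite(dm.distances)):
        raise SaturatedDistanceError("distance matrix contains non-finite entries")
    d = dm.distances.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name=t) for t in dm.ids]

    def _blen(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair among the minima
        best = np.min(q)
        ii, jj = min(zip(*np.where(np.isclose(q, best))))
        if ii > jj:
            ii, jj = jj, ii
        dij = d[ii, jj]
        li = dij / 2.0 + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        u = TreeNode(children=[nodes[ii], nodes[jj]])
        nodes[ii].length = _blen(li)
        nodes[jj].length = _blen(lj)
        du = 0.5 * (d[ii, :] + d[jj, :] - dij)
        keep = [k for k in range(m) if k not in (ii, jj)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [u]

    # connect the last three nodes to a trifurcating root
    (d01, d02, d12) = d[0, 1], d[0, 2], d[1, 2]
    lengths = (
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    )
    root = TreeNode(children=list(nodes))
    for node, length in zip(nodes, lengths):
        node.length = _blen(length)
    return root


Bipartition = FrozenSet[str]


def bipartitions(tree: TreeNode) -> FrozenSet[Bipartition]:
    """Non-trivial bipartitions (splits) induced by internal edges.

    Each split is canonicalized as the side not containing the
    lexicographically smallest leaf; splits separating fewer than two
    leaves on either side are excluded.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = leaves - side
        splits.add(side)
    return frozenset(splits)


def shared_bipartition_fraction(t1: TreeNode, t2: TreeNode) -> float:
    """Fraction of t1's non-trivial bipartitions also present in t2."""
    l1 = frozenset(t.name for t in t1.tips())
    l2 = frozenset(t.name for t in t2.tips())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    if not b1:
        return 1.0 if not b2 else 0.0
    return len(b1 & b2) / len(b1)


def _resample_columns(msa: MSA, rng: np.random.Generator) -> MSA:
    cols = rng.integers(0, msa.n_columns, size=msa.n_columns)
    rows = tuple("".join(row[c] for c in cols) for row in msa.rows)
    return MSA(msa.ids, rows)


def bootstrap(
    msa: MSA,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "poisson",
) -> Tuple[TreeNode, Dict[Bipartition, float]]:
    """Bootstrap support for the NJ tree of an alignment.

    Columns are resampled with replacement ``n_reps`` times, the NJ tree
    is rebuilt for each replicate, and the support of each bipartition
    of the original tree is the fraction of replicate trees containing
    it.  Supports are attached to the corresponding internal nodes of
    the returned tree (as ``.bootstrap_support`` and as the node name).  Deterministic per seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if msa.n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj(distance_matrix(msa, correction))
    target = bipartitions(tree)
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = _resample_columns(msa, rng)
        try:
            rep_tree = nj(distance_matrix(rep, correction))
        except (SaturatedDistanceError, NoUsableSitesError):
            continue  # replicate dropped; counts stay conservative
        rep_bips = bipartitions(rep_tree)
        for b in target:
            if b in rep_bips:
                counts[b] += 1
    supports = {b: c / n_reps for b, c in counts.items()}
    _attach_supports(tree, supports)
    return tree, supports


def _attach_supports(tree: TreeNode, supports: Dict[Bipartition, float]) -> None:
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if side in supports:
            node.bootstrap_support = supports[side]
            node.name = f"{supports[side]:.3f}"


# --- serialization -----------------------------------------------------

def write_newick(tree: TreeNode, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a tree to Newick (supports as internal-node labels)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source: Union[str, Path]) -> TreeNode:
    """Parse Newick text or a Newick file; raises on malformed input."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and "(" not in source and Path(str(source)).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise ValueError("malformed Newick: unbalanced parentheses")
    return TreeNode.read(io.StringIO(text), format="newick")


def write_phylip(dm: DistanceMatrix, path: Optional[Union[str, Path]] = None) -> str:
    """PHYLIP square distance-matrix export."""
    lines = [f"{dm.size}"]
    for i, name in enumerate(dm.ids):
        row = " ".join(f"{x:.6f}" for x in dm.distances[i])
        lines.append(f"{name:<10s} {row}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
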