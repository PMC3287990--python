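"""Poisson-corrected NJ trees, bootstrap and bipartition comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fungiglobin import phylo
from fungiglobin.msa import MSA
from fungiglobin.phylo import (
    DistanceMatrix,
    NoUsableSitesError,
    SaturatedDistanceError,
    bipartitions,
    bootstrap,
    distance_matrix,
    nj,
    p_distance,
    poisson_correct,
    read_newick,
    shared_bipartition_fraction,
    write_newick,
    write_phylip,
)
from fungiglobin.simulate import two_clade_alignment


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("MKVA", "MKVA") == (0.0, 4)

    def test_hand_count_with_gap(self):
        assert p_distance("AC-A", "AG-A") == (1 / 3, 3)

    def test_pairwise_deletion_is_per_pair(self):
        rows = ("ACDA", "AC-A", "AGDA")
        # the gap only affects pairs involving the second row
        assert p_distance(rows[0], rows[1])[1] == 3
        assert p_distance(rows[0], rows[2])[1] == 4

    def test_x_treated_as_missing(self):
        assert p_distance("AXCA", "AGCA")[1] == 3

    def test_symmetric(self):
        a, b = "MKVLIAGH", "MRVLDAGH"
        assert p_distance(a, b) == p_distance(b, a)

    def test_all_missing_rejected(self):
        with pytest.raises(NoUsableSitesError):
            p_distance("--X", "AC-")


class TestPoissonCorrection:
    def test_closed_forms(self):
        assert poisson_correct(0.0) == 0.0
        assert poisson_correct(1 - math.exp(-1)) == pytest.approx(1.0)
        assert poisson_correct(0.5) == pytest.approx(math.log(2))

    def test_saturated_flagged(self):
        with pytest.raises(SaturatedDistanceError):
            poisson_correct(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_correction_is_increasing_and_dominates_p(self, p):
        d = poisson_correct(p)
        assert d >= p
        assert poisson_correct(min(p + 1e-6, 0.99)) >= d


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_additive_matrix_recovered_exactly(self):
        # tree ((a:2,b:3):1,c:4,d:5) -> path-length matrix
        D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        tree = nj(DistanceMatrix(("a", "b", "c", "d"), D))
        tips = {t.name: t for t in tree.tips()}
        for (i, a), (j, b) in itertools.combinations(enumerate("abcd"), 2):
            assert tips[a].distance(tips[b]) == pytest.approx(D[i, j], abs=1e-12)

    def test_identical_rows_join_first_with_zero_lengths(self):
        D = np.array([
            [0, 0, 4, 4, 5],
            [0, 0, 4, 4, 5],
            [4, 4, 0, 2, 3],
            [4, 4, 2, 0, 3],
            [5, 5, 3, 3, 0],
        ], float)
        tree = nj(DistanceMatrix(tuple("abcde"), D))
        a = next(t for t in tree.tips() if t.name == "a")
        b = next(t for t in tree.tips() if t.name == "b")
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0

    def test_agrees_with_skbio_on_generic_matrices(self, rng):
        """Topologies match scikit-bio's independent NJ implementation."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(3):
            pts = rng.normal(size=(8, 4))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            ids = tuple(f"t{i}" for i in range(8))
            ours = nj(DistanceMatrix(ids, D))
            theirs = skbio_nj(SkbioDM(D, ids))
            assert bipartitions(ours) == bipartitions(theirs)

    def test_requires_three_taxa_and_finite_distances(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(("a", "b"), np.zeros((2, 2))))
        D = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(SaturatedDistanceError):
            nj(DistanceMatrix(("a", "b", "c"), D))


class TestBootstrap:
    def test_central_split_of_two_clades_is_strongly_supported(self):
        ids, rows, gen = two_clade_alignment(n_per_clade=5, seed=1)
        msa = MSA(tuple(ids), tuple(rows))
        tree, supports = bootstrap(msa, n_reps=100, seed=42)
        central = next(iter(bipartitions(gen)))
        assert supports[central] >= 0.95

    def test_deterministic_per_seed(self):
        ids, rows, _ = two_clade_alignment(n_per_clade=3, seed=2)
        msa = MSA(tuple(ids), tuple(rows))
        _, s1 = bootstrap(msa, n_reps=50, seed=7)
        _, s2 = bootstrap(msa, n_reps=50, seed=7)
        assert s1 == s2

    def test_supports_invariant_under_taxon_relabeling(self):
        ids, rows, _ = two_clade_alignment(n_per_clade=3, seed=3)
        msa = MSA(tuple(ids), tuple(rows))
        _, s1 = bootstrap(msa, n_reps=50, seed=11)
        # relabel taxa by a fixed permutation of names (same data order)
        mapping = {i: f"z{k}" for k, i in enumerate(ids)}
        relabeled = MSA(tuple(mapping[i] for i in ids), tuple(rows))
        _, s2 = bootstrap(relabeled, n_reps=50, seed=11)
        remapped = {frozenset(mapping[x] for x in b): v for b, v in s1.items()}
        # canonical sides may flip under renaming; compare via complements
        leaves = frozenset(mapping.values())
        def canon(d):
            out = {}
            for b, v in d.items():
                side = min(b, leaves - b, key=lambda s: sorted(s))
                out[side] = v
            return out
        assert canon(remapped) == canon(s2)

    def test_rejects_degenerate_input(self):
        msa = MSA(("a", "b", "c"), ("M", "K", "V"))
        with pytest.raises(ValueError):
            bootstrap(msa, n_reps=0)
        with pytest.raises(ValueError):
            bootstrap(msa, n_reps=10, seed=0)  # single column


class TestBipartitions:
    def test_identical_trees_share_everything(self):
        t = read_newick("((a,b),(c,d),(e,f));")
        assert shared_bipartition_fraction(t, t) == 1.0

    def test_star_vs_resolved_is_zero(self):
        star = read_newick("(a,b,c,d);")
        resolved = read_newick("((a,b),(c,d));")
        assert shared_bipartition_fraction(star, resolved) == 0.0

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shared_bipartition_fraction(read_newick("(a,b,c);"), read_newick("(a,b,d);"))


class TestNewickIO:
    def test_round_trip_preserves_bipartitions_and_lengths(self):
        ids, rows, _ = two_clade_alignment(n_per_clade=3, seed=5)
        tree = nj(distance_matrix(MSA(tuple(ids), tuple(rows))))
        text = write_newick(tree)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(tree)
        d1 = {t.name: t.length for t in tree.tips()}
        d2 = {t.name: t.length for t in back.tips()}
        for name in d1:
            assert d2[name] == pytest.approx(d1[name], abs=1e-6)

    def test_supports_serialized_as_internal_labels(self):
        ids, rows, _ = two_clade_alignment(n_per_clade=3, seed=6)
        tree, supports = bootstrap(MSA(tuple(ids), tuple(rows)), n_reps=20, seed=1)
        text = write_newick(tree)
        back = read_newick(text)
        labels = {n.name for n in back.non_tips() if n.name}
        assert labels == {f"{v:.3f}" for v in supports.values()}

    def test_rejects_unbalanced_parentheses(self):
        with pytest.raises(ValueError):
            read_newick("((a,b),(c,d);")

    def test_phylip_export_shape(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float))
        text = write_phylip(dm)
        lines = text.strip().split("\n")
        assert lines[0] == "3" and len(lines) == 4
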