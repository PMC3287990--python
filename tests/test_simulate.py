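"""The synthetic-proteome generator and its planted ground truth."""

import numpy as np
import pytest

from fungiglobin import simulate
from fungiglobin.simulate import (
    ArchitectureSpec,
    CensusBlock,
    MutationModel,
    TaxonProfile,
    build_census_fixture,
    build_protein,
    build_proteome,
    identity_to_template,
    mutate_template,
)
from fungiglobin.templates import GLB3F, get_template


class TestMutateTemplate:
    def test_identity_one_no_indels_is_identity_map(self, glb3f):
        md = mutate_template(glb3f, MutationModel(1.0, indel_rate=0.0, seed=5))
        assert md.sequence == glb3f.sequence
        assert dict(md.annotations) == dict(glb3f.annotations)

    def test_measured_identity_tracks_target(self, glb3f):
        """Mean identity over 100 draws is within 0.05 of the 0.6 target."""
        idents = []
        for seed in range(100):
            md = mutate_template(glb3f, MutationModel(0.6, seed=seed))
            idents.append(identity_to_template(glb3f, md))
        assert abs(np.mean(idents) - 0.6) <= 0.05

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_conserve_checklist_keeps_f8_his(self, glb3f, seed):
        md = mutate_template(glb3f, MutationModel(0.4, seed=seed))
        assert md.sequence[md.annotations["F8"] - 1] == "H"

    def test_annotations_remapped_through_indels(self, glb3f):
        md = mutate_template(glb3f, MutationModel(0.8, indel_rate=5.0, seed=3))
        # every label survives and points at the residue the template
        # position carries after the edit script
        for label, t_idx in glb3f.annotations.items():
            new_idx = md.annotations[label]
            assert md.sequence[new_idx - 1] == md.aligned[t_idx - 1]

    def test_identity_monotone_in_divergence(self, glb3f):
        means = []
        for target in (0.9, 0.7, 0.5):
            vals = [
                identity_to_template(
                    glb3f, mutate_template(glb3f, MutationModel(target, seed=s))
                )
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestBuildProtein:
    def test_three_domain_grammar_is_fhb(self):
        rec, truth, _ = build_protein(
            simulate.DEFAULT_GRAMMARS["FHb"], MutationModel(0.7, indel_rate=0.0, seed=1)
        )
        assert truth.true_class == "FHb"
        assert len(rec[1]) == 396  # normal-length flavohemoglobin

    def test_missing_cqx3_is_incomplete_fhb(self):
        rec, truth, _ = build_protein(
            simulate.DEFAULT_GRAMMARS["FHb_incomplete"], MutationModel(0.7, seed=1)
        )
        assert truth.true_class == "FHb_incomplete"

    def test_single_truncated_domain_is_t1(self):
        rec, truth, _ = build_protein(
            simulate.DEFAULT_GRAMMARS["T1"], MutationModel(0.7, indel_rate=0.0, seed=1)
        )
        assert truth.true_class == "T1"
        assert len(rec[1]) == 116

    def test_spans_tile_the_protein(self):
        rec, truth, _ = build_protein(
            simulate.DEFAULT_GRAMMARS["T1Chimera"], MutationModel(0.7, seed=4)
        )
        last = 0
        for _, start, end in truth.spans:
            assert start == last + 1
            last = end
        assert last == len(rec[1])

    def test_unknown_template_rejected(self):
        with pytest.raises(KeyError):
            ArchitectureSpec(("NOPE",))

    def test_two_globins_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(("GLB3F", "GLB2"))


class TestBuildProteome:
    def test_presence_probability_one_gives_every_class(self):
        profile = TaxonProfile("t", ("P", "S", "C"), {"FHb": 1.0, "T1": 1.0})
        proteome = build_proteome(profile, n_genomes=10, seed=2)
        classes = {t.true_class for t in proteome.truth}
        assert classes == {"FHb", "T1"}
        assert len(proteome.records) == 20

    def test_deterministic_outputs(self, tmp_path):
        profile = TaxonProfile("t", ("P", "S", "C"), {"FHb": 0.7, "Sgb": 0.7})
        a = build_proteome(profile, n_genomes=6, seed=3)
        b = build_proteome(profile, n_genomes=6, seed=3)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_presence_fraction_matches_binomial(self):
        profile = TaxonProfile("t", ("P", "S", "C"), {"T1": 0.6})
        proteome = build_proteome(profile, n_genomes=200, seed=1)
        frac = len(proteome.records) / 200
        assert abs(frac - 0.6) <= 0.07

    def test_rejects_zero_genomes(self):
        profile = TaxonProfile("t", ("P", "S", "C"), {"T1": 1.0})
        with pytest.raises(ValueError):
            build_proteome(profile, n_genomes=0)

    def test_true_msa_rows_degap_to_domain_sequences(self, small_proteome):
        """True alignments reproduce each protein's globin domain exactly."""
        truth = {t.protein_id: t for t in small_proteome.truth}
        seqs = dict(small_proteome.records)
        for label, (ids, rows) in small_proteome.true_msas.items():
            assert len({len(r) for r in rows}) == 1  # rectangular
            for pid, row in zip(ids, rows):
                spans = dict(
                    (k, (s, e)) for k, s, e in truth[pid].spans
                )
                kind = next(
                    k for k in spans
                    if k not in ("EXT", "SIG") and get_template(k).is_globin
                )
                s, e = spans[kind]
                assert row.replace("-", "") == seqs[pid][s - 1:e]


class TestCensusFixture:
    def test_default_totals(self):
        df = build_census_fixture()
        assert len(df) == 165

    def test_all_zero_config_is_empty_but_valid(self):
        df = build_census_fixture(
            (CensusBlock("P", "S", "C", 2, ()),)
        )
        assert len(df) == 2
        assert df[["FHb", "Sgb"]].to_numpy().sum() == 0

    def test_overfull_block_rejected(self):
        with pytest.raises(ValueError):
            CensusBlock("P", "S", "C", 2, ((3, {"FHb": 1}),))
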