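"""Generators: reproducibility, median-law exactness, planted-truth bookkeeping."""

import numpy as np
import pytest

from denovostruct.descriptors import classify_full_isd, ss_proportions, track_fraction
from denovostruct.synthetic_data import (
    COHORT_PRESETS,
    CohortSpec,
    SequenceCohortSpec,
    SSCohortSpec,
    gen_disorder_cohort,
    gen_expression_matrix,
    gen_sequence_cohort,
    gen_ss_cohort,
    gen_synteny_fixture,
    gen_toy_complex,
    gen_value_cohort,
    get_preset,
)
from denovostruct.coexpression import pearson_with_p

TIMES = {"br1": 0.1, "br2": 0.3, "br3": 0.5, "br4": 0.94, "br5": 1.0, "br6": 2.41}


class TestDisorderCohort:
    def test_zero_noise_branch_medians_equal_law(self):
        spec = CohortSpec(
            branch_times=TIMES, n_per_branch=51, intercept=0.8, slope=-0.1,
            sigma=0.0, seed=4, length_range=(1000, 1000),
        )
        records, truth = gen_disorder_cohort(spec)
        for branch, t in TIMES.items():
            fracs = [
                track_fraction(r.disorder_track) for r in records if r.branch == branch
            ]
            assert np.median(fracs) == pytest.approx(spec.law(t), abs=1e-3)

    def test_law_outside_unit_interval_rejected(self):
        spec = CohortSpec(
            branch_times=TIMES, n_per_branch=10, intercept=0.2, slope=-0.1
        )
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            spec.validate()

    def test_planted_full_isd_bookkeeping(self):
        spec = get_preset("denovo-full-isd", seed=9)
        records, truth = gen_disorder_cohort(spec, n_full_isd=68)
        n_full = sum(
            classify_full_isd(track_fraction(r.disorder_track)) for r in records
        )
        assert len(records) == 181
        assert n_full == truth["planted_full_isd"].sum() == 68

    def test_reproducibility_same_seed(self):
        spec = COHORT_PRESETS["denovo-isd"]
        r1, t1 = gen_disorder_cohort(spec)
        r2, t2 = gen_disorder_cohort(spec)
        assert t1.equals(t2)
        for a, b in zip(r1, r2):
            assert a.sequence == b.sequence
            np.testing.assert_array_equal(a.disorder_track, b.disorder_track)

    def test_different_seed_differs(self):
        from dataclasses import replace

        spec = COHORT_PRESETS["denovo-isd"]
        _, t1 = gen_disorder_cohort(spec)
        _, t2 = gen_disorder_cohort(replace(spec, seed=99))
        assert not t1["planted_value"].equals(t2["planted_value"])

    def test_value_cohort_median_preserved_under_noise(self):
        spec = CohortSpec(
            branch_times=TIMES, n_per_branch=4001, intercept=0.35, slope=0.048,
            sigma=0.4, seed=0,
        )
        truth = gen_value_cohort(spec)
        for branch, t in TIMES.items():
            vals = truth.loc[truth.branch == branch, "planted_value"]
            # logit-scale noise is median-preserving
            assert np.median(vals) == pytest.approx(spec.law(t), abs=0.01)


class TestSSCohort:
    def test_single_class_target_gives_uniform_string(self):
        spec = SSCohortSpec(
            branch_times={"br1": 0.1}, n_per_branch=3, length=50,
            laws={"coil": (1.0, 0.0), "helix": (0.0, 0.0),
                  "strand": (0.0, 0.0), "g310": (0.0, 0.0)},
            seed=1,
        )
        records, _ = gen_ss_cohort(spec)
        for r in records:
            assert set(r.ss_string) <= {"C", "T"}
            assert ss_proportions(r.ss_string).p_coil == 1.0

    def test_targets_recovered_within_multinomial_error(self):
        spec = SSCohortSpec(
            branch_times={"br1": 0.1}, n_per_branch=20, length=1000,
            laws={"coil": (0.5, 0.0), "helix": (0.3, 0.0),
                  "strand": (0.2, 0.0), "g310": (0.0, 0.0)},
            seed=2,
        )
        records, _ = gen_ss_cohort(spec)
        props = [ss_proportions(r.ss_string) for r in records]
        assert np.mean([p.p_coil for p in props]) == pytest.approx(0.5, abs=0.05)
        assert np.mean([p.p_helix for p in props]) == pytest.approx(0.3, abs=0.05)
        assert np.mean([p.p_strand for p in props]) == pytest.approx(0.2, abs=0.05)

    def test_negative_class_proportion_rejected(self):
        spec = SSCohortSpec(
            branch_times={"br6": 2.41}, n_per_branch=1, length=10,
            laws={"coil": (0.9, 0.1), "helix": (0.2, 0.0),
                  "strand": (0.1, 0.0), "g310": (0.0, 0.0)},
        )
        with pytest.raises(ValueError, match="negative"):
            gen_ss_cohort(spec)


class TestSequenceCohort:
    def test_degenerate_single_aa_composition(self):
        spec = SequenceCohortSpec(
            branch_times={"br1": 0.1}, n_per_branch=2, length=30,
            aa_trends={}, seed=0,
        )
        import denovostruct.synthetic_data as sd

        records, truth = gen_sequence_cohort(spec)
        comp = truth.iloc[0][[f"target_{a}" for a in "ACDEFGHIKLMNPQRSTVWY"]]
        assert comp.sum() == pytest.approx(1.0)

    def test_planted_trends_show_in_branch_compositions(self):
        spec = SequenceCohortSpec(branch_times=TIMES, n_per_branch=1, seed=0)
        _, truth = gen_sequence_cohort(spec)
        by_time = truth.sort_values("time_mya")
        assert by_time["target_G"].is_monotonic_decreasing
        assert by_time["target_Y"].is_monotonic_increasing


class TestToyComplex:
    def test_zero_contacts(self):
        from denovostruct.complex_interface import interface_contacts

        model, planted = gen_toy_complex(6, 5, 0, seed=1)
        assert planted == []
        assert interface_contacts(model).raw_count == 0

    def test_single_contact(self):
        from denovostruct.complex_interface import interface_contacts

        model, planted = gen_toy_complex(6, 5, 1, seed=1)
        assert len(planted) == 1
        assert sorted(interface_contacts(model).pair_set()) == planted

    def test_infeasible_k_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_toy_complex(4, 3, 5)


class TestSyntenyFixture:
    def test_br1_genes_absent_from_all_outgroups(self):
        fix = gen_synteny_fixture(n_genes=40, seed=3)
        br1_genes = [g for g, b in fix.planted.items() if b == "br1"]
        assert br1_genes, "fixture should plant some focal-specific genes"
        for og, (hits_fo, _, _) in fix.outgroups.items():
            subjects = {s for _, s, _ in hits_fo}
            for g in br1_genes:
                assert f"{g}@{og}" not in subjects

    def test_presence_spans_outgroups_up_to_planted_branch(self):
        fix = gen_synteny_fixture(n_genes=40, seed=3)
        for g, b in fix.planted.items():
            rank = int(b[2:])
            for og, (hits_fo, _, order_o) in fix.outgroups.items():
                expected = int(og[2:]) <= rank
                assert (f"{g}@{og}" in order_o) is expected


class TestExpressionMatrix:
    def test_zero_noise_partners_perfectly_correlated(self):
        matrix, partners = gen_expression_matrix(
            n_genes=10, n_samples=30, n_partners=2, r_target=1.0, seed=1
        )
        x = matrix.loc["denovo_target"]
        for p in partners:
            r, _ = pearson_with_p(x, matrix.loc[p])
            assert r == pytest.approx(1.0)

    def test_independent_genes_weakly_correlated(self):
        matrix, _ = gen_expression_matrix(
            n_genes=50, n_samples=100, n_partners=0, r_target=0.95, seed=2
        )
        x = matrix.loc["denovo_target"]
        rs = [
            pearson_with_p(x, matrix.loc[g])[0]
            for g in matrix.index
            if g.startswith("gene_")
        ]
        assert np.max(np.abs(rs)) < 0.5

    def test_r_target_out_of_range(self):
        with pytest.raises(ValueError):
            gen_expression_matrix(r_target=1.5)
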