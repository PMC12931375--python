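"""Spot-level scoring algebra, conditional statistics and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stscore import (
    GeneSetPanel,
    SampleSet,
    compare_groups,
    conditional_percent,
    conditional_polarization,
    cooccurrence_percent,
    geneset_percent,
    positivity_matrix,
)
from stscore.io import annotation_from_arrays
from stscore.panels import resolve_symbol

from conftest import make_spot_matrix


ISG = ["IFIT1", "USP18", "MX1", "IFI27", "IFI44L", "OAS1"]
APO = ["CASP3", "CASP8", "BAX", "BAK1", "CYCS"]


class TestPositivity:
    def test_single_hit_positive_at_k1(self):
        counts = np.zeros((6, 1), dtype=int)
        counts[0, 0] = 1  # IFIT1 only
        sm = make_spot_matrix(counts, symbols=ISG)
        assert positivity_matrix(sm, GeneSetPanel("isg", ISG)).tolist() == [True]

    def test_k_of_n_rule_four_of_five_markers(self):
        counts = np.zeros((5, 1), dtype=int)
        counts[:4, 0] = 2  # 4 of 5 apoptosis markers expressed
        sm = make_spot_matrix(counts, symbols=APO)
        assert not positivity_matrix(sm, GeneSetPanel("apo", APO, k_required=5))[0]
        assert positivity_matrix(sm, GeneSetPanel("apo", APO, k_required=2))[0]

    def test_all_zero_spot_negative(self):
        sm = make_spot_matrix(np.zeros((6, 3), dtype=int), symbols=ISG)
        assert not positivity_matrix(sm, GeneSetPanel("isg", ISG)).any()

    def test_absent_genes_dropped_with_warning(self):
        sm = make_spot_matrix(np.ones((2, 1), dtype=int), symbols=["IFIT1", "MX1"])
        with pytest.warns(UserWarning, match="absent"):
            pos = positivity_matrix(sm, GeneSetPanel("isg", ISG))
        assert pos[0]

    def test_panel_with_no_present_genes_errors(self):
        sm = make_spot_matrix(np.ones((1, 1), dtype=int), symbols=["ACTB"])
        with pytest.raises(ValueError):
            positivity_matrix(sm, GeneSetPanel("isg", ISG))

    def test_min_count_threshold(self):
        counts = np.array([[1, 2]])
        sm = make_spot_matrix(counts, symbols=["IFIT1"])
        panel = GeneSetPanel("p", ["IFIT1"], min_count=2)
        assert positivity_matrix(sm, panel).tolist() == [False, True]

    def test_protein_style_alias_resolution(self):
        assert resolve_symbol("TNFα") == "TNF"
        assert resolve_symbol("IL-1β") == "IL1B"
        panel = GeneSetPanel("cyt", ["IL-1β", "TNFα"])
        assert panel.genes == ["IL1B", "TNF"]


def _annotated_sample(comp_labels, counts, symbols):
    sm = make_spot_matrix(counts, symbols=symbols, sample_id="s1")
    samples = SampleSet(samples=[sm], groups=["lesion"])
    clusters = {"s1": np.array([0 if c == "epidermis" else 1 if c == "dermis" else 2 for c in comp_labels])}
    ann = annotation_from_arrays(samples, clusters, {0: "epidermis", 1: "dermis"})
    return samples, ann


class TestGenesetPercent:
    def test_direct_count(self):
        counts = np.zeros((1, 10), dtype=int)
        counts[0, :9] = 1
        samples, ann = _annotated_sample(["dermis"] * 10, counts, ["IFIT1"])
        rep = geneset_percent(samples, GeneSetPanel("isg", ["IFIT1"]), ann, "total")
        assert rep.iloc[0]["percent"] == 90.0

    def test_empty_scope_flagged_missing(self):
        counts = np.ones((1, 4), dtype=int)
        samples, ann = _annotated_sample(["dermis"] * 4, counts, ["IFIT1"])
        rep = geneset_percent(samples, GeneSetPanel("isg", ["IFIT1"]), ann, "epidermis")
        assert rep.iloc[0]["missing"]
        assert np.isnan(rep.iloc[0]["percent"])

    def test_scope_additivity(self, small_dataset):
        samples, ann, _ = small_dataset
        panel = GeneSetPanel("isg", ISG)
        total = geneset_percent(samples, panel, ann, "total")
        parts = [
            geneset_percent(samples, panel, ann, scope)
            for scope in ("epidermis", "dermis", "other")
        ]
        for sid in samples.sample_ids:
            t = total.loc[total.sample_id == sid, "numerator"].sum()
            p = sum(f.loc[f.sample_id == sid, "numerator"].sum() for f in parts)
            assert t == p

    def test_k_monotonicity_spot_for_spot(self, small_dataset):
        samples, _, _ = small_dataset
        s = samples[1]
        p1 = positivity_matrix(s, GeneSetPanel("apo", APO, k_required=1))
        p2 = positivity_matrix(s, GeneSetPanel("apo", APO, k_required=2))
        assert not np.any(p2 & ~p1)

    def test_adding_gene_never_decreases_positive_fraction(self, small_dataset):
        samples, _, _ = small_dataset
        s = samples[1]
        small = positivity_matrix(s, GeneSetPanel("p", ISG[:3]))
        big = positivity_matrix(s, GeneSetPanel("p", ISG))
        assert not np.any(small & ~big)

    def test_per_gene_mode_reports_each_gene(self, small_dataset):
        samples, ann, _ = small_dataset
        rep = geneset_percent(samples, GeneSetPanel("isg", ISG), ann, "total", per_gene=True)
        assert set(rep["panel"]) == set(ISG)
        assert len(rep) == len(ISG) * len(samples)

    def test_planted_fraction_recovered(self, small_dataset):
        samples, ann, truth = small_dataset
        rep = geneset_percent(samples, GeneSetPanel("isg", ISG), ann, "total")
        planted = truth.sample_fractions.set_index("sample_id")["inflamed_fraction"]
        for _, row in rep.iterrows():
            p = planted[row.sample_id]
            se = 100 * np.sqrt(max(p * (1 - p), 1e-9) / row.denominator)
            assert abs(row.percent - 100 * p) <= max(3 * se, 1.0)


class TestConditional:
    def _polarization_sample(self):
        # anchor=CD68 row0; A genes rows 1-2; B genes rows 3-4
        symbols = ["CD68", "FCGR3A", "FCGR1A", "CD163", "ARG1"]
        #          spot: 0=A-only 1=B-only 2=B-only 3=both 4=non-anchor
        counts = np.array(
            [
                [1, 1, 1, 1, 0],
                [1, 0, 0, 1, 1],
                [0, 0, 0, 0, 0],
                [0, 1, 1, 1, 0],
                [0, 0, 1, 0, 0],
            ]
        )
        return make_spot_matrix(counts, symbols=symbols)

    def test_polarization_direct_count(self):
        sm = self._polarization_sample()
        out = conditional_polarization(
            sm,
            GeneSetPanel("anchor", ["CD68"]),
            GeneSetPanel("m1", ["FCGR3A", "FCGR1A"]),
            GeneSetPanel("m2", ["CD163", "ARG1"]),
        )
        assert (out["a_only"], out["b_only"], out["both"]) == (25.0, 50.0, 25.0)

    def test_polarization_sums_to_100_exactly(self, small_dataset):
        samples, _, _ = small_dataset
        out = conditional_polarization(
            samples[1],
            GeneSetPanel("anchor", ["CD68"]),
            GeneSetPanel("m1", ["FCGR3A", "FCGR1A"]),
            GeneSetPanel("m2", ["CD163", "ARG1"]),
        )
        assert out["a_only"] + out["b_only"] + out["both"] == 100.0

    def test_no_anchor_spots_missing_record(self):
        sm = make_spot_matrix(np.zeros((3, 4), dtype=int), symbols=["CD68", "FCGR3A", "CD163"])
        out = conditional_polarization(
            sm,
            GeneSetPanel("anchor", ["CD68"]),
            GeneSetPanel("m1", ["FCGR3A"]),
            GeneSetPanel("m2", ["CD163"]),
        )
        assert out["missing"]

    def test_overlapping_marker_panels_rejected(self):
        sm = self._polarization_sample()
        with pytest.raises(ValueError, match="share genes"):
            conditional_polarization(
                sm,
                GeneSetPanel("anchor", ["CD68"]),
                GeneSetPanel("m1", ["FCGR3A", "ARG1"]),
                GeneSetPanel("m2", ["CD163", "ARG1"]),
            )

    def test_conditional_percent_direct(self):
        # 5 anchor+ spots, 2 of them target+
        counts = np.array([[1, 1, 1, 1, 1, 0], [1, 1, 0, 0, 0, 1]])
        sm = make_spot_matrix(counts, symbols=["CD68", "TGFB1"])
        out = conditional_percent(
            sm, GeneSetPanel("anchor", ["CD68"]), GeneSetPanel("t", ["TGFB1"])
        )
        assert out["percent"] == 40.0

    def test_target_equal_anchor_is_100(self):
        counts = np.array([[1, 0, 1]])
        sm = make_spot_matrix(counts, symbols=["CD68"])
        out = conditional_percent(
            sm, GeneSetPanel("anchor", ["CD68"]), GeneSetPanel("t", ["CD68"])
        )
        assert out["percent"] == 100.0

    def test_generator_conditional_rate_recovered(self):
        from stscore import SimConfig, generate_dataset, default_panels

        cfg = SimConfig(
            n_samples=1, groups=("lesion",), grid_rows=60, grid_cols=70,
            epidermis_band_rows=10, inflamed_fraction=(0.5,),
            anchor_fraction=0.5, m1_given_anchor=0.0, m2_given_anchor=0.3,
            both_given_anchor=0.0, n_background_genes=150, seed=13,
        )
        samples, _, truth = generate_dataset(cfg)
        panels = default_panels()
        out = conditional_percent(samples[0], panels["anchor_cd68"], panels["m2_markers"])
        assert out["denominator"] >= 1000
        se = 100 * np.sqrt(0.3 * 0.7 / out["denominator"])
        assert abs(out["percent"] - 30.0) <= 3 * se


class TestCooccurrence:
    def test_outcome_subset_of_conditioning(self):
        # every outcome+ spot is conditioning+
        counts = np.array([[1, 1, 0, 0], [1, 0, 0, 0]])
        sm = make_spot_matrix(counts, symbols=["CASP3", "IFIT1"])
        out = cooccurrence_percent(
            sm, GeneSetPanel("cond", ["CASP3"]), GeneSetPanel("isg", ["IFIT1"])
        )
        assert out["percent_in_negative"] == 0.0
        assert out["percent_in_positive"] == 50.0

    def test_independent_planting_gives_similar_rates(self):
        from stscore import SimConfig, generate_dataset, default_panels

        cfg = SimConfig(
            n_samples=1, groups=("lesion",), grid_rows=60, grid_cols=70,
            epidermis_band_rows=10, inflamed_fraction=(0.5,),
            apoptosis_given_isg_pos=0.3, apoptosis_given_isg_neg=0.3,
            n_background_genes=150, seed=21,
        )
        samples, _, _ = generate_dataset(cfg)
        panels = default_panels()
        out = cooccurrence_percent(samples[0], panels["isg"], panels["apoptosis"])
        n = min(out["denominator_positive"], out["denominator_negative"])
        se = 100 * np.sqrt(2 * 0.3 * 0.7 / n)
        assert abs(out["percent_in_positive"] - out["percent_in_negative"]) <= 3 * se

    def test_positive_correlation_detected(self, small_dataset):
        from stscore import default_panels

        samples, _, _ = small_dataset
        panels = default_panels()
        out = cooccurrence_percent(samples[1], panels["isg"], panels["apoptosis"])
        # generator plants apoptosis_given_isg_pos > apoptosis_given_isg_neg
        assert out["percent_in_positive"] > out["percent_in_negative"]


class TestCompareGroups:
    def test_student_closed_form(self):
        out = compare_groups([1, 2, 3], [4, 5, 6], method="student")
        assert out.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert out.df == 4
        assert out.p == pytest.approx(0.02131, abs=1e-5)

    def test_identical_groups_p_one(self):
        out = compare_groups([5, 5], [5, 5], method="student")
        assert out.statistic == 0.0
        assert out.p == 1.0

    def test_exact_permutation_multiples_of_one_twentieth(self):
        out = compare_groups([1, 2, 3], [4, 5, 6], method="permutation", n_perm=100)
        assert out.exact_permutations
        assert out.n_perm == 20
        assert (out.p * 20) == pytest.approx(round(out.p * 20))

    def test_monte_carlo_uses_add_one_estimator(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        out = compare_groups(a, b, method="permutation", n_perm=200, seed=1)
        assert not out.exact_permutations
        assert ((1 + 200) * out.p) == pytest.approx(round((1 + 200) * out.p))

    def test_small_groups_rejected_for_t(self):
        with pytest.raises(ValueError, match="permutation"):
            compare_groups([1], [2, 3], method="student")

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.0]
        b = [5.0, 9.0, 1.0, 7.0]
        student = compare_groups(a, b, method="student")
        welch = compare_groups(a, b, method="welch")
        assert welch.df < student.df

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=6),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=6),
    )
    def test_p_in_unit_interval(self, a, b):
        out = compare_groups(a, b, method="student")
        assert 0.0 <= out.p <= 1.0
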