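import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import spermethylome as sm
from spermethylome.longitudinal import (
    classify_dynamic,
    common_across_subjects,
    delta_counts,
    dynamic_fraction_of_changes,
    filter_common_covered,
    fold_vs_reference,
    intersect_timepoints,
    reference_drift,
    yates_chisq,
)


class TestDeltaCounts:
    def test_worked_example(self):
        base = pd.Series([0.10, 0.50, 0.90, 0.40], index=list("abcd"))
        follow = pd.Series([0.35, 0.50, 0.60, 0.61], index=list("abcd"))
        dc = delta_counts(base, follow, 0.2)
        assert (dc.n_hyper, dc.n_hypo) == (2, 1)
        assert dc.altered == {"a", "c", "d"}

    def test_change_of_exactly_cutoff_not_counted(self):
        base = pd.Series([0.30], index=["a"])
        follow = pd.Series([0.50], index=["a"])
        assert delta_counts(base, follow, 0.2).n_total == 0

    def test_identical_samples_give_empty(self):
        s = pd.Series([0.1, 0.9], index=["a", "b"])
        dc = delta_counts(s, s)
        assert (dc.n_hypo, dc.n_hyper, dc.altered) == (0, 0, frozenset())

    def test_missing_in_either_sample_excluded(self):
        base = pd.Series([0.1, np.nan], index=["a", "b"])
        follow = pd.Series([0.9, 0.9], index=["a", "b"])
        dc = delta_counts(base, follow)
        assert dc.altered == {"a"}

    def test_disjoint_probe_sets_rejected(self):
        with pytest.raises(ValueError, match="share no probes"):
            delta_counts(pd.Series([0.1], index=["a"]), pd.Series([0.1], index=["b"]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(vals=st.lists(
        st.tuples(st.floats(0, 1, width=32), st.floats(0, 1, width=32)),
        min_size=1, max_size=60,
    ))
    def test_antisymmetric_under_swap(self, vals):
        idx = [f"p{i}" for i in range(len(vals))]
        a = pd.Series([v[0] for v in vals], index=idx, dtype=float)
        b = pd.Series([v[1] for v in vals], index=idx, dtype=float)
        fwd, rev = delta_counts(a, b), delta_counts(b, a)
        assert (fwd.n_hypo, fwd.n_hyper) == (rev.n_hyper, rev.n_hypo)
        assert fwd.altered == rev.altered


class TestReferenceAndFold:
    def test_reference_drift_is_mean_over_cc_followups(self):
        report = pd.DataFrame({
            "cohort": ["CC", "CC", "HD"],
            "timepoint_months": [6.0, 12.0, 6.0],
            "n_total": [100, 190, 4000],
        })
        assert reference_drift(report) == pytest.approx(145.0)

    def test_reference_requires_cc_followups(self):
        report = pd.DataFrame({"cohort": ["HD"], "timepoint_months": [6.0], "n_total": [5]})
        with pytest.raises(ValueError, match="CC"):
            reference_drift(report)

    def test_fold_examples(self):
        assert fold_vs_reference(2900, 145.0) == pytest.approx(20.0)
        assert fold_vs_reference(145, 145.0) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="positive"):
            fold_vs_reference(10, 0.0)


class TestIntersections:
    def test_venn_cells_and_persistence(self):
        sets = {"m6": {"a", "b", "c"}, "m12": {"b", "c"}, "m24": {"c"}}
        cells, persistent = intersect_timepoints(sets)
        assert persistent == {"c"}
        assert cells == {("m6",): 1, ("m6", "m12"): 1, ("m6", "m12", "m24"): 1}

    def test_disjoint_sets_have_empty_persistence(self):
        cells, persistent = intersect_timepoints({"a": {1}, "b": {2}})
        assert persistent == frozenset()
        assert cells == {("a",): 1, ("b",): 1}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(data=st.lists(
        st.sets(st.integers(0, 40), max_size=25), min_size=2, max_size=4,
    ))
    def test_cells_partition_the_union(self, data):
        sets = {f"t{i}": s for i, s in enumerate(data)}
        cells, _ = intersect_timepoints(sets)
        assert sum(cells.values()) == len(set().union(*data))

    def test_common_across_subjects(self):
        shared, frac = common_across_subjects({"s1": set(range(10)), "s2": set(range(10))})
        assert len(shared) == 10 and frac == {"s1": 1.0, "s2": 1.0}
        shared, _ = common_across_subjects({"s1": {1}, "s2": {2}})
        assert shared == frozenset()


class TestCoverageFilter:
    def _bm(self, cov_rows):
        idx = [f"p{i}" for i in range(len(cov_rows))]
        beta = pd.DataFrame(0.5, index=idx, columns=["s1", "s2"])
        cov = pd.DataFrame(cov_rows, index=idx, columns=["s1", "s2"])
        return sm.BetaMatrix(beta, cov)

    def test_low_coverage_anywhere_drops_cpg_everywhere(self):
        bm = self._bm([[9, 30], [30, 30]])
        out = filter_common_covered(bm, 10)
        assert out.probes == ["p1"]

    def test_threshold_inclusive_by_default_exclusive_on_request(self):
        bm = self._bm([[10, 10]])
        assert filter_common_covered(bm, 10).probes == ["p0"]
        with pytest.warns(UserWarning, match="no CpGs"):
            assert filter_common_covered(bm, 10, exclusive=True).probes == []

    def test_requires_coverage_matrix(self, tiny_beta):
        with pytest.raises(ValueError, match="coverage"):
            filter_common_covered(tiny_beta, 10)


class TestDynamicClassification:
    def test_bounds_inclusive(self):
        means = pd.Series({"a": 0.50, "b": 0.05, "c": 0.20, "d": 0.80, "e": 0.81})
        cls = classify_dynamic(means)
        assert cls["dynamic"].tolist() == [True, False, True, True, False]

    def test_fraction_of_changes(self):
        cls = classify_dynamic(pd.Series(
            {f"p{i}": (0.5 if i < 8 else 0.05) for i in range(12)}
        ))
        altered = [f"p{i}" for i in range(10)]  # 8 dynamic + 2 static
        assert dynamic_fraction_of_changes(altered, cls) == pytest.approx(80.0)
        assert dynamic_fraction_of_changes([], cls) is None
        assert dynamic_fraction_of_changes(
            ["p9", "p10"], cls
        ) == pytest.approx(0.0)  # no dynamic sites among altered


class TestYatesChisq:
    def test_worked_example(self):
        chi2, p = yates_chisq(30, 100, 10, 100)
        # N(|ad-bc|-N/2)^2 / margins = 200*1900^2/(100*100*40*160)
        assert chi2 == pytest.approx(11.28125, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(11.28125, 1))

    def test_equal_proportions_floor_to_zero(self):
        chi2, p = yates_chisq(10, 100, 10, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_printed_capture_counts_highly_significant(self):
        _, p = yates_chisq(53_011, 1_711_875, 39_656, 1_711_875)
        assert p < 1e-4

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b = rng.integers(1, 50, 2)
            na, nb = a + rng.integers(1, 200), b + rng.integers(1, 200)
            chi2, p = yates_chisq(int(a), int(na), int(b), int(nb))
            table = [[a, na - a], [b, nb - b]]
            ref = stats.chi2_contingency(table, correction=True)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=st.integers(1, 40), b=st.integers(1, 40),
        extra_a=st.integers(1, 200), extra_b=st.integers(1, 200),
    )
    def test_correction_only_shrinks(self, a, b, extra_a, extra_b):
        chi2, _ = yates_chisq(a, a + extra_a, b, b + extra_b)
        raw = stats.chi2_contingency(
            [[a, extra_a], [b, extra_b]], correction=False
        ).statistic
        assert chi2 <= raw + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chisq(0, 10, 0, 10)


class TestLongitudinalModel:
    def test_treated_pulse_recovered_untreated_near_reference(self, small_cohort):
        lon = sm.LongitudinalModel(small_cohort.betas, small_cohort.manifest).fit()
        t = lon.table
        six = t[t["timepoint_months"] == 6.0]
        treated = six[six["cohort"] != "CC"]
        cc = t[t["cohort"] == "CC"]
        assert (treated["n_total"] > lon.reference_mean).all()
        assert (treated["fold_vs_reference"] > 5).all()
        assert cc["fold_vs_reference"].mean() == pytest.approx(1.0, abs=0.5)

    def test_acute_pulse_decays_except_persister(self, small_cohort):
        lon = sm.LongitudinalModel(small_cohort.betas, small_cohort.manifest).fit()
        t = lon.table.set_index(["subject_id", "timepoint_months"])
        # HD1 persists at full magnitude; HD2 decays back toward drift
        assert t.loc[("HD1", 12.0), "n_total"] > 5 * lon.reference_mean
        assert t.loc[("HD2", 12.0), "n_total"] < t.loc[("HD2", 6.0), "n_total"]

    def test_shared_pulse_pool_gives_expected_overlap(self, small_cohort):
        lon = sm.LongitudinalModel(small_cohort.betas, small_cohort.manifest).fit()
        shared, frac = lon.common_sites(["HD2", "HD3"], 6.0)
        # pool overlap 0.25, attenuated by per-site detection (~0.93^2)
        assert 0.10 < np.mean(list(frac.values())) < 0.35
        assert len(shared) > 0

    def test_dynamic_changes_enriched_over_universe_fraction(self):
        cfg = sm.SimulationConfig.capture(n_probes=30_000, rng_seed=31,
                                          treated_extra_dynamic_fraction=0.0076)
        co = sm.simulate_cohort(cfg)
        lon = sm.LongitudinalModel(co.betas, co.manifest, mode="capture").fit()
        universe_dynamic = 100 * lon.classification["dynamic"].mean()
        fr = lon.dynamic_fractions()
        assert (fr > universe_dynamic).all()

    def test_capture_mode_compares_consecutive_followups(self):
        cfg = sm.SimulationConfig.capture(n_probes=25_000, rng_seed=33,
                                          treated_extra_dynamic_fraction=0.0076)
        co = sm.simulate_cohort(cfg)
        lon = sm.LongitudinalModel(co.betas, co.manifest, mode="capture").fit()
        assert set(lon.table["baseline_months"]) == {12.0}
        assert set(lon.table["timepoint_months"]) == {18.0}
        # coverage filter was applied
        assert lon.n_probes < 25_000
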