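import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spermethylome as sm
from spermethylome.differential import (
    HypoHyper,
    _studentized_range_sf,
    cluster_and_purity,
    filter_probes,
    oneway_anova,
    random_probe_purities,
    region_summary,
    tukey_kramer,
)


def _anova_single(groups):
    """Run the vectorised ANOVA on one probe laid out as concatenated groups."""
    data = np.concatenate(groups)[None, :]
    cols, start = [], 0
    for g in groups:
        cols.append(np.arange(start, start + len(g)))
        start += len(g)
    return oneway_anova(data, cols)


class TestFilterProbes:
    def _ann(self, multi, maf):
        n = len(multi)
        return sm.ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": ["chr1"] * n, "pos": list(range(0, 100 * n, 100)),
            "strand": ["+"] * n, "multi_mapped": multi, "snp_maf": maf,
        }))

    def test_multi_mapped_and_common_snp_probes_dropped(self):
        ann = self._ann([False, True, False, False, False],
                        [np.nan, np.nan, 0.02, 0.005, np.nan])
        assert filter_probes(ann) == ["p0", "p3", "p4"]

    def test_all_clean_is_identity(self):
        ann = self._ann([False] * 3, [np.nan] * 3)
        assert filter_probes(ann) == ["p0", "p1", "p2"]

    def test_maf_exactly_at_cutoff_retained(self):
        # the rule is strictly greater than 1%
        ann = self._ann([False], [0.01])
        assert filter_probes(ann) == ["p0"]


class TestOnewayAnova:
    def test_worked_example_f27(self):
        res = _anova_single([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        assert res["F"][0] == pytest.approx(27.0, abs=1e-12)
        assert res["msw"][0] == pytest.approx(0.01)
        assert res["df_within"][0] == 6
        assert res["p"][0] == pytest.approx(stats.f.sf(27.0, 2, 6))

    def test_identical_groups_give_f0_p1(self):
        res = _anova_single([[0.3, 0.3], [0.3, 0.3], [0.3, 0.3]])
        assert res["F"][0] == 0.0
        assert res["p"][0] == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(7), rng.random(6)
        res = _anova_single([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res["F"][0] == pytest.approx(t.statistic**2, rel=1e-12)

    def test_matches_scipy_f_oneway_to_1e10(self):
        rng = np.random.default_rng(2)
        data = rng.random((60, 20))
        cols = [np.arange(0, 7), np.arange(7, 14), np.arange(14, 20)]
        res = oneway_anova(data, cols)
        for i in range(60):
            ref = stats.f_oneway(data[i, :7], data[i, 7:14], data[i, 14:])
            assert res["F"][i] == pytest.approx(ref.statistic, abs=1e-10)
            assert res["p"][i] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_missing_values_excluded_pairwise(self):
        data = np.array([[0.1, np.nan, 0.3, 0.4, 0.5, 0.6]])
        cols = [np.arange(0, 3), np.arange(3, 6)]
        res = oneway_anova(data, cols)
        ref = stats.f_oneway([0.1, 0.3], [0.4, 0.5, 0.6])
        assert res["F"][0] == pytest.approx(ref.statistic, abs=1e-12)

    def test_probe_with_single_populated_group_skipped(self):
        data = np.array([[0.1, 0.2, np.nan, np.nan]])
        cols = [np.arange(0, 2), np.arange(2, 4)]
        res = oneway_anova(data, cols)
        assert not res["valid"][0]
        assert np.isnan(res["F"][0])


class TestTukeyKramer:
    def test_worked_example_q(self):
        res = _anova_single([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        diff, q, p = tukey_kramer(res["means"], res["n"], res["msw"],
                                  res["df_within"], 3, (0, 2))
        assert q[0] == pytest.approx(10.392304845, abs=1e-6)
        assert diff[0] == pytest.approx(-0.6)

    def test_equal_pair_means_give_p1(self):
        res = _anova_single([[0.1, 0.3], [0.1, 0.3], [0.5, 0.7]])
        _, _, p = tukey_kramer(res["means"], res["n"], res["msw"],
                               res["df_within"], 3, (0, 1))
        assert p[0] == pytest.approx(1.0)

    def test_zero_msw_convention(self):
        res = _anova_single([[0.2, 0.2], [0.4, 0.4], [0.2, 0.2]])
        d01, _, p01 = tukey_kramer(res["means"], res["n"], res["msw"],
                                   res["df_within"], 3, (0, 1))
        d02, _, p02 = tukey_kramer(res["means"], res["n"], res["msw"],
                                   res["df_within"], 3, (0, 2))
        assert p01[0] == 0.0 and d01[0] != 0
        assert p02[0] == 1.0 and d02[0] == 0

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b, c = rng.random(7), rng.random(7), rng.random(6)
            res = _anova_single([a, b, c])
            vals = np.concatenate([a, b, c])
            labels = np.array(["A"] * 7 + ["B"] * 7 + ["C"] * 6)
            ref = pairwise_tukeyhsd(vals, labels)
            # statsmodels pair order: (A,B), (A,C), (B,C); meandiff = g2 - g1
            for (i, j), rp, rd in zip(((0, 1), (0, 2), (1, 2)), ref.pvalues, ref.meandiffs):
                diff, _, p = tukey_kramer(res["means"], res["n"], res["msw"],
                                          res["df_within"], 3, (i, j))
                assert diff[0] == pytest.approx(-rd, abs=1e-10)
                assert p[0] == pytest.approx(rp, abs=1e-8)

    def test_interpolated_sf_accurate(self):
        rng = np.random.default_rng(4)
        q = rng.uniform(0.05, 18.0, 400)  # > 300 triggers the spline path
        approx = _studentized_range_sf(q, 3, 17.0)
        exact = stats.studentized_range.sf(q, 3, 17)
        assert np.max(np.abs(approx - exact)) < 1e-6


class TestModelAndSelection:
    def test_significance_flag_matches_alpha(self, small_differential):
        _, res = small_differential
        t = res.table
        valid = np.isfinite(t["p"])
        assert (t.loc[valid, "significant"] == (t.loc[valid, "p"] < 0.05)).all()

    def test_top_k_orders_by_p_with_f_tiebreak(self, small_differential):
        _, res = small_differential
        top = res.top_probes(2)
        sub = res.table.loc[top]
        rest = res.table.drop(top)["p"].min()
        assert sub["p"].max() <= rest

    def test_top_k_explicit_tie_rule(self):
        table = pd.DataFrame(
            {"p": [0.3, 0.001, 0.04], "F": [1.0, 30.0, 5.0], "significant": [False, True, True]},
            index=["a", "b", "c"],
        )
        res = sm.CohortDifferentialResults(
            table=table, config=sm.AnalysisConfig(), cohorts=["CC", "HD"],
            manifest=pd.DataFrame(), betas=None,
        )
        assert res.top_probes(2) == ["b", "c"]
        table2 = pd.DataFrame(
            {"p": [0.01, 0.01, 0.5], "F": [5.0, 9.0, 1.0], "significant": [True, True, False]},
            index=["a", "b", "c"],
        )
        res2 = sm.CohortDifferentialResults(
            table=table2, config=sm.AnalysisConfig(), cohorts=["CC", "HD"],
            manifest=pd.DataFrame(), betas=None,
        )
        assert res2.top_probes(1) == ["b"]  # larger F wins the tie
        assert res2.top_probes(0) == []

    def test_top_k_deterministic_under_probe_permutation(self, small_differential):
        _, res = small_differential
        top = res.top_probes(50)
        shuffled = res.table.sample(frac=1.0, random_state=1)
        res2 = sm.CohortDifferentialResults(
            table=shuffled, config=res.config, cohorts=res.cohorts,
            manifest=res.manifest, betas=res.betas,
        )
        assert res2.top_probes(50) == top

    def test_hypo_hyper_sign_convention(self, small_differential):
        _, res = small_differential
        hh = res.hypo_hyper_fractions("TC_CC")
        # the implanted TC signatures are hypo-biased
        assert hh.n_hypo > hh.n_hyper
        sub = res.pair_significant("TC_CC")
        assert (sub["diff_TC_CC"] < 0).sum() == hh.n_hypo

    def test_hypo_fraction_from_counts(self):
        assert HypoHyper.from_counts(2277, 3265).pct_hypo == pytest.approx(69.7, abs=0.05)
        assert HypoHyper.from_counts(4904, 7760).pct_hypo == pytest.approx(63.2, abs=0.05)
        assert HypoHyper.from_counts(0, 10).pct_hypo == 0.0
        assert HypoHyper.from_counts(0, 0).pct_hypo is None

    def test_type_one_error_calibrated_under_null(self):
        cfg = sm.SimulationConfig(
            n_probes=20_000, timepoints_months=(0.0,),
            signatures=(), pulse=sm.TreatmentPulse(n_sites=0), rng_seed=17,
        )
        co = sm.simulate_cohort(cfg)
        res = sm.CohortDifferential(co.betas, co.manifest, co.annotation).fit(tukey="none")
        frac = res.table["significant"].mean()
        assert abs(frac - 0.05) < 0.01


class TestClustering:
    def test_implanted_signature_probes_separate_cohorts_perfectly(self, small_cohort, small_differential):
        _, res = small_differential
        cl = res.cluster_top_probes(500)
        assert cl.purity == 1.0

    def test_single_cohort_trivially_pure(self, small_cohort):
        co = small_cohort
        base = co.manifest.baseline_samples()
        cc = base.loc[base["cohort"] == "CC", "sample_id"].tolist()
        labels = pd.Series("CC", index=cc)
        cl = cluster_and_purity(co.betas.beta[cc], labels)
        assert cl.purity == 1.0

    def test_random_probe_sets_cluster_worse_than_signature(self, medium_differential):
        model, res = medium_differential
        labels = model.manifest.set_index("sample_id")["cohort"]
        rng = np.random.default_rng(23)
        rand = random_probe_purities(model.betas.beta, labels, k=500, n_draws=10, rng=rng)
        assert rand.mean() < 1.0
        assert rand.max() <= res.cluster_top_probes(500).purity

    def test_fewer_samples_than_clusters_rejected(self):
        data = pd.DataFrame({"s1": [0.1], "s2": [0.2]})
        with pytest.raises(ValueError, match="clusters"):
            cluster_and_purity(data, pd.Series({"s1": "CC", "s2": "HD"}))


class TestRegionSummary:
    def _fixture(self, cc_val, tc_val, n=6):
        probes = [f"p{i}" for i in range(4)]
        ann = sm.ProbeAnnotation(pd.DataFrame({
            "probe_id": probes, "chrom": ["chr1"] * 4,
            "pos": [100, 200, 300, 400], "strand": ["+"] * 4,
            "multi_mapped": [False] * 4, "snp_maf": [np.nan] * 4,
        }))
        region = pd.Series({"chrom": "chr1", "start": 0, "end": 500, "name": "R"})
        samples = [f"cc{i}" for i in range(n)] + [f"tc{i}" for i in range(n)]
        beta = pd.DataFrame(
            {s: [cc_val] * 4 for s in samples[:n]} | {s: [tc_val] * 4 for s in samples[n:]},
            index=probes,
        )
        manifest = sm.SampleManifest(pd.DataFrame({
            "sample_id": samples,
            "subject_id": samples,
            "cohort": ["CC"] * n + ["TC"] * n,
            "timepoint_months": [0] * 2 * n,
        }))
        return sm.BetaMatrix(beta), ann, region, manifest

    def test_twenty_point_difference_recovered(self):
        bm, ann, region, manifest = self._fixture(0.75, 0.55)
        rc = region_summary(bm, ann, region, manifest)
        assert rc.difference == pytest.approx(0.20)
        assert rc.means == (pytest.approx(0.75), pytest.approx(0.55))

    def test_identical_groups_give_zero_difference_p1(self):
        bm, ann, region, manifest = self._fixture(0.6, 0.6)
        rc = region_summary(bm, ann, region, manifest)
        assert rc.difference == 0.0
        assert rc.p == 1.0

    def test_mann_whitney_complete_separation_exact_p(self):
        bm, ann, region, manifest = self._fixture(0.75, 0.55)
        # add distinct within-group jitter so ranks are unambiguous but
        # groups stay completely separated
        beta = bm.beta.copy()
        for i, s in enumerate(beta.columns):
            beta[s] = beta[s] + i * 1e-4
        rc = region_summary(sm.BetaMatrix(beta), ann, region, manifest, test="mann_whitney")
        # exact two-sided p for U=0 with n=6 vs 6: 2 * 6!6!/12! = 2/924
        assert rc.p == pytest.approx(2 / 924, rel=1e-9)

    def test_small_group_rejected_for_t(self):
        bm, ann, region, manifest = self._fixture(0.7, 0.5, n=6)
        mf = manifest.frame.drop(index=manifest.frame.index[-5:])
        small = sm.SampleManifest(mf)
        with pytest.raises(ValueError, match="TC"):
            region_summary(bm, ann, region, small)
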