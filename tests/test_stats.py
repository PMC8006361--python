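"""Statistical battery: rank tests, agreement, ROC/Youden/DeLong, ICC —
each checked against an independent oracle (hand computation, scipy,
sklearn, pingouin, bootstrap, permutation or closed form)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cmrperf.stats import (
    binormal_auc,
    bland_altman,
    delong_compare,
    dunn_posthoc,
    friedman_test,
    icc_oneway,
    ischemic_burden,
    regress_vs_reference,
    roc_analysis,
    run_location_comparison,
)


class TestFriedman:
    def test_identical_columns_null(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 4))
        stat, p = friedman_test(x)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_4x3_table(self):
        """Statistic equals 12/(nk(k+1)) * sum(Rj^2) - 3n(k+1) on a
        tie-free table, computed by hand from the rank sums."""
        x = np.array([[1.0, 2.0, 3.0],
                      [2.0, 3.0, 1.0],
                      [1.0, 3.0, 2.0],
                      [1.0, 2.0, 3.0]])
        ranks = np.apply_along_axis(sps.rankdata, 1, x)
        rj = ranks.sum(axis=0)
        expected = 12.0 / (4 * 3 * 4) * np.sum(rj**2) - 3 * 4 * 4
        stat, _ = friedman_test(x)
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        x = rng.normal(size=(20, 5)) + rng.normal(size=(20, 1))
        stat, p = friedman_test(x)
        ref_stat, ref_p = sps.friedmanchisquare(*[x[:, j] for j in range(5)])
        assert stat == pytest.approx(ref_stat, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_permutation_null_calibration(self, rng):
        """Under within-block permutation the statistic matches the
        chi-square null: the exact small-sample mean is k-1."""
        k, n = 3, 6
        stats_ = []
        for _ in range(2000):
            x = np.array([rng.permutation([1.0, 2.0, 3.0]) for _ in range(n)])
            stats_.append(friedman_test(x)[0])
        assert np.mean(stats_) == pytest.approx(k - 1, abs=0.15)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((2, 4)))


class TestDunn:
    def test_family_size_and_cap(self, rng):
        x = rng.normal(size=(25, 5))
        p = dunn_posthoc(x)
        iu = np.triu_indices(5, 1)
        assert len(p[iu]) == 10
        assert np.all(p[iu] <= 1.0)
        np.testing.assert_allclose(p, p.T, equal_nan=True)

    def test_identical_columns_all_one(self):
        x = np.tile(np.arange(8.0)[:, None], (1, 5))
        p = dunn_posthoc(x)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(p[iu], 1.0)

    def test_bonferroni_is_min_one_c_times_raw(self, rng):
        """Adjusted p equals min(1, 10 x raw p) recomputed from the z."""
        x = rng.normal(size=(30, 5)) + np.linspace(0, 1, 5)
        adj = dunn_posthoc(x)
        ranks = np.apply_along_axis(sps.rankdata, 1, x)
        mean_ranks = ranks.mean(axis=0)
        n, k = x.shape
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        for i in range(5):
            for j in range(i + 1, 5):
                z = (mean_ranks[i] - mean_ranks[j]) / se
                raw = 2 * sps.norm.sf(abs(z))
                assert adj[i, j] == pytest.approx(min(1.0, 10 * raw), rel=1e-9)


class TestAgreement:
    def test_perfect_identity(self):
        x = np.linspace(1, 4, 50)
        slope, ci, r2, p = regress_vs_reference(x, x)
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert ci[0] == pytest.approx(1.0) and ci[1] == pytest.approx(1.0)

    def test_attenuated_slope(self, rng):
        x = np.linspace(1, 4, 400)
        y = 0.9 * x + rng.normal(0, 1e-6, 400)
        slope, _, _, _ = regress_vs_reference(x, y)
        assert slope == pytest.approx(0.9, abs=1e-4)

    def test_r2_at_configured_correlation(self, rng):
        """n=400 pairs at correlation 0.93 give R^2 near 0.86."""
        z = rng.normal(size=400)
        e = rng.normal(size=400)
        rho = 0.93
        x, y = z, rho * z + np.sqrt(1 - rho**2) * e
        _, _, r2, _ = regress_vs_reference(x, y)
        assert r2 == pytest.approx(rho**2, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regress_vs_reference(np.ones(10), np.arange(10.0))

    def test_bland_altman_identity_and_offset(self):
        x = np.linspace(0, 5, 30)
        bias, loa = bland_altman(x, x)
        assert bias == 0.0 and loa == 0.0
        bias, _ = bland_altman(x, x + 0.5)
        assert bias == pytest.approx(0.5)

    def test_bias_sign_convention(self, rng):
        """A location reading consistently below the reference has a
        negative bias (overestimation would be positive)."""
        ref = rng.uniform(1, 4, 200)
        lower = ref - 0.19 + rng.normal(0, 0.05, 200)
        bias, _ = bland_altman(ref, lower)
        assert bias < 0


class TestRoc:
    def test_perfect_separation(self):
        values = np.r_[np.full(10, 1.0), np.full(20, 3.0)]
        labels = np.r_[["abnormal"] * 10, ["normal"] * 20]
        r = roc_analysis(values, labels)
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_youden_from_sens_spec(self):
        # J = sens + spec - 1 by definition: 0.80 + 0.85 - 1 = 0.65
        values = np.r_[np.full(80, 1.0), np.full(20, 3.0), np.full(255, 3.0), np.full(45, 1.0)]
        labels = np.r_[["abnormal"] * 100, ["normal"] * 300]
        r = roc_analysis(values, labels)
        assert r.sensitivity == pytest.approx(0.80)
        assert r.specificity == pytest.approx(0.85)
        assert r.youden_j == pytest.approx(0.65)

    def test_auc_equals_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.normal(2, 0.7, 300)
        labels = np.where(rng.uniform(size=300) < 0.3, "abnormal", "normal")
        values[labels == "abnormal"] -= 0.6
        r = roc_analysis(values, labels)
        ref = roc_auc_score((labels == "abnormal").astype(int), -values)
        assert r.auc == pytest.approx(ref, abs=1e-12)

    def test_auc_equals_mann_whitney(self, rng):
        values = np.round(rng.normal(2, 0.5, 200), 1)  # induce ties
        labels = np.where(rng.uniform(size=200) < 0.25, "abnormal", "normal")
        values[labels == "abnormal"] -= 0.5
        r = roc_analysis(values, labels)
        pos = -values[labels == "abnormal"]
        neg = -values[labels == "normal"]
        u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert r.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_youden_cutoff_equals_brute_force(self, rng):
        """Exhaustive threshold search oracle on many random instances."""
        for _ in range(20):
            values = np.round(rng.normal(2, 0.6, 120), 1)
            labels = np.where(rng.uniform(size=120) < 0.3, "abnormal", "normal")
            values[labels == "abnormal"] -= rng.uniform(0.2, 0.8)
            r = roc_analysis(values, labels)
            pos = labels == "abnormal"
            best = (-np.inf, -np.inf, np.nan)
            for c in np.unique(values):
                sens = np.mean(values[pos] <= c)
                spec = np.mean(values[~pos] > c)
                j = sens + spec - 1
                if (j, spec) > (best[0], best[1]):
                    best = (j, spec, c)
            assert r.cutoff == best[2]
            assert r.youden_j == pytest.approx(best[0], abs=1e-12)

    def test_inclusive_rule_cutoff_is_attained_datum(self, rng):
        values = np.round(rng.normal(2, 0.6, 100), 2)
        labels = np.where(rng.uniform(size=100) < 0.3, "abnormal", "normal")
        values[labels == "abnormal"] -= 0.5
        r = roc_analysis(values, labels)
        assert r.cutoff in values

    def test_direction_invariance(self, rng):
        """Negating the predictor and flipping the rule is handled by
        construction: AUC on -x with high-positive orientation matches."""
        from sklearn.metrics import roc_auc_score

        values = rng.normal(size=150)
        labels = np.where(rng.uniform(size=150) < 0.4, "abnormal", "normal")
        values[labels == "abnormal"] -= 1.0
        r = roc_analysis(values, labels)
        y = (labels == "abnormal").astype(int)
        assert r.auc == pytest.approx(roc_auc_score(1 - y, values), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.array(["normal"] * 5))

    def test_binormal_closed_form(self, rng):
        """Large-sample AUC matches Phi(delta/sqrt(s0^2+s1^2))."""
        n0, n1 = 30000, 10000
        neg = rng.normal(2.4, 0.5, n0)
        pos = rng.normal(1.7, 0.5, n1)
        values = np.r_[neg, pos]
        labels = np.r_[["normal"] * n0, ["abnormal"] * n1]
        r = roc_analysis(values, labels)
        closed = binormal_auc(2.4, 1.7, 0.5, 0.5)
        assert closed == pytest.approx(sps.norm.cdf(0.7 / np.sqrt(0.5)), rel=1e-12)
        assert r.auc == pytest.approx(closed, abs=0.01)


class TestDeLong:
    def _sample(self, rng, n=150, shift=0.8):
        labels = np.where(rng.uniform(size=n) < 0.35, "abnormal", "normal")
        a = rng.normal(2, 0.5, n)
        b = 0.7 * a + rng.normal(0, 0.35, n)
        a[labels == "abnormal"] -= shift
        b[labels == "abnormal"] -= 0.5 * shift
        return a, b, labels

    def test_identical_rocs_p_one(self, rng):
        a, _, labels = self._sample(rng)
        r = roc_analysis(a, labels)
        assert delong_compare(r, r) == 1.0

    def test_paired_variance_matches_bootstrap(self, rng):
        """DeLong variance of the AUC difference within 15% of a
        2000-replicate paired bootstrap."""
        a, b, labels = self._sample(rng, n=300)
        ra, rb = roc_analysis(a, labels), roc_analysis(b, labels)
        # recover the implied variance from the reported p-value
        p = delong_compare(ra, rb)
        z = sps.norm.isf(p / 2)
        var_delong = ((ra.auc - rb.auc) / z) ** 2
        idx = np.arange(len(a))
        diffs = []
        for _ in range(2000):
            s = rng.choice(idx, size=len(idx), replace=True)
            ls = labels[s]
            if len(np.unique(ls)) < 2:
                continue
            diffs.append(roc_analysis(a[s], ls).auc - roc_analysis(b[s], ls).auc)
        var_boot = np.var(diffs, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)

    def test_unpaired_variance_is_sum(self, rng):
        a, _, la = self._sample(rng, n=200)
        b, _, lb = self._sample(rng, n=180)
        ra, rb = roc_analysis(a, la), roc_analysis(b, lb)
        p = delong_compare(ra, rb, paired=False)
        z = sps.norm.isf(p / 2)
        implied = ((ra.auc - rb.auc) / z) ** 2
        assert implied == pytest.approx(ra.auc_variance + rb.auc_variance, rel=1e-6)

    def test_paired_requires_same_cases(self, rng):
        a, _, la = self._sample(rng, n=100)
        b, _, lb = self._sample(rng, n=90)
        with pytest.raises(ValueError):
            delong_compare(roc_analysis(a, la), roc_analysis(b, lb), paired=True)


class TestIcc:
    def test_perfect_clustering(self):
        values = np.repeat([1.0, 5.0, 9.0], 8)
        ids = np.repeat([0, 1, 2], 8)
        assert icc_oneway(values, ids) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_destroys_clustering(self, rng):
        values = np.repeat(rng.normal(size=20), 16) + rng.normal(0, 0.5, 320)
        ids = np.repeat(np.arange(20), 16)
        high = icc_oneway(values, ids)
        perm = [icc_oneway(rng.permutation(values), ids) for _ in range(200)]
        assert high > 0.5
        assert abs(np.mean(perm)) < 0.05

    def test_matches_pingouin_balanced(self, rng):
        import pingouin as pg

        values = np.repeat(rng.normal(size=12), 6) + rng.normal(0, 1, 72)
        ids = np.repeat(np.arange(12), 6)
        df = pd.DataFrame(
            {"targets": ids, "raters": np.tile(np.arange(6), 12), "ratings": values}
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert icc_oneway(values, ids) == pytest.approx(icc1, abs=1e-10)

    def test_anova_decomposition_oracle(self, rng):
        """Balanced design: direct sums-of-squares reproduction."""
        a, k = 10, 5
        values = np.repeat(rng.normal(size=a), k) + rng.normal(0, 1, a * k)
        ids = np.repeat(np.arange(a), k)
        grand = values.mean()
        groups = values.reshape(a, k)
        msb = k * np.sum((groups.mean(axis=1) - grand) ** 2) / (a - 1)
        msw = np.sum((groups - groups.mean(axis=1, keepdims=True)) ** 2) / (a * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        assert icc_oneway(values, ids) == pytest.approx(expected, abs=1e-10)

    def test_singleton_clusters_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.arange(4.0), np.arange(4))


class TestIschemicBurden:
    def _segments(self, mbf):
        return pd.DataFrame(
            {"patient": 0, "segment": np.arange(1, 17), "stress_mbf": mbf}
        )

    def test_none_below_cutoff(self):
        b = ischemic_burden(self._segments(np.full(16, 3.0)), cutoff=2.0)
        assert b.iloc[0] == 0.0

    def test_quarter_below_cutoff(self):
        mbf = np.full(16, 3.0)
        mbf[:4] = 1.5
        b = ischemic_burden(self._segments(mbf), cutoff=2.0)
        assert b.iloc[0] == 25.0

    def test_offset_locations_fixed_cutoff_differ(self):
        """Systematically offset MBF with one fixed cutoff changes the
        apparent burden — the transferability failure."""
        mbf = np.linspace(1.5, 3.0, 16)
        low = ischemic_burden(self._segments(mbf), cutoff=2.02)
        high = ischemic_burden(self._segments(mbf + 0.6), cutoff=2.02)
        assert low.iloc[0] > high.iloc[0]

    def test_missing_segments_listed(self):
        df = self._segments(np.full(16, 2.0)).iloc[:-2]
        with pytest.raises(ValueError, match=r"15"):
            ischemic_burden(df, cutoff=1.0)


@st.composite
def _roc_instance(draw):
    n = draw(st.integers(min_value=12, max_value=60))
    vals = draw(
        st.lists(st.integers(min_value=0, max_value=15), min_size=n, max_size=n)
    )
    labs = draw(
        st.lists(st.sampled_from(["normal", "abnormal"]), min_size=n, max_size=n)
    )
    return np.asarray(vals, float) / 3.0, np.asarray(labs)


@given(_roc_instance())
@settings(max_examples=60, deadline=None)
def test_youden_brute_force_property(instance):
    """Property: the reported cutoff attains the maximal J over every
    observed threshold on arbitrary tied integer-valued data."""
    values, labels = instance
    pos = labels == "abnormal"
    if pos.all() or (~pos).all():
        return
    r = roc_analysis(values, labels)
    js = []
    for c in np.unique(values):
        js.append(np.mean(values[pos] <= c) + np.mean(values[~pos] > c) - 1)
    assert r.youden_j == pytest.approx(max(js), abs=1e-12)


class TestRunLocationComparison:
    def _null_table(self, rng):
        rows = []
        for pid in range(12):
            base_s = rng.lognormal(np.log(2.2), 0.2, 16)
            base_r = rng.lognormal(0.0, 0.15, 16)
            labels = np.where(np.arange(16) < 4, "abnormal", "normal")
            base_s[labels == "abnormal"] *= 0.7
            for loc in ("LA", "bLV", "mLV", "aLV", "AoR"):
                noise = 1 + rng.normal(0, 1e-3, 16)
                for seg in range(16):
                    s = base_s[seg] * noise[seg]
                    r = base_r[seg]
                    rows.append(
                        {
                            "patient": pid,
                            "segment": seg + 1,
                            "location": loc,
                            "stress_mbf": s,
                            "rest_mbf": r,
                            "mpr": s / r,
                            "label": labels[seg],
                        }
                    )
        return pd.DataFrame(rows)

    def test_null_configuration_no_location_differences(self, rng):
        """Near-identical locations: Dunn-adjusted p saturate at 1 and
        paired AUC comparisons are non-significant."""
        report = run_location_comparison(self._null_table(rng))
        dunn = report.dunn[("stress_mbf", "normal")].to_numpy()
        iu = np.triu_indices(5, 1)
        assert np.nanmin(dunn[iu]) > 0.2
        assert report.delong["stress_mbf"].to_numpy()[iu].min() > 0.2

    def test_report_shape_and_families(self, rng):
        report = run_location_comparison(self._null_table(rng))
        assert len(report.roc) == 10  # 5 locations x 2 metrics
        assert len(report.group_summaries) == 20
        assert set(report.delong) == {"stress_mbf", "mpr"}
        assert len(report.delong_cross_metric) == 5
        assert set(report.icc) == {"LA", "bLV", "mLV", "aLV", "AoR"}
        burdens = report.ischemic_burden_aor_cutoff
        assert burdens.shape == (12, 10)  # patients x (2 metrics x 5 locations)
        js = report.to_json_dict()
        assert "roc" in js and "friedman" in js
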