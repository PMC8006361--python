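"""Diagnostic-accuracy statistics for comparing AIF sampling locations.

Within-subject comparisons across the five locations use Friedman's
two-way analysis of variance by ranks with Dunn-Bonferroni post-hoc
tests; agreement with the clinical reference (basal LV) uses ordinary
least squares and Bland-Altman limits of agreement; diagnostic accuracy
against expert labels uses ROC analysis with Youden-index cutoffs and
paired DeLong comparisons of AUCs; the intraclass correlation
coefficient quantifies intra-patient clustering of segments.

Conventions fixed throughout (they match the clinical reporting):
abnormal perfusion is the positive class, *low* predictor values call a
segment positive, and the optimal cutoff is inclusive (value <= cutoff
is positive), so the reported cutoff is an attainable datum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocResult",
    "AgreementResult",
    "DiagnosticReport",
    "friedman_test",
    "dunn_posthoc",
    "regress_vs_reference",
    "bland_altman",
    "roc_analysis",
    "delong_compare",
    "icc_oneway",
    "ischemic_burden",
    "run_location_comparison",
    "binormal_auc",
]

POSITIVE_LABEL = "abnormal"
REFERENCE_LOCATION = "bLV"


# --------------------------------------------------------------------------
# rank-based group contrasts
# --------------------------------------------------------------------------

def _block_ranks(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, x)


def friedman_test(block_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman two-way ANOVA by ranks with tie correction.

    ``block_matrix`` is (n_blocks, k_treatments); blocks containing NaN
    are dropped. Returns (chi-square statistic, p) with k-1 degrees of
    freedom. Identical treatments in every block give statistic 0, p 1.
    """
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an (n_blocks, k>=2) matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete blocks")
    ranks = _block_ranks(x)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0, 1.0
    stat = stat / denom
    stat = max(stat, 0.0)
    return float(stat), float(sps.chi2.sf(stat, k - 1))


def dunn_posthoc(block_matrix: np.ndarray) -> np.ndarray:
    """Dunn's pairwise tests on Friedman ranks, Bonferroni-adjusted.

    Returns a symmetric (k, k) matrix of two-sided p-values multiplied
    by C = k(k-1)/2 and capped at 1; the diagonal is NaN.
    """
    x = np.asarray(block_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an (n_blocks, k>=2) matrix")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete blocks")
    ranks = _block_ranks(x)
    mean_ranks = ranks.mean(axis=0)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    se2 = k * (k + 1) / (6.0 * n) - ties / (6.0 * n * k * (k - 1))
    c_family = k * (k - 1) // 2
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            if se2 <= 0:
                praw = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
                praw = 2.0 * sps.norm.sf(abs(z))
            p[i, j] = p[j, i] = min(1.0, c_family * praw)
    return p


# --------------------------------------------------------------------------
# agreement with the reference location
# --------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """OLS and Bland-Altman agreement of one location against the
    reference. Positive bias means the location overestimates it."""

    slope: float
    slope_ci: tuple[float, float]
    r_squared: float
    p_value: float
    bias: float
    loa_half_width: float  # 1.96 * SD of the differences
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "bias": self.bias,
            "loa_half_width": self.loa_half_width,
            "n": self.n,
        }


def regress_vs_reference(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], float, float]:
    """OLS of y on the reference x: slope, 95% CI (t), R^2, slope p."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("reference values have zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)[1]
    return float(model.params[1]), (float(ci[0]), float(ci[1])), float(model.rsquared), float(
        model.pvalues[1]
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Bias (mean of y - x) and limit-of-agreement half-width 1.96*SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    d = y[ok] - x[ok]
    if len(d) < 2:
        raise ValueError("need at least 2 paired values")
    return float(np.mean(d)), float(1.96 * np.std(d, ddof=1))


# --------------------------------------------------------------------------
# ROC / Youden / DeLong
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC summary with the DeLong placement values kept for pairing."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    cutoff: float
    n_pos: int
    n_neg: int
    direction: str = "<= cutoff -> abnormal"
    v_pos: np.ndarray = field(default=None, repr=False)  # placements of positives
    v_neg: np.ndarray = field(default=None, repr=False)
    pos_index: np.ndarray = field(default=None, repr=False)
    neg_index: np.ndarray = field(default=None, repr=False)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def auc_variance(self) -> float:
        return float(
            np.var(self.v_pos, ddof=1) / self.n_pos + np.var(self.v_neg, ddof=1) / self.n_neg
        )

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cutoff": self.cutoff,
            "youden_j": self.youden_j,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "direction": self.direction,
        }


def _placements(score_pos: np.ndarray, score_neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values with half credit for ties (higher score
    = more positive)."""
    m, n = len(score_pos), len(score_neg)
    allv = np.concatenate([score_pos, score_neg])
    rank_all = sps.rankdata(allv)
    rank_pos = sps.rankdata(score_pos)
    rank_neg = sps.rankdata(score_neg)
    v_pos = (rank_all[:m] - rank_pos) / n
    v_neg = 1.0 - (rank_all[m:] - rank_neg) / m
    return v_pos, v_neg


def roc_analysis(values: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC with low values predicting the abnormal (positive) class.

    AUC is the Mann-Whitney statistic (half credit for ties) on the
    negated predictor; its 95% CI uses the DeLong variance with a normal
    approximation. The cutoff maximizes Youden's J over the observed
    values under the inclusive rule (value <= cutoff is positive), with
    J ties broken toward higher specificity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    index = np.flatnonzero(ok)
    pos = labels == POSITIVE_LABEL
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    # low value -> positive: negate so that higher score = more positive
    score = -values
    v_pos, v_neg = _placements(score[pos], score[~pos])
    auc = float(v_pos.mean())
    n1, n0 = int(pos.sum()), int((~pos).sum())
    var = np.var(v_pos, ddof=1) / n1 + np.var(v_neg, ddof=1) / n0
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (auc - half, auc + half)

    # Youden search over observed thresholds (inclusive rule)
    cands = np.unique(values)
    best = (-np.inf, -np.inf, np.nan, np.nan, np.nan)  # J, specificity, cutoff, sens, spec
    for c in cands:
        called_pos = values <= c
        sens = np.mean(called_pos[pos])
        spec = np.mean(~called_pos[~pos])
        j = sens + spec - 1.0
        if (j, spec) > (best[0], best[1]):
            best = (j, spec, c, sens, spec)
    _, _, cutoff, sens, spec = best
    return RocResult(
        auc,
        ci,
        float(sens),
        float(spec),
        float(cutoff),
        n1,
        n0,
        v_pos=v_pos,
        v_neg=v_neg,
        pos_index=index[pos],
        neg_index=index[~pos],
    )


def delong_compare(roc_a: RocResult, roc_b: RocResult, paired: bool = True) -> float:
    """Two-sided DeLong test of AUC_a == AUC_b.

    Paired comparisons require the two ROCs to come from the same cases
    in the same order; the covariance of the AUC estimates is then
    estimated from the placement values. Unpaired comparisons sum the
    two DeLong variances. Identical placements give p = 1.
    """
    if paired:
        same = (
            roc_a.n_pos == roc_b.n_pos
            and roc_a.n_neg == roc_b.n_neg
            and np.array_equal(roc_a.pos_index, roc_b.pos_index)
            and np.array_equal(roc_a.neg_index, roc_b.neg_index)
        )
        if not same:
            raise ValueError("paired DeLong comparison requires identical case sets")
        m, n = roc_a.n_pos, roc_a.n_neg
        s10 = np.cov(roc_a.v_pos, roc_b.v_pos, ddof=1)
        s01 = np.cov(roc_a.v_neg, roc_b.v_neg, ddof=1)
        var = s10[0, 0] / m + s01[0, 0] / n + s10[1, 1] / m + s01[1, 1] / n
        cov = s10[0, 1] / m + s01[0, 1] / n
        var_diff = var - 2.0 * cov
    else:
        var_diff = roc_a.auc_variance + roc_b.auc_variance
    diff = roc_a.auc - roc_b.auc
    if var_diff <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2.0 * sps.norm.sf(abs(z)))


def binormal_auc(mu_neg: float, mu_pos: float, sd_neg: float, sd_pos: float) -> float:
    """Closed-form AUC when both classes are normal and low values are
    positive: Phi((mu_neg - mu_pos) / sqrt(sd_neg^2 + sd_pos^2))."""
    return float(sps.norm.cdf((mu_neg - mu_pos) / np.hypot(sd_neg, sd_pos)))


# --------------------------------------------------------------------------
# clustering and burden
# --------------------------------------------------------------------------

def icc_oneway(values: np.ndarray, cluster_ids: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) for possibly unbalanced clusters.

    ICC = (MSB - MSW) / (MSB + (k_bar - 1) MSW) with the standard
    unbalanced-design average cluster size
    k_bar = (N - sum(n_i^2)/N) / (a - 1). Negative estimates are
    reported as computed.
    """
    values = np.asarray(values, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    ok = np.isfinite(values)
    values, cluster_ids = values[ok], cluster_ids[ok]
    clusters = pd.Series(values).groupby(pd.Series(cluster_ids)).agg(["mean", "count"])
    a = len(clusters)
    n_i = clusters["count"].to_numpy(dtype=float)
    if a < 2:
        raise ValueError("need at least 2 clusters")
    if np.all(n_i < 2):
        raise ValueError("need at least one cluster with >= 2 members")
    n_total = n_i.sum()
    grand = values.mean()
    ssb = float(np.sum(n_i * (clusters["mean"].to_numpy() - grand) ** 2))
    ssw = float(np.sum((values - pd.Series(cluster_ids).map(clusters["mean"]).to_numpy()) ** 2))
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    k_bar = (n_total - np.sum(n_i**2) / n_total) / (a - 1)
    return float((msb - msw) / (msb + (k_bar - 1) * msw))


def ischemic_burden(
    segments: pd.DataFrame, cutoff: float, metric: str = "stress_mbf"
) -> pd.Series:
    """Percent of each patient's 16 segments at or below ``cutoff``.

    ``segments`` is a tidy table for a single location with columns
    (patient, segment, <metric>). Missing segments raise with a listing.
    """
    if metric not in segments.columns:
        raise ValueError(f"no column {metric!r}")
    expected = set(range(1, 17))
    out = {}
    for pid, grp in segments.groupby("patient"):
        missing = expected - set(grp["segment"])
        if missing:
            raise ValueError(f"patient {pid} missing segments {sorted(missing)}")
        out[pid] = 100.0 * float((grp[metric] <= cutoff).sum()) / 16.0
    return pd.Series(out, name=f"{metric}_burden_pct")


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """The full five-location comparison for stress MBF and MPR."""

    group_summaries: pd.DataFrame  # median/IQR by metric, location, label
    friedman: dict  # (metric, label) -> (stat, p)
    dunn: dict  # (metric, label) -> DataFrame (location x location)
    agreement: dict  # (metric, location) -> AgreementResult
    roc: dict  # (metric, location) -> RocResult
    delong: dict  # metric -> DataFrame of Bonferroni-adjusted p
    delong_cross_metric: pd.Series  # per location, stress MBF vs MPR (x5)
    icc: dict  # location -> ICC of stress MBF clustered by patient
    ischemic_burden_aor_cutoff: pd.DataFrame  # per patient x location

    def to_json_dict(self) -> dict:
        return {
            "group_summaries": self.group_summaries.to_dict(orient="records"),
            "friedman": {f"{m}|{g}": list(v) for (m, g), v in self.friedman.items()},
            "dunn": {f"{m}|{g}": df.to_dict() for (m, g), df in self.dunn.items()},
            "agreement": {f"{m}|{L}": a.to_dict() for (m, L), a in self.agreement.items()},
            "roc": {f"{m}|{L}": r.to_dict() for (m, L), r in self.roc.items()},
            "delong": {m: df.to_dict() for m, df in self.delong.items()},
            "delong_cross_metric": self.delong_cross_metric.to_dict(),
            "icc": dict(self.icc),
            "ischemic_burden_aor_cutoff": {
                "|".join(map(str, col)) if isinstance(col, tuple) else str(col): ser.to_dict()
                for col, ser in self.ischemic_burden_aor_cutoff.items()
            },
        }


def _location_block(segments: pd.DataFrame, metric: str, locations: list[str]) -> np.ndarray:
    """(n_segments, k_locations) matrix blocked by (patient, segment)."""
    wide = segments.pivot_table(
        index=["patient", "segment"], columns="location", values=metric, aggfunc="first"
    )
    return wide[locations].to_numpy(dtype=float)


def run_location_comparison(
    segments: pd.DataFrame,
    locations: tuple[str, ...] = ("LA", "bLV", "mLV", "aLV", "AoR"),
    metrics: tuple[str, ...] = ("stress_mbf", "mpr"),
) -> DiagnosticReport:
    """Run the whole statistical battery on a tidy segment table.

    ``segments`` has columns (patient, segment, location, stress_mbf,
    rest_mbf, mpr, label). Bonferroni families: the 10 location pairs
    within each metric; the 5 same-location stress-MBF-vs-MPR
    comparisons form their own family.
    """
    need = {"patient", "segment", "location", "label"} | set(metrics)
    if not need.issubset(segments.columns):
        raise ValueError(f"segment table lacks columns {sorted(need - set(segments.columns))}")
    locations = list(locations)

    summaries = []
    friedman: dict = {}
    dunn: dict = {}
    agreement: dict = {}
    roc: dict = {}
    delong: dict = {}

    for metric in metrics:
        for label in ("normal", "abnormal"):
            sub = segments[segments["label"] == label]
            for loc in locations:
                v = sub.loc[sub["location"] == loc, metric].dropna()
                summaries.append(
                    {
                        "metric": metric,
                        "location": loc,
                        "label": label,
                        "median": float(v.median()),
                        "q1": float(v.quantile(0.25)),
                        "q3": float(v.quantile(0.75)),
                        "n": int(len(v)),
                    }
                )
            block = _location_block(sub, metric, locations)
            friedman[(metric, label)] = friedman_test(block)
            dunn[(metric, label)] = pd.DataFrame(
                dunn_posthoc(block), index=locations, columns=locations
            )

        wide = segments.pivot_table(
            index=["patient", "segment", "label"],
            columns="location",
            values=metric,
            aggfunc="first",
        ).reset_index()
        # paired analyses (regression, Bland-Altman, DeLong) need one
        # common case set: drop segments missing at any location
        wide = wide.dropna(subset=locations).reset_index(drop=True)
        ref = wide[REFERENCE_LOCATION].to_numpy(dtype=float)
        for loc in locations:
            if loc == REFERENCE_LOCATION:
                continue
            other = wide[loc].to_numpy(dtype=float)
            slope, ci, r2, p = regress_vs_reference(ref, other)
            bias, loa = bland_altman(ref, other)
            agreement[(metric, loc)] = AgreementResult(slope, ci, r2, p, bias, loa, len(ref))

        for loc in locations:
            roc[(metric, loc)] = roc_analysis(
                wide[loc].to_numpy(dtype=float), wide["label"].to_numpy()
            )

        k = len(locations)
        fam = k * (k - 1) // 2
        mat = pd.DataFrame(np.nan, index=locations, columns=locations)
        for i in range(k):
            for j in range(i + 1, k):
                p = delong_compare(roc[(metric, locations[i])], roc[(metric, locations[j])])
                mat.iloc[i, j] = mat.iloc[j, i] = min(1.0, fam * p)
        delong[metric] = mat

    cross = {}
    if set(metrics) >= {"stress_mbf", "mpr"}:
        for loc in locations:
            p = delong_compare(roc[("stress_mbf", loc)], roc[("mpr", loc)])
            cross[loc] = min(1.0, len(locations) * p)
    cross = pd.Series(cross, name="delong_stress_vs_mpr_p")

    icc = {}
    for loc in locations:
        sub = segments[segments["location"] == loc]
        icc[loc] = icc_oneway(
            sub["stress_mbf"].to_numpy(dtype=float), sub["patient"].to_numpy()
        )

    burdens = {}
    for metric in metrics:
        cutoff = roc[(metric, "AoR")].cutoff if ("AoR" in locations) else np.nan
        per_loc = {}
        for loc in locations:
            sub = segments[segments["location"] == loc]
            per_loc[loc] = ischemic_burden(sub, cutoff, metric)
        burdens[metric] = pd.DataFrame(per_loc)
    burden_df = pd.concat(burdens, axis=1)

    return DiagnosticReport(
        pd.DataFrame(summaries),
        friedman,
        dunn,
        agreement,
        roc,
        delong,
        cross,
        icc,
        burden_df,
    )
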