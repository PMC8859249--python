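"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q, the Egger intercept test, a simulation-based residual
sum-of-squares global/outlier/distortion battery (MR-PRESSO style),
leave-one-out estimates, and funnel-plot data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tsmr.harmonization import HarmonizedSet
from tsmr.mr_estimators import MREstimate, RatioSet, _estimate, egger, ivw, wald_ratios


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outliers: list[str]
    outlier_pvals: dict[str, float]
    raw: MREstimate
    corrected: MREstimate
    distortion_pval: float | None


@dataclass
class PleiotropyReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: MREstimate
    presso: PressoResult | None
    loo_series: list[MREstimate]
    funnel_points: list[tuple[str, float, float]]
    funnel_reference: float

    def to_dict(self) -> dict:
        return {
            "cochran_q": {"q": self.q_stat, "df": self.q_df, "pval": self.q_pval},
            "egger_intercept": self.egger_intercept.to_dict(),
            "mr_presso": None
            if self.presso is None
            else {
                "global_rss": self.presso.global_rss,
                "global_pval": self.presso.global_pval,
                "outliers": self.presso.outliers,
                "outlier_pvals": self.presso.outlier_pvals,
                "raw": self.presso.raw.to_dict(),
                "corrected": self.presso.corrected.to_dict(),
                "distortion_pval": self.presso.distortion_pval,
            },
            "leave_one_out": [e.to_dict() for e in self.loo_series],
            "funnel": {
                "points": [
                    {"snp_id": s, "ratio": r, "precision": p}
                    for s, r, p in self.funnel_points
                ],
                "reference": self.funnel_reference,
            },
        }


def cochran_q(r: RatioSet, theta: float) -> tuple[float, int, float]:
    """Cochran's Q of the ratio set around ``theta``.

    Q = sum_j w_j (ratio_j - theta)^2, p from the chi-square upper tail
    with J-1 degrees of freedom.
    """
    j = len(r)
    if j < 2:
        raise ValueError(f"Cochran's Q requires >= 2 SNPs, got {j}")
    q = float((r.weight * (r.ratio - theta) ** 2).sum())
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p) of the MR-Egger intercept z-test."""
    _, intercept = egger(h)
    return intercept.beta, intercept.se, intercept.pval


def _loo_thetas(ratio: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized over the last axis."""
    s_w = weight.sum(axis=-1, keepdims=True)
    s_wb = (weight * ratio).sum(axis=-1, keepdims=True)
    return (s_wb - weight * ratio) / (s_w - weight)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_sig: float = 0.05,
) -> PressoResult:
    """Simulation-based pleiotropy residual-sum and outlier battery.

    1. Global test: the observed weighted residual sum of squares around
       leave-one-out IVW predictions is compared with ``n_sim`` parametric
       simulations under the no-pleiotropy null; the p-value is the
       upper-tail proportion with a +1/(n_sim+1) continuity correction.
    2. Outlier test: each SNP's observed residual against its simulated
       distribution, Bonferroni-adjusted across SNPs.
    3. Corrected estimate: fixed-effect IVW after removing flagged SNPs.
    4. Distortion test: the raw-vs-corrected difference against a null of
       removing equally many random SNPs.
    """
    bx, sx, by, sy = h.arrays()
    j = bx.size
    if j < 4:
        raise ValueError(f"MR-PRESSO requires >= 4 SNPs, got {j}")
    snp_ids = h.snp_ids()
    rng = np.random.default_rng(seed)

    w_out = 1.0 / sy**2
    ratio = by / bx
    weight = bx**2 / sy**2
    theta_loo = _loo_thetas(ratio, weight)
    resid_obs = w_out * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    # parametric simulations under the null of no pleiotropy
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    ratio_star = by_star / bx_star
    weight_star = bx_star**2 / sy**2
    theta_loo_star = _loo_thetas(ratio_star, weight_star)
    resid_star = w_out * (by_star - theta_loo_star * bx_star) ** 2
    rss_star = resid_star.sum(axis=1)

    n_ge = int((rss_star >= rss_obs).sum())
    global_pval = (n_ge + 1.0) / (n_sim + 1.0)

    # per-SNP outlier p-values, Bonferroni-adjusted
    per_snp_ge = (resid_star >= resid_obs).sum(axis=0)
    per_snp_p = (per_snp_ge + 1.0) / (n_sim + 1.0)
    adj_p = np.minimum(1.0, per_snp_p * j)
    outlier_pvals = {snp_ids[k]: float(adj_p[k]) for k in range(j)}
    outliers = [snp_ids[k] for k in range(j) if adj_p[k] < outlier_sig]

    raw = ivw(h, model="fixed")
    if len(outliers) == j:
        raise ValueError("no stable subset: every SNP flagged as an outlier")

    if outliers:
        corrected = ivw(h.drop(outliers), model="fixed")
        diff_obs = raw.beta - corrected.beta
        n_out = len(outliers)
        null_diffs = np.empty(n_sim)
        all_idx = np.arange(j)
        s_w, s_wb = weight.sum(), (weight * ratio).sum()
        for i in range(n_sim):
            drop = rng.choice(all_idx, size=n_out, replace=False)
            theta_sub = (s_wb - (weight[drop] * ratio[drop]).sum()) / (
                s_w - weight[drop].sum()
            )
            null_diffs[i] = raw.beta - theta_sub
        n_extreme = int((np.abs(null_diffs) >= abs(diff_obs)).sum())
        distortion_pval = (n_extreme + 1.0) / (n_sim + 1.0)
    else:
        corrected = raw
        distortion_pval = None

    return PressoResult(
        global_rss=rss_obs,
        global_pval=float(global_pval),
        outliers=outliers,
        outlier_pvals=outlier_pvals,
        raw=raw,
        corrected=corrected,
        distortion_pval=distortion_pval,
    )


def leave_one_out(h: HarmonizedSet) -> list[MREstimate]:
    """Fixed-effect IVW omitting each SNP in turn, in input order."""
    kept = h.kept_records
    if len(kept) < 3:
        raise ValueError(f"leave-one-out requires >= 3 SNPs, got {len(kept)}")
    r = wald_ratios(h)
    ratio, weight = r.ratio, r.weight
    theta_loo = _loo_thetas(ratio, weight)
    se_loo = (weight.sum() - weight) ** -0.5
    return [
        _estimate(f"loo_without_{snp}", theta_loo[k], se_loo[k], len(kept) - 1)
        for k, snp in enumerate(r.snp_ids)
    ]


def funnel_data(r: RatioSet) -> tuple[list[tuple[str, float, float]], float]:
    """Per-SNP (snp_id, ratio, precision) points plus the IVW reference."""
    points = [
        (snp, float(b), float(1.0 / s))
        for snp, b, s in zip(r.snp_ids, r.ratio, r.ratio_se)
    ]
    reference = float((r.weight * r.ratio).sum() / r.weight.sum())
    return points, reference


def funnel_symmetry_test(r: RatioSet) -> float:
    """Exploratory precision-split t-test of funnel symmetry.

    Splits SNPs at the median precision and compares mean ratios of the
    two halves (Welch t-test); returns the two-sided p-value.  Not part
    of the core diagnostic battery.
    """
    precision = 1.0 / r.ratio_se
    cut = np.median(precision)
    top = r.ratio[precision >= cut]
    bottom = r.ratio[precision < cut]
    if top.size < 2 or bottom.size < 2:
        return float("nan")
    return float(stats.ttest_ind(top, bottom, equal_var=False).pvalue)


def diagnose(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_sig: float = 0.05,
    run_presso: bool = True,
) -> PleiotropyReport:
    """Assemble the full diagnostic report for a harmonized dataset."""
    r = wald_ratios(h)
    fixed = ivw(h, model="fixed")
    q, df, q_p = cochran_q(r, fixed.beta)
    _, intercept = egger(h)
    presso = (
        mr_presso(h, n_sim=n_sim, seed=seed, outlier_sig=outlier_sig)
        if run_presso and len(r) >= 4
        else None
    )
    loo = leave_one_out(h)
    points, reference = funnel_data(r)
    return PleiotropyReport(
        q_stat=q,
        q_df=df,
        q_pval=q_p,
        egger_intercept=intercept,
        presso=presso,
        loo_series=loo,
        funnel_points=points,
        funnel_reference=reference,
    )
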