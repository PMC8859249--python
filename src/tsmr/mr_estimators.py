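"""Causal-effect estimators for two-sample MR from harmonized summary data.

Implements the full battery: per-SNP Wald ratios, inverse-variance
weighted meta-analysis (fixed / multiplicative-random, penalized and
robust variants), MR-Egger regression, simple and weighted medians with
parametric-bootstrap standard errors, and profile maximum likelihood.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from tsmr.harmonization import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))

#: weight-penalization constant for penalized IVW
PENALTY_CONSTANT = 20.0
#: bisquare tuning constant for robust IVW
BISQUARE_TUNING = 4.685


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the beta (log-OR for binary) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_scale: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(
                f"{self.method}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket beta {self.beta}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.or_scale is not None:
            d["or_scale"] = {
                "or": self.or_scale[0],
                "ci_low": self.or_scale[1],
                "ci_high": self.or_scale[2],
            }
        return d


@dataclass(frozen=True)
class RatioSet:
    """Per-SNP Wald ratios with first-order delta-method SEs."""

    snp_ids: tuple[str, ...]
    ratio: np.ndarray
    ratio_se: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2

    def __len__(self) -> int:
        return self.ratio.size


def _estimate(method: str, beta: float, se: float, n_snps: int) -> MREstimate:
    beta, se = float(beta), float(se)
    z = beta / se
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_snps=n_snps,
    )


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> RatioSet:
    """Per-SNP causal-effect ratios beta_out / beta_exp.

    The default SE is the first-order delta-method value
    ``se_out / |beta_exp|``; ``second_order=True`` adds the exposure
    uncertainty term.
    """
    bx, sx, by, sy = h.arrays()
    zero = np.flatnonzero(bx == 0.0)
    if zero.size:
        names = [h.snp_ids()[i] for i in zero]
        raise ValueError(f"zero exposure beta for SNP(s): {', '.join(names)}")
    ratio = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return RatioSet(snp_ids=tuple(h.snp_ids()), ratio=ratio, ratio_se=se)


def _ivw_point(ratio: np.ndarray, weight: np.ndarray) -> tuple[float, float]:
    wsum = weight.sum()
    theta = float((weight * ratio).sum() / wsum)
    se = float(wsum**-0.5)
    return theta, se


def _penalized_weights(ratio: np.ndarray, weight: np.ndarray, theta: float) -> np.ndarray:
    q = weight * (ratio - theta) ** 2
    pj = stats.chi2.sf(q, df=1)
    return weight * np.minimum(1.0, PENALTY_CONSTANT * pj)


def _robust_fit(bx: np.ndarray, by: np.ndarray, pen: np.ndarray, sy: np.ndarray):
    """Bisquare through-origin fit of by on bx with weights pen/sy^2."""
    scale = np.sqrt(pen) / sy
    x = (bx * scale)[:, None]
    y = by * scale
    model = sm.RLM(y, x, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
    fit = model.fit()
    return float(fit.params[0]), float(fit.bse[0])


def ivw(
    h: HarmonizedSet,
    model: str = "fixed",
    penalized: bool = False,
    robust: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Parameters
    ----------
    h
        Harmonized dataset (>= 2 kept SNPs).
    model
        ``"fixed"`` or ``"random"`` (multiplicative: SE inflated by
        ``max(1, sqrt(Q/(J-1)))``, floored at the fixed-effect SE).
    penalized
        Downweight heterogeneous SNPs by ``min(1, 20 * p_j)`` where
        ``p_j`` is the chi-square(1) upper-tail p of the SNP's Q
        contribution; re-solved iteratively to 1e-10.
    robust
        Redescending bisquare (c = 4.685) through-origin fit instead of
        weighted least squares.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    r = wald_ratios(h)
    j = len(r)
    if j < 2:
        raise ValueError(f"IVW requires >= 2 SNPs, got {j}")
    ratio, weight = r.ratio, r.weight

    pen = np.ones(j)
    theta, _ = _ivw_point(ratio, weight)
    if penalized:
        for _ in range(100):
            w_pen = _penalized_weights(ratio, weight, theta)
            theta_new = float((w_pen * ratio).sum() / w_pen.sum())
            if abs(theta_new - theta) < 1e-10:
                theta = theta_new
                break
            theta = theta_new
        w_pen = _penalized_weights(ratio, weight, theta)
        pen = w_pen / weight
        weight_eff = w_pen
    else:
        weight_eff = weight

    if robust:
        bx, sx, by, sy = h.arrays()
        theta, se = _robust_fit(bx, by, pen, sy)
    else:
        theta, se = _ivw_point(ratio, weight_eff)

    if model == "random":
        q = float((weight_eff * (ratio - theta) ** 2).sum())
        se *= max(1.0, np.sqrt(q / (j - 1)))

    label = "ivw_" + model
    if penalized:
        label += "_penalized"
    if robust:
        label += "_robust"
    return _estimate(label, theta, se, j)


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of outcome on exposure betas with
    intercept, after orienting every SNP-exposure beta positive.

    Returns ``(slope, intercept)`` estimates.  SEs carry multiplicative
    random-effects scaling ``max(1, residual SD)``.
    """
    bx, sx, by, sy = h.arrays()
    j = bx.size
    if j < 3:
        raise ValueError(f"MR-Egger requires >= 3 SNPs, got {j}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = fit.params
    resid = by - fit.fittedvalues
    rss = float((w * resid**2).sum())
    sigma = np.sqrt(rss / (j - 2))
    scale = max(1.0, sigma)
    # WLS SEs with unit dispersion, then multiplicative scaling
    cov = np.asarray(fit.normalized_cov_params)
    se_int, se_slope = np.sqrt(np.diag(cov)) * scale
    return (
        _estimate("egger_slope", slope, se_slope, j),
        _estimate("egger_intercept", intercept, se_int, j),
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio)
    b = ratio[order]
    w = weight[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, b))


def _weighted_median_rows(ratio: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (n_boot, J) matrices."""
    order = np.argsort(ratio, axis=1)
    b = np.take_along_axis(ratio, order, axis=1)
    w = np.take_along_axis(weight, order, axis=1)
    s = (np.cumsum(w, axis=1) - 0.5 * w) / w.sum(axis=1, keepdims=True)
    out = np.empty(ratio.shape[0])
    for i in range(ratio.shape[0]):
        out[i] = np.interp(0.5, s[i], b[i])
    return out


def median_estimate(
    h: HarmonizedSet,
    weighting: str = "weighted",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MREstimate:
    """Simple or weighted median of the Wald ratios.

    The SE is the standard deviation of the estimator over ``n_boot``
    parametric-bootstrap replicates (betas redrawn from their sampling
    distributions); reproducible given ``seed``.
    """
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    bx, sx, by, sy = h.arrays()
    j = bx.size
    if j < 3:
        raise ValueError(f"median estimator requires >= 3 SNPs, got {j}")
    r = wald_ratios(h)
    if weighting == "simple":
        theta = float(np.median(r.ratio))
    else:
        theta = _weighted_median(r.ratio, r.weight)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    ratio_star = by_star / bx_star
    if weighting == "simple":
        boot = np.median(ratio_star, axis=1)
    else:
        weight_star = bx_star**2 / sy**2
        boot = _weighted_median_rows(ratio_star, weight_star)
    se = float(boot.std(ddof=1))
    return _estimate(f"{weighting}_median", theta, se, j)


def _ml_profile_objective(theta: float, bx, sx, by, sy) -> float:
    # per-SNP true exposure effects profiled out in closed form
    return float(((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)).sum())


def max_likelihood(h: HarmonizedSet) -> MREstimate:
    """Profile maximum-likelihood estimate under a bivariate Gaussian
    measurement model with independent errors.

    The per-SNP true exposure effects are profiled out analytically,
    leaving a one-dimensional objective minimized numerically from the
    fixed-effect IVW start point; the SE comes from the curvature of the
    profile objective.
    """
    bx, sx, by, sy = h.arrays()
    j = bx.size
    if j < 2:
        raise ValueError(f"maximum likelihood requires >= 2 SNPs, got {j}")
    theta0 = _ivw_point(by / bx, bx**2 / sy**2)[0]

    res = optimize.minimize_scalar(
        _ml_profile_objective,
        bracket=(theta0 - 1.0, theta0, theta0 + 1.0),
        args=(bx, sx, by, sy),
        method="brent",
        options={"xtol": 1e-12, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"maximum-likelihood optimizer failed: {res}")
    theta = float(res.x)

    hstep = 1e-5 * max(1.0, abs(theta))
    g = _ml_profile_objective
    curv = (
        g(theta + hstep, bx, sx, by, sy)
        - 2.0 * g(theta, bx, sx, by, sy)
        + g(theta - hstep, bx, sx, by, sy)
    ) / hstep**2
    if curv <= 0:
        raise RuntimeError(
            f"non-positive profile curvature {curv} at theta={theta}; "
            "cannot form a standard error"
        )
    se = float(np.sqrt(2.0 / curv))  # objective is -2 log-likelihood + const
    return _estimate("max_likelihood", theta, se, j)


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Attach the OR-scale transform (exp of beta and CI bounds)."""
    return dataclasses.replace(
        est,
        or_scale=(
            float(np.exp(est.beta)),
            float(np.exp(est.ci_low)),
            float(np.exp(est.ci_high)),
        ),
    )


def estimate_all(
    h: HarmonizedSet,
    n_boot: int = 10_000,
    seed: int | None = None,
    binary_outcome: bool = True,
) -> list[MREstimate]:
    """Run the full eight-method battery in report order."""
    slope, _ = egger(h)
    estimates = [
        ivw(h, model="fixed"),
        ivw(h, model="random"),
        ivw(h, model="random", penalized=True),
        ivw(h, model="random", penalized=True, robust=True),
        max_likelihood(h),
        median_estimate(h, "simple", n_boot=n_boot, seed=seed),
        median_estimate(h, "weighted", n_boot=n_boot, seed=seed),
        slope,
    ]
    if binary_outcome:
        estimates = [to_odds_ratio(e) for e in estimates]
    return estimates
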