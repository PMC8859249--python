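"""Multivariable MR: joint weighted regression of outcome betas on
several exposures' betas, yielding direct effects adjusted for the
secondary trait(s)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tsmr.harmonization import HarmonizeAction, harmonize
from tsmr.mr_estimators import _estimate, MREstimate
from tsmr.summary_data import AssociationTable


@dataclass
class MvmrInput:
    """Row-complete multivariable design: K exposure-beta columns
    (primary exposure first) against one outcome column."""

    snp_ids: list[str]
    beta_exp_matrix: np.ndarray  # (J, K)
    se_exp_matrix: np.ndarray  # (J, K)
    beta_out: np.ndarray  # (J,)
    se_out: np.ndarray  # (J,)
    exposure_labels: list[str] = field(default_factory=list)
    n_dropped_per_source: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.beta_exp_matrix = np.atleast_2d(np.asarray(self.beta_exp_matrix, dtype=float))
        self.se_exp_matrix = np.atleast_2d(np.asarray(self.se_exp_matrix, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        if self.beta_exp_matrix.shape[1] < 2:
            raise ValueError("multivariable MR needs K >= 2 exposure columns")
        if self.beta_exp_matrix.shape[0] != self.beta_out.size:
            raise ValueError("exposure matrix and outcome vector row counts differ")

    @property
    def n_snps(self) -> int:
        return self.beta_out.size

    @property
    def k(self) -> int:
        return self.beta_exp_matrix.shape[1]


def assemble_mvmr(
    exposure: AssociationTable,
    covariates: AssociationTable | list[AssociationTable],
    outcome: AssociationTable,
    palindrome_maf: float = 0.42,
    palindrome_mode: str = "both",
) -> MvmrInput:
    """Harmonize covariate and outcome tables to the exposure's allele
    frame and build the row-complete multivariable design.

    SNPs missing from any source (or dropped by harmonization) are
    excluded; per-source drop counts are recorded.
    """
    if isinstance(covariates, AssociationTable):
        covariates = [covariates]
    labels = [exposure.trait_label] + [c.trait_label for c in covariates]

    harmonized = [
        harmonize(exposure, tbl, palindrome_maf, palindrome_mode)
        for tbl in [*covariates, outcome]
    ]
    dropped: dict[str, int] = {}
    kept_ids: list[str] | None = None
    for tbl, hset in zip([*covariates, outcome], harmonized):
        ids = set(hset.snp_ids())
        dropped[tbl.trait_label or "unnamed"] = sum(
            1 for r in hset.records if not r.kept
        )
        kept_ids = ids if kept_ids is None else kept_ids & ids
    assert kept_ids is not None
    ordered = [r.snp_id for r in exposure.records if r.snp_id in kept_ids]

    k = 1 + len(covariates)
    if len(ordered) < k + 2:
        raise ValueError(
            f"only {len(ordered)} complete SNPs for K={k} exposures; "
            "model underdetermined"
        )

    exp_index = exposure.index()
    cov_maps = [
        {r.snp_id: r for r in hset.kept_records} for hset in harmonized[:-1]
    ]
    out_map = {r.snp_id: r for r in harmonized[-1].kept_records}

    beta_exp = np.empty((len(ordered), k))
    se_exp = np.empty((len(ordered), k))
    beta_out = np.empty(len(ordered))
    se_out = np.empty(len(ordered))
    for i, sid in enumerate(ordered):
        rec = exp_index[sid]
        beta_exp[i, 0] = rec.beta
        se_exp[i, 0] = rec.se
        for c, cmap in enumerate(cov_maps, start=1):
            beta_exp[i, c] = cmap[sid].beta_out
            se_exp[i, c] = cmap[sid].se_out
        beta_out[i] = out_map[sid].beta_out
        se_out[i] = out_map[sid].se_out

    return MvmrInput(
        snp_ids=ordered,
        beta_exp_matrix=beta_exp,
        se_exp_matrix=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        exposure_labels=labels,
        n_dropped_per_source=dropped,
    )


def mvmr_ivw(m: MvmrInput, model: str = "random") -> list[MREstimate]:
    """Weighted multivariable regression of outcome betas on the exposure
    columns without intercept (weights 1 / se_out^2).

    ``model="random"`` (default) applies multiplicative random-effects SE
    scaling floored at 1; ``"fixed"`` keeps unit dispersion.  Returns one
    estimate per exposure column, primary first.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    X = m.beta_exp_matrix
    y = m.beta_out
    w = 1.0 / m.se_out**2
    j, k = X.shape
    labels = m.exposure_labels or [f"exposure_{i}" for i in range(k)]

    # identically-zero columns carry no information: exclude them so the
    # fit reduces exactly to the lower-dimensional model
    active = [i for i in range(k) if np.any(X[:, i] != 0.0)]
    Xa = X[:, active]
    ka = len(active)
    if ka == 0:
        raise ValueError("all exposure columns are zero")

    if np.linalg.matrix_rank(Xa) < ka:
        corr = np.corrcoef(Xa, rowvar=False)
        pairs = [
            (labels[active[a]], labels[active[b]])
            for a in range(ka)
            for b in range(a + 1, ka)
            if abs(corr[a, b]) > 1.0 - 1e-10
        ]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {pairs}")

    sw = np.sqrt(w)
    Xw = Xa * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    coef_a = np.linalg.solve(xtx, Xw.T @ yw)
    cov = np.linalg.inv(xtx)
    resid = yw - Xw @ coef_a
    if model == "random":
        sigma2 = float((resid**2).sum() / (j - ka))
        scale = max(1.0, np.sqrt(sigma2))
    else:
        scale = 1.0
    ses_a = np.sqrt(np.diag(cov)) * scale

    coef = np.zeros(k)
    ses = np.full(k, np.inf)
    coef[active] = coef_a
    ses[active] = ses_a

    out = []
    for i in range(k):
        role = "primary" if i == 0 else "secondary"
        out.append(_estimate(f"mvmr_{role}:{labels[i]}", coef[i], ses[i], j))
    return out
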