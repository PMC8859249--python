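"""Seeded generators for two-sample MR summary statistics with known
ground truth.

The generative model: true SNP-exposure effects gamma_j ~ Normal(0,
gamma_sd^2) truncated away from zero; observed exposure betas
gamma_hat_j ~ Normal(gamma_j, se_exp_j^2); SNP-outcome means
theta * gamma_j + alpha_j with pleiotropy alpha_j controlled by
``pleiotropy_mode``; observed outcome betas add Normal noise at
se_out_j.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tsmr.summary_data import (
    AssociationTable,
    LdTable,
    SnpAssociation,
    TraitAnnotationTable,
)

#: confounder trait list used for instrument exclusion
DEFAULT_CONFOUNDER_TRAITS = frozenset(
    {
        "body mass index",
        "height",
        "weight",
        "waist circumference",
        "cholesterol level",
        "blood pressure",
        "diabetes",
        "alcohol intake",
        "smoking",
    }
)

_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the synthetic two-sample dataset.

    Defaults mimic the scale of a large intelligence-on-CAD analysis:
    121 instruments, true log-OR theta = ln(0.76), exposure/outcome SEs
    sized so the fixed-effect IVW SE lands near 0.054.
    """

    j_snps: int = 121
    theta: float = math.log(0.76)
    gamma_sd: float = 0.02
    # exposure SEs kept small so per-SNP instrument strength is high and
    # finite-sample Wald-ratio attenuation is negligible at default scale
    se_exp_range: tuple[float, float] = (0.0005, 0.001)
    se_out_range: tuple[float, float] = (0.010, 0.015)
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    prop_invalid: float = 0.0
    inside_slope: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindrome_fraction: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    observation_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.j_snps < 1:
            raise ValueError("j_snps must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValueError("prop_invalid must be in [0,1]")
        for name in ("se_exp_range", "se_out_range", "maf_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must be positive with lo <= hi")
        if not 0.0 <= self.palindrome_fraction <= 1.0:
            raise ValueError("palindrome_fraction must be in [0,1]")


def snp_ids(j: int) -> list[str]:
    """Deterministic rsID-style identifiers used by all generators."""
    return [f"rs{100000 + i}" for i in range(j)]


def _truncated_gammas(rng: np.random.Generator, j: int, sd: float) -> np.ndarray:
    """Normal(0, sd^2) truncated away from zero at 0.1*sd (rejection)."""
    cut = 0.1 * sd
    out = rng.normal(0.0, sd, size=j)
    bad = np.abs(out) < cut
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) < cut
    return out


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, dict]:
    """Generate matched exposure/outcome tables plus the truth record.

    The truth record stores every latent quantity (true gammas, alphas,
    outlier flags, allele assignments), sufficient to recompute all
    simulated observables.
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.j_snps
    ids = snp_ids(j)

    gamma = _truncated_gammas(rng, j, cfg.gamma_sd)
    se_exp = rng.uniform(*cfg.se_exp_range, size=j)
    se_out = rng.uniform(*cfg.se_out_range, size=j)

    n_invalid = int(round(cfg.prop_invalid * j))
    invalid = np.zeros(j, dtype=bool)
    if n_invalid and cfg.pleiotropy_mode != "none":
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if cfg.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.pleio_sd, size=int(invalid.sum()))
    elif cfg.pleiotropy_mode == "directional":
        alpha[invalid] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=int(invalid.sum()))
    elif cfg.pleiotropy_mode == "inside_violating":
        k = int(invalid.sum())
        alpha[invalid] = cfg.inside_slope * gamma[invalid] + rng.normal(
            cfg.pleio_mean, cfg.pleio_sd, size=k
        )

    if cfg.observation_noise:
        beta_exp = rng.normal(gamma, se_exp)
        beta_out = rng.normal(cfg.theta * gamma + alpha, se_out)
    else:
        beta_exp = gamma.copy()
        beta_out = cfg.theta * gamma + alpha

    outlier = np.zeros(j, dtype=bool)
    if cfg.n_outliers:
        outlier[rng.choice(j, size=cfg.n_outliers, replace=False)] = True
        beta_out = np.where(outlier, beta_out + cfg.outlier_shift * se_out, beta_out)

    n_pal = int(round(cfg.palindrome_fraction * j))
    is_pal = np.zeros(j, dtype=bool)
    if n_pal:
        is_pal[rng.choice(j, size=n_pal, replace=False)] = True
    pair_pal = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    pair_non = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=j)
    maf = rng.uniform(*cfg.maf_range, size=j)
    minor_is_effect = rng.random(j) < 0.5
    eaf = np.where(minor_is_effect, maf, 1.0 - maf)

    pvals = 2.0 * stats.norm.sf(np.abs(beta_exp / se_exp))
    pvals_out = 2.0 * stats.norm.sf(np.abs(beta_out / se_out))

    exp_records, out_records = [], []
    alleles = []
    for i in range(j):
        ea, oa = (
            _PALINDROMIC_PAIRS[pair_pal[i]]
            if is_pal[i]
            else _NON_PALINDROMIC_PAIRS[pair_non[i]]
        )
        alleles.append((ea, oa))
        chrom = str(i % 22 + 1)
        pos = 20_000_000 * (i // 22 + 1)
        common = dict(
            snp_id=ids[i], chrom=chrom, pos=pos,
            effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
        )
        exp_records.append(
            SnpAssociation(
                beta=float(beta_exp[i]), se=float(se_exp[i]),
                pval=float(max(pvals[i], 5e-324)), n=269_867.0, **common,
            )
        )
        out_records.append(
            SnpAssociation(
                beta=float(beta_out[i]), se=float(se_out[i]),
                pval=float(max(pvals_out[i], 5e-324)), **common,
            )
        )

    truth = {
        "theta": cfg.theta,
        "snp_ids": ids,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "invalid": invalid.tolist(),
        "outlier": outlier.tolist(),
        "se_exp": se_exp.tolist(),
        "se_out": se_out.tolist(),
        "eaf": eaf.tolist(),
        "alleles": alleles,
        "config": cfg.__dict__ | {
            "se_exp_range": list(cfg.se_exp_range),
            "se_out_range": list(cfg.se_out_range),
            "maf_range": list(cfg.maf_range),
        },
    }
    exposure = AssociationTable("simulated_exposure", exp_records, {"simulated": True})
    outcome = AssociationTable("simulated_outcome", out_records, {"simulated": True})
    return exposure, outcome, truth


def simulate_annotation_table(
    cfg: SimulationConfig,
    flagged_ids: set[str],
    confounder_traits: frozenset[str] | set[str] = DEFAULT_CONFOUNDER_TRAITS,
    innocuous_fraction: float = 0.3,
) -> TraitAnnotationTable:
    """Annotation rows giving each flagged SNP a genome-wide-significant
    confounder trait; a random fraction of the rest get innocuous traits."""
    ids = snp_ids(cfg.j_snps)
    unknown = set(flagged_ids) - set(ids)
    if unknown:
        raise ValueError(f"flagged_ids not in simulated SNP set: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    traits = sorted(confounder_traits)
    innocuous = ["educational attainment", "reaction time", "chronotype"]
    rows: list[tuple[str, str, float]] = []
    for sid in ids:
        if sid in flagged_ids:
            trait = traits[int(rng.integers(0, len(traits)))]
            log_p = rng.uniform(-30.0, math.log10(5e-8) - 0.5)
            rows.append((sid, trait, float(10.0**log_p)))
        elif rng.random() < innocuous_fraction:
            trait = innocuous[int(rng.integers(0, len(innocuous)))]
            rows.append((sid, trait, float(rng.uniform(1e-6, 1.0))))
    return TraitAnnotationTable(rows=rows)


def simulate_ld_table(
    cfg: SimulationConfig,
    block_structure: list[int],
    within_r2: float,
) -> LdTable:
    """LD table placing the first ``sum(block_structure)`` SNPs into
    blocks with pairwise ``within_r2``; cross-block pairs are absent."""
    if sum(block_structure) > cfg.j_snps:
        raise ValueError("block sizes exceed j_snps")
    ids = snp_ids(cfg.j_snps)
    table = LdTable()
    start = 0
    for size in block_structure:
        members = ids[start : start + size]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                table.add(members[a], members[b], within_r2)
        start += size
    return table


def assign_block_positions(
    table: AssociationTable,
    block_structure: list[int],
    spacing_bp: int = 10_000,
) -> AssociationTable:
    """Re-position the first ``sum(block_structure)`` records so each
    block's members sit adjacently (same chromosome, ``spacing_bp``
    apart) inside the clump window; remaining records keep their
    far-apart layout."""
    import dataclasses as _dc

    records = list(table.records)
    idx = 0
    for b, size in enumerate(block_structure):
        chrom = str(b % 22 + 1)
        base = 50_000_000 + 100_000_000 * (b // 22)
        for m in range(size):
            records[idx] = _dc.replace(
                records[idx], chrom=chrom, pos=base + m * spacing_bp
            )
            idx += 1
    return AssociationTable(table.trait_label, records, dict(table.metadata))
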