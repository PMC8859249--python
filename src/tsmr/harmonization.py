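"""Align exposure and outcome summary tables onto a shared effect-allele
frame, producing the estimator-ready dataset."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from tsmr.summary_data import COMPLEMENT, AssociationTable, SnpAssociation


class HarmonizeAction(str, Enum):
    KEPT = "kept"
    SIGN_FLIPPED = "sign_flipped"
    DROPPED_PALINDROME = "dropped_palindrome"
    DROPPED_MISSING = "dropped_missing"
    DROPPED_ALLELE_MISMATCH = "dropped_allele_mismatch"


_DROPPED = {
    HarmonizeAction.DROPPED_PALINDROME,
    HarmonizeAction.DROPPED_MISSING,
    HarmonizeAction.DROPPED_ALLELE_MISMATCH,
}


@dataclass(frozen=True)
class HarmonizedRecord:
    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: HarmonizeAction
    effect_allele: str | None = None
    other_allele: str | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None

    @property
    def kept(self) -> bool:
        return self.action not in _DROPPED


@dataclass
class HarmonizedSet:
    """SNP-aligned exposure/outcome betas and SEs after harmonization.

    Kept rows share the exposure's effect-allele frame; dropped rows are
    retained with their action for audit purposes.
    """

    records: list[HarmonizedRecord] = field(default_factory=list)
    exposure_label: str = ""
    outcome_label: str = ""

    @property
    def kept_records(self) -> list[HarmonizedRecord]:
        return [r for r in self.records if r.kept]

    def __len__(self) -> int:
        return len(self.kept_records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) over kept rows."""
        kept = self.kept_records
        return (
            np.array([r.beta_exp for r in kept], dtype=float),
            np.array([r.se_exp for r in kept], dtype=float),
            np.array([r.beta_out for r in kept], dtype=float),
            np.array([r.se_out for r in kept], dtype=float),
        )

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.kept_records]

    def action_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.action.value] = counts.get(r.action.value, 0) + 1
        return counts

    def drop(self, snp_ids) -> "HarmonizedSet":
        """New set with the given SNPs removed from the kept rows."""
        omit = set(snp_ids)
        return HarmonizedSet(
            records=[r for r in self.records if r.snp_id not in omit or not r.kept],
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out, snp_ids=None) -> "HarmonizedSet":
        """Build a pre-harmonized set directly from aligned arrays."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        se_exp = np.asarray(se_exp, dtype=float)
        beta_out = np.asarray(beta_out, dtype=float)
        se_out = np.asarray(se_out, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i+1}" for i in range(beta_exp.size)]
        records = [
            HarmonizedRecord(
                snp_id=sid,
                beta_exp=float(bx),
                se_exp=float(sx),
                beta_out=float(by),
                se_out=float(sy),
                action=HarmonizeAction.KEPT,
            )
            for sid, bx, sx, by, sy in zip(snp_ids, beta_exp, se_exp, beta_out, se_out)
        ]
        return cls(records=records)


def _inferrable(eaf: float | None, maf_cutoff: float) -> bool:
    return eaf is not None and min(eaf, 1.0 - eaf) < maf_cutoff


def _harmonize_one(
    exp: SnpAssociation,
    out: SnpAssociation,
    palindrome_maf: float,
    palindrome_mode: str,
) -> HarmonizedRecord:
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    common = dict(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        effect_allele=e_ea,
        other_allele=e_oa,
        eaf_exp=exp.eaf,
    )

    if exp.is_palindromic():
        # Allele orientation cannot distinguish strand for A/T and C/G
        # pairs; resolve via allele frequency or drop.
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return HarmonizedRecord(
                beta_out=out.beta, se_out=out.se, eaf_out=out.eaf,
                action=HarmonizeAction.DROPPED_ALLELE_MISMATCH, **common,
            )
        # nominal alignment: if outcome lists the pair swapped, flip first
        beta_out, eaf_out = out.beta, out.eaf
        if o_ea != e_ea:
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        check_outcome = palindrome_mode == "both"
        if not _inferrable(exp.eaf, palindrome_maf):
            return HarmonizedRecord(
                beta_out=beta_out, se_out=out.se, eaf_out=eaf_out,
                action=HarmonizeAction.DROPPED_PALINDROME, **common,
            )
        if check_outcome:
            if not _inferrable(eaf_out, palindrome_maf):
                return HarmonizedRecord(
                    beta_out=beta_out, se_out=out.se, eaf_out=eaf_out,
                    action=HarmonizeAction.DROPPED_PALINDROME, **common,
                )
            # consistent orientation: effect allele minor in both or major in both
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                return HarmonizedRecord(
                    beta_out=beta_out, se_out=out.se, eaf_out=eaf_out,
                    action=HarmonizeAction.DROPPED_PALINDROME, **common,
                )
        action = HarmonizeAction.SIGN_FLIPPED if o_ea != e_ea else HarmonizeAction.KEPT
        return HarmonizedRecord(
            beta_out=beta_out, se_out=out.se, eaf_out=eaf_out, action=action, **common
        )

    # non-palindromic: try direct, swapped, strand-complement, complement-swapped
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (o_ea, o_oa) == (e_ea, e_oa) or (c_ea, c_oa) == (e_ea, e_oa):
        return HarmonizedRecord(
            beta_out=out.beta, se_out=out.se, eaf_out=out.eaf,
            action=HarmonizeAction.KEPT, **common,
        )
    if (o_oa, o_ea) == (e_ea, e_oa) or (c_oa, c_ea) == (e_ea, e_oa):
        return HarmonizedRecord(
            beta_out=-out.beta, se_out=out.se,
            eaf_out=None if out.eaf is None else 1.0 - out.eaf,
            action=HarmonizeAction.SIGN_FLIPPED, **common,
        )
    return HarmonizedRecord(
        beta_out=out.beta, se_out=out.se, eaf_out=out.eaf,
        action=HarmonizeAction.DROPPED_ALLELE_MISMATCH, **common,
    )


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    palindrome_maf: float = 0.42,
    palindrome_mode: str = "both",
) -> HarmonizedSet:
    """Harmonize outcome associations onto the exposure's effect-allele frame.

    Parameters
    ----------
    exposure, outcome
        Association tables sharing snp_ids (matching is by snp_id only).
    palindrome_maf
        MAF cutoff below which a palindromic SNP's strand is inferrable.
    palindrome_mode
        ``"both"`` (default) requires inferability and a consistent minor
        allele in both tables; ``"exposure-only"`` applies the frequency
        rule to the exposure table only.

    Raises
    ------
    ValueError
        If no exposure SNP is present in the outcome table.
    """
    if palindrome_mode not in ("both", "exposure-only"):
        raise ValueError(f"unknown palindrome_mode {palindrome_mode!r}")
    out_index = outcome.index()
    records: list[HarmonizedRecord] = []
    for exp in exposure.records:
        out = out_index.get(exp.snp_id)
        if out is None:
            records.append(
                HarmonizedRecord(
                    snp_id=exp.snp_id,
                    beta_exp=exp.beta,
                    se_exp=exp.se,
                    beta_out=float("nan"),
                    se_out=float("nan"),
                    action=HarmonizeAction.DROPPED_MISSING,
                    effect_allele=exp.effect_allele,
                    other_allele=exp.other_allele,
                    eaf_exp=exp.eaf,
                )
            )
            continue
        records.append(_harmonize_one(exp, out, palindrome_maf, palindrome_mode))

    if not any(out_index.get(e.snp_id) is not None for e in exposure.records):
        raise ValueError("no overlapping instruments between exposure and outcome tables")

    return HarmonizedSet(
        records=records,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
    )
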