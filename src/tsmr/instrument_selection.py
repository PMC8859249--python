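"""Instrument construction: significance, MAF, palindrome, LD-clump and
confounder-annotation filters, with a per-stage audit trail.

All thresholds use strict inequalities (p < 5e-8, MAF < .42 for
palindrome inferability); boundary values fail the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from tsmr.summary_data import (
    AssociationTable,
    LdTable,
    TraitAnnotationTable,
)

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_MAF = 0.01
PALINDROME_MAF = 0.42
DEFAULT_R2 = 0.001
DEFAULT_WINDOW_KB = 10_000


class PalindromeClass(str, Enum):
    NOT_PALINDROMIC = "not_palindromic"
    INFERRABLE = "palindromic_inferrable"
    AMBIGUOUS = "palindromic_ambiguous"


@dataclass
class SelectionAudit:
    """Per-stage record of how many SNPs each filter removed."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, removed_snp_ids: list[str], **extra) -> None:
        entry = {
            "stage": stage,
            "n_in": n_in,
            "n_removed": len(removed_snp_ids),
            "n_out": n_in - len(removed_snp_ids),
            "removed_snp_ids": list(removed_snp_ids),
        }
        entry.update(extra)
        if self.stages and self.stages[-1]["n_out"] != n_in:
            raise ValueError(
                f"audit discontinuity: stage {stage!r} n_in={n_in} but previous "
                f"stage left {self.stages[-1]['n_out']}"
            )
        self.stages.append(entry)

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def filter_significance(
    table: AssociationTable,
    p_threshold: float = GENOME_WIDE_P,
    audit: SelectionAudit | None = None,
) -> AssociationTable:
    """Keep records with ``pval < p_threshold`` (strict)."""
    removed = [r.snp_id for r in table.records if r.pval is None or not r.pval < p_threshold]
    kept = [r for r in table.records if r.snp_id not in set(removed)]
    if audit is not None:
        audit.record("significance", len(table), removed, p_threshold=p_threshold)
    return AssociationTable(table.trait_label, kept, dict(table.metadata))


def filter_maf(
    table: AssociationTable,
    maf_threshold: float = DEFAULT_MAF,
    audit: SelectionAudit | None = None,
) -> AssociationTable:
    """Keep records with minor-allele frequency strictly above ``maf_threshold``.

    Records lacking eaf pass unchanged but are flagged in the audit.
    """
    removed: list[str] = []
    flagged: list[str] = []
    kept = []
    for rec in table.records:
        if rec.maf is None:
            flagged.append(rec.snp_id)
            kept.append(rec)
        elif rec.maf > maf_threshold:
            kept.append(rec)
        else:
            removed.append(rec.snp_id)
    if audit is not None:
        audit.record(
            "maf", len(table), removed, maf_threshold=maf_threshold, missing_eaf=flagged
        )
    return AssociationTable(table.trait_label, kept, dict(table.metadata))


def classify_palindrome(record, maf_cutoff: float = PALINDROME_MAF) -> PalindromeClass:
    """Classify a SNP's strand-inference status.

    A/T and C/G pairs are palindromic; such a SNP is inferrable only when
    its MAF is strictly below ``maf_cutoff``.  Palindromic SNPs with
    missing eaf are ambiguous.
    """
    if not record.is_palindromic():
        return PalindromeClass.NOT_PALINDROMIC
    if record.maf is not None and record.maf < maf_cutoff:
        return PalindromeClass.INFERRABLE
    return PalindromeClass.AMBIGUOUS


def filter_palindromic(
    table: AssociationTable,
    maf_cutoff: float = PALINDROME_MAF,
    audit: SelectionAudit | None = None,
) -> AssociationTable:
    """Remove palindromic SNPs whose strand cannot be inferred."""
    removed = [
        r.snp_id
        for r in table.records
        if classify_palindrome(r, maf_cutoff) is PalindromeClass.AMBIGUOUS
    ]
    kept = [r for r in table.records if r.snp_id not in set(removed)]
    if audit is not None:
        audit.record("palindrome", len(table), removed, maf_cutoff=maf_cutoff)
    return AssociationTable(table.trait_label, kept, dict(table.metadata))


def ld_clump(
    table: AssociationTable,
    ld: LdTable,
    r2_threshold: float = DEFAULT_R2,
    window_kb: float = DEFAULT_WINDOW_KB,
    audit: SelectionAudit | None = None,
) -> AssociationTable:
    """Greedy LD clumping.

    SNPs are visited in ascending p-value order (ties broken by snp_id);
    each accepted SNP prunes remaining same-chromosome SNPs within
    ``window_kb`` kilobases whose r^2 with it is >= ``r2_threshold``.
    The accepted set is returned in original table order.
    """
    for rec in table.records:
        if rec.pval is None or rec.chrom is None or rec.pos is None:
            raise ValueError(f"ld_clump requires pval/chrom/pos for all records ({rec.snp_id})")

    window_bp = window_kb * 1000.0
    order = sorted(table.records, key=lambda r: (r.pval, r.snp_id))
    remaining = {r.snp_id for r in table.records}
    accepted: set[str] = set()
    removed: list[str] = []
    n_missing_pairs = 0

    for rec in order:
        if rec.snp_id not in remaining:
            continue
        accepted.add(rec.snp_id)
        remaining.discard(rec.snp_id)
        for other in table.records:
            if other.snp_id not in remaining:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            if not ld.has_pair(rec.snp_id, other.snp_id):
                n_missing_pairs += 1
            if ld.r2(rec.snp_id, other.snp_id) >= r2_threshold:
                remaining.discard(other.snp_id)
                removed.append(other.snp_id)

    if n_missing_pairs:
        logger.warning(
            "%d within-window SNP pairs absent from LD table; treated as r2=0",
            n_missing_pairs,
        )
    kept = [r for r in table.records if r.snp_id in accepted]
    if audit is not None:
        audit.record(
            "ld_clump",
            len(table),
            removed,
            r2_threshold=r2_threshold,
            window_kb=window_kb,
            n_missing_ld_pairs=n_missing_pairs,
        )
    return AssociationTable(table.trait_label, kept, dict(table.metadata))


def exclude_confounder_associated(
    table: AssociationTable,
    annotations: TraitAnnotationTable,
    confounder_traits: set[str],
    p_threshold: float = GENOME_WIDE_P,
    audit: SelectionAudit | None = None,
) -> AssociationTable:
    """Remove SNPs with a genome-wide-significant confounder annotation.

    Trait names are compared case-insensitively.  A SNP is removed iff it
    carries at least one annotation row whose trait is in
    ``confounder_traits`` with ``pval < p_threshold``.
    """
    traits_norm = {t.strip().lower() for t in confounder_traits}
    removed_by_trait: dict[str, list[str]] = {}
    removed: list[str] = []
    for rec in table.records:
        hits = [
            trait
            for trait, pval in annotations.annotations_for(rec.snp_id)
            if trait.strip().lower() in traits_norm and pval < p_threshold
        ]
        if hits:
            removed.append(rec.snp_id)
            for trait in hits:
                removed_by_trait.setdefault(trait.strip().lower(), []).append(rec.snp_id)
    kept = [r for r in table.records if r.snp_id not in set(removed)]
    if audit is not None:
        audit.record(
            "confounder",
            len(table),
            removed,
            p_threshold=p_threshold,
            removed_by_trait=removed_by_trait,
        )
    return AssociationTable(table.trait_label, kept, dict(table.metadata))


def select_instruments(
    table: AssociationTable,
    ld: LdTable | None = None,
    annotations: TraitAnnotationTable | None = None,
    confounder_traits: set[str] | None = None,
    p_threshold: float = GENOME_WIDE_P,
    maf_threshold: float = DEFAULT_MAF,
    palindrome_maf: float = PALINDROME_MAF,
    r2_threshold: float = DEFAULT_R2,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> tuple[AssociationTable, SelectionAudit]:
    """Run the full four-stage instrument-construction pipeline."""
    audit = SelectionAudit()
    out = filter_significance(table, p_threshold, audit)
    out = filter_maf(out, maf_threshold, audit)
    out = filter_palindromic(out, palindrome_maf, audit)
    if ld is not None:
        out = ld_clump(out, ld, r2_threshold, window_kb, audit)
    if annotations is not None and confounder_traits:
        out = exclude_confounder_associated(
            out, annotations, confounder_traits, p_threshold, audit
        )
    return out, audit
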