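"""Data model and I/O for GWAS summary statistics.

Tables are thin ordered containers of per-SNP records plus free-form
metadata.  Files are plain TSV/CSV with a header row; arbitrary source
headers are supported through a ``column_map``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: complementary base pairs, used for strand handling downstream
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

_FIELD_ORDER = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass(frozen=True)
class SnpAssociation:
    """A single SNP-trait association from a GWAS summary file.

    ``beta`` is the per-effect-allele association (SD units for a
    continuous trait, log-odds for a binary trait), ``se`` its standard
    error.  ``eaf`` is the effect-allele frequency and may be ``None``
    when the source file does not report it.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pval: float | None = None
    n: float | None = None

    def validate(self) -> None:
        """Raise ``ValueError`` if any field violates its invariant."""
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf must be in (0,1), got {self.eaf}")
        if self.pval is not None and not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``None`` when eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        """True for A/T and C/G allele pairs (strand-ambiguous)."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class AssociationTable:
    """Ordered collection of :class:`SnpAssociation` for one trait."""

    trait_label: str
    records: list[SnpAssociation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes = {i for i in ids if i in seen or seen.add(i)}
            raise ValueError(f"duplicate snp_id in table {self.trait_label!r}: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return any(r.snp_id == snp_id for r in self.records)

    def get(self, snp_id: str) -> SnpAssociation | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def index(self) -> dict[str, SnpAssociation]:
        return {r.snp_id: r for r in self.records}

    def subset(self, snp_ids: Iterable[str]) -> "AssociationTable":
        """New table with only the given ids, preserving original order."""
        wanted = set(snp_ids)
        return AssociationTable(
            trait_label=self.trait_label,
            records=[r for r in self.records if r.snp_id in wanted],
            metadata=dict(self.metadata),
        )


@dataclass
class LdTable:
    """Pairwise LD lookups; symmetric, defaulting to r^2 = 0."""

    _r2: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, float]]) -> "LdTable":
        table = cls()
        for snp_a, snp_b, r2 in rows:
            table.add(snp_a, snp_b, r2)
        return table

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {r2} for ({snp_a},{snp_b})")
        self._r2[frozenset((snp_a, snp_b))] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)

    def has_pair(self, snp_a: str, snp_b: str) -> bool:
        return frozenset((snp_a, snp_b)) in self._r2

    def __len__(self) -> int:
        return len(self._r2)


@dataclass
class TraitAnnotationTable:
    """SNP -> (trait, p-value) annotation rows for confounder lookup."""

    rows: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for snp_id, trait, pval in self.rows:
            if not 0.0 < pval <= 1.0:
                raise ValueError(f"annotation pval out of (0,1]: {snp_id}/{trait} = {pval}")

    def annotations_for(self, snp_id: str) -> list[tuple[str, float]]:
        return [(trait, p) for sid, trait, p in self.rows if sid == snp_id]

    def __len__(self) -> int:
        return len(self.rows)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_optional_float(token: str) -> float | None:
    token = token.strip()
    if token in ("", "NA", "nan", "NaN", "."):
        return None
    return float(token)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
) -> AssociationTable:
    """Read a TSV/CSV summary-statistics file into an :class:`AssociationTable`.

    Parameters
    ----------
    path
        File with a header row; delimiter (tab or comma) is auto-detected
        from the header line.
    column_map
        Mapping from canonical field names (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``) to the file's column headers.  Fields absent from
        the map are read from same-named columns when present.
    trait_label
        Label stored on the returned table.

    Rows violating record invariants (bad alleles, non-positive SE, ...)
    or with unparseable numerics are dropped; the count is recorded in
    ``metadata["n_dropped"]``.  Duplicate snp_ids keep the smallest
    p-value.  A missing mandatory column raises ``ValueError``.
    """
    path = Path(path)
    column_map = dict(column_map or {})

    with path.open(newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(header_line)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        fieldnames = reader.fieldnames or []

        resolved: dict[str, str] = {}
        for canonical in _FIELD_ORDER:
            source = column_map.get(canonical, canonical)
            if source in fieldnames:
                resolved[canonical] = source
        missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s): {', '.join(missing)} "
                f"(available: {', '.join(fieldnames)})"
            )

        records: list[SnpAssociation] = []
        n_dropped = 0
        n_non_acgt = 0
        for row in reader:
            try:
                rec = SnpAssociation(
                    snp_id=row[resolved["snp_id"]].strip(),
                    chrom=str(row[resolved["chrom"]]).strip() if "chrom" in resolved else None,
                    pos=int(float(row[resolved["pos"]])) if "pos" in resolved and row[resolved["pos"]].strip() else None,
                    effect_allele=row[resolved["effect_allele"]].strip().upper(),
                    other_allele=row[resolved["other_allele"]].strip().upper(),
                    eaf=_parse_optional_float(row[resolved["eaf"]]) if "eaf" in resolved else None,
                    beta=float(row[resolved["beta"]]),
                    se=float(row[resolved["se"]]),
                    pval=_parse_optional_float(row[resolved["pval"]]) if "pval" in resolved else None,
                    n=_parse_optional_float(row[resolved["n"]]) if "n" in resolved else None,
                )
                if rec.effect_allele not in VALID_ALLELES or rec.other_allele not in VALID_ALLELES:
                    n_non_acgt += 1
                    n_dropped += 1
                    logger.info("dropping %s: non-ACGT alleles", rec.snp_id)
                    continue
                rec.validate()
            except (ValueError, KeyError) as exc:
                n_dropped += 1
                logger.info("dropping row: %s", exc)
                continue
            records.append(rec)

    # duplicate rsIDs: keep the smallest p-value, log the action
    by_id: dict[str, SnpAssociation] = {}
    n_dup = 0
    for rec in records:
        prev = by_id.get(rec.snp_id)
        if prev is None:
            by_id[rec.snp_id] = rec
            continue
        n_dup += 1
        prev_p = prev.pval if prev.pval is not None else 1.0
        rec_p = rec.pval if rec.pval is not None else 1.0
        if rec_p < prev_p:
            by_id[rec.snp_id] = rec
        logger.info("duplicate snp_id %s: keeping smallest p-value", rec.snp_id)
    n_dropped += n_dup
    deduped = list(by_id.values())

    return AssociationTable(
        trait_label=trait_label,
        records=deduped,
        metadata={
            "source": str(path),
            "n_dropped": n_dropped,
            "n_non_acgt": n_non_acgt,
            "n_duplicates": n_dup,
        },
    )


def _format_value(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".12g")
    return str(value)


def write_table(obj, path: str | Path) -> None:
    """Write an :class:`AssociationTable` (TSV) or a mapping report (JSON).

    Column order is deterministic and floats carry 12 significant digits
    so a write/read round trip is lossless at analysis precision.
    """
    path = Path(path)
    if isinstance(obj, AssociationTable):
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_FIELD_ORDER)
            for rec in obj.records:
                writer.writerow(
                    [_format_value(getattr(rec, name)) for name in _FIELD_ORDER]
                )
    elif isinstance(obj, Mapping):
        path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        path.write_text(
            json.dumps(_jsonable(dataclasses.asdict(obj)), indent=2, sort_keys=True) + "\n"
        )
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def _jsonable(obj):
    """Recursively coerce numpy scalars / dataclasses to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item") and callable(obj.item):  # numpy scalar
        return obj.item()
    return obj


def read_ld_table(path: str | Path) -> LdTable:
    """Read an LD table file with columns ``snp_a``, ``snp_b``, ``r2``."""
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        delim = _sniff_delimiter(header_line)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        rows = [(row["snp_a"], row["snp_b"], float(row["r2"])) for row in reader]
    return LdTable.from_rows(rows)


def write_ld_table(table: LdTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_a", "snp_b", "r2"])
        for pair, r2 in sorted(table._r2.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            writer.writerow([a, b, _format_value(r2)])


def read_annotations(path: str | Path) -> TraitAnnotationTable:
    """Read an annotation file with columns ``snp_id``, ``trait_name``, ``pval``."""
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        delim = _sniff_delimiter(header_line)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        rows = [
            (row["snp_id"], row["trait_name"], float(row["pval"])) for row in reader
        ]
    return TraitAnnotationTable(rows=rows)


def write_annotations(table: TraitAnnotationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_id", "trait_name", "pval"])
        for snp_id, trait, pval in table.rows:
            writer.writerow([snp_id, trait, _format_value(pval)])
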