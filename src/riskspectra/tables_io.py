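"""Strict TSV readers and writers for the pipeline's input tables.

All tables are UTF-8 tab-separated files with a header row. Readers
validate every row against the domain invariants and fail with errors
that name the offending column and 1-based data row; they never coerce
out-of-range values. Writers are exact inverses, so write-then-read is
the identity on validated collections.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "LiteratureCounts",
    "PlatformManifest",
    "SelectedSnpSet",
    "SchemaError",
    "ValidationError",
    "read_association_table",
    "write_association_table",
    "read_literature_counts",
    "write_literature_counts",
    "read_manifest",
    "write_snp_list",
    "read_selected",
]


class SchemaError(ValueError):
    """The file's header does not match the expected schema."""


class ValidationError(ValueError):
    """A data row violates a domain invariant; message carries the row number."""


@dataclass(frozen=True)
class AssociationRecord:
    """One reported disease-SNP association.

    ``risk_allele_freq`` is the control-population frequency F of the
    risk-associated allele, strictly inside (0, 1). ``sample_size`` and
    ``p_value`` are optional (None = not reported).
    """

    disease: str
    snp_id: str
    risk_allele_freq: float
    sample_size: int | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not self.disease.strip():
            raise ValidationError("disease label must be non-empty")
        if not self.snp_id.strip():
            raise ValidationError("snp_id must be non-empty")
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValidationError(
                f"risk_allele_freq must lie in (0,1), got {self.risk_allele_freq}"
            )
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValidationError(f"sample_size must be positive, got {self.sample_size}")
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p_value must lie in (0,1], got {self.p_value}")


@dataclass(frozen=True)
class LiteratureCounts:
    """Per-disease PubMed abstract counts feeding the environment/lifestyle index.

    ``n_disease`` counts abstracts mentioning the disease; ``n_env``,
    ``n_lifestyle`` and the optional ``n_exposure`` count abstracts
    co-mentioning the disease with the respective term.
    """

    disease: str
    n_disease: int
    n_env: int
    n_lifestyle: int
    n_exposure: int | None = None

    def __post_init__(self) -> None:
        if not self.disease.strip():
            raise ValidationError("disease label must be non-empty")
        if self.n_disease < 1:
            raise ValidationError(f"n_disease must be >= 1, got {self.n_disease}")
        for name in ("n_env", "n_lifestyle", "n_exposure"):
            value = getattr(self, name)
            if value is None:
                continue
            if not 0 <= value <= self.n_disease:
                raise ValidationError(
                    f"{name}={value} outside [0, n_disease={self.n_disease}]"
                )


@dataclass(frozen=True)
class PlatformManifest:
    """SNP id set for one genotyping platform (set semantics, non-empty)."""

    name: str
    snp_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", frozenset(self.snp_ids))
        if not self.snp_ids:
            raise ValidationError(f"manifest {self.name!r} must be non-empty")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class SelectedSnpSet:
    """Set of rsIDs flagged as carrying a signature of recent positive selection."""

    snp_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", frozenset(self.snp_ids))

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snp_ids


def normalize_disease(label: str) -> str:
    """Canonical join key for disease labels: trimmed and case-folded."""
    return label.strip().casefold()


_ASSOC_REQUIRED = ("disease", "snp_id", "risk_allele_freq")
_ASSOC_OPTIONAL = ("sample_size", "p_value")
_COUNTS_REQUIRED = ("disease", "n_disease", "n_env", "n_lifestyle")
_COUNTS_OPTIONAL = ("n_exposure",)


def _check_header(
    header: Sequence[str], required: Sequence[str], optional: Sequence[str], path: Path
) -> None:
    seen = list(header)
    for col in required:
        if col not in seen:
            raise SchemaError(f"{path}: missing required column {col!r}")
    allowed = set(required) | set(optional)
    extra = [c for c in seen if c not in allowed]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    if len(set(seen)) != len(seen):
        raise SchemaError(f"{path}: duplicated column in header")


def _parse_float(text: str, column: str, row: int, path: Path) -> float:
    text = text.strip()
    if "," in text:
        raise ValidationError(
            f"{path} row {row}: column {column!r} contains a thousands separator "
            f"or comma decimal ({text!r}); clean the table first"
        )
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(f"{path} row {row}: column {column!r} not a number ({text!r})") from exc
    if not math.isfinite(value):
        raise ValidationError(f"{path} row {row}: column {column!r} not finite ({text!r})")
    return value


def _parse_int(text: str, column: str, row: int, path: Path) -> int:
    text = text.strip()
    if "," in text:
        raise ValidationError(
            f"{path} row {row}: column {column!r} contains a comma ({text!r})"
        )
    try:
        return int(text)
    except ValueError as exc:
        raise ValidationError(f"{path} row {row}: column {column!r} not an integer ({text!r})") from exc


def _is_missing(text: str | None) -> bool:
    return text is None or text.strip() in ("", "NA", "na", ".")


def read_association_table(path: str | Path) -> list[AssociationRecord]:
    """Read a disease-SNP association table, preserving row order.

    Required columns: disease, snp_id, risk_allele_freq; optional:
    sample_size, p_value (blank, ``NA`` or ``.`` = unknown). Raises
    :class:`SchemaError` for a malformed header and
    :class:`ValidationError` citing the 1-based data row for any value
    outside its domain.
    """
    path = Path(path)
    records: list[AssociationRecord] = []
    n_missing_n = n_missing_p = 0
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, _ASSOC_REQUIRED, _ASSOC_OPTIONAL, path)
        for i, row in enumerate(reader, start=1):
            freq = _parse_float(row["risk_allele_freq"], "risk_allele_freq", i, path)
            sample_size: int | None = None
            if not _is_missing(row.get("sample_size")):
                sample_size = _parse_int(row["sample_size"], "sample_size", i, path)
            else:
                n_missing_n += 1
            p_value: float | None = None
            if not _is_missing(row.get("p_value")):
                p_value = _parse_float(row["p_value"], "p_value", i, path)
            else:
                n_missing_p += 1
            try:
                records.append(
                    AssociationRecord(
                        disease=row["disease"].strip(),
                        snp_id=row["snp_id"].strip(),
                        risk_allele_freq=freq,
                        sample_size=sample_size,
                        p_value=p_value,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    if n_missing_n or n_missing_p:
        logger.info(
            "%s: %d rows without sample_size, %d without p_value (kept, excluded "
            "from operations that need them)", path, n_missing_n, n_missing_p,
        )
    return records


def write_association_table(records: Iterable[AssociationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_ASSOC_REQUIRED + _ASSOC_OPTIONAL)
        for rec in records:
            writer.writerow(
                [
                    rec.disease,
                    rec.snp_id,
                    repr(rec.risk_allele_freq),
                    "" if rec.sample_size is None else rec.sample_size,
                    "" if rec.p_value is None else repr(rec.p_value),
                ]
            )


def read_literature_counts(path: str | Path) -> list[LiteratureCounts]:
    """Read per-disease literature co-occurrence counts.

    The ``n_exposure`` column is optional; when the column is absent every
    record's ``n_exposure`` is None.
    """
    path = Path(path)
    records: list[LiteratureCounts] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, _COUNTS_REQUIRED, _COUNTS_OPTIONAL, path)
        has_exposure = "n_exposure" in reader.fieldnames
        for i, row in enumerate(reader, start=1):
            n_exposure: int | None = None
            if has_exposure and not _is_missing(row.get("n_exposure")):
                n_exposure = _parse_int(row["n_exposure"], "n_exposure", i, path)
            try:
                records.append(
                    LiteratureCounts(
                        disease=row["disease"].strip(),
                        n_disease=_parse_int(row["n_disease"], "n_disease", i, path),
                        n_env=_parse_int(row["n_env"], "n_env", i, path),
                        n_lifestyle=_parse_int(row["n_lifestyle"], "n_lifestyle", i, path),
                        n_exposure=n_exposure,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    return records


def write_literature_counts(records: Iterable[LiteratureCounts], path: str | Path) -> None:
    records = list(records)
    with_exposure = any(rec.n_exposure is not None for rec in records)
    columns = _COUNTS_REQUIRED + (_COUNTS_OPTIONAL if with_exposure else ())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            row = [rec.disease, rec.n_disease, rec.n_env, rec.n_lifestyle]
            if with_exposure:
                row.append("" if rec.n_exposure is None else rec.n_exposure)
            writer.writerow(row)


def _read_snp_lines(path: Path) -> frozenset[str]:
    ids: set[str] = set()
    with path.open(encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.add(line)
    return frozenset(ids)


def read_manifest(path: str | Path, name: str | None = None) -> PlatformManifest:
    """Read a platform manifest: one rsID per line, '#' comments allowed.

    Duplicate ids collapse silently (set semantics); an empty manifest is
    an error. ``name`` defaults to the file stem.
    """
    path = Path(path)
    ids = _read_snp_lines(path)
    if not ids:
        raise ValidationError(f"{path}: manifest is empty")
    logger.info("%s: %d unique SNP ids", path, len(ids))
    return PlatformManifest(name=name or path.stem, snp_ids=ids)


def read_selected(path: str | Path) -> SelectedSnpSet:
    """Read the positively-selected SNP id list (same line format as manifests)."""
    path = Path(path)
    ids = _read_snp_lines(path)
    logger.info("%s: %d unique selected SNP ids", path, len(ids))
    return SelectedSnpSet(snp_ids=ids)


def write_snp_list(snp_ids: Iterable[str], path: str | Path) -> None:
    """Write SNP ids one per line, sorted for byte-stable output."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for snp_id in sorted(set(snp_ids)):
            handle.write(snp_id + "\n")
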