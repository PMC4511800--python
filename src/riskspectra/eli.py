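"""Environment/Lifestyle Index (ELI): literature-based scoring of how much
a disease's etiology depends on environment and lifestyle.

ELI is the number of PubMed abstracts co-mentioning the disease with
"environment" or "lifestyle" per 1,000 abstracts mentioning the disease:
ELI = (n_env + n_lifestyle) / n_disease * 1000. The extended ELI adds a
third co-occurrence term, "exposure". Counts are term-level, so one
abstract matching two terms contributes to both numerator terms.

Values are kept unrounded internally; tables round to 1 decimal for
presentation only, so downstream rank statistics never compound rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .stats import TestResult, midranks, spearman
from .tables_io import LiteratureCounts

__all__ = [
    "EliRecord",
    "compute_eli",
    "compute_extended_eli",
    "eli_table",
    "rank_and_correlate",
    "assign_tertiles",
]


@dataclass(frozen=True)
class EliRecord:
    """Per-disease index values and (optional) tertile assignment.

    ``eli`` and ``eeli`` are per-1,000-abstract rates; ``tertile`` is 1
    (lowest ELI: environment/lifestyle-independent) through 3 (highest:
    dependent), or None before assignment.
    """

    disease: str
    eli: float
    eeli: float | None = None
    tertile: int | None = None


def compute_eli(counts: LiteratureCounts) -> float:
    """(n_env + n_lifestyle) / n_disease * 1000, unrounded."""
    if counts.n_disease <= 0:
        raise ValueError("n_disease must be positive")
    return (counts.n_env + counts.n_lifestyle) / counts.n_disease * 1000.0


def compute_extended_eli(counts: LiteratureCounts) -> float:
    """(n_env + n_lifestyle + n_exposure) / n_disease * 1000, unrounded."""
    if counts.n_exposure is None:
        raise ValueError(
            f"{counts.disease!r} has no n_exposure count; use compute_eli instead"
        )
    return (counts.n_env + counts.n_lifestyle + counts.n_exposure) / counts.n_disease * 1000.0


def eli_table(counts: Sequence[LiteratureCounts]) -> list[EliRecord]:
    """ELI (and extended ELI where exposure counts exist) for every disease."""
    records = []
    for c in counts:
        eeli = compute_extended_eli(c) if c.n_exposure is not None else None
        records.append(EliRecord(disease=c.disease, eli=compute_eli(c), eeli=eeli))
    return records


def rank_and_correlate(
    eli_values: dict[str, float], eeli_values: dict[str, float]
) -> tuple[dict[str, float], dict[str, float], TestResult]:
    """Rank diseases under each index and correlate the two rankings.

    Both dicts must cover the same disease set (n >= 3). Returns
    ``(ranks_eli, ranks_eeli, spearman_result)`` where rank 1 is the
    highest index value and ties share their mid-rank.
    """
    if set(eli_values) != set(eeli_values):
        only_a = sorted(set(eli_values) - set(eeli_values))
        only_b = sorted(set(eeli_values) - set(eli_values))
        raise ValueError(f"disease sets differ: only-ELI={only_a}, only-extended={only_b}")
    diseases = sorted(eli_values)
    if len(diseases) < 3:
        raise ValueError("need at least 3 diseases")
    a = [eli_values[d] for d in diseases]
    b = [eeli_values[d] for d in diseases]
    # midranks are ascending; highest value = rank 1
    ranks_a = len(a) + 1 - midranks(a)
    ranks_b = len(b) + 1 - midranks(b)
    result = spearman(a, b)
    return (
        dict(zip(diseases, ranks_a.tolist())),
        dict(zip(diseases, ranks_b.tolist())),
        result,
    )


def assign_tertiles(records: Sequence[EliRecord], n_groups: int = 3) -> list[EliRecord]:
    """Split diseases into ELI tertiles (or ``n_groups`` quantile groups).

    Diseases are sorted ascending by ELI (ties broken by case-folded
    name), then cut into groups as equal as possible; when the count does
    not divide evenly the extra diseases go to the lower-numbered groups.
    Group 1 holds the lowest-ELI diseases. Input order is preserved in the
    returned list.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if len(records) < n_groups:
        raise ValueError(f"need at least {n_groups} diseases, got {len(records)}")
    order = sorted(range(len(records)), key=lambda i: (records[i].eli, records[i].disease.casefold()))
    n = len(records)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
    tertile_of_index: dict[int, int] = {}
    pos = 0
    for g, size in enumerate(sizes, start=1):
        for i in order[pos : pos + size]:
            tertile_of_index[i] = g
        pos += size
    return [replace(rec, tertile=tertile_of_index[i]) for i, rec in enumerate(records)]
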