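"""Read and write CDC WONDER-style age-binned mortality tables.

WONDER exports are tab-delimited text with one row per (year, age group)
holding an integer death count; counts below the reporting threshold are
censored as "Suppressed".  Age-group labels vary with export options, so
both the verbose dialect ("< 1 year", "1-4 years", ..., "100+ years") and
the bare dialect ("0"/"<1", "1-4", ..., "100+") are accepted and
canonicalised onto the 22-group schema by bin edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sud_model import AgeBinSchema

__all__ = ["MortalityTable", "read_wonder", "write_wonder", "to_cumulative",
           "write_forecast"]

logger = logging.getLogger(__name__)

_YEAR_COLUMNS = ("year",)
_AGE_COLUMNS = ("age group", "age groups", "five-year age groups", "age")
_DEATH_COLUMNS = ("deaths", "death count")
_SUPPRESSED = {"suppressed", ""}


def _canonical_label_map(schema: AgeBinSchema) -> dict[str, int]:
    """Accepted spellings of every age-group label -> bin index."""
    mapping: dict[str, int] = {}
    for idx, (lo, hi) in enumerate(zip(schema.edges[:-1], schema.edges[1:])):
        lo_i, hi_i = int(lo), int(hi)
        if idx == 0:
            variants = ["< 1 year", "<1 year", "< 1", "<1", "0", "0 years"]
        elif hi >= schema.edges[-1]:
            variants = [f"{lo_i}+ years", f"{lo_i}+", f"{lo_i}-{hi_i} years",
                        f"{lo_i}-{hi_i}"]
        else:
            variants = [f"{lo_i}-{hi_i - 1} years", f"{lo_i}-{hi_i - 1}"]
        for v in variants:
            mapping[v.lower()] = idx
    return mapping


@dataclass
class MortalityTable:
    """Annual death counts on the 22-group schema.

    ``deaths[y, b]`` is the count for calendar year ``years[y]`` and bin
    ``b``; ``suppressed`` masks censored cells (their counts are 0).
    """

    years: np.ndarray
    schema: AgeBinSchema
    deaths: np.ndarray = field(repr=False)
    suppressed: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.suppressed = np.asarray(self.suppressed, dtype=bool)
        shape = (self.years.size, self.schema.n_bins)
        if self.deaths.shape != shape or self.suppressed.shape != shape:
            raise ValueError(f"deaths/suppressed must have shape {shape}")
        if np.any(self.deaths[~self.suppressed] < 0):
            raise ValueError("death counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for y, year in enumerate(self.years):
            for b, label in enumerate(self.schema.labels):
                rows.append(
                    {
                        "Year": int(year),
                        "Age Group": label,
                        "Deaths": "Suppressed"
                        if self.suppressed[y, b]
                        else int(round(self.deaths[y, b])),
                    }
                )
        return pd.DataFrame(rows)


def _find_column(columns, accepted, kind) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for name in accepted:
        if name in lowered:
            return lowered[name]
    raise ValueError(
        f"no {kind} column found; accepted names: {list(accepted)}, "
        f"got {list(columns)}"
    )


def read_wonder(path: str | Path, schema: AgeBinSchema | None = None) -> MortalityTable:
    """Parse a WONDER-style tab-delimited export.

    Rows may appear in any order; every (year, bin) pair must occur at
    most once, and each year present must cover all 22 bins (missing or
    "Suppressed" counts are masked).  Unknown age-group labels and
    non-integer counts raise with enough context to fix the file.
    """
    schema = schema or AgeBinSchema.cdc_22()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    year_col = _find_column(frame.columns, _YEAR_COLUMNS, "year")
    age_col = _find_column(frame.columns, _AGE_COLUMNS, "age-group")
    death_col = _find_column(frame.columns, _DEATH_COLUMNS, "death-count")
    label_map = _canonical_label_map(schema)

    records: dict[tuple[int, int], tuple[float, bool]] = {}
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        raw = dict(zip(frame.columns, row))
        label = raw[age_col].strip().lower()
        if label not in label_map:
            raise ValueError(
                f"unknown age-group label {raw[age_col]!r} on line {row_number}; "
                f"accepted labels: {sorted(set(label_map))}"
            )
        b = label_map[label]
        try:
            year = int(raw[year_col])
        except ValueError as exc:
            raise ValueError(
                f"non-integer year {raw[year_col]!r} on line {row_number}"
            ) from exc
        count_raw = raw[death_col].strip()
        if count_raw.lower() in _SUPPRESSED:
            value, masked = 0.0, True
        else:
            try:
                value, masked = float(int(count_raw)), False
            except ValueError as exc:
                raise ValueError(
                    f"non-integer death count {count_raw!r} on line {row_number}"
                ) from exc
        if (year, b) in records:
            raise ValueError(f"duplicate cell (year={year}, bin={b}) in {path}")
        records[(year, b)] = (value, masked)

    if not records:
        raise ValueError(f"no data rows in {path}")
    years = np.array(sorted({y for y, _ in records}))
    deaths = np.zeros((years.size, schema.n_bins))
    suppressed = np.zeros((years.size, schema.n_bins), dtype=bool)
    for yi, year in enumerate(years):
        for b in range(schema.n_bins):
            if (year, b) not in records:
                suppressed[yi, b] = True  # absent cell treated like censored
            else:
                deaths[yi, b], suppressed[yi, b] = records[(year, b)]
    return MortalityTable(years=years, schema=schema, deaths=deaths,
                          suppressed=suppressed)


def write_wonder(table: MortalityTable, path: str | Path) -> None:
    """Write the canonical tab-delimited dialect read by :func:`read_wonder`."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def to_cumulative(table: MortalityTable) -> np.ndarray:
    """Running per-bin sums from the first year, shape (n_years, 22).

    Years must be contiguous; suppressed cells contribute 0 with a logged
    warning (they are small by construction of the censoring rule).
    """
    if np.any(np.diff(table.years) != 1):
        raise ValueError(f"years are not contiguous: {table.years.tolist()}")
    n_suppressed = int(table.suppressed.sum())
    if n_suppressed:
        logger.warning(
            "treating %d suppressed cells as zero deaths in cumulative totals",
            n_suppressed,
        )
    return np.cumsum(table.deaths, axis=0)


def write_forecast(
    path: str | Path,
    years,
    schema: AgeBinSchema,
    predicted: np.ndarray,
    sigma: np.ndarray,
    n_sigma: float = 2.0,
) -> None:
    """Forecast table as CSV: year, bin label, predicted deaths, band half-width."""
    predicted = np.atleast_2d(predicted)
    sigma = np.atleast_2d(sigma)
    rows = []
    for yi, year in enumerate(np.atleast_1d(years)):
        for b, label in enumerate(schema.labels):
            rows.append(
                {
                    "year": int(year),
                    "age_group": label,
                    "predicted_deaths": predicted[yi, b],
                    f"{n_sigma:g}_sigma_half_width": n_sigma * sigma[yi, b],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
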