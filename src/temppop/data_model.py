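"""Domain types, CSV readers/writers and validation for the pipeline tables.

The pipeline works on five kinds of input tables, all plain CSV:

* a region attribute table (climate zone, remoteness class per region);
* monthly person-night count panels (destination nights from short-stay
  accommodation; origin nights from the domestic visitor survey);
* four annual national person-night totals;
* monthly estimated resident population (ERP) per region;
* a national monthly average-population-present control series.

Panels and series are carried in memory as :class:`pandas.Series` with a
``(region_id, year, month)`` MultiIndex (or ``(year, month)`` for the
national series).  Every reader validates against a closed schema and a
complete rectangular panel: a missing cell is a hard error, never a silent
zero, because downstream share fits and accounting identities assume
completeness.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "CLIMATE_ZONES",
    "REMOTENESS_CLASSES",
    "SchemaError",
    "ValidationError",
    "AlignmentError",
    "Month",
    "days_in_month",
    "months_of_year",
    "majority_class",
    "panel_index",
    "AnnualTotals",
    "read_regions",
    "write_regions",
    "read_count_panel",
    "write_count_panel",
    "read_erp",
    "write_erp",
    "read_national",
    "write_national",
    "read_annual_totals",
    "write_annual_totals",
]

#: The six temperature/humidity climate zones regions are classified into.
CLIMATE_ZONES: tuple[str, ...] = (
    "Hot humid summer",
    "Warm humid summer",
    "Hot dry summer, mild winter",
    "Hot dry summer, cold winter",
    "Warm summer, cool winter",
    "Mild warm summer, cold winter",
)

#: The four accessibility/remoteness classes (most to least accessible).
REMOTENESS_CLASSES: tuple[str, ...] = (
    "Major Cities",
    "Inner Regional",
    "Outer Regional",
    "Remote",
)

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A CSV file does not match its documented column schema."""


class ValidationError(ValueError):
    """A table violates a domain invariant (labels, signs, completeness)."""


class AlignmentError(ValueError):
    """Two tables that must share identical (region, month) keys do not."""


class Month(NamedTuple):
    """A calendar month, keyed by (year, month)."""

    year: int
    month: int

    @property
    def n_days(self) -> int:
        return days_in_month(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.year}-{self.month:02d}"


def days_in_month(m: Month | tuple[int, int]) -> int:
    """Gregorian length of a month, including the leap-year rule."""
    year, month = m
    if not 1 <= month <= 12:
        raise ValidationError(f"month must be in 1..12, got {month!r}")
    return calendar.monthrange(year, month)[1]


def months_of_year(year: int) -> list[Month]:
    """The twelve months of one calendar year, in order."""
    return [Month(year, m) for m in range(1, 13)]


def majority_class(weights: Mapping[str, float]) -> str:
    """Label with the largest total weight; ties broken lexicographically.

    Used to collapse a sub-region weighting (population shares for
    remoteness, area shares for climate) onto a single class label per
    region.  All-zero weights carry no information and are rejected.
    """
    if not weights:
        raise ValidationError("no weights supplied")
    if any(w < 0 for w in weights.values()):
        raise ValidationError("weights must be non-negative")
    if all(w == 0 for w in weights.values()):
        raise ValidationError("all weights are zero: no basis for classification")
    # max weight first, then lexicographically smallest label
    return min(weights, key=lambda k: (-weights[k], k))


def panel_index(
    region_ids: Iterable[str], months: Sequence[Month]
) -> pd.MultiIndex:
    """The complete rectangular (region_id, year, month) index."""
    return pd.MultiIndex.from_tuples(
        [(r, m.year, m.month) for r in region_ids for m in months],
        names=["region_id", "year", "month"],
    )


@dataclass(frozen=True)
class AnnualTotals:
    """Annual national person-night totals from the visitor surveys.

    ``nvs_visitor_nights`` and ``ivs_visitor_nights`` are destination-side
    nights spent by domestic and international visitors; the two origin
    totals are nights that usual residents spend away, domestically and
    internationally.
    """

    nvs_visitor_nights: float
    ivs_visitor_nights: float
    nvs_domestic_origin_nights: float
    nvs_international_origin_nights: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "nvs_visitor_nights": self.nvs_visitor_nights,
            "ivs_visitor_nights": self.ivs_visitor_nights,
            "nvs_domestic_origin_nights": self.nvs_domestic_origin_nights,
            "nvs_international_origin_nights": self.nvs_international_origin_nights,
        }


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read and validate the region attribute table.

    Columns: ``region_id, region_name, climate_zone, remoteness_class``.
    Class labels must come from the closed vocabularies
    :data:`CLIMATE_ZONES` and :data:`REMOTENESS_CLASSES`.
    """
    df = _read_csv(path, ["region_id", "region_name", "climate_zone", "remoteness_class"])
    df = df.astype({"region_id": str})
    dupes = df["region_id"][df["region_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate region_id values: {dupes}")
    bad_climate = sorted(set(df["climate_zone"]) - set(CLIMATE_ZONES))
    if bad_climate:
        raise ValidationError(
            f"unknown climate_zone label(s) {bad_climate}; "
            f"valid labels: {list(CLIMATE_ZONES)}"
        )
    bad_remote = sorted(set(df["remoteness_class"]) - set(REMOTENESS_CLASSES))
    if bad_remote:
        raise ValidationError(
            f"unknown remoteness_class label(s) {bad_remote}; "
            f"valid labels: {list(REMOTENESS_CLASSES)}"
        )
    return df.reset_index(drop=True)


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    cols = ["region_id", "region_name", "climate_zone", "remoteness_class"]
    regions[cols].to_csv(path, index=False)


def _read_panel_values(
    path: str | Path,
    value_column: str,
    regions: pd.DataFrame,
    months: Sequence[Month],
) -> pd.Series:
    """Shared machinery for long-format (region_id, year, month, value) CSVs."""
    if len(months) == 0:
        raise ValidationError("months sequence is empty")
    if len(regions) == 0:
        raise ValidationError("regions table is empty")
    df = _read_csv(path, ["region_id", "year", "month", value_column])
    df = df.astype({"region_id": str, "year": int, "month": int})
    name = Path(path).name

    known = set(regions["region_id"])
    unknown = sorted(set(df["region_id"]) - known)
    if unknown:
        raise ValidationError(f"{name}: rows for unknown region(s) {unknown}")
    if (df[value_column] < 0).any():
        bad = df.loc[df[value_column] < 0].iloc[0]
        raise ValidationError(
            f"{name}: negative {value_column} "
            f"({bad[value_column]}) at region {bad['region_id']} "
            f"{int(bad['year'])}-{int(bad['month']):02d}"
        )

    keys = list(zip(df["region_id"], df["year"], df["month"]))
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{name}: duplicated (region_id, year, month) rows")
    expected = panel_index(regions["region_id"], months)
    missing = sorted(set(expected) - set(keys))
    extra = sorted(set(keys) - set(expected))
    if missing or extra:
        msg = [f"{name}: panel is not the complete {len(regions)} regions x "
               f"{len(months)} months rectangle"]
        if missing:
            shown = ", ".join(f"({r}, {y}-{m:02d})" for r, y, m in missing[:10])
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            msg.append(f"missing cells: {shown}{more}")
        if extra:
            shown = ", ".join(f"({r}, {y}-{m:02d})" for r, y, m in extra[:10])
            msg.append(f"unexpected cells: {shown}")
        raise ValidationError("; ".join(msg))

    series = pd.Series(
        df[value_column].to_numpy(),
        index=pd.MultiIndex.from_tuples(keys, names=["region_id", "year", "month"]),
        name=value_column,
    )
    return series.reindex(expected)


def read_count_panel(
    path: str | Path,
    regions: pd.DataFrame,
    months: Sequence[Month],
    label: str = "nights",
) -> pd.Series:
    """Read a complete person-night count panel.

    Counts must be non-negative integers; every (region, month) cell must
    be present in the file.
    """
    series = _read_panel_values(path, "nights", regions, months)
    values = series.to_numpy()
    if not (values == values.astype(int)).all():
        raise ValidationError(f"{Path(path).name}: nights must be integers")
    return series.astype(int).rename(label)


def write_count_panel(panel: pd.Series, path: str | Path) -> None:
    df = panel.rename("nights").reset_index()
    df.to_csv(path, index=False)


def read_erp(
    path: str | Path, regions: pd.DataFrame, months: Sequence[Month]
) -> pd.Series:
    """Read the monthly estimated-resident-population panel (persons)."""
    return _read_panel_values(path, "erp", regions, months).astype(float)


def write_erp(erp: pd.Series, path: str | Path) -> None:
    erp.rename("erp").reset_index().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_national(path: str | Path, months: Sequence[Month]) -> pd.Series:
    """Read the national monthly average-population-present control series."""
    df = _read_csv(path, ["year", "month", "average_population_present"])
    df = df.astype({"year": int, "month": int})
    keys = list(zip(df["year"], df["month"]))
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{Path(path).name}: duplicated (year, month) rows")
    expected = [(m.year, m.month) for m in months]
    missing = sorted(set(expected) - set(keys))
    if missing:
        raise ValidationError(
            f"{Path(path).name}: missing month(s) "
            + ", ".join(f"{y}-{m:02d}" for y, m in missing)
        )
    series = pd.Series(
        df["average_population_present"].to_numpy(dtype=float),
        index=pd.MultiIndex.from_tuples(keys, names=["year", "month"]),
        name="average_population_present",
    ).reindex(pd.MultiIndex.from_tuples(expected, names=["year", "month"]))
    if (series <= 0).any():
        raise ValidationError(
            f"{Path(path).name}: average_population_present must be positive"
        )
    return series


def write_national(national: pd.Series, path: str | Path) -> None:
    national.rename("average_population_present").reset_index().to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_annual_totals(path: str | Path) -> AnnualTotals:
    """Read the four annual person-night totals from a key,value CSV."""
    df = _read_csv(path, ["key", "value"])
    mapping = dict(zip(df["key"], df["value"]))
    required = [
        "nvs_visitor_nights",
        "ivs_visitor_nights",
        "nvs_domestic_origin_nights",
        "nvs_international_origin_nights",
    ]
    missing = [k for k in required if k not in mapping]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing key(s) {missing}")
    return AnnualTotals(**{k: float(mapping[k]) for k in required})


def write_annual_totals(totals: AnnualTotals, path: str | Path) -> None:
    pd.DataFrame(
        {"key": list(totals.as_dict()), "value": list(totals.as_dict().values())}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
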