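"""Post-estimation analytics: APP/ERP ratios, peak seasons, correlations.

The APP/ERP ratio contrasts the dynamic average-population-present with
the static usual-residence population; its monthly trajectory classifies
each region as summer-peaking or winter-peaking.  Month sets follow the
Southern-Hemisphere half-years by default (summer: November-April,
winter: May-October) and are configurable.  Percentages in the peak-share
summary truncate toward zero, matching the convention of reporting
"75 per cent" for 253 of 335.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .data_model import AlignmentError, ValidationError

__all__ = [
    "SUMMER_MONTHS",
    "WINTER_MONTHS",
    "SeasonalClassification",
    "app_erp_ratio",
    "classify_peak_season",
    "summarize_peak_shares",
    "correlation_matrix",
    "write_classification",
    "write_correlations",
]

#: Southern-Hemisphere warm half-year.
SUMMER_MONTHS = frozenset({11, 12, 1, 2, 3, 4})
#: Southern-Hemisphere cool half-year.
WINTER_MONTHS = frozenset({5, 6, 7, 8, 9, 10})


@dataclass
class SeasonalClassification:
    """Per-region peak month and season, with run-level season counts."""

    table: pd.DataFrame  # columns: region_id, peak_month, season
    counts: dict[str, int]

    @property
    def n_regions(self) -> int:
        return len(self.table)


def app_erp_ratio(app_table: pd.DataFrame) -> pd.Series:
    """Per-cell APP / ERP; zero-ERP regions must be excluded upstream."""
    zero = app_table.index[app_table["erp"] <= 0]
    if len(zero):
        regions = sorted({r for r, _, _ in zero})
        raise ValidationError(
            f"ERP is not positive for region(s) {regions}; "
            "exclude them before computing ratios"
        )
    return (app_table["app"] / app_table["erp"]).rename("app_erp_ratio")


def classify_peak_season(
    ratios: pd.Series,
    summer_months: frozenset[int] = SUMMER_MONTHS,
) -> SeasonalClassification:
    """Classify each region by the month its APP/ERP ratio peaks in.

    ``ratios`` is indexed by (region_id, year, month) with exactly 12
    months per region.  The peak month is the argmax, earliest month on
    exact ties (a constant series therefore classifies by its first
    month); the season is "summer" if the peak month falls in
    ``summer_months``, else "winter".
    """
    rows = []
    for region_id, series in ratios.groupby(level="region_id", sort=True):
        series = series.droplevel("region_id")
        series = series.sort_index()
        if len(series) != 12 or series.index.get_level_values("month").nunique() != 12:
            raise ValidationError(
                f"region {region_id!r} does not have exactly 12 months of ratios"
            )
        _, peak_month = series.idxmax()  # first occurrence on ties
        season = "summer" if peak_month in summer_months else "winter"
        rows.append((region_id, int(peak_month), season))
    if not rows:
        raise ValidationError("no regions to classify")
    table = pd.DataFrame(rows, columns=["region_id", "peak_month", "season"])
    counts = table["season"].value_counts().to_dict()
    return SeasonalClassification(table=table, counts=counts)


def summarize_peak_shares(
    classification: SeasonalClassification | Mapping[str, int],
) -> dict[str, tuple[int, int]]:
    """Season -> (count, integer percent), percent truncated toward zero."""
    counts = (
        dict(classification.counts)
        if isinstance(classification, SeasonalClassification)
        else dict(classification)
    )
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("no classified regions to summarise")
    return {season: (n, (100 * n) // total) for season, n in counts.items()}


def correlation_matrix(
    panels: Mapping[str, pd.Series], method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations of candidate panels over aligned cells.

    All panels must share identical (region, month) keys and have
    positive variance.  ``method`` is "pearson" (default) or "spearman".
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if len(panels) < 2:
        raise ValidationError("need at least 2 panels to correlate")
    labels = list(panels)
    reference = panels[labels[0]].index
    for label, panel in panels.items():
        if not panel.index.equals(reference):
            raise AlignmentError(f"panel {label!r} keys differ from {labels[0]!r}")
        if float(panel.astype(float).var()) == 0.0:
            raise ValidationError(f"panel {label!r} has zero variance")
    df = pd.DataFrame({k: v.to_numpy(dtype=float) for k, v in panels.items()})
    return df.corr(method=method)


def write_classification(classification: SeasonalClassification, path) -> None:
    classification.table.to_csv(path, index=False)


def write_correlations(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True, float_format="%.6g")
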