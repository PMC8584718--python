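"""Assemble unscaled region-month populations and constrain them nationally.

The unscaled average population present of a region in a month is the
demographic account

    unscaled = ERP + visitors_domestic + visitors_international
                   - absent_domestic  - absent_international

Summed over regions this need not match the independently produced
national monthly average-population-present series, so the monthly gap

    delta(t) = national(t) - sum_s unscaled(t, s)

is allocated back to regions proportionally to their unscaled share of
the month, and added on:

    proportion(t, s) = unscaled(t, s) / sum_s unscaled(t, s)
    app(t, s)        = unscaled(t, s) + delta(t) * proportion(t, s)

which conserves the national total exactly each month.  Negative unscaled
cells (absent residents exceeding ERP plus visitors) are retained with a
warning rather than clamped — clamping would silently break conservation.
"""

from __future__ import annotations

import logging

import pandas as pd

from .components import COMPONENT_COLUMNS
from .data_model import AlignmentError, ValidationError

__all__ = [
    "assemble_unscaled",
    "national_gap",
    "apply_constraint",
    "constrain_to_national",
    "write_app_estimates",
]

logger = logging.getLogger(__name__)

_MONTH_LEVELS = ["year", "month"]


def assemble_unscaled(erp: pd.Series, components: pd.DataFrame) -> pd.Series:
    """ERP plus visitors minus absent residents, per (region, month) cell."""
    if not erp.index.equals(components.index):
        raise AlignmentError(
            "ERP and component panels are misaligned: "
            f"{sorted(set(erp.index).symmetric_difference(components.index))[:5]}"
        )
    unscaled = (
        erp
        + components["visitors_domestic"]
        + components["visitors_international"]
        - components["absent_domestic"]
        - components["absent_international"]
    ).rename("unscaled")
    n_negative = int((unscaled < 0).sum())
    if n_negative:
        worst = unscaled.idxmin()
        logger.warning(
            "%d unscaled cell(s) are negative (most negative: %r = %.3f); "
            "values retained to preserve the accounting identity",
            n_negative, worst, unscaled.min(),
        )
    return unscaled


def national_gap(national: pd.Series, unscaled: pd.Series) -> pd.Series:
    """Per-month difference national(t) - sum_s unscaled(t, s); sign kept."""
    monthly = unscaled.groupby(level=_MONTH_LEVELS, sort=False).sum()
    missing = sorted(set(monthly.index) - set(national.index))
    if missing:
        raise ValidationError(
            f"months missing from the national series: "
            + ", ".join(f"{y}-{m:02d}" for y, m in missing)
        )
    return (national.reindex(monthly.index) - monthly).rename("delta")


def apply_constraint(unscaled: pd.Series, delta: pd.Series) -> pd.DataFrame:
    """Allocate each month's gap proportionally and add it on.

    Returns a table with columns ``unscaled, proportion, adjustment, app``;
    per month, the proportions sum to 1 and sum_s app = sum_s unscaled +
    delta exactly.
    """
    monthly = unscaled.groupby(level=_MONTH_LEVELS, sort=False).sum()
    nonpos = monthly[monthly <= 0]
    if len(nonpos):
        y, m = nonpos.index[0]
        raise ValidationError(
            f"monthly unscaled total is not positive in {y}-{m:02d}: "
            "proportions are undefined"
        )
    month_keys = list(zip(unscaled.index.get_level_values("year"),
                          unscaled.index.get_level_values("month")))
    month_totals = monthly.loc[month_keys].to_numpy()
    delta_cells = delta.loc[month_keys].to_numpy()
    proportion = unscaled.to_numpy() / month_totals
    adjustment = delta_cells * proportion
    return pd.DataFrame(
        {
            "unscaled": unscaled.to_numpy(),
            "proportion": proportion,
            "adjustment": adjustment,
            "app": unscaled.to_numpy() + adjustment,
        },
        index=unscaled.index,
    )


def constrain_to_national(
    erp: pd.Series, components: pd.DataFrame, national: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Full assembly-and-constraint stage.

    Returns ``(app_table, delta)`` where ``app_table`` carries the ERP,
    the four components, the unscaled total, the proportional adjustment
    and the final average population present per (region, month) cell.
    """
    unscaled = assemble_unscaled(erp, components)
    delta = national_gap(national, unscaled)
    constrained = apply_constraint(unscaled, delta)
    table = pd.DataFrame({"erp": erp.to_numpy()}, index=erp.index)
    for col in COMPONENT_COLUMNS:
        table[col] = components[col].to_numpy()
    for col in ["unscaled", "proportion", "adjustment", "app"]:
        table[col] = constrained[col].to_numpy()
    return table, delta


def write_app_estimates(app_table: pd.DataFrame, path) -> None:
    cols = ["erp", *COMPONENT_COLUMNS, "unscaled", "adjustment", "app"]
    if "app_erp_ratio" in app_table.columns:
        cols.append("app_erp_ratio")
    app_table[cols].reset_index().to_csv(path, index=False, float_format="%.12g")
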