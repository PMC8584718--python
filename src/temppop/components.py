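"""Monthly average visitor and absent-resident components.

Each component allocates an annual national person-night total across
(region, month) cells by a normalised share surface and converts nights
into an average nightly head count by dividing by the number of nights in
the month:

    component(t, s) = share(t, s) * annual_total / n_days(t)

The destination (short-stay) share surface distributes both the domestic
and the international visitor-night totals; the origin share surface
distributes both absent-resident totals.  Because shares sum to one,
person-nights are conserved: sum over cells of component * n_days equals
the annual total exactly (up to float rounding).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AlignmentError, AnnualTotals, ValidationError, days_in_month
from .share_models import ShareSurface

__all__ = [
    "estimate_visitor_component",
    "estimate_absent_component",
    "assemble_components",
    "components_from_shares",
    "write_components",
    "COMPONENT_COLUMNS",
]

COMPONENT_COLUMNS = [
    "visitors_domestic",
    "visitors_international",
    "absent_domestic",
    "absent_international",
]


def _share_series(shares: ShareSurface | pd.Series) -> pd.Series:
    s = shares.shares if isinstance(shares, ShareSurface) else shares
    total = float(s.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(
            f"share surface is not normalised (sum = {total!r})"
        )
    return s


def _cell_n_days(index: pd.MultiIndex) -> np.ndarray:
    return np.array([days_in_month((y, m)) for _, y, m in index], dtype=float)


def estimate_visitor_component(
    shares: ShareSurface | pd.Series, annual_total: float
) -> pd.Series:
    """Average nightly visitors per cell from an annual night total.

    Called once with the domestic and once with the international
    visitor-night total, both over the destination share surface.
    """
    if annual_total < 0:
        raise ValidationError("annual_total must be non-negative")
    s = _share_series(shares)
    return s * annual_total / _cell_n_days(s.index)


def estimate_absent_component(
    shares: ShareSurface | pd.Series, annual_total: float
) -> pd.Series:
    """Average nightly absent residents per cell from an annual night total.

    Same arithmetic as the visitor component but over the origin share
    surface (where residents depart from rather than stay).
    """
    return estimate_visitor_component(shares, annual_total)


def assemble_components(
    visitors_domestic: pd.Series,
    visitors_international: pd.Series,
    absent_domestic: pd.Series,
    absent_international: pd.Series,
) -> pd.DataFrame:
    """Combine the four aligned component panels into one table."""
    panels = {
        "visitors_domestic": visitors_domestic,
        "visitors_international": visitors_international,
        "absent_domestic": absent_domestic,
        "absent_international": absent_international,
    }
    reference = visitors_domestic.index
    for name, panel in panels.items():
        if not panel.index.equals(reference):
            only_ref = sorted(set(reference) - set(panel.index))[:5]
            only_panel = sorted(set(panel.index) - set(reference))[:5]
            raise AlignmentError(
                f"component panel {name!r} is misaligned; "
                f"cells only in reference: {only_ref}; only in {name}: {only_panel}"
            )
    return pd.DataFrame({k: v.to_numpy() for k, v in panels.items()}, index=reference)


def components_from_shares(
    visitor_shares: ShareSurface | pd.Series,
    origin_shares: ShareSurface | pd.Series,
    totals: AnnualTotals,
) -> pd.DataFrame:
    """All four components from the two share surfaces and the annual totals."""
    return assemble_components(
        estimate_visitor_component(visitor_shares, totals.nvs_visitor_nights),
        estimate_visitor_component(visitor_shares, totals.ivs_visitor_nights),
        estimate_absent_component(origin_shares, totals.nvs_domestic_origin_nights),
        estimate_absent_component(origin_shares, totals.nvs_international_origin_nights),
    )


def write_components(components: pd.DataFrame, path) -> None:
    components.reset_index().to_csv(path, index=False, float_format="%.12g")
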