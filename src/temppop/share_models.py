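"""Offset Poisson GLMs that turn count panels into normalised share surfaces.

The destination model explains monthly short-stay visitor nights by month,
month x climate and month x remoteness effects; the origin model explains
resident-departure nights by month and month x remoteness effects.  Both
use a log link with a constant offset equal to the log of the panel grand
total, so the fitted mean of each (region, month) cell divided by the
grand total is a share, and with an intercept and the canonical link the
shares sum to one over the fitting cells by the score equations.

The model contract is stated on the design *column space* (intercept,
month indicators, month x class indicators in a full-rank treatment
coding), not on a particular coding: fitted cell means — the only
quantity consumed downstream — are invariant to the coding choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .data_model import Month, ValidationError, panel_index

__all__ = [
    "ShareSurface",
    "ShareModelFit",
    "fit_airbnb_share_model",
    "fit_origin_share_model",
    "fit_share_model",
    "predict_shares",
]

logger = logging.getLogger(__name__)

#: Fitted shares below this are treated as numerically zero and clamped.
SHARE_CLAMP = 1e-12

#: IRLS iteration cap and deviance-change convergence tolerance.
MAX_ITER = 100
TOL = 1e-8


@dataclass
class ShareSurface:
    """A normalised proportion surface over (region, month) cells.

    ``shares`` sums to 1 over all cells (within 1e-9 after
    renormalisation); ``renormalization_factor`` records the multiplier
    applied to the raw predicted shares (1 when the prediction set is the
    fitting set, since the score equations already normalise the fit).
    """

    shares: pd.Series
    source: str
    renormalization_factor: float = 1.0

    def __post_init__(self) -> None:
        if (self.shares < 0).any():
            raise ValidationError("shares must be non-negative")
        total = float(self.shares.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"shares must sum to 1 (got {total!r}); renormalise first"
            )


@dataclass
class ShareModelFit:
    """A fitted share model: coefficients, fitted shares and diagnostics."""

    params: pd.Series
    shares: pd.Series
    deviance: float
    converged: bool
    offset_total: float
    source: str
    include_climate: bool
    levels: dict = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficients as a (term, estimate) table for CSV export."""
        return pd.DataFrame(
            {"term": self.params.index, "estimate": self.params.to_numpy()}
        )


def _month_label(year: int, month: int) -> str:
    return f"{year}-{month:02d}"


def _observed_levels(
    regions: pd.DataFrame, months: Sequence[Month], include_climate: bool
) -> dict:
    """Factor levels seen in the data; first level of each is the reference."""
    levels = {
        "months": [_month_label(m.year, m.month) for m in months],
        "remoteness": sorted(regions["remoteness_class"].unique()),
        "climate": sorted(regions["climate_zone"].unique()) if include_climate else None,
    }
    return levels


def build_design(
    regions: pd.DataFrame,
    months: Sequence[Month],
    include_climate: bool,
    levels: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the treatment-coded design matrix over (region, month) cells.

    Columns: intercept; month indicators (reference = first month);
    month x climate indicators (all months, reference = first observed
    climate) when ``include_climate``; month x remoteness indicators
    likewise.  When ``levels`` is given (prediction), every cell's level
    must have been observed at fit time — no extrapolation.
    """
    if len(months) == 0:
        raise ValidationError("months sequence is empty")
    fitted_levels = levels is not None
    if levels is None:
        levels = _observed_levels(regions, months, include_climate)

    month_labels = [_month_label(m.year, m.month) for m in months]
    if fitted_levels:
        unseen = sorted(set(month_labels) - set(levels["months"]))
        if unseen:
            raise ValidationError(f"month level(s) not seen at fit time: {unseen}")
        for attr, key in (("climate_zone", "climate"), ("remoteness_class", "remoteness")):
            if levels[key] is None:
                continue
            unseen = sorted(set(regions[attr]) - set(levels[key]))
            if unseen:
                raise ValidationError(
                    f"{attr} level(s) not seen at fit time: {unseen}"
                )

    index = panel_index(regions["region_id"], months)
    n_regions = len(regions)
    n_months = len(months)
    cell_month = np.tile(month_labels, n_regions)
    cell_remote = np.repeat(regions["remoteness_class"].to_numpy(), n_months)
    cell_climate = (
        np.repeat(regions["climate_zone"].to_numpy(), n_months)
        if include_climate
        else None
    )

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(index))}
    for lab in levels["months"][1:]:
        cols[f"month[{lab}]"] = (cell_month == lab).astype(float)
    if include_climate:
        for lab in levels["months"]:
            in_month = cell_month == lab
            for c in levels["climate"][1:]:
                cols[f"month[{lab}]:climate[{c}]"] = (
                    in_month & (cell_climate == c)
                ).astype(float)
    for lab in levels["months"]:
        in_month = cell_month == lab
        for r in levels["remoteness"][1:]:
            cols[f"month[{lab}]:remoteness[{r}]"] = (
                in_month & (cell_remote == r)
            ).astype(float)

    X = pd.DataFrame(cols, index=index)
    return X, levels


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming the aliased columns if the design is rank deficient."""
    A = X.to_numpy()
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [X.columns[j] for j in piv[rank:]]
        raise ValidationError(
            f"rank-deficient design ({rank}/{X.shape[1]}): "
            f"aliased column(s) {sorted(aliased)}"
        )


def _normalize(raw: pd.Series) -> tuple[pd.Series, float]:
    """Clamp numerically-zero shares and renormalise.

    Returns the normalised shares and the multiplier applied to the raw
    shares (> 1 when the raw shares summed to less than one, e.g. when
    predicting over a subset of the fitting cells).
    """
    clamped = raw.where(raw >= SHARE_CLAMP, 0.0)
    total = float(clamped.sum())
    if total <= 0:
        raise ValidationError("all shares are zero after clamping")
    return clamped / total, 1.0 / total


def fit_share_model(
    panel: pd.Series,
    regions: pd.DataFrame,
    *,
    include_climate: bool,
    source: str,
    ridge: float = 0.0,
) -> ShareModelFit:
    """Fit an offset Poisson GLM to a count panel and return fitted shares.

    One observation per (region, month) cell; offset -log(panel total);
    fitted share = fitted mean / panel total.  ``ridge`` adds an optional
    L2 penalty for degenerate user data (default off).
    """
    months = _panel_months(panel)
    if len(months) < 2:
        raise ValidationError("need at least 2 months to fit a share model")
    total = float(panel.sum())
    if total <= 0:
        raise ValidationError("panel total must be positive for model fitting")

    X, levels = build_design(regions, months, include_climate)
    _check_full_rank(X)
    y = panel.reindex(X.index)
    if y.isna().any():
        raise ValidationError("panel does not cover all (region, month) cells")

    offset = np.full(len(y), np.log(total))
    model = sm.GLM(y.to_numpy(dtype=float), X.to_numpy(), family=sm.families.Poisson(),
                   offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-separation style warnings on empty strata
        if ridge > 0:
            res = model.fit_regularized(alpha=ridge, L1_wt=0.0)
            converged = True
        else:
            res = model.fit(maxiter=MAX_ITER, tol=TOL)
            converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("share model %r did not converge within %d iterations",
                       source, MAX_ITER)

    mu = np.asarray(res.fittedvalues if ridge == 0 else model.predict(res.params, offset=offset))
    shares_raw = pd.Series(mu / total, index=X.index, name=source)
    shares, _ = _normalize(shares_raw)
    deviance = float(getattr(res, "deviance", np.nan))
    params = pd.Series(np.asarray(res.params), index=X.columns, name="estimate")
    return ShareModelFit(
        params=params,
        shares=shares,
        deviance=deviance,
        converged=converged,
        offset_total=total,
        source=source,
        include_climate=include_climate,
        levels=levels,
    )


def fit_airbnb_share_model(panel: pd.Series, regions: pd.DataFrame,
                           ridge: float = 0.0) -> ShareModelFit:
    """Destination share model: month + month x climate + month x remoteness."""
    return fit_share_model(panel, regions, include_climate=True,
                           source="airbnb", ridge=ridge)


def fit_origin_share_model(panel: pd.Series, regions: pd.DataFrame,
                           ridge: float = 0.0) -> ShareModelFit:
    """Origin share model: month + month x remoteness (no climate terms)."""
    return fit_share_model(panel, regions, include_climate=False,
                           source="origin", ridge=ridge)


def predict_shares(
    fit: ShareModelFit,
    regions: pd.DataFrame,
    months: Sequence[Month],
    *,
    allow_nonconverged: bool = False,
) -> ShareSurface:
    """Predict a normalised share surface for a (region, month) set.

    Per-cell share = exp(x'beta) / offset_total, then renormalised to sum
    to one over the prediction set; the renormalisation factor is recorded
    and equals 1 (within 1e-9) when the prediction set is the fitting set.
    Factor levels unseen at fit time are an error — no extrapolation.
    """
    if not fit.converged and not allow_nonconverged:
        raise ValidationError(
            "model did not converge; pass allow_nonconverged=True to override"
        )
    if len(months) == 0:
        raise ValidationError("months sequence is empty")
    X, _ = build_design(regions, months, fit.include_climate, levels=fit.levels)
    # offset included at fit time, so log mu = x'beta + log(total) and
    # exp(x'beta) = mu / total is already the share
    eta = X.to_numpy() @ fit.params.to_numpy()
    raw = pd.Series(np.exp(eta), index=X.index, name=fit.source)
    shares, factor = _normalize(raw)
    return ShareSurface(shares=shares, source=fit.source,
                        renormalization_factor=factor)


def _panel_months(panel: pd.Series) -> list[Month]:
    """Ordered unique months of a (region_id, year, month)-indexed panel."""
    seen: dict[tuple[int, int], None] = {}
    for _, y, m in panel.index:
        seen[(int(y), int(m))] = None
    return [Month(y, m) for y, m in seen]
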