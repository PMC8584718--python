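"""Synthetic study inputs with known ground truth.

The real inputs to the pipeline — short-stay accommodation night panels,
visitor-survey totals, resident population series — are proprietary, so
this module builds an internally consistent substitute world:

* regions with climate and remoteness classes drawn from a configured mix;
* a ground-truth log-linear share surface over (region, month) cells with
  month, month x climate and month x remoteness effects (the same column
  space the share models fit), normalised to sum to one;
* independent Poisson counts around ``share x total_nights`` per cell —
  matching the fitting likelihood, so the realised panel total differs
  from the configured total only by sampling noise;
* ERP held constant over the year per region (no sub-annual resident
  dynamics are emulated);
* a national control series derived from the truth, optionally perturbed
  by a configured relative gap so the constraint stage has a known
  expected adjustment.

Everything is driven by one integer seed; identical configurations give
byte-identical CSV output.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import components as components_mod
from . import constrain as constrain_mod
from .data_model import (
    CLIMATE_ZONES,
    REMOTENESS_CLASSES,
    AnnualTotals,
    Month,
    ValidationError,
    months_of_year,
    panel_index,
    write_annual_totals,
    write_count_panel,
    write_erp,
    write_national,
    write_regions,
)
from .share_models import ShareSurface

__all__ = [
    "ShareCoefficients",
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "default_coefficients",
    "default_class_mix",
    "generate_regions",
    "true_share_surface",
    "simulate_count_panel",
    "generate_erp",
    "build_scenario",
    "write_scenario",
    "load_scenario_config",
]

#: Climate zones used by the default scenario (3 of the 6 labels).
DEFAULT_CLIMATES: tuple[str, ...] = (
    "Hot humid summer",
    "Warm summer, cool winter",
    "Mild warm summer, cold winter",
)

_MAX_REGION_REDRAWS = 100


@dataclass(frozen=True)
class ShareCoefficients:
    """Ground-truth log-linear effects for the share surfaces.

    ``month`` maps month number (1-12) to a seasonal log effect;
    ``climate_month`` and ``remoteness_month`` map (class label, month
    number) to interaction log effects.  The destination surface uses all
    three groups; the origin surface uses month and remoteness only.
    """

    month: Mapping[int, float]
    climate_month: Mapping[tuple[str, int], float]
    remoteness_month: Mapping[tuple[str, int], float]


def default_coefficients(
    climates: Sequence[str] = DEFAULT_CLIMATES,
    remoteness: Sequence[str] = REMOTENESS_CLASSES,
) -> ShareCoefficients:
    """Smooth seasonal defaults: a national summer peak (January, as in the
    Southern Hemisphere) modulated by climate and remoteness.

    Remote classes get a phase shift toward a winter peak, emulating dry-
    season tourism in hot-climate interior regions; amplitudes are modest
    (|log effect| <= ~0.5) so cell shares stay within about one order of
    magnitude of uniform.
    """
    month = {m: 0.35 * math.cos(2 * math.pi * (m - 1) / 12) for m in range(1, 13)}
    climate_month = {
        (c, m): 0.15 * i * math.cos(2 * math.pi * (m - 1) / 12 + 0.5 * i)
        for i, c in enumerate(climates)
        for m in range(1, 13)
    }
    remoteness_month = {
        (r, m): 0.12 * i * math.cos(2 * math.pi * (m - 1) / 12 + math.pi * i / 3)
        for i, r in enumerate(remoteness)
        for m in range(1, 13)
    }
    return ShareCoefficients(month, climate_month, remoteness_month)


def default_class_mix() -> tuple[tuple[tuple[str, str], float], ...]:
    """Uniform mix over the default 3 climates x 4 remoteness classes."""
    pairs = [(c, r) for c in DEFAULT_CLIMATES for r in REMOTENESS_CLASSES]
    return tuple(((c, r), 1.0 / len(pairs)) for c, r in pairs)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to build one synthetic study world.

    Defaults describe the standard test scenario: 20 regions over the 12
    months of 2018, a uniform 3-climate x 4-remoteness class mix, one
    million nights in each count panel, annual totals of tens of millions
    of person-nights against a ~50k-person regional ERP base, and a
    national series exactly consistent with the truth
    (``national_perturbation = 0``).
    """

    seed: int
    n_regions: int = 20
    year: int = 2018
    class_mix: tuple[tuple[tuple[str, str], float], ...] = field(
        default_factory=default_class_mix
    )
    coefficients: ShareCoefficients | None = None
    airbnb_total_nights: int = 1_000_000
    origin_total_nights: int = 1_000_000
    annual_totals: AnnualTotals = field(
        default_factory=lambda: AnnualTotals(
            nvs_visitor_nights=30_000_000.0,
            ivs_visitor_nights=10_000_000.0,
            nvs_domestic_origin_nights=30_000_000.0,
            nvs_international_origin_nights=12_000_000.0,
        )
    )
    erp_base: float = 50_000.0
    national_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValidationError("n_regions must be at least 2")
        if self.airbnb_total_nights <= 0 or self.origin_total_nights <= 0:
            raise ValidationError("panel total nights must be positive")
        probs = [p for _, p in self.class_mix]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("class_mix must be a probability distribution")
        for (climate, remote), _ in self.class_mix:
            if climate not in CLIMATE_ZONES:
                raise ValidationError(f"unknown climate zone {climate!r}")
            if remote not in REMOTENESS_CLASSES:
                raise ValidationError(f"unknown remoteness class {remote!r}")

    @property
    def months(self) -> list[Month]:
        return months_of_year(self.year)


@dataclass
class GroundTruth:
    """The true surfaces and outputs the estimators are measured against."""

    lambda_true: ShareSurface
    eta_true: ShareSurface
    app_true: pd.DataFrame
    delta_true: pd.Series


@dataclass
class Scenario:
    """A complete synthetic input set plus its ground truth."""

    config: ScenarioConfig
    regions: pd.DataFrame
    airbnb_panel: pd.Series
    origin_panel: pd.Series
    annual_totals: AnnualTotals
    erp: pd.Series
    national: pd.Series
    truth: GroundTruth


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_regions(cfg: ScenarioConfig) -> pd.DataFrame:
    """Draw region class labels from the configured mix, deterministically.

    When at least 4 regions are requested, the draw is repeated (bounded)
    until at least 2 distinct remoteness classes appear, so the origin
    model always has something to estimate; if the mix cannot supply two
    classes the degenerate single-class table is accepted.
    """
    rng = np.random.default_rng(_child_seeds(cfg.seed, 4)[0])
    pairs = [pair for pair, _ in cfg.class_mix]
    probs = np.array([p for _, p in cfg.class_mix])
    attainable = len({r for (_, r), p in cfg.class_mix if p > 0}) >= 2
    for _ in range(_MAX_REGION_REDRAWS):
        idx = rng.choice(len(pairs), size=cfg.n_regions, p=probs)
        drawn = [pairs[i] for i in idx]
        n_remote = len({r for _, r in drawn})
        if cfg.n_regions < 4 or n_remote >= 2 or not attainable:
            break
    else:
        raise ValidationError(
            "could not draw at least 2 remoteness classes within "
            f"{_MAX_REGION_REDRAWS} attempts"
        )
    return pd.DataFrame(
        {
            "region_id": [f"R{i + 1:03d}" for i in range(cfg.n_regions)],
            "region_name": [f"Region {i + 1:03d}" for i in range(cfg.n_regions)],
            "climate_zone": [c for c, _ in drawn],
            "remoteness_class": [r for _, r in drawn],
        }
    )


def true_share_surface(
    regions: pd.DataFrame,
    months: Sequence[Month],
    coefficients: ShareCoefficients,
    *,
    include_climate: bool = True,
    source: str = "true",
) -> ShareSurface:
    """Normalised shares proportional to exp(linear predictor) per cell."""
    index = panel_index(regions["region_id"], months)
    region_attrs = regions.set_index("region_id")
    lp = []
    for region_id, _, m in index:
        try:
            value = coefficients.month[m]
            row = region_attrs.loc[region_id]
            if include_climate:
                value += coefficients.climate_month[(row["climate_zone"], m)]
            value += coefficients.remoteness_month[(row["remoteness_class"], m)]
        except KeyError as exc:
            raise ValidationError(
                f"missing ground-truth coefficient for level {exc.args[0]!r}"
            ) from None
        lp.append(value)
    weights = np.exp(np.array(lp))
    shares = pd.Series(weights / weights.sum(), index=index, name=source)
    return ShareSurface(shares=shares, source=source)


def simulate_count_panel(
    truth: ShareSurface | pd.Series, total_nights: int, seed: int
) -> pd.Series:
    """Independent Poisson counts with mean ``share x total_nights`` per cell."""
    if total_nights <= 0:
        raise ValidationError("total_nights must be positive")
    shares = truth.shares if isinstance(truth, ShareSurface) else truth
    rng = np.random.default_rng(seed)
    counts = rng.poisson(shares.to_numpy() * float(total_nights))
    return pd.Series(counts, index=shares.index, name="nights")


def generate_erp(cfg: ScenarioConfig, regions: pd.DataFrame) -> pd.Series:
    """Monthly ERP, constant within the year per region.

    Region sizes are ``erp_base`` scaled by a seeded lognormal factor
    (sigma 0.4), giving the right order of spread between small rural and
    large urban regions without sub-annual dynamics.
    """
    rng = np.random.default_rng(_child_seeds(cfg.seed, 4)[1])
    factors = rng.lognormal(mean=0.0, sigma=0.4, size=len(regions))
    index = panel_index(regions["region_id"], cfg.months)
    values = np.repeat(cfg.erp_base * factors, len(cfg.months))
    return pd.Series(values, index=index, name="erp")


def build_scenario(cfg: ScenarioConfig) -> Scenario:
    """Build every input table plus the ground truth for one configuration.

    The ground-truth output table is produced by running the exact
    component/accounting/constraint pipeline on the true share surfaces;
    the national series is the monthly sum of the true unscaled account
    scaled by ``1 + national_perturbation``, so with zero perturbation the
    constraint stage is a no-op on the truth.
    """
    seeds = _child_seeds(cfg.seed, 4)
    regions = generate_regions(cfg)
    coeffs = cfg.coefficients or default_coefficients(
        climates=sorted(set(regions["climate_zone"])),
        remoteness=sorted(set(regions["remoteness_class"])),
    )
    lambda_true = true_share_surface(
        regions, cfg.months, coeffs, include_climate=True, source="airbnb"
    )
    eta_true = true_share_surface(
        regions, cfg.months, coeffs, include_climate=False, source="origin"
    )
    airbnb_panel = simulate_count_panel(lambda_true, cfg.airbnb_total_nights, seeds[2])
    origin_panel = simulate_count_panel(eta_true, cfg.origin_total_nights, seeds[3])
    erp = generate_erp(cfg, regions)

    true_components = components_mod.components_from_shares(
        lambda_true, eta_true, cfg.annual_totals
    )
    unscaled_true = constrain_mod.assemble_unscaled(erp, true_components)
    monthly = unscaled_true.groupby(level=["year", "month"], sort=False).sum()
    national = (monthly * (1.0 + cfg.national_perturbation)).rename(
        "average_population_present"
    )
    app_true, delta_true = constrain_mod.constrain_to_national(
        erp, true_components, national
    )
    truth = GroundTruth(
        lambda_true=lambda_true,
        eta_true=eta_true,
        app_true=app_true,
        delta_true=delta_true,
    )
    return Scenario(
        config=cfg,
        regions=regions,
        airbnb_panel=airbnb_panel,
        origin_panel=origin_panel,
        annual_totals=cfg.annual_totals,
        erp=erp,
        national=national,
        truth=truth,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> list[Path]:
    """Write the six input CSVs and three ground-truth CSVs; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _wrote(name: str) -> Path:
        p = outdir / name
        paths.append(p)
        return p

    write_regions(scenario.regions, _wrote("regions.csv"))
    write_count_panel(scenario.airbnb_panel, _wrote("airbnb_nights.csv"))
    write_count_panel(scenario.origin_panel, _wrote("origin_nights.csv"))
    write_annual_totals(scenario.annual_totals, _wrote("annual_totals.csv"))
    write_erp(scenario.erp, _wrote("erp_monthly.csv"))
    write_national(scenario.national, _wrote("national_monthly.csv"))
    scenario.truth.lambda_true.shares.rename("share").reset_index().to_csv(
        _wrote("lambda_true.csv"), index=False, float_format="%.12g"
    )
    scenario.truth.eta_true.shares.rename("share").reset_index().to_csv(
        _wrote("eta_true.csv"), index=False, float_format="%.12g"
    )
    scenario.truth.app_true.reset_index().to_csv(
        _wrote("app_true.csv"), index=False, float_format="%.12g"
    )
    return paths


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Read a ScenarioConfig from a flat TOML file.

    The ``[scenario]`` table must contain ``seed`` (no silent default).
    Optional keys: ``n_regions, year, airbnb_total_nights,
    origin_total_nights, erp_base, national_perturbation``, an
    ``annual_totals`` sub-table, and a ``class_mix`` array of
    ``{climate, remoteness, weight}`` tables.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "scenario" not in raw:
        raise ValidationError(f"{path}: missing [scenario] table")
    sc = raw["scenario"]
    if "seed" not in sc:
        raise ValidationError(f"{path}: scenario.seed is required")
    kwargs: dict = {"seed": int(sc["seed"])}
    for key in ("n_regions", "year", "airbnb_total_nights", "origin_total_nights"):
        if key in sc:
            kwargs[key] = int(sc[key])
    for key in ("erp_base", "national_perturbation"):
        if key in sc:
            kwargs[key] = float(sc[key])
    if "annual_totals" in sc:
        kwargs["annual_totals"] = AnnualTotals(
            **{k: float(v) for k, v in sc["annual_totals"].items()}
        )
    if "class_mix" in sc:
        entries = sc["class_mix"]
        weight = sum(float(e.get("weight", 1.0)) for e in entries)
        kwargs["class_mix"] = tuple(
            ((e["climate"], e["remoteness"]), float(e.get("weight", 1.0)) / weight)
            for e in entries
        )
    return ScenarioConfig(**kwargs)


def perturbed(cfg: ScenarioConfig, **changes) -> ScenarioConfig:
    """A copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **changes)
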