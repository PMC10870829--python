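"""Configuration objects and seeded random-number substreams.

All randomness in the package flows from a single root seed. Each stage
(inventory, truth, deaths, parcels, ...) draws from its own named
substream so that any stage can be regenerated in isolation and still
produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


# Named substreams: the integer id enters the SeedSequence spawn key, so
# adding a stream never perturbs existing ones.
_STAGE_IDS = {
    "inventory": 0,
    "truth": 1,
    "deaths": 2,
    "parcels": 3,
    "background": 4,
    "no2": 5,
    "confounder": 6,
    "population": 7,
}


def substream(seed: int, stage: str, *key: int) -> np.random.Generator:
    """Return the RNG for a named stage (and optional sub-key, e.g. EGU id)."""
    if stage not in _STAGE_IDS:
        raise ConfigError(f"unknown RNG stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_IDS[stage], *map(int, key)))
    return np.random.default_rng(ss)


#: Default strata: 2 age bands x 2 sexes with Medicare-like baseline
#: all-cause mortality rates (deaths per person-year).
DEFAULT_STRATA: tuple[tuple[str, float], ...] = (
    ("age65_74_f", 0.018),
    ("age65_74_m", 0.024),
    ("age75p_f", 0.060),
    ("age75p_m", 0.075),
)


@dataclass
class ConfoundingConfig:
    """A time-invariant, spatially smooth confounder.

    When enabled, a standardized zip-level covariate ``u`` is built from the
    long-run spatial pattern of coal PM2.5 (plus independent noise) and enters
    the mortality model multiplicatively as ``exp(gamma * u)``. Because ``u``
    does not vary over time, a first-differences analysis removes it by
    construction while a cross-sectional regression does not.
    """

    enabled: bool = False
    gamma: float = 0.0          # log-rate change per 1 SD of the confounder
    noise_sd: float = 0.3       # independent noise mixed into u (SD units)

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("confounding.noise_sd must be >= 0")


@dataclass
class WorldConfig:
    """Parameters of the synthetic study region.

    The geography is a unit-square lattice of ``grid_size**2`` cells, one cell
    per "ZIP code". Wind blows predominantly eastward by default, producing
    the eastward-skewed exposure gradients characteristic of secondary sulfate
    transport from coal plants.
    """

    # --- scale of the world -------------------------------------------------
    n_egus: int = 25
    n_years: int = 12
    grid_size: int = 20
    start_year: int = 1999
    strata: Sequence[tuple[str, float]] = DEFAULT_STRATA
    person_years_mean: float = 2000.0   # mean person-years per zip-stratum-year
    person_years_spread: float = 0.5    # lognormal sigma of zip population sizes

    # --- truth / health model ----------------------------------------------
    beta_true: float = float(np.log(1.0125))  # log RR per 1 ug/m3 coal PM2.5
    truth_scale: float = 0.1      # ug/m3 per unit emissions-weighted residence
    background_mean: float = 7.0  # mean non-coal PM2.5 (ug/m3)
    background_sd: float = 0.3    # lognormal sigma of the smooth background
    background_smooth: float = 3.0  # gaussian smoothing length (cells)
    background_year_sd: float = 0.05  # iid annual multiplicative jitter
    no2_mean: float = 10.0        # ppb
    no2_sd: float = 0.3
    confounding: ConfoundingConfig = field(default_factory=ConfoundingConfig)

    # --- emissions ----------------------------------------------------------
    emissions_base_mean: float = 100.0  # median annual SO2 mass (arbitrary units)
    emissions_base_sigma: float = 1.0   # lognormal sigma: heavy-tailed plant sizes
    emissions_decline: float = 0.92     # annual multiplicative factor
    scrubber_effect: float = 0.25       # multiplier applied from scrubber_year on
    scrubber_prob: float = 0.5
    retire_prob: float = 0.15

    # --- transport ----------------------------------------------------------
    wind_mean: tuple[float, float] = (0.35, 0.05)  # (east, north) cells/step
    diffusion_sd: float = 0.6     # isotropic random-walk step SD (cells)
    parcel_lifetime: float = 4.0  # e-folding survival time (steps)
    horizon: int = 10             # steps each parcel is tracked
    n_parcels: int = 500          # parcels per release
    releases_per_year: int = 6

    seed: int = 0

    def validate(self) -> None:
        if self.n_egus < 1 or self.n_years < 1 or self.grid_size < 1:
            raise ConfigError("n_egus, n_years and grid_size must all be >= 1")
        if not self.strata:
            raise ConfigError("at least one stratum is required")
        for label, rate in self.strata:
            if not 0 < rate < 1:
                raise ConfigError(f"baseline rate for stratum {label!r} must be in (0,1)")
        if not 0 < self.emissions_decline <= 1:
            raise ConfigError("emissions_decline must be in (0, 1]")
        if not 0 < self.scrubber_effect < 1:
            raise ConfigError("scrubber_effect must be in (0, 1)")
        if self.parcel_lifetime <= 0:
            raise ConfigError("parcel_lifetime must be > 0")
        if self.diffusion_sd < 0:
            raise ConfigError("diffusion_sd must be >= 0")
        if self.n_parcels < 1 or self.releases_per_year < 1 or self.horizon < 1:
            raise ConfigError("n_parcels, releases_per_year and horizon must be >= 1")
        if self.person_years_mean <= 0:
            raise ConfigError("person_years_mean must be > 0")
        if self.truth_scale <= 0:
            raise ConfigError("truth_scale must be > 0")
        self.confounding.validate()

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def n_zips(self) -> int:
        return self.grid_size * self.grid_size

    def zip_of_cell(self, i, j):
        """Row-major zip id of lattice cell (i east, j north)."""
        return np.asarray(j) * self.grid_size + np.asarray(i)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata"] = [list(s) for s in self.strata]
        d["wind_mean"] = list(self.wind_mean)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        d = dict(d)
        if "strata" in d:
            d["strata"] = tuple((str(l), float(r)) for l, r in d["strata"])
        if "wind_mean" in d:
            d["wind_mean"] = tuple(float(v) for v in d["wind_mean"])
        if "confounding" in d and not isinstance(d["confounding"], ConfoundingConfig):
            d["confounding"] = ConfoundingConfig(**d["confounding"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """Top-level run configuration: the world plus analysis options."""

    world: WorldConfig = field(default_factory=WorldConfig)
    training_year: int | None = None  # default: first study year
    copollutant_sets: Sequence[Sequence[str]] = (("no2",), ("residual_pm25",))
    period_subsets: Sequence[tuple[int, int]] | None = None  # default: thirds
    rr_comparisons: Sequence[Mapping] = (
        {"label": "medicare_total_pm25", "rr": 1.0060, "per_ug": 1.0,
         "ci": [1.0053, 1.0067]},
        {"label": "general_total_pm25", "rr": 1.016, "per_ug": 10.0,
         "ci": [1.014, 1.018]},
    )
    fd_mode: str = "consecutive"   # or "endpoints"
    fd_scale: str = "rate"         # or "log"
    emissions_quantile: float = 0.5

    def validate(self) -> None:
        self.world.validate()
        if self.fd_mode not in ("consecutive", "endpoints"):
            raise ConfigError("fd_mode must be 'consecutive' or 'endpoints'")
        if self.fd_scale not in ("rate", "log"):
            raise ConfigError("fd_scale must be 'rate' or 'log'")
        if not 0 < self.emissions_quantile <= 1:
            raise ConfigError("emissions_quantile must be in (0, 1]")

    def resolved_training_year(self) -> int:
        return self.world.start_year if self.training_year is None else int(self.training_year)

    def resolved_period_subsets(self) -> list[tuple[int, int]]:
        if self.period_subsets is not None:
            return [tuple(map(int, r)) for r in self.period_subsets]
        ys = self.world.years
        thirds = np.array_split(ys, 3)
        return [(int(t[0]), int(t[-1])) for t in thirds if len(t)]

    def to_dict(self) -> dict:
        return {
            "world": self.world.to_dict(),
            "training_year": self.training_year,
            "copollutant_sets": [list(s) for s in self.copollutant_sets],
            "period_subsets": None if self.period_subsets is None
            else [list(r) for r in self.period_subsets],
            "rr_comparisons": [dict(s) for s in self.rr_comparisons],
            "fd_mode": self.fd_mode,
            "fd_scale": self.fd_scale,
            "emissions_quantile": self.emissions_quantile,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "world" in d:
            d["world"] = WorldConfig.from_dict(d["world"])
        if "period_subsets" in d and d["period_subsets"] is not None:
            d["period_subsets"] = [tuple(map(int, r)) for r in d["period_subsets"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
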