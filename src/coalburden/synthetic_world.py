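"""Synthetic study region with known ground truth.

Generates, from one root seed:

* an EGU inventory — heavy-tailed plant sizes, declining annual SO2
  emissions with step drops at scrubber installation and zeroing at
  retirement;
* a ground-truth concentration field — coal PM2.5 as an *exact* linear
  functional of emissions through the analytic transport kernel, plus a
  smooth lognormal background and an independent NO2 field;
* a stratified person-time panel and Poisson death counts drawn from the
  log-linear concentration-response model
  deaths ~ Poisson(person_years * baseline(stratum)
                   * exp(beta_true * coal_pm25 + gamma * confounder)).

Because the generator inverts the analysis model with known parameters,
every downstream stage can be tested for parameter recovery without any
external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import ConfigError, WorldConfig, substream
from .dispersion import analytic_kernel

INVENTORY_COLUMNS = ["egu_id", "x", "y", "year", "so2_emissions",
                     "scrubber_year", "retire_year"]
CONCENTRATION_COLUMNS = ["zip_id", "year", "true_coal_pm25", "total_pm25", "no2"]
PANEL_COLUMNS = ["zip_id", "year", "stratum_id", "person_years", "deaths"]


def generate_inventory(config: WorldConfig, seed: int | None = None) -> pd.DataFrame:
    """One row per EGU-year: location, annual SO2 emissions, control events.

    Emissions follow base * decline^(year - start), multiplied by
    ``scrubber_effect`` from the scrubber year onward and set to zero from
    the retirement year onward.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = substream(seed, "inventory")
    g, ny = config.grid_size, config.n_years
    xs = rng.integers(0, g, size=config.n_egus)
    ys = rng.integers(0, g, size=config.n_egus)
    base = config.emissions_base_mean * rng.lognormal(
        0.0, config.emissions_base_sigma, size=config.n_egus)

    has_scrubber = rng.random(config.n_egus) < config.scrubber_prob
    scrub_lo = config.start_year + min(2, ny - 1)
    scrubber_year = rng.integers(scrub_lo, config.start_year + ny,
                                 size=config.n_egus)
    has_retire = rng.random(config.n_egus) < config.retire_prob
    retire_lo = config.start_year + max(ny // 2, 1)
    retire_year = rng.integers(retire_lo, config.start_year + ny,
                               size=config.n_egus)

    years = config.years
    rows = []
    for k in range(config.n_egus):
        decline = base[k] * config.emissions_decline ** (years - config.start_year)
        emis = decline.copy()
        sy = int(scrubber_year[k]) if has_scrubber[k] else None
        ry = int(retire_year[k]) if has_retire[k] else None
        if sy is not None:
            emis[years >= sy] *= config.scrubber_effect
        if ry is not None:
            emis[years >= ry] = 0.0
        rows.append(pd.DataFrame({
            "egu_id": k, "x": int(xs[k]), "y": int(ys[k]), "year": years,
            "so2_emissions": emis,
            "scrubber_year": pd.array([sy] * len(years), dtype="Int64"),
            "retire_year": pd.array([ry] * len(years), dtype="Int64"),
        }))
    return pd.concat(rows, ignore_index=True)[INVENTORY_COLUMNS]


def _smooth_field(rng: np.random.Generator, config: WorldConfig) -> np.ndarray:
    """Standardized spatially smooth field, one value per zip."""
    g = config.grid_size
    z = gaussian_filter(rng.standard_normal((g, g)), config.background_smooth,
                        mode="wrap")
    z = (z - z.mean()) / max(z.std(), 1e-12)
    # grid is indexed [j, i]; zip = j * g + i
    return z.reshape(-1)


def true_coal_field(inventory: pd.DataFrame, config: WorldConfig) -> pd.DataFrame:
    """Exact per-zip-year coal PM2.5: truth_scale * sum_egu emissions * kernel."""
    kernels = {}
    for egu_id, grp in inventory.groupby("egu_id"):
        x, y = float(grp["x"].iloc[0]), float(grp["y"].iloc[0])
        kernels[egu_id] = analytic_kernel((x + 0.5, y + 0.5), config)
    frames = []
    for year in config.years:
        conc = np.zeros(config.n_zips)
        yr = inventory[inventory["year"] == year]
        for egu_id, e in zip(yr["egu_id"], yr["so2_emissions"]):
            if e > 0:
                conc += e * kernels[egu_id]
        frames.append(pd.DataFrame({
            "zip_id": np.arange(config.n_zips), "year": int(year),
            "true_coal_pm25": config.truth_scale * conc}))
    return pd.concat(frames, ignore_index=True)


def generate_truth(inventory: pd.DataFrame, config: WorldConfig,
                   seed: int | None = None) -> pd.DataFrame:
    """Ground-truth concentrations: coal PM2.5, total PM2.5 and NO2 per zip-year."""
    config.validate()
    seed = config.seed if seed is None else seed
    field = true_coal_field(inventory, config)

    bg_rng = substream(seed, "background")
    bg_spatial = config.background_mean * np.exp(
        config.background_sd * _smooth_field(bg_rng, config))
    year_jitter = np.exp(config.background_year_sd
                         * bg_rng.standard_normal(config.n_years))
    no2_rng = substream(seed, "no2")
    no2_spatial = config.no2_mean * np.exp(
        config.no2_sd * _smooth_field(no2_rng, config))

    years = config.years
    field = field.sort_values(["year", "zip_id"]).reset_index(drop=True)
    bg = np.concatenate([bg_spatial * year_jitter[t] for t in range(len(years))])
    field["total_pm25"] = field["true_coal_pm25"] + bg
    field["no2"] = np.tile(no2_spatial, len(years))
    return field[CONCENTRATION_COLUMNS]


def generate_confounder(field: pd.DataFrame, config: WorldConfig,
                        seed: int | None = None) -> pd.Series:
    """Time-invariant zip covariate correlated with long-run coal PM2.5.

    Built as the standardized time-mean exposure pattern plus independent
    noise, restandardized — so its correlation with exposure is strong but
    not degenerate. Returns a Series indexed by zip_id.
    """
    seed = config.seed if seed is None else seed
    rng = substream(seed, "confounder")
    mean_x = field.groupby("zip_id")["true_coal_pm25"].mean()
    z = (mean_x - mean_x.mean()) / max(mean_x.std(), 1e-12)
    u = z + config.confounding.noise_sd * rng.standard_normal(len(z))
    u = (u - u.mean()) / max(u.std(), 1e-12)
    return u.rename("cov_confounder")


def generate_panel_skeleton(config: WorldConfig, seed: int | None = None,
                            confounder: pd.Series | None = None) -> pd.DataFrame:
    """Complete zip x year x stratum person-time table (no deaths yet)."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = substream(seed, "population")
    labels = [s[0] for s in config.strata]
    # zip-level population scale shared across strata and constant over time
    zip_scale = rng.lognormal(0.0, config.person_years_spread, size=config.n_zips)
    zip_scale /= zip_scale.mean()
    stratum_scale = rng.lognormal(0.0, 0.1, size=(config.n_zips, len(labels)))

    idx = pd.MultiIndex.from_product(
        [np.arange(config.n_zips), config.years, labels],
        names=["zip_id", "year", "stratum_id"])
    panel = idx.to_frame(index=False)
    py = (config.person_years_mean
          * zip_scale[panel["zip_id"]]
          * stratum_scale[panel["zip_id"],
                          pd.Categorical(panel["stratum_id"], labels).codes])
    panel["person_years"] = np.round(py, 1)
    if confounder is not None:
        panel["cov_confounder"] = confounder.reindex(panel["zip_id"]).to_numpy()
    return panel


def expected_deaths(panel: pd.DataFrame, field: pd.DataFrame,
                    config: WorldConfig) -> np.ndarray:
    """Poisson mean per panel row under the generator's log-linear model."""
    rates = dict(config.strata)
    merged = panel.merge(field[["zip_id", "year", "true_coal_pm25"]],
                         on=["zip_id", "year"], how="left")
    if merged["true_coal_pm25"].isna().any():
        bad = merged.loc[merged["true_coal_pm25"].isna(), ["zip_id", "year"]]
        zy = tuple(bad.iloc[0])
        raise ValueError(f"no concentration row for zip-year {zy}")
    base = merged["stratum_id"].map(rates).to_numpy(float)
    lin = config.beta_true * merged["true_coal_pm25"].to_numpy()
    if config.confounding.enabled:
        if "cov_confounder" not in merged:
            raise ValueError("confounding enabled but panel has no cov_confounder")
        lin = lin + config.confounding.gamma * merged["cov_confounder"].to_numpy()
    return merged["person_years"].to_numpy() * base * np.exp(lin)


def simulate_deaths(panel: pd.DataFrame, field: pd.DataFrame,
                    config: WorldConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw Poisson death counts onto a panel skeleton; seeded, reproducible."""
    config.validate()
    seed = config.seed if seed is None else seed
    if (panel["person_years"] <= 0).any():
        raise ValueError("person_years must be > 0 in every panel row")
    mu = expected_deaths(panel, field, config)
    rng = substream(seed, "deaths")
    out = panel.copy()
    out["deaths"] = rng.poisson(mu)
    cov_cols = [c for c in out.columns if c.startswith("cov_")]
    return out[PANEL_COLUMNS + cov_cols]


def generate_world(config: WorldConfig, seed: int | None = None) -> dict:
    """Full synthetic world: inventory, concentrations and death panel."""
    config.validate()
    seed = config.seed if seed is None else seed
    inventory = generate_inventory(config, seed)
    field = generate_truth(inventory, config, seed)
    confounder = (generate_confounder(field, config, seed)
                  if config.confounding.enabled else None)
    skeleton = generate_panel_skeleton(config, seed, confounder)
    panel = simulate_deaths(skeleton, field, config, seed)
    return {"inventory": inventory, "concentrations": field, "panel": panel}
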