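"""Reduced-complexity, trajectory-based exposure model.

Air parcels are released from each emitting plant, advected by a mean wind,
perturbed by isotropic Gaussian diffusion, and discounted by an exponential
survival weight standing in for SO2-to-sulfate conversion and deposition.
The emissions-weighted parcel residence count per zip cell is the unitless
raw exposure, mirroring the structure of trajectory-count source models:

    hyads_raw(zip, year, egu) =
        so2_emissions(egu, year) * weighted residence(zip) / n_parcels_released

Positions at step t of the walk are exactly N(start + t*wind, t*sigma^2 I),
which is what :func:`analytic_kernel` integrates cell-by-cell; the Monte
Carlo residence counts converge to that kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ConfigError, WorldConfig, substream

RAW_COLUMNS = ["zip_id", "year", "egu_id", "hyads_raw"]


@dataclass
class ParcelBatch:
    """All parcels released from one EGU in one year.

    positions has shape (n_parcels, horizon + 1, 2): recorded at steps
    0..horizon, starting at the source cell centre. weights[t] is the
    survival weight exp(-t / parcel_lifetime) shared by every parcel.
    """

    egu_id: int
    year: int
    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("parcel positions must be finite")
        if np.any(np.diff(self.weights) > 0):
            raise ValueError("survival weights must be nonincreasing")


def survival_weights(horizon: int, lifetime: float) -> np.ndarray:
    return np.exp(-np.arange(horizon + 1) / float(lifetime))


def simulate_batch(start_xy, n_parcels: int, wind, diffusion_sd: float,
                   lifetime: float, horizon: int, rng: np.random.Generator):
    """Random-walk trajectories for one release: returns (positions, weights)."""
    if diffusion_sd < 0:
        raise ConfigError("diffusion_sd must be >= 0")
    if n_parcels < 1:
        raise ConfigError("n_parcels must be >= 1")
    steps = np.asarray(wind, float) + rng.normal(
        0.0, diffusion_sd, size=(n_parcels, horizon, 2))
    positions = np.empty((n_parcels, horizon + 1, 2))
    positions[:, 0, :] = np.asarray(start_xy, float)
    positions[:, 1:, :] = positions[:, :1, :] + np.cumsum(steps, axis=1)
    return positions, survival_weights(horizon, lifetime)


def transport_parcels(inventory: pd.DataFrame, config: WorldConfig,
                      seed: int | None = None) -> Iterator[ParcelBatch]:
    """Yield one ParcelBatch per emitting EGU-year.

    Each (EGU, year) pair draws from its own counter-based substream, so the
    exposure of a single plant is reproducible in isolation.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    wind = np.asarray(config.wind_mean, float)
    n_total = config.n_parcels * config.releases_per_year
    emitting = inventory[inventory["so2_emissions"] > 0]
    for (egu_id, year), grp in emitting.groupby(["egu_id", "year"], sort=True):
        x, y = float(grp["x"].iloc[0]), float(grp["y"].iloc[0])
        rng = substream(seed, "parcels", int(egu_id), int(year))
        positions, weights = simulate_batch(
            (x + 0.5, y + 0.5), n_total, wind, config.diffusion_sd,
            config.parcel_lifetime, config.horizon, rng)
        yield ParcelBatch(int(egu_id), int(year), positions, weights)


def residence_counts(batch: ParcelBatch, grid_size: int) -> np.ndarray:
    """Survival-weighted residence per cell, flattened to zip order."""
    cells = np.floor(batch.positions).astype(np.int64)      # (n, T+1, 2)
    i, j = cells[..., 0], cells[..., 1]
    inside = (i >= 0) & (i < grid_size) & (j >= 0) & (j < grid_size)
    zips = (j * grid_size + i)[inside]
    w = np.broadcast_to(batch.weights, i.shape)[inside]
    return np.bincount(zips, weights=w, minlength=grid_size * grid_size)


def accumulate_exposure(batches: Iterable[ParcelBatch], inventory: pd.DataFrame,
                        config: WorldConfig) -> pd.DataFrame:
    """Emissions-weighted residence counts -> raw exposure table.

    Returns a DataFrame with columns zip_id, year, egu_id, hyads_raw,
    restricted to nonzero entries. Raises if an emitting EGU-year has no
    parcel batch.
    """
    n_total = config.n_parcels * config.releases_per_year
    emis = inventory.set_index(["egu_id", "year"])["so2_emissions"]
    frames = []
    seen = set()
    for batch in batches:
        key = (batch.egu_id, batch.year)
        seen.add(key)
        e = float(emis.loc[key])
        if e == 0:
            continue
        counts = residence_counts(batch, config.grid_size) * (e / n_total)
        nz = np.nonzero(counts)[0]
        frames.append(pd.DataFrame({
            "zip_id": nz, "year": batch.year, "egu_id": batch.egu_id,
            "hyads_raw": counts[nz]}))
    missing = {(int(k), int(y)) for (k, y), v in emis.items() if v > 0} - seen
    if missing:
        raise ValueError(
            f"no parcel batch for emitting EGU-years: {sorted(missing)[:5]}...")
    if not frames:
        return pd.DataFrame(columns=RAW_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["year", "zip_id", "egu_id"]).reset_index(drop=True)


def compute_raw_exposure(inventory: pd.DataFrame, config: WorldConfig,
                         seed: int | None = None) -> pd.DataFrame:
    """Convenience: transport + accumulate in one call."""
    return accumulate_exposure(
        transport_parcels(inventory, config, seed), inventory, config)


def exposure_totals(raw: pd.DataFrame, config: WorldConfig,
                    value_col: str = "hyads_raw") -> pd.DataFrame:
    """Per zip-year totals over EGUs, complete over the full zip x year grid."""
    full = pd.MultiIndex.from_product(
        [np.arange(config.n_zips), config.years], names=["zip_id", "year"])
    tot = raw.groupby(["zip_id", "year"])[value_col].sum()
    tot = tot.reindex(full, fill_value=0.0).rename(value_col).reset_index()
    return tot


def analytic_kernel(start_xy, config: WorldConfig) -> np.ndarray:
    """Expected survival-weighted residence per zip cell for one parcel.

    Dense quadrature of the transport kernel: at step t the parcel position is
    N(start + t*wind, t*diffusion_sd^2 I), so the expected residence in cell
    [i,i+1)x[j,j+1) is a product of 1-D normal CDF differences, summed over
    steps with survival weights. At t=0 (or with zero diffusion) the Gaussian
    degenerates to a point mass.
    """
    g = config.grid_size
    edges = np.arange(g + 1, dtype=float)
    wind = np.asarray(config.wind_mean, float)
    start = np.asarray(start_xy, float)
    weights = survival_weights(config.horizon, config.parcel_lifetime)
    out = np.zeros((g, g))
    for t in range(config.horizon + 1):
        mu = start + t * wind
        sd = config.diffusion_sd * np.sqrt(t)
        if sd == 0:
            ci, cj = int(np.floor(mu[0])), int(np.floor(mu[1]))
            if 0 <= ci < g and 0 <= cj < g:
                out[ci, cj] += weights[t]
            continue
        px = np.diff(norm.cdf(edges, loc=mu[0], scale=sd))
        py = np.diff(norm.cdf(edges, loc=mu[1], scale=sd))
        out += weights[t] * np.outer(px, py)
    # flatten in zip order: zip = j * g + i
    return out.T.reshape(-1)
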