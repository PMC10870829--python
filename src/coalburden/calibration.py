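"""Scaling of unitless raw exposure to coal PM2.5 (ug/m3).

The raw trajectory-count exposure is unitless; a single national
coefficient is fitted by zero-intercept least squares against a reference
concentration field for one training year. Zero intercept keeps per-EGU
apportionment exact: every microgram of coal PM2.5 remains attributable
to a specific plant. Alternative metrics (unscaled counts, an annual
sulfate adjustment) feed the sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FIELD_COLUMNS = ["zip_id", "year", "egu_id", "coal_pm25", "metric_tag"]


@dataclass
class ScalingModel:
    """Zero-intercept scaling coefficient with training-year diagnostics."""

    coefficient: float          # ug/m3 per unit raw exposure
    training_year: int
    r2: float
    rmse: float

    def to_dict(self) -> dict:
        return asdict(self)


def fit_scaling(raw_totals: pd.DataFrame, reference: pd.DataFrame,
                training_year: int) -> ScalingModel:
    """Fit c = argmin_{c>=0} sum_zips (reference - c * raw_total)^2.

    Closed form sum(x*y)/sum(x^2), clipped at zero; diagnostics (R^2, RMSE)
    are computed on the training year only.
    """
    ref_y = reference.loc[reference["year"] == training_year,
                          ["zip_id", "true_coal_pm25"]]
    raw_y = raw_totals.loc[raw_totals["year"] == training_year,
                           ["zip_id", "hyads_raw"]]
    if ref_y.empty or raw_y.empty:
        raise ValueError(f"training year {training_year} absent from inputs")
    m = ref_y.merge(raw_y, on="zip_id", how="left").fillna({"hyads_raw": 0.0})
    x = m["hyads_raw"].to_numpy(float)
    y = m["true_coal_pm25"].to_numpy(float)
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("unidentifiable scaling: all raw exposure totals are zero")
    c = float(x @ y) / sxx
    if c < 0:
        log.warning("scaling coefficient %.4g < 0; clipped to 0", c)
        c = 0.0
    resid = y - c * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return ScalingModel(c, int(training_year), r2, rmse)


def apply_scaling(raw: pd.DataFrame, model: ScalingModel) -> pd.DataFrame:
    """Multiply every per-EGU raw value by the coefficient; additivity is exact."""
    out = raw[["zip_id", "year", "egu_id"]].copy()
    out["coal_pm25"] = raw["hyads_raw"].to_numpy() * model.coefficient
    out["metric_tag"] = "scaled"
    return out


def make_unscaled_metric(raw: pd.DataFrame) -> pd.DataFrame:
    """Pass-through of raw trajectory counts, tagged as its own metric."""
    out = raw[["zip_id", "year", "egu_id"]].copy()
    out["coal_pm25"] = raw["hyads_raw"].to_numpy(float)
    out["metric_tag"] = "unscaled"
    return out


def sulfate_adjust(field: pd.DataFrame,
                   annual_adjustment: Mapping[int, float] | Callable[[int], float]
                   ) -> pd.DataFrame:
    """Multiply each year's values by a positive year-specific factor."""
    getter = (annual_adjustment.__getitem__
              if isinstance(annual_adjustment, Mapping) else annual_adjustment)
    years = np.sort(field["year"].unique())
    factors = {}
    for y in years:
        f = float(getter(int(y)))
        if f <= 0:
            raise ValueError(f"sulfate adjustment factor for year {y} must be > 0")
        factors[int(y)] = f
    out = field.copy()
    out["coal_pm25"] = out["coal_pm25"] * out["year"].map(factors)
    out["metric_tag"] = "sulfate_adjusted"
    return out


def field_totals(field: pd.DataFrame, config=None) -> pd.DataFrame:
    """Per zip-year total coal PM2.5 summed over EGUs.

    With a WorldConfig, the result is completed to the full zip x year grid
    with zeros so downstream joins never drop unexposed zips.
    """
    tot = field.groupby(["zip_id", "year"])["coal_pm25"].sum()
    if config is not None:
        full = pd.MultiIndex.from_product(
            [np.arange(config.n_zips), config.years], names=["zip_id", "year"])
        tot = tot.reindex(full, fill_value=0.0)
    return tot.reset_index()
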