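"""Confounding and specification sensitivity analyses.

Three tools probe how fragile the CRF and burden estimates are:

* the E-value — the minimum relative-risk association an unmeasured
  confounder would need with both exposure and mortality to explain away
  an observed RR;
* a first-differences panel estimator — regressing within-zip changes in
  death rate on changes in exposure, which removes *all* time-invariant
  zip-level confounding by construction (a companion cross-sectional
  estimator is provided to exhibit the bias it removes);
* an exposure-metric invariance audit — refitting the CRF and burden under
  the raw (unitless) and scaled metrics; because the burden depends on
  beta*x only, a pure rescaling must leave total excess deaths unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import round_sig
from .burden import compute_burden
from .crf import fit_stratified_poisson


def e_value(rr: float) -> float:
    """E-value of a relative risk, E = RR + sqrt(RR*(RR-1)), 4 sig. figures.

    Protective associations (rr < 1) are handled by the usual reciprocal
    transformation before applying the formula.
    """
    if rr <= 0:
        raise ValueError("relative risk must be > 0")
    r = 1.0 / rr if rr < 1 else float(rr)
    return round_sig(r + np.sqrt(r * (r - 1.0)), 4)


@dataclass
class FDEstimate:
    slope: float        # change in death rate per unit change in exposure
    se: float
    n_pairs: int
    mode: str           # "consecutive" or "endpoints"
    scale: str          # "rate" or "log"
    weighting: str = "person_years"

    def to_dict(self) -> dict:
        return {"slope": self.slope, "se": self.se, "n_pairs": self.n_pairs,
                "mode": self.mode, "scale": self.scale,
                "weighting": self.weighting}


def _rates(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
           exposure_col: str) -> pd.DataFrame:
    agg = (panel.groupby(["zip_id", "year"])[["deaths", "person_years"]]
           .sum().reset_index())
    agg["rate"] = agg["deaths"] / agg["person_years"]
    m = agg.merge(exposure_totals[["zip_id", "year", exposure_col]],
                  on=["zip_id", "year"], how="left")
    if m[exposure_col].isna().any():
        raise ValueError("exposure does not cover all panel zip-years")
    return m.rename(columns={exposure_col: "x"})


def first_differences(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
                      mode: str = "consecutive", scale: str = "rate",
                      exposure_col: str = "coal_pm25") -> FDEstimate:
    """Within-zip changes regression: WLS of delta-rate on delta-exposure.

    Strata are pooled to zip-year rates; year pairs are either all
    consecutive pairs pooled or the first/last endpoints only. Weights are
    the mean person-years of each pair. On the log scale, pairs touching a
    zero rate are dropped (zip-level annual counts can be zero).
    """
    if mode not in ("consecutive", "endpoints"):
        raise ValueError("mode must be 'consecutive' or 'endpoints'")
    if scale not in ("rate", "log"):
        raise ValueError("scale must be 'rate' or 'log'")
    df = _rates(panel, exposure_totals, exposure_col)
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("first differences need at least two years")
    pairs = (list(zip(years[:-1], years[1:])) if mode == "consecutive"
             else [(years[0], years[-1])])

    wide = df.set_index(["zip_id", "year"])
    frames = []
    for y1, y2 in pairs:
        a = wide.xs(y1, level="year")
        b = wide.xs(y2, level="year")
        j = a.join(b, lsuffix="_1", rsuffix="_2", how="inner")
        f = pd.DataFrame({
            "dx": j["x_2"] - j["x_1"],
            "w": 0.5 * (j["person_years_1"] + j["person_years_2"]),
        })
        if scale == "rate":
            f["dy"] = j["rate_2"] - j["rate_1"]
        else:
            ok = (j["rate_1"] > 0) & (j["rate_2"] > 0)
            f = f[ok.to_numpy()]
            f["dy"] = np.log(j.loc[ok, "rate_2"]) - np.log(j.loc[ok, "rate_1"])
        frames.append(f)
    d = pd.concat(frames, ignore_index=True)
    if d["dx"].nunique() < 2:
        raise ValueError("unidentifiable slope: exposure changes are constant")
    X = sm.add_constant(d["dx"].to_numpy())
    res = sm.WLS(d["dy"].to_numpy(), X, weights=d["w"].to_numpy()).fit()
    return FDEstimate(slope=float(res.params[1]), se=float(res.bse[1]),
                      n_pairs=int(len(d)), mode=mode, scale=scale)


def cross_sectional_slope(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
                          scale: str = "rate",
                          exposure_col: str = "coal_pm25") -> FDEstimate:
    """Pooled between-zip regression of death rate on exposure (no zip controls).

    Deliberately naive: subject to any time-invariant spatial confounding
    the first-differences estimator removes. Year fixed effects are included
    so the comparison isolates cross-sectional (spatial) confounding. On the
    log scale, zip-years with zero deaths are dropped.
    """
    if scale not in ("rate", "log"):
        raise ValueError("scale must be 'rate' or 'log'")
    df = _rates(panel, exposure_totals, exposure_col)
    if scale == "log":
        df = df[df["rate"] > 0]
    y = (np.log(df["rate"]) if scale == "log" else df["rate"]).to_numpy()
    year_fe = pd.get_dummies(df["year"], dtype=float)
    X = np.column_stack([df["x"].to_numpy(), year_fe.to_numpy()])
    res = sm.WLS(y, X, weights=df["person_years"].to_numpy()).fit()
    return FDEstimate(slope=float(res.params[0]), se=float(res.bse[0]),
                      n_pairs=int(len(df)), mode="cross_sectional", scale=scale)


def invariance_audit(panel: pd.DataFrame, raw_totals: pd.DataFrame,
                     scaled_totals: pd.DataFrame,
                     raw_col: str = "hyads_raw",
                     scaled_col: str = "coal_pm25") -> dict:
    """Refit CRF and burden under raw vs scaled exposure metrics.

    For scaled = c * raw the fitted slopes satisfy beta_raw = c * beta_scaled
    and total excess deaths coincide, since the burden depends on the product
    beta * x only. The audit reports the beta ratio and the relative burden
    difference without asserting them, so it can also flag genuinely
    different metrics.
    """
    fit_raw = fit_stratified_poisson(panel, raw_totals, exposure_col=raw_col,
                                     metric_tag="unscaled")
    fit_scaled = fit_stratified_poisson(panel, scaled_totals,
                                        exposure_col=scaled_col,
                                        metric_tag="scaled")
    deaths = (panel.groupby(["zip_id", "year"])["deaths"].sum().reset_index())
    b_raw = compute_burden(deaths, raw_totals, fit_raw, exposure_col=raw_col)
    b_scaled = compute_burden(deaths, scaled_totals, fit_scaled,
                              exposure_col=scaled_col)
    t_raw, t_scaled = b_raw.total(), b_scaled.total()
    denom = max(abs(t_scaled), 1e-300)
    return {
        "beta_raw": fit_raw.beta, "beta_scaled": fit_scaled.beta,
        "beta_ratio_raw_over_scaled": fit_raw.beta / fit_scaled.beta,
        "total_excess_raw": t_raw, "total_excess_scaled": t_scaled,
        "relative_burden_difference": (t_raw - t_scaled) / denom,
    }
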