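"""Concentration-response function estimation.

The CRF is a log-linear Poisson model for stratified death counts,

    deaths_{z,y,s} ~ Poisson(person_years_{z,y,s}
                             * exp(alpha_s + beta * x_{z,y} + gamma' w_{z,y})),

with stratum intercepts alpha_s as explicit fixed effects (for a Poisson
likelihood these give the same beta as conditioning the strata out) and a
log person-time offset. exp(beta) is the relative risk per 1 ug/m3 of coal
PM2.5, with a 95% Wald interval on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class CRFEstimate:
    beta: float                 # log RR per 1 ug/m3
    se_beta: float
    converged: bool
    n_obs: int
    loglike: float
    descriptor: dict = dc_field(default_factory=dict)

    @property
    def rr_per_unit(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - Z975 * self.se_beta)),
                float(np.exp(self.beta + Z975 * self.se_beta)))

    @property
    def beta_ci95(self) -> tuple[float, float]:
        return (self.beta - Z975 * self.se_beta, self.beta + Z975 * self.se_beta)

    @property
    def pct_increase(self) -> float:
        """Percent increase in mortality per 1 ug/m3, 100*(exp(beta)-1)."""
        return 100.0 * (self.rr_per_unit - 1.0)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "beta": self.beta, "se_beta": self.se_beta,
            "rr_per_unit": self.rr_per_unit,
            "ci95": [lo, hi], "pct_increase": self.pct_increase,
            "converged": self.converged, "n_obs": self.n_obs,
            "loglike": self.loglike, "descriptor": self.descriptor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CRFEstimate":
        return cls(beta=d["beta"], se_beta=d["se_beta"],
                   converged=d.get("converged", True), n_obs=d.get("n_obs", 0),
                   loglike=d.get("loglike", float("nan")),
                   descriptor=d.get("descriptor", {}))


def _merge_exposure(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
                    exposure_col: str) -> pd.DataFrame:
    df = panel.merge(exposure_totals[["zip_id", "year", exposure_col]],
                     on=["zip_id", "year"], how="left")
    if df[exposure_col].isna().any():
        bad = df.loc[df[exposure_col].isna(), ["zip_id", "year"]].iloc[0]
        raise ValueError(
            f"exposure missing for zip-year ({int(bad['zip_id'])}, {int(bad['year'])})")
    return df


def fit_stratified_poisson(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
                           adjust: Sequence[str] = (),
                           exposure_col: str = "coal_pm25",
                           metric_tag: str | None = None,
                           years: Sequence[int] | None = None) -> CRFEstimate:
    """Maximum-likelihood fit of the stratified Poisson CRF.

    Parameters
    ----------
    panel : complete zip x year x stratum table with person_years and deaths.
    exposure_totals : per zip-year exposure (column ``exposure_col``).
    adjust : names of extra covariate columns (taken from the merged table)
        entering linearly alongside the exposure.
    years : optional subset of calendar years to fit on.
    """
    df = _merge_exposure(panel, exposure_totals, exposure_col)
    if years is not None:
        years = list(map(int, years))
        df = df[df["year"].isin(years)]
        if df.empty:
            raise ValueError(f"no panel rows in year range {years}")
    if (df["person_years"] <= 0).any():
        raise ValueError("person_years must be > 0")
    if df["deaths"].sum() == 0:
        raise ValueError("zero total deaths: CRF not estimable")
    x = df[exposure_col].to_numpy(float)
    if np.unique(x).size < 2:
        raise ValueError("unidentifiable beta: exposure is constant")

    strata = pd.get_dummies(df["stratum_id"], prefix="stratum", dtype=float)
    X = pd.concat([strata.reset_index(drop=True),
                   df[[exposure_col, *adjust]].reset_index(drop=True)], axis=1)
    model = sm.GLM(df["deaths"].to_numpy(), X.to_numpy(),
                   family=sm.families.Poisson(),
                   offset=np.log(df["person_years"].to_numpy()))
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"Poisson IRLS failed to converge after {res.fit_history['iteration']} "
            f"iterations (deviance trace: {res.fit_history['deviance'][-3:]})")
    j = list(X.columns).index(exposure_col)
    beta = float(res.params[j])
    se = float(res.bse[j])
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise RuntimeError("non-finite CRF estimate: model not identifiable")
    desc = {
        "exposure_metric": metric_tag or exposure_col,
        "adjustment": list(adjust),
        "years": sorted(int(y) for y in df["year"].unique()),
        "strata": sorted(df["stratum_id"].unique()),
    }
    return CRFEstimate(beta=beta, se_beta=se, converged=bool(res.converged),
                       n_obs=int(len(df)), loglike=float(res.llf),
                       descriptor=desc)


def fit_with_copollutants(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
                          concentrations: pd.DataFrame,
                          copollutants: Sequence[str] = (),
                          exposure_col: str = "coal_pm25",
                          metric_tag: str | None = None) -> CRFEstimate:
    """CRF adjusted for co-pollutant markers.

    ``copollutants`` may include ``total_pm25``, ``residual_pm25`` (total
    minus coal, a marker for all other sources) and ``no2`` (a traffic
    marker). Residual PM2.5 is computed before fitting; negative residuals
    are clipped at zero and counted in the log.
    """
    allowed = {"total_pm25", "residual_pm25", "no2"}
    bad = set(copollutants) - allowed
    if bad:
        raise ValueError(f"unknown copollutants: {sorted(bad)}")
    if not copollutants:
        return fit_stratified_poisson(panel, exposure_totals,
                                      exposure_col=exposure_col,
                                      metric_tag=metric_tag)
    conc = concentrations[["zip_id", "year", "total_pm25", "no2"]].merge(
        exposure_totals[["zip_id", "year", exposure_col]],
        on=["zip_id", "year"], how="right")
    if conc[["total_pm25", "no2"]].isna().any().any():
        raise ValueError("concentration field does not cover all exposed zip-years")
    resid = conc["total_pm25"] - conc[exposure_col]
    n_neg = int((resid < 0).sum())
    if n_neg:
        log.warning("clipped %d negative residual PM2.5 values at 0", n_neg)
    conc["residual_pm25"] = resid.clip(lower=0.0)

    aug = panel.merge(conc[["zip_id", "year", *set(copollutants)]],
                      on=["zip_id", "year"], how="left")
    est = fit_stratified_poisson(aug, exposure_totals, adjust=list(copollutants),
                                 exposure_col=exposure_col, metric_tag=metric_tag)
    est.descriptor["residual_clipped_rows"] = n_neg
    return est


def fit_period_subset(panel: pd.DataFrame, exposure_totals: pd.DataFrame,
                      year_ranges: Sequence[tuple[int, int]],
                      exposure_col: str = "coal_pm25") -> list[CRFEstimate]:
    """Refit the CRF on inclusive calendar-year ranges (one estimate each)."""
    panel_years = set(panel["year"].unique())
    out = []
    for y0, y1 in year_ranges:
        ys = [y for y in range(int(y0), int(y1) + 1) if y in panel_years]
        if not ys:
            raise ValueError(f"year range ({y0}, {y1}) has no panel data")
        est = fit_stratified_poisson(panel, exposure_totals,
                                     exposure_col=exposure_col, years=ys)
        est.descriptor["year_range"] = [int(y0), int(y1)]
        out.append(est)
    return out


def excess_risk_ratio(rr_a: float, rr_b: float) -> float:
    """Ratio of excess risks (rr_a - 1)/(rr_b - 1), to 2 significant figures.

    Quantifies how much steeper one concentration-response slope is than
    another on the excess-risk scale (e.g. coal PM2.5 vs all-source PM2.5).
    """
    from ._util import round_sig
    if rr_b <= 1:
        raise ValueError("reference relative risk must be > 1")
    if rr_a <= 1:
        raise ValueError("relative risk must be > 1")
    return round_sig((rr_a - 1.0) / (rr_b - 1.0), 2)
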