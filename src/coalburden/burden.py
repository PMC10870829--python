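"""Attributable-death accounting.

Excess deaths are computed with the standard health-impact function: the
attributable fraction AF = 1 - exp(-beta * x) applied to observed (or
projected) deaths per zip-year, relative to a counterfactual with zero
coal PM2.5. Confidence bounds propagate only the CRF interval (beta at
its 95% endpoints), matching the convention that burden uncertainty
scales with the relative-risk uncertainty rather than with Poisson noise
in the observed counts. Zip-year burden is then apportioned to individual
plants in proportion to each plant's share of that zip-year's coal PM2.5,
which conserves totals to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_sig
from .crf import CRFEstimate


def attributable_fraction(beta: float, x) -> np.ndarray | float:
    """Fraction of deaths attributable to exposure x: 1 - exp(-beta*x)."""
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("exposure must be nonnegative")
    out = 1.0 - np.exp(-beta * x)
    return float(out) if out.ndim == 0 else out


@dataclass
class BurdenTable:
    """Zip-year excess deaths with CI bounds, plus run metadata."""

    zip_year: pd.DataFrame   # zip_id, year, deaths, exposure, excess_deaths, ci_low, ci_high
    meta: dict = dc_field(default_factory=dict)

    def total(self) -> float:
        return float(self.zip_year["excess_deaths"].sum())

    def total_ci(self) -> tuple[float, float]:
        return (float(self.zip_year["ci_low"].sum()),
                float(self.zip_year["ci_high"].sum()))

    def annual(self) -> pd.DataFrame:
        return (self.zip_year.groupby("year")[["excess_deaths", "ci_low", "ci_high"]]
                .sum().reset_index())


def project_deaths(deaths: pd.DataFrame, project_years: Sequence[int],
                   trailing: int = 3) -> pd.DataFrame:
    """Extend a zip-year death table to later years by trailing-mean projection.

    Each projected year's deaths in a zip equal the mean of the last
    ``trailing`` observed years — the rule used to carry baseline mortality
    past the end of the observed record.
    """
    project_years = sorted(int(y) for y in project_years)
    if not project_years:
        return deaths
    observed = sorted(deaths["year"].unique())
    prior = [y for y in observed if y < project_years[0]]
    if len(prior) < trailing:
        raise ValueError(
            f"projection needs >= {trailing} observed years before "
            f"{project_years[0]}; have {len(prior)}")
    tail = prior[-trailing:]
    base = (deaths[deaths["year"].isin(tail)]
            .groupby("zip_id")["deaths"].mean().reset_index())
    frames = [deaths]
    for y in project_years:
        f = base.copy()
        f["year"] = y
        frames.append(f)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["year", "zip_id"]).reset_index(drop=True)


def compute_burden(deaths: pd.DataFrame, exposure_totals: pd.DataFrame,
                   crf: CRFEstimate, project_years: Sequence[int] = (),
                   trailing: int = 3,
                   exposure_col: str = "coal_pm25") -> BurdenTable:
    """Excess deaths per zip-year relative to zero coal PM2.5.

    ``deaths`` holds observed zip-year totals; ``project_years`` are appended
    via :func:`project_deaths` before applying the attributable fraction.
    """
    deaths = project_deaths(deaths[["zip_id", "year", "deaths"]],
                            project_years, trailing)
    df = deaths.merge(exposure_totals[["zip_id", "year", exposure_col]],
                      on=["zip_id", "year"], how="left")
    if df[exposure_col].isna().any():
        bad = df.loc[df[exposure_col].isna(), ["zip_id", "year"]].iloc[0]
        raise ValueError(
            f"exposure missing for zip-year ({int(bad['zip_id'])}, {int(bad['year'])})")
    x = df[exposure_col].to_numpy(float)
    d = df["deaths"].to_numpy(float)
    b_lo, b_hi = crf.beta_ci95
    df["excess_deaths"] = d * attributable_fraction(crf.beta, x)
    df["ci_low"] = d * attributable_fraction(b_lo, x)
    df["ci_high"] = d * attributable_fraction(b_hi, x)
    df = df.rename(columns={exposure_col: "exposure"})
    meta = {
        "beta": crf.beta, "rr_per_unit": crf.rr_per_unit,
        "exposure_metric": crf.descriptor.get("exposure_metric", exposure_col),
        "projection": {"years": sorted(int(y) for y in project_years),
                       "trailing": trailing},
    }
    return BurdenTable(zip_year=df, meta=meta)


def apportion_to_egus(burden: BurdenTable, field: pd.DataFrame) -> pd.DataFrame:
    """Split each zip-year's excess deaths across plants by exposure share.

    Zip-years with zero total exposure (hence zero burden) contribute zero
    to every plant. Returns an egu_id x year table with CI columns.
    """
    per = field[["zip_id", "year", "egu_id", "coal_pm25"]].copy()
    tot = per.groupby(["zip_id", "year"])["coal_pm25"].transform("sum")
    per["share"] = np.where(tot > 0, per["coal_pm25"] / tot, 0.0)
    m = per.merge(burden.zip_year[["zip_id", "year", "excess_deaths",
                                   "ci_low", "ci_high"]],
                  on=["zip_id", "year"], how="inner")
    for c in ("excess_deaths", "ci_low", "ci_high"):
        m[c] = m[c] * m["share"]
    out = (m.groupby(["egu_id", "year"])[["excess_deaths", "ci_low", "ci_high"]]
           .sum().reset_index())
    return out.sort_values(["egu_id", "year"]).reset_index(drop=True)


def compare_rrs(deaths: pd.DataFrame, exposure_totals: pd.DataFrame,
                rr_specs: Sequence[Mapping], project_years: Sequence[int] = (),
                trailing: int = 3) -> pd.DataFrame:
    """Burden under alternative published relative risks.

    Each spec has ``label``, ``rr`` and ``per_ug`` (the concentration
    increment the RR refers to, e.g. 1.016 per 10 ug/m3) and optionally a
    ``ci`` pair on the same increment. RRs are converted to per-1-ug/m3
    log slopes beta = ln(rr)/per_ug before applying the burden machinery.
    """
    rows = []
    for spec in rr_specs:
        rr, per_ug = float(spec["rr"]), float(spec.get("per_ug", 1.0))
        if rr <= 1:
            raise ValueError(f"relative risk must be > 1 (got {rr})")
        if per_ug <= 0:
            raise ValueError("per_ug scale must be > 0")
        beta = np.log(rr) / per_ug
        ci = spec.get("ci")
        if ci is not None:
            lo, hi = (np.log(float(c)) / per_ug for c in ci)
            se = (hi - lo) / (2 * 1.959963984540054)
        else:
            lo = hi = beta
            se = 0.0
        est = CRFEstimate(beta=beta, se_beta=se, converged=True, n_obs=0,
                          loglike=float("nan"),
                          descriptor={"exposure_metric": "coal_pm25",
                                      "rr_spec": spec.get("label", "")})
        tbl = compute_burden(deaths, exposure_totals, est,
                             project_years=project_years, trailing=trailing)
        t_lo, t_hi = tbl.total_ci()
        rows.append({"label": spec.get("label", f"rr={rr}"),
                     "rr": rr, "per_ug": per_ug,
                     "rr_per_unit": float(np.exp(beta)),
                     "total_excess_deaths": tbl.total(),
                     "ci_low": t_lo, "ci_high": t_hi})
    return pd.DataFrame(rows)


def burden_share(total_attributable: float, total_deaths: float) -> float:
    """Attributable deaths as a percentage of all deaths, 2 significant figures."""
    if total_deaths <= 0:
        raise ValueError("total_deaths must be > 0")
    return round_sig(100.0 * total_attributable / total_deaths, 2)


def concentration_curve(egu_deaths: pd.Series, egu_emissions: pd.Series,
                        emissions_quantile: float) -> float:
    """Share of deaths from the top emitters holding a given emissions share.

    Plants are sorted by study-period emissions, descending; the smallest
    prefix whose cumulative emissions reach ``emissions_quantile`` of the
    total is selected and its share of total attributed deaths returned.
    """
    if not 0 < emissions_quantile <= 1:
        raise ValueError("emissions_quantile must be in (0, 1]")
    e = pd.Series(egu_emissions, dtype=float)
    d = pd.Series(egu_deaths, dtype=float).reindex(e.index)
    if (e < 0).any() or (d < 0).any():
        raise ValueError("emissions and deaths must be nonnegative")
    total_e = float(e.sum())
    if total_e <= 0:
        raise ValueError("total emissions must be > 0")
    order = e.sort_values(ascending=False).index
    cum = e.loc[order].cumsum() / total_e
    n_prefix = int(np.searchsorted(cum.to_numpy(), emissions_quantile) + 1)
    prefix = order[:n_prefix]
    total_d = float(d.sum())
    return float(d.loc[prefix].sum() / total_d) if total_d > 0 else 0.0
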