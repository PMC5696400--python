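"""Acoustic-signal analysis: temperature correction, call-vs-hybrid-index
regressions, and reproductive character displacement (RCD) metrics.

Advertisement-call characters of male frogs (pulse rate in pulses/s and
pulse number per call) depend on body temperature, so calls are first
corrected to a common temperature of 14 degrees C using per-population
linear slopes (corrected = observed - b * (T - 14)).  Corrected characters
are then (natural-log transformed) regressed on hybrid index, candidate
predictor sets are compared with AIC/BIC, regional displacement is
summarized as the Euclidean distance D_RCD between sympatric and pooled
allopatric character means, and D_RCD is regressed on regional admixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

CALL_VARIABLES = ("pulse_rate", "pulse_number")
TARGET_TEMP = 14.0

CALL_COLUMNS = [
    "individual",
    "locality",
    "species",
    "region",
    "sympatry",
    "pulse_rate",
    "pulse_number",
    "temperature",
]


@dataclass
class AcousticModelFit:
    """An OLS fit of hybrid index on one or two log call characters."""

    response: str
    predictors: tuple[str, ...]
    params: pd.Series
    r_squared: float
    p_value: float
    aic: float
    bic: float
    nobs: int


@dataclass
class RcdRegionSummary:
    """Displacement of one sympatric region's calls from allopatric baseline."""

    region: str
    species: str
    mean_pulse_rate: float
    mean_pulse_number: float
    baseline_pulse_rate: float
    baseline_pulse_number: float
    d_rcd: float
    n_sympatric: int
    n_allopatric: int


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    calls = calls.copy()
    for col in ("pulse_rate", "pulse_number", "temperature"):
        if col not in calls.columns:
            raise ValueError(f"call table missing column {col!r}")
    if (calls["pulse_rate"] <= 0).any():
        raise ValueError("pulse_rate must be positive")
    if (calls["pulse_number"] < 1).any():
        raise ValueError("pulse_number must be >= 1")
    if not np.isfinite(calls["temperature"]).all():
        raise ValueError("temperatures must be finite")
    return calls


# ---------------------------------------------------------------------------
# temperature correction
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    denom = np.sum(x**2)
    return float(np.sum(x * y) / denom) if denom > 0 else 0.0


def temperature_correct(
    calls: pd.DataFrame,
    target: float = TARGET_TEMP,
    min_n: int = 3,
    variables=CALL_VARIABLES,
) -> pd.DataFrame:
    """Correct call characters to a common temperature.

    For each population (locality) and variable, the slope b of variable on
    temperature is estimated by linear regression and the correction
    ``corrected = observed - b * (T - target)`` applied.  Populations with
    fewer than ``min_n`` recordings (or no temperature spread) fall back to
    the pooled within-species slope, with a log message.  Because OLS
    residuals are uncorrelated with the regressor, re-correcting corrected
    values is the identity.
    """
    calls = validate_calls(calls)
    if calls["temperature"].isna().all():
        raise ValueError("no temperatures available for correction")
    out = calls.copy()
    t = calls["temperature"].to_numpy(float)
    for var in variables:
        y = calls[var].to_numpy(float)
        species_slope = {
            sp: _ols_slope(
                t[calls["species"].to_numpy() == sp],
                y[calls["species"].to_numpy() == sp],
            )
            for sp in calls["species"].dropna().unique()
        }
        corrected = np.empty_like(y)
        for loc, grp_idx in calls.groupby("locality").indices.items():
            xt, yt = t[grp_idx], y[grp_idx]
            if len(grp_idx) >= min_n and np.ptp(xt) > 0:
                b = _ols_slope(xt, yt)
            else:
                sp = calls["species"].to_numpy()[grp_idx[0]]
                b = species_slope.get(sp, 0.0)
                logger.info(
                    "population %s: n=%d below min_n for %s; using pooled "
                    "%s slope %.4g",
                    loc, len(grp_idx), var, sp, b,
                )
            corrected[grp_idx] = yt - b * (xt - target)
        out[var] = corrected
    return out


# ---------------------------------------------------------------------------
# call ~ hybrid-index regressions
# ---------------------------------------------------------------------------

def _merged(calls: pd.DataFrame, hindex_df: pd.DataFrame) -> pd.DataFrame:
    merged = calls.merge(
        hindex_df[["individual", "h_hat"]], on="individual", how="inner"
    )
    dropped = len(calls) - len(merged)
    if dropped:
        logger.info("%d call records without matching genotypes dropped", dropped)
    return merged


def _fit(df: pd.DataFrame, predictors: tuple[str, ...]) -> AcousticModelFit:
    X = sm.add_constant(np.log(df[list(predictors)].to_numpy(float)))
    model = sm.OLS(df["h_hat"].to_numpy(float), X).fit()
    names = ["const"] + [f"log_{p}" for p in predictors]
    return AcousticModelFit(
        response="h_hat",
        predictors=predictors,
        params=pd.Series(model.params, index=names),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        aic=float(model.aic),
        bic=float(model.bic),
        nobs=int(model.nobs),
    )


def regress_call_on_hindex(
    calls: pd.DataFrame, hindex_df: pd.DataFrame, variable: str
) -> AcousticModelFit:
    """OLS of hybrid index on the natural-log of one corrected call variable."""
    if variable not in CALL_VARIABLES:
        raise ValueError(f"unknown call variable {variable!r}")
    df = _merged(calls, hindex_df)
    if len(df) < 3:
        raise ValueError("need at least 3 matched individuals")
    return _fit(df, (variable,))


def stepwise_select(
    calls: pd.DataFrame, hindex_df: pd.DataFrame
) -> dict:
    """Compare the three candidate predictor sets {PR}, {PN}, {PR, PN}.

    Returns a dict with the three fits and the AIC- and BIC-preferred
    predictor sets.  Near-perfectly collinear call variables are flagged
    and only the single-variable models compared.
    """
    df = _merged(calls, hindex_df)
    if len(df) < 4:
        raise ValueError("need at least 4 matched individuals")
    lx = np.log(df[list(CALL_VARIABLES)].to_numpy(float))
    collinear = bool(
        np.ptp(lx[:, 0]) == 0
        or np.ptp(lx[:, 1]) == 0
        or abs(np.corrcoef(lx[:, 0], lx[:, 1])[0, 1]) > 1.0 - 1e-12
    )
    fits = {
        ("pulse_rate",): _fit(df, ("pulse_rate",)),
        ("pulse_number",): _fit(df, ("pulse_number",)),
    }
    if not collinear:
        fits[CALL_VARIABLES] = _fit(df, CALL_VARIABLES)
    else:
        logger.warning("call variables collinear to machine precision; "
                       "joint model skipped")
    best_aic = min(fits, key=lambda k: fits[k].aic)
    best_bic = min(fits, key=lambda k: fits[k].bic)
    return {
        "fits": fits,
        "best_aic": best_aic,
        "best_bic": best_bic,
        "collinear": collinear,
    }


# ---------------------------------------------------------------------------
# RCD metrics
# ---------------------------------------------------------------------------

def rcd_distance(
    sympatric_calls: pd.DataFrame,
    allopatric_calls: pd.DataFrame,
    species: str,
    region: str = "",
    standardize: bool = False,
) -> RcdRegionSummary:
    """Euclidean displacement of a sympatric region from allopatric baseline.

    Means are taken over temperature-corrected pulse rate and pulse number
    of the given species; the pooled allopatric means are the nondisplaced
    baseline.  With ``standardize=True`` each variable is z-scored by the
    pooled (sympatric + allopatric) SD before the distance is computed,
    removing the unit mismatch between the two characters.
    """
    sym = sympatric_calls[sympatric_calls["species"] == species]
    allo = allopatric_calls[allopatric_calls["species"] == species]
    if sym.empty or allo.empty:
        raise ValueError(f"species {species!r}: empty sympatric or allopatric side")
    scale = {v: 1.0 for v in CALL_VARIABLES}
    if standardize:
        pooled = pd.concat([sym, allo])
        for v in CALL_VARIABLES:
            s = pooled[v].std(ddof=1)
            scale[v] = s if s > 0 else 1.0
    deltas = [
        (sym[v].mean() - allo[v].mean()) / scale[v] for v in CALL_VARIABLES
    ]
    return RcdRegionSummary(
        region=region,
        species=species,
        mean_pulse_rate=float(sym["pulse_rate"].mean()),
        mean_pulse_number=float(sym["pulse_number"].mean()),
        baseline_pulse_rate=float(allo["pulse_rate"].mean()),
        baseline_pulse_number=float(allo["pulse_number"].mean()),
        d_rcd=float(np.hypot(*deltas)),
        n_sympatric=len(sym),
        n_allopatric=len(allo),
    )


def rcd_region_table(
    calls: pd.DataFrame, species: str, standardize: bool = False
) -> pd.DataFrame:
    """D_RCD per sympatric region for one species, from corrected calls."""
    allo = calls[(calls["species"] == species) & (calls["sympatry"] == "allopatric")]
    rows = []
    sym = calls[(calls["species"] == species) & (calls["sympatry"] == "sympatric")]
    for region, grp in sym.dropna(subset=["region"]).groupby("region"):
        summ = rcd_distance(grp, allo, species, region, standardize=standardize)
        rows.append(
            {
                "region": region,
                "species": species,
                "d_rcd": summ.d_rcd,
                "mean_pulse_rate": summ.mean_pulse_rate,
                "mean_pulse_number": summ.mean_pulse_number,
                "baseline_pulse_rate": summ.baseline_pulse_rate,
                "baseline_pulse_number": summ.baseline_pulse_number,
                "n_sympatric": summ.n_sympatric,
                "n_allopatric": summ.n_allopatric,
            }
        )
    return pd.DataFrame(rows)


def rcd_vs_admixture(
    region_table: pd.DataFrame,
    admixture: pd.DataFrame,
    metrics=("prop_f1", "prop_undetermined", "prop_advanced"),
) -> pd.DataFrame:
    """OLS of each regional admixture metric on D_RCD.

    ``region_table`` comes from :func:`rcd_region_table`; ``admixture`` is a
    per-region summary with the metric columns.  Requires at least 3 regions
    (the regional replication is intrinsically small — a handful of
    sympatric regions per species — so these fits have low power).
    """
    df = region_table.merge(admixture, on="region", how="inner")
    if len(df) < 3:
        raise ValueError(
            "need at least 3 sympatric regions with both RCD and admixture "
            "estimates (regional regressions are low-powered by design)"
        )
    rows = []
    x = sm.add_constant(df["d_rcd"].to_numpy(float))
    for metric in metrics:
        y = df[metric].to_numpy(float)
        if np.ptp(y) == 0:
            slope, r2, p = 0.0, 0.0, 1.0
        else:
            fit = sm.OLS(y, x).fit()
            slope = float(fit.params[1])
            r2 = float(fit.rsquared)
            p = float(fit.f_pvalue)
        rows.append(
            {
                "species": df["species"].iloc[0],
                "metric": metric,
                "slope": slope,
                "r_squared": r2,
                "p_value": p,
                "n_regions": len(df),
            }
        )
    return pd.DataFrame(rows)
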