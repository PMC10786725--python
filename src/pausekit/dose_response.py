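"""Drug-response quantification: 4PL IC50, death ratio, growth rate, ΔΔCt.

The dose-response model is the four-parameter logistic (4PL)

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

with the plateaus restrained to the 0–100% response scale
(0 <= bottom <= top <= 100) and the IC50 optimized in log-space from a
multi-start grid.  Per-experiment IC50s are summarized by their mean with
a t-based 95% CI.  Tumour growth is fit as exponential (OLS on
log-transformed signal); qPCR relative expression uses the 2^-ΔΔCt method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "FourPLFit",
    "IC50Summary",
    "ExponentialFit",
    "RelativeExpression",
    "percent_response",
    "four_pl",
    "fit_4pl",
    "fit_4pl_by_experiment",
    "ic50_summary",
    "death_ratio",
    "exponential_fit",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class IC50Summary:
    mean: float
    ci_low: float
    ci_high: float
    n: int
    valid: bool


@dataclass(frozen=True)
class ExponentialFit:
    k: float  # per day
    intercept: float  # ln(signal) at t = 0
    r2: float  # on the log scale


@dataclass(frozen=True)
class RelativeExpression:
    delta_delta_ct: float
    fold_change: float


def percent_response(treated_endpoint: float, vehicle_endpoint: float) -> float:
    """Endpoint signal as percent of same-plate vehicle (= 100%)."""
    if vehicle_endpoint <= 0:
        raise ValueError("vehicle endpoint must be positive")
    pct = 100.0 * treated_endpoint / vehicle_endpoint
    if pct > 100.0:
        logger.info("response %.1f%% exceeds vehicle; not clipped", pct)
    return pct


def four_pl(x, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL curve; x = 0 returns the hill-sign-appropriate plateau."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / ic50) ** hill, np.inf if hill < 0 else 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def _residuals(params, logx, y):
    top, bottom, log_ic50, hill = params
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logx - log_ic50))) - y


def fit_4pl(
    doses,
    responses,
    n_starts: int = 10,
) -> FourPLFit:
    """Constrained 4PL least squares fit.

    Vehicle rows (dose 0) anchor the % normalization and are excluded from
    the curve fit.  The fit is run from a log-spaced grid of IC50 starting
    points spanning the dose range (hill starts ±1), the best RSS wins,
    and the (top, bottom, hill) triple is canonicalized so bottom <= top.
    Degenerate data (constant response) yields converged=False, never an
    exception.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    pos = doses > 0
    x, y = doses[pos], responses[pos]
    if np.unique(x).size < 3:
        raise ValueError("need >=3 distinct nonzero doses")
    if np.ptp(y) < 1e-9:
        logger.warning("constant responses; 4PL fit is degenerate")
        return FourPLFit(float(y.mean()), float(y.mean()), math.nan, 0.0,
                         0.0, converged=False)

    logx = np.log(x)
    lo = np.array([0.0, 0.0, logx.min() - 3.0, -10.0])
    hi = np.array([100.0, 100.0, logx.max() + 3.0, 10.0])
    top0 = float(np.clip(y.max(), 0, 100))
    bot0 = float(np.clip(y.min(), 0, 100))
    best = None
    for log_ic50_0 in np.linspace(logx.min(), logx.max(), n_starts):
        for hill0 in (1.0, -1.0):
            x0 = np.clip([top0, bot0, log_ic50_0, hill0], lo, hi)
            try:
                sol = optimize.least_squares(
                    _residuals, x0, bounds=(lo, hi), args=(logx, y), xtol=1e-12,
                    ftol=1e-12, gtol=1e-12,
                )
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol)
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.inf, False)
    rss, sol = best
    top, bottom, log_ic50, hill = sol.x
    if bottom > top:
        # the 4PL is symmetric under (top, bottom, hill) -> (bottom, top, -hill)
        top, bottom, hill = bottom, top, -hill
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(np.exp(log_ic50)),
        hill=float(hill),
        rss=rss,
        converged=bool(sol.success),
    )


def fit_4pl_by_experiment(
    table: pd.DataFrame,
    dose_col: str = "dose_nM",
    response_col: str = "response_pct",
    experiment_col: str = "experiment",
) -> dict[str, FourPLFit]:
    """Fit one 4PL per experiment from a long-format table."""
    return {
        str(exp): fit_4pl(grp[dose_col].to_numpy(), grp[response_col].to_numpy())
        for exp, grp in table.groupby(experiment_col)
    }


def ic50_summary(fits) -> IC50Summary:
    """Mean IC50 over converged per-experiment fits with a t-based 95% CI."""
    vals = np.array([f.ic50 for f in fits if f.converged and np.isfinite(f.ic50)])
    if vals.size < 2:
        logger.warning("fewer than 2 converged fits; CI undefined")
        mean = float(vals.mean()) if vals.size else math.nan
        return IC50Summary(mean, math.nan, math.nan, int(vals.size), valid=False)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    tcrit = float(stats.t.ppf(0.975, vals.size - 1))
    return IC50Summary(mean, mean - tcrit * sem, mean + tcrit * sem,
                       int(vals.size), valid=True)


def death_ratio(caspase_positive: float, live: float) -> float:
    """Apoptotic ratio: caspase-3/7-positive cells over live cells."""
    if live <= 0:
        raise ValueError("live cell count must be positive")
    if caspase_positive < 0:
        raise ValueError("caspase-positive count must be non-negative")
    return caspase_positive / live


def exponential_fit(time, signal) -> ExponentialFit:
    """OLS of ln(signal) on time (days): k = slope, R² on the log scale."""
    t = np.asarray(time, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.shape != s.shape or t.size < 3:
        raise ValueError("need >=3 matched timepoints")
    bad = np.nonzero(s <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive signal at timepoint t={t[bad[0]]}")
    res = stats.linregress(t, np.log(s))
    r2 = float(res.rvalue**2) if np.ptp(np.log(s)) > 0 else 1.0
    if np.ptp(np.log(s)) == 0:  # constant signal: k = 0, perfect flat fit
        return ExponentialFit(k=0.0, intercept=float(np.log(s[0])), r2=1.0)
    return ExponentialFit(k=float(res.slope), intercept=float(res.intercept), r2=r2)


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_vehicle: float,
    ct_ref_vehicle: float,
) -> RelativeExpression:
    """2^-ΔΔCt relative expression, target normalized to reference gene."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_vehicle, ct_ref_vehicle):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = float(
        (ct_target_treated - ct_ref_treated) - (ct_target_vehicle - ct_ref_vehicle)
    )
    return RelativeExpression(delta_delta_ct=ddct, fold_change=float(2.0**-ddct))
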