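"""Batch-culture growth kinetics and model-vs-experiment correlation.

From a batch time course (time, biomass, substrate concentration) the
per-interval specific growth rate and substrate uptake flux are

    mu_i    = ln(x_{i+1} / x_i) / dt_i
    v_s,i   = mu_i (C_{i+1} - C_i) / (x_i (exp(mu_i dt_i) - 1))

(uptake flux is negative for consumption, matching the exchange-reaction
sign convention).  Predicted growth rates from FBA are confronted with
observations using a through-origin linear fit plus the ordinary Pearson
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .lp import solve_fba
from .model import MetabolicModel, Medium, apply_medium

__all__ = [
    "BatchTimeCourse",
    "CorrelationReport",
    "growth_rate_series",
    "uptake_series",
    "fit_through_origin",
    "predicted_vs_observed",
]

#: below this |mu| the uptake formula switches to its analytic mu -> 0 limit
MU_SINGULARITY_TOL = 1e-9


@dataclass
class BatchTimeCourse:
    """(t_i, x_i, C_i) series: time (h), biomass (gDW/L), substrate (mmol/L)."""

    times: np.ndarray
    biomass: np.ndarray
    substrate: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValueError("time course needs at least 2 points")
        if len(self.biomass) != n or len(self.substrate) != n:
            raise ValueError("times, biomass and substrate must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.biomass <= 0):
            raise ValueError("biomass must be positive")
        if np.any(self.substrate < -1e-12):
            raise ValueError("substrate concentration must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CorrelationReport:
    """Through-origin slope plus the standard Pearson R and its p-value."""

    slope: float
    pearson_r: float
    p_value: float
    n: int


def growth_rate_series(tc: BatchTimeCourse) -> List[float]:
    """Per-interval specific growth rates mu_i = ln(x_{i+1}/x_i) / dt_i (1/h)."""
    dt = np.diff(tc.times)
    mu = np.log(tc.biomass[1:] / tc.biomass[:-1]) / dt
    return [float(m) for m in mu]


def uptake_series(tc: BatchTimeCourse) -> List[float]:
    """Per-interval substrate uptake fluxes (mmol/gDW/h), negative = consumption.

    Applies v_i = mu_i (C_{i+1} - C_i) / (x_i (exp(mu_i dt_i) - 1)); for
    |mu_i| below 1e-9 the removable singularity is replaced by its limit
    v_i = (C_{i+1} - C_i) / (x_i dt_i).
    """
    mu = growth_rate_series(tc)
    dt = np.diff(tc.times)
    dC = np.diff(tc.substrate)
    out: List[float] = []
    for i, m in enumerate(mu):
        if abs(m) < MU_SINGULARITY_TOL:
            out.append(float(dC[i] / (tc.biomass[i] * dt[i])))
        else:
            out.append(float(m * dC[i] / (tc.biomass[i] * (math.exp(m * dt[i]) - 1.0))))
    return out


def fit_through_origin(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Least-squares line through the origin plus Pearson correlation.

    The slope is sum(xy)/sum(x^2) (intercept forced to zero); R and its
    two-sided p-value are the ordinary Pearson statistics of (x, y), with
    the p-value from the t transform at n-2 degrees of freedom (NaN when
    n < 3 or either variable is constant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("x is identically zero; through-origin slope undefined")
    slope = float(np.sum(x * y) / sxx)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        r = np.nan if (np.ptp(x) == 0 or np.ptp(y) == 0) else _pearson_r(x, y)
        return CorrelationReport(slope=slope, pearson_r=r, p_value=math.nan, n=len(x))
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(slope=slope, pearson_r=float(r), p_value=float(p), n=len(x))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(np.sum(xc**2) * np.sum(yc**2)))
    return float(np.sum(xc * yc) / denom) if denom else math.nan


def predicted_vs_observed(
    model: MetabolicModel,
    conditions: Sequence[Mapping],
) -> Tuple[CorrelationReport, pd.DataFrame]:
    """FBA-predicted vs observed growth rates across culture conditions.

    Each condition is a mapping with keys ``medium`` (a Medium: exchange id
    -> uptake magnitude), ``observed`` (measured specific growth rate, 1/h)
    and optional ``label``.  Per condition the medium is applied, FBA
    solved, and the predicted growth rate recorded (0 when infeasible);
    observations and predictions are then compared with a through-origin
    fit.  Returns the correlation report and the per-condition table.
    """
    rows = []
    for i, cond in enumerate(conditions):
        conditioned = apply_medium(model, cond["medium"])
        result = solve_fba(conditioned)
        predicted = result.objective_value if result.ok else 0.0
        rows.append(
            {
                "label": cond.get("label", f"condition_{i + 1}"),
                "observed": float(cond["observed"]),
                "predicted": float(predicted),
                "status": result.status,
            }
        )
    table = pd.DataFrame(rows)
    report = fit_through_origin(table["observed"].to_numpy(), table["predicted"].to_numpy())
    return report, table
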