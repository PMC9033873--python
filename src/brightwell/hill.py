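"""Four-parameter Hill (sigmoidal) dose-response model and IC50 fitting.

The model is

    Y(X) = Min + (Max - Min) / (1 + (X / IC50)**h)

where ``Max`` and ``Min`` are the response plateaus at zero and saturating
drug concentration (OD450-like units on a 0-2 scale), ``IC50`` is the
concentration (µM) producing the half-maximal response, and ``h`` is the
Hill coefficient controlling slope steepness.  Fitting is unweighted least
squares over (Max, Min, log10 IC50, h) from a multi-start grid, so the fit
is robust when the dose window does not bracket the IC50.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseParams",
    "SeriesResponse",
    "HillFitResult",
    "hill_response",
    "fit_hill",
    "ic50_per_series",
]


@dataclass(frozen=True)
class DoseResponseParams:
    """The four Hill parameters governing one viability curve.

    ``max_response`` and ``min_response`` are on the OD-like 0-2 scale,
    ``ic50`` is in µM, ``hill_coefficient`` is dimensionless and positive.
    """

    max_response: float
    min_response: float
    ic50: float
    hill_coefficient: float

    def __post_init__(self) -> None:
        if not self.max_response > self.min_response:
            raise ValueError(
                f"max_response ({self.max_response}) must exceed "
                f"min_response ({self.min_response})"
            )
        if self.min_response < 0:
            raise ValueError("min_response must be >= 0")
        if self.max_response > 2:
            raise ValueError("max_response must be <= 2 (OD-like scale)")
        if not self.ic50 > 0:
            raise ValueError("ic50 must be positive")
        if not self.hill_coefficient > 0:
            raise ValueError("hill_coefficient must be positive")


@dataclass
class SeriesResponse:
    """One dose ladder: ordered (concentration, response) pairs.

    A series is the unit for IC50 fitting -- typically the 11 doses of one
    replicate of one experiment set.  ``source`` records whether responses
    are measured labels or model predictions.
    """

    series_id: str
    concentrations_um: np.ndarray
    responses: np.ndarray
    source: str = "measured"

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations_um.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations_um <= 0):
            raise ValueError("all concentrations must be positive")
        if len(np.unique(self.concentrations_um)) < 5:
            raise ValueError("a series needs >= 5 distinct concentrations")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass
class HillFitResult:
    """Outcome of a four-parameter sigmoidal least-squares fit."""

    params: DoseResponseParams | None
    rss: float
    converged: bool
    n_starts: int
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False
    non_inhibitory: bool = False
    extrapolated: bool = False

    @property
    def ic50(self) -> float:
        return self.params.ic50 if self.params is not None else math.nan


def hill_response(
    params: DoseResponseParams, concentration_um: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate the Hill curve at one or more concentrations (µM).

    Zero dose is valid and returns ``max_response`` exactly (the power term
    vanishes for positive Hill coefficient).  Monotonically non-increasing
    in concentration.
    """
    x = np.asarray(concentration_um, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    p = params
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / p.ic50) ** p.hill_coefficient, 0.0)
    y = p.min_response + (p.max_response - p.min_response) / (1.0 + ratio)
    if np.isscalar(concentration_um):
        return float(y)
    return y


# ---------------------------------------------------------------------------
# fitting

_H_BOUNDS = (0.1, 10.0)
_RESP_BOUNDS = (-0.5, 3.0)  # slightly outside the 0-2 label range, absorbs noise


def _hill_curve(x: np.ndarray, mx: float, mn: float, p: float, h: float) -> np.ndarray:
    # p = log10(ic50); positivity of IC50 by construction
    with np.errstate(over="ignore"):
        ratio = np.where(x > 0, 10.0 ** (h * (np.log10(x) - p)), 0.0)
    return mn + (mx - mn) / (1.0 + ratio)


def fit_hill(
    series: SeriesResponse,
    h_starts: Sequence[float] = (0.5, 1.0, 2.0),
    n_p_starts: int = 5,
    degenerate_span: float = 1e-6,
) -> HillFitResult:
    """Fit the four-parameter Hill model to one series by damped least squares.

    Optimizes (Max, Min, log10 IC50, h) from a multi-start grid:
    ``n_p_starts`` log-IC50 values spanning the tested concentration range
    crossed with ``h_starts``, with (Max, Min) initialized at the observed
    response extremes.  Returns the lowest-RSS converged solution.

    Flags set on the result:

    * ``degenerate`` -- fitted Max - Min below ``degenerate_span`` (flat
      data; IC50 is not identifiable and params are withheld).
    * ``non_inhibitory`` -- responses increase with dose: the mirrored
      (rising) curve fits with lower RSS than the inhibitory one.
    * ``extrapolated`` -- fitted IC50 outside [lowest dose / 10,
      highest dose * 10]; the number is an extrapolation of the window.
    """
    x = series.concentrations_um
    y = series.responses
    logx = np.log10(x)
    p_starts = np.linspace(logx.min(), logx.max(), n_p_starts)
    mx0 = float(y.max())
    mn0 = float(y.min())
    if mx0 - mn0 < 1e-12:  # exactly flat: solver has nothing to do
        return HillFitResult(
            params=None, rss=0.0, converged=False, n_starts=0,
            fitted=np.full_like(y, y.mean()), degenerate=True,
        )

    lo = [_RESP_BOUNDS[0], _RESP_BOUNDS[0], logx.min() - 2.0, _H_BOUNDS[0]]
    hi = [_RESP_BOUNDS[1], _RESP_BOUNDS[1], logx.max() + 2.0, _H_BOUNDS[1]]

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _hill_curve(x, *theta) - y

    best = None
    n_used = 0
    for p0 in p_starts:
        for h0 in h_starts:
            theta0 = np.clip([mx0, mn0, p0, h0], lo, hi)
            n_used += 1
            try:
                sol = least_squares(
                    residuals, theta0, bounds=(lo, hi),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)

    # non-inhibitory check: fit the mirrored (dose-ascending) curve and
    # compare RSS; a clearly better rising fit means responses grow with dose
    def rising_residuals(theta: np.ndarray) -> np.ndarray:
        mx_, mn_, p_, h_ = theta
        ratio = 10.0 ** (h_ * (np.log10(x) - p_))
        return (mn_ + (mx_ - mn_) * ratio / (1.0 + ratio)) - y

    rising_rss = math.inf
    try:
        rsol = least_squares(
            rising_residuals, np.clip([mx0, mn0, float(logx.mean()), 1.0], lo, hi),
            bounds=(lo, hi), method="trf", max_nfev=2000,
        )
        if rsol.success:
            rising_rss = float(np.sum(rsol.fun**2))
    except Exception:
        pass

    if best is None:
        return HillFitResult(
            params=None, rss=math.nan, converged=False, n_starts=n_used,
            fitted=np.full_like(y, math.nan),
            non_inhibitory=rising_rss < math.inf,
        )

    rss, (mx, mn, p, h) = best
    fitted = _hill_curve(x, mx, mn, p, h)
    # inverted plateaus (Max < Min) mean the optimizer found a rising curve
    non_inhibitory = (mx < mn - degenerate_span) or rising_rss < rss * (1 - 1e-6)
    degenerate = abs(mx - mn) < degenerate_span
    if degenerate or mx < mn:
        return HillFitResult(
            params=None, rss=rss, converged=False, n_starts=n_used,
            fitted=fitted, degenerate=degenerate, non_inhibitory=non_inhibitory,
        )

    ic50 = 10.0**p
    extrapolated = not (x.min() / 10.0 <= ic50 <= x.max() * 10.0)
    # fitted plateaus may dip slightly below 0 or above 2 on noisy data;
    # DoseResponseParams enforces the physical scale, so clamp for the
    # record while keeping RSS/fitted from the raw solution
    params = DoseResponseParams(
        max_response=min(float(mx), 2.0),
        min_response=max(float(mn), 0.0),
        ic50=float(ic50),
        hill_coefficient=float(h),
    )
    return HillFitResult(
        params=params, rss=rss, converged=True, n_starts=n_used,
        fitted=fitted, degenerate=degenerate,
        non_inhibitory=non_inhibitory, extrapolated=extrapolated,
    )


def ic50_per_series(series_list: Sequence[SeriesResponse]) -> pd.DataFrame:
    """Fit every series and tabulate one IC50 per series.

    Returns a DataFrame with columns ``series_id, ic50_um, max, min, hill,
    rss, converged, extrapolated``; non-converged series carry NaN
    parameters and are excluded from any downstream mean with a warning.
    An empty input yields an empty table, not an error.
    """
    rows = []
    for s in series_list:
        res = fit_hill(s)
        if not res.converged:
            warnings.warn(
                f"series {s.series_id!r} did not converge; excluded from summary",
                stacklevel=2,
            )
        p = res.params
        rows.append(
            {
                "series_id": s.series_id,
                "ic50_um": p.ic50 if p else math.nan,
                "max": p.max_response if p else math.nan,
                "min": p.min_response if p else math.nan,
                "hill": p.hill_coefficient if p else math.nan,
                "rss": res.rss,
                "converged": res.converged,
                "extrapolated": res.extrapolated,
            }
        )
    columns = [
        "series_id", "ic50_um", "max", "min", "hill",
        "rss", "converged", "extrapolated",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_ic50(table: pd.DataFrame) -> dict:
    """Mean +/- SD of IC50 over converged series (the n=6 summary)."""
    ok = table[table["converged"]]
    return {
        "n": int(len(ok)),
        "mean_ic50_um": float(ok["ic50_um"].mean()) if len(ok) else math.nan,
        "sd_ic50_um": float(ok["ic50_um"].std(ddof=1)) if len(ok) > 1 else math.nan,
    }
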