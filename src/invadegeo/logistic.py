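"""Four-parameter logistic invasion model.

An invading population founded at time ``t0`` with (proxy) size ``N0``
grows at intrinsic rate ``r`` toward a (proxy) carrying capacity ``K``:

    N(t) = N0 * K / (N0 + (K - N0) * exp(-r * (t - t0)))

Annual observation counts are assumed proportional to population size,
``n_t = c * N_t`` with an unknown constant ``c``.  The model is fit
directly to the counts, so the fitted N0 and K absorb ``c`` and are
proxies only; ``r`` and ``t0`` are invariant to ``c`` and are the
scientifically meaningful estimates.

Identifiability.  The curve can be rewritten as K / (1 + C*exp(-r*t))
with C = (K - N0)/N0 * exp(r*t0): only (K, r, C) are determined by the
data, and (N0, t0) trade off along an exact zero-residual ridge.  The
fitter therefore reports the ridge point at a canonical *founding
fraction* N0/K (default 1e-3): t0 is the time at which the population
stood at one thousandth of carrying capacity.  The convention is
scale-invariant, so t0 and r are unaffected by the unknown constant c.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from invadegeo.occurrences import AnnualCountSeries


class DegenerateSeriesError(ValueError):
    """The series carries no growth signal (e.g. all zeros)."""


class InsufficientDataError(ValueError):
    """Fewer observations than a 4-parameter fit can support."""


@dataclass
class LogisticParams:
    """Parameters of the logistic invasion curve.

    n0 : initial population proxy (> 0), in observation units (c * N0)
    k  : carrying-capacity proxy (> 0), in observation units (c * K)
    r  : instantaneous rate of increase, per year
    t0 : invasion time, decimal calendar year
    """

    n0: float
    k: float
    r: float
    t0: float

    def __post_init__(self) -> None:
        if not (self.n0 > 0):
            raise ValueError("n0 must be > 0")
        if not (self.k > 0):
            raise ValueError("k must be > 0")
        if not math.isfinite(self.r):
            raise ValueError("r must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.n0, self.k, self.r, self.t0], dtype=float)


@dataclass
class LogisticFitResult:
    params: LogisticParams
    rss: float
    fitted: list[float]
    n_starts: int
    converged: bool

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")


def logistic_nt(params: LogisticParams, t) -> np.ndarray | float:
    """Expected count at time ``t`` (scalar or array of decimal years).

    At ``t == t0`` the value is exactly ``n0``; as ``t`` grows (with
    r > 0) it saturates at ``k``.  The denominator is positive for all
    valid parameters, so the curve is defined everywhere.
    """
    n0, k, r, t0 = params.n0, params.k, params.r, params.t0
    t = np.asarray(t, dtype=float)
    # clip the exponent to avoid overflow far in the past; the curve is
    # indistinguishable from its limit there
    z = np.clip(-r * (t - t0), -700.0, 700.0)
    out = n0 * k / (n0 + (k - n0) * np.exp(z))
    return float(out) if out.ndim == 0 else out


def _model(theta: np.ndarray, years: np.ndarray) -> np.ndarray:
    n0, k, r, t0 = theta
    z = np.clip(-r * (years - t0), -700.0, 700.0)
    return n0 * k / (n0 + (k - n0) * np.exp(z))


def default_bounds(series: AnnualCountSeries) -> tuple[np.ndarray, np.ndarray]:
    """Box constraints for the fit.

    The invasion must precede the first detection, so t0 is bounded
    above by the first positive-count year and below by 15 years before
    the window (a sparsely observed invasion is unlikely to have gone
    unnoticed longer).  K cannot be far below the observed maximum count
    nor astronomically above it.
    """
    counts = np.asarray(series.counts, dtype=float)
    max_count = float(counts.max())
    first_positive = series.years[int(np.argmax(counts > 0))]
    lower = np.array([1e-6, max_count / 2.0, 1e-6, series.window_start - 15.0])
    upper = np.array([max_count, 100.0 * max_count, 5.0, float(first_positive)])
    # guard degenerate windows where max_count/2 < 1e-6 cannot happen (positive count required)
    return lower, upper


def ridge_project(params: LogisticParams, founding_fraction: float) -> LogisticParams:
    """Move along the exact zero-residual (n0, t0) ridge to the point
    where n0/k equals ``founding_fraction``, keeping the curve identical.

    Uses log((k - n0)/n0) + r*t0 = const, computed in log space so large
    r*t0 cannot overflow.  Requires 0 < n0 < k on both ends.
    """
    if not (0 < founding_fraction < 1):
        raise ValueError("founding_fraction must be in (0, 1)")
    n0, k, r, t0 = params.n0, params.k, params.r, params.t0
    if not (0 < n0 < k) or r == 0:
        return params  # flat or inverted fit: ridge reparameterization undefined
    new_n0 = founding_fraction * k
    new_t0 = t0 + (math.log((k - n0) / n0) - math.log((1 - founding_fraction) / founding_fraction)) / r
    return LogisticParams(n0=new_n0, k=k, r=r, t0=new_t0)


def fit_logistic(
    series: AnnualCountSeries,
    bounds: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    n_starts: int = 50,
    seed: int = 0,
    founding_fraction: Optional[float] = 1e-3,
) -> LogisticFitResult:
    """Least-squares fit of the logistic curve to an annual count series.

    Unweighted ordinary least squares on the raw counts, evaluated at
    the integer calendar year of each entry; zero-count years contribute
    to the residual sum of squares.  The 4-parameter surface is
    multimodal, so the optimizer runs ``n_starts`` bounded trust-region
    least-squares fits from Latin-hypercube starting points and returns
    the lowest-RSS solution.

    Because (n0, t0) are only jointly identified (see module docstring),
    the best solution is projected along the exact ridge to the point
    with n0/k = ``founding_fraction`` before being returned; pass
    ``founding_fraction=None`` to get the raw optimizer solution.
    """
    counts = np.asarray(series.counts, dtype=float)
    if len(counts) < 5:
        raise InsufficientDataError(
            f"need at least 5 years for a 4-parameter fit, got {len(counts)}"
        )
    if not np.any(counts > 0):
        raise DegenerateSeriesError("all counts are zero; no signal to fit")
    years = np.asarray(series.years, dtype=float)

    if bounds is None:
        lower, upper = default_bounds(series)
    else:
        lower, upper = np.asarray(bounds[0], float), np.asarray(bounds[1], float)

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    # sample n0, k on log scale (their plausible ranges span orders of magnitude)
    log_mask = np.array([True, True, False, False])
    lo = np.where(log_mask, np.log(lower), lower)
    hi = np.where(log_mask, np.log(upper), upper)
    unit = sampler.random(n=n_starts)
    starts = lo + unit * (hi - lo)
    starts[:, log_mask] = np.exp(starts[:, log_mask])

    def resid(theta: np.ndarray) -> np.ndarray:
        return _model(theta, years) - counts

    best = None
    any_converged = False
    for x0 in starts:
        x0 = np.minimum(np.maximum(x0, lower), upper)
        try:
            sol = least_squares(
                resid, x0, bounds=(lower, upper), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        any_converged = any_converged or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    rss, theta, _ = best
    params = LogisticParams(*theta)
    if founding_fraction is not None:
        params = ridge_project(params, founding_fraction)
    fitted = _model(params.as_array(), years)
    return LogisticFitResult(
        params=params,
        rss=rss,
        fitted=fitted.tolist(),
        n_starts=n_starts,
        converged=any_converged,
    )


def decimal_year_to_date(y: float, day_count: str = "365") -> _dt.date:
    """Convert a decimal year to a calendar date.

    The fractional part is mapped to whole days elapsed since 1 January:
    a fixed 365-day year by default, or the true year length (365/366)
    with ``day_count="calendar"``.  Month-level precision is all the
    decimal-year estimates claim.
    """
    year = math.floor(y)
    frac = y - year
    if not (0.0 <= frac < 1.0):
        raise ValueError("fractional part must lie in [0, 1)")
    if day_count == "calendar":
        ndays = 366 if _is_leap(year) else 365
    elif day_count == "365":
        ndays = 365
    else:
        raise ValueError("day_count must be '365' or 'calendar'")
    return _dt.date(int(year), 1, 1) + _dt.timedelta(days=math.floor(frac * ndays))


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
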