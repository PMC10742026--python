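"""Four-parameter logistic (4PL) concentration-response fitting.

The model, in log10-concentration space, is

    R(C) = inf + (zero - inf) / (1 + 10**(h * (log10 C - log10 AC50)))

where ``zero`` is the response asymptote at zero concentration, ``inf``
the asymptote at infinite concentration (both % of DMSO control), AC50
the midpoint and ``h`` the Hill slope.  With h > 0 the curve falls from
``zero`` toward ``inf`` as concentration grows; a fit with
``asym_inf > asym_zero`` describes a stimulatory (rising) response and
is flagged as such by the scoring layer rather than refit.

Fitting is bounded nonlinear least squares with a deterministic
multi-start over Hill slopes; R^2 is reported against the mean-response
null on the raw points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .types import DoseResponseSeries, NoFitError, ScreenTable

#: asymptote bounds, % control — wide enough for >100% low-dose responses
ASYM_BOUNDS = (-50.0, 250.0)
#: maximum |Hill slope|
MAX_HILL = 10.0
#: multi-start Hill slopes, tried in order; ties in SSR go to smaller |h|
START_SLOPES = (0.5, -0.5, 1.0, -1.0, 2.0, -2.0)
#: minimum distinct concentrations for a full 4-parameter fit
MIN_POINTS = 5


@dataclass(frozen=True)
class CurveFit4PL:
    """Fitted 4PL parameters and quality measures.

    ``lac50`` is log10 of AC50 in **molar** units (matching the deposited
    screen tables); ``auc`` is the area under the fitted curve over the
    tested log10-concentration range, in (% control) x decades.
    """

    asym_zero: Optional[float]
    asym_inf: Optional[float]
    lac50: Optional[float]
    hill_slope: Optional[float]
    r2: Optional[float]
    auc: Optional[float]
    converged: bool
    n_points: int
    reason: Optional[str] = None

    @property
    def stimulatory(self) -> bool:
        return (
            self.converged
            and self.asym_inf is not None
            and self.asym_zero is not None
            and self.asym_inf > self.asym_zero
        )


def logistic4(log_c, asym_zero: float, asym_inf: float, log_ac50: float, hill: float):
    """Evaluate the 4PL response at log10 concentration(s) ``log_c``.

    ``log_c`` and ``log_ac50`` must be on the same concentration scale.
    """
    log_c = np.asarray(log_c, dtype=float)
    return asym_inf + (asym_zero - asym_inf) / (1.0 + 10.0 ** (hill * (log_c - log_ac50)))


def r_squared(observed, predicted) -> Optional[float]:
    """Coefficient of determination against the mean-response null.

    Returns ``None`` (no-fit) when the observed values have zero total
    sum of squares, where R^2 is undefined.  May be negative for fits
    worse than the mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def auc_from_curve(
    fit: CurveFit4PL,
    log_c_min_um: float,
    log_c_max_um: float,
    n_grid: int = 1001,
) -> float:
    """Trapezoidal area under the fitted curve over [log_c_min, log_c_max].

    Limits are log10 micromolar.  Converges to the analytic integral as
    the grid is refined.  Raises :class:`NoFitError` on a non-converged fit.
    """
    if not fit.converged:
        raise NoFitError(f"cannot integrate a non-converged fit ({fit.reason})")
    if not log_c_min_um < log_c_max_um:
        raise ValueError("log_c_min must be < log_c_max")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    grid = np.linspace(log_c_min_um, log_c_max_um, n_grid)
    lac50_um = fit.lac50 + 6.0  # molar -> micromolar log scale
    vals = logistic4(grid, fit.asym_zero, fit.asym_inf, lac50_um, fit.hill_slope)
    return float(np.trapezoid(vals, grid))


def raw_trapezoid_auc(series: DoseResponseSeries) -> float:
    """AUC of the observed points themselves over log10 concentration."""
    log_c = np.log10(np.asarray(series.concentrations))
    return float(np.trapezoid(np.asarray(series.responses), log_c))


def _no_fit(n_points: int, reason: str) -> CurveFit4PL:
    return CurveFit4PL(
        asym_zero=None, asym_inf=None, lac50=None, hill_slope=None,
        r2=None, auc=None, converged=False, n_points=n_points, reason=reason,
    )


def fit_4pl(
    series: DoseResponseSeries,
    auc_n_grid: int = 1001,
    extra_slopes: tuple[float, ...] = (),
) -> CurveFit4PL:
    """Fit the 4PL model to one concentration-response series.

    Requires at least five distinct concentrations; a flat series (all
    responses equal) is returned as a no-fit with reason
    ``"no concentration-response"``.  The optimizer runs from a fixed set
    of starting Hill slopes with asymptotes seeded at the response
    extremes and the midpoint at the concentration whose response is
    nearest half-range; the start with the lowest residual sum of
    squares wins, ties broken toward the smaller |Hill slope|.
    """
    log_c = np.log10(np.asarray(series.concentrations, dtype=float))
    resp = np.asarray(series.responses, dtype=float)
    n = resp.size
    if n < MIN_POINTS:
        return _no_fit(n, "insufficient points")
    if np.ptp(resp) == 0.0:
        return _no_fit(n, "no concentration-response")

    lo = np.array([ASYM_BOUNDS[0], ASYM_BOUNDS[0], log_c.min() - 3.0, -MAX_HILL])
    hi = np.array([ASYM_BOUNDS[1], ASYM_BOUNDS[1], log_c.max() + 3.0, MAX_HILL])

    zero0 = float(np.clip(resp.max(), *ASYM_BOUNDS))
    inf0 = float(np.clip(resp.min(), *ASYM_BOUNDS))
    half = 0.5 * (resp.max() + resp.min())
    lac0 = float(log_c[np.argmin(np.abs(resp - half))])

    def residuals(p):
        return logistic4(log_c, *p) - resp

    best = None  # (ssr, |hill|, params)
    for slope in tuple(START_SLOPES) + tuple(extra_slopes):
        p0 = np.clip(np.array([zero0, inf0, lac0, slope]), lo, hi)
        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not res.success:
            continue
        ssr = float(np.sum(res.fun ** 2))
        key = (ssr, abs(res.x[3]))
        if best is None or (key[0] < best[0] - 1e-12 * max(1.0, best[0])) or (
            abs(key[0] - best[0]) <= 1e-12 * max(1.0, best[0]) and key[1] < best[1]
        ):
            best = (ssr, key[1], res.x)
    if best is None:
        return _no_fit(n, "non-convergence")

    zero, inf_, lac50_um, hill = (float(v) for v in best[2])
    # The model is invariant under (zero, inf, h) -> (inf, zero, -h).
    # Canonicalize so asym_zero is the zero-concentration limit (h >= 0);
    # direction then lives in the asymptote order (zero < inf = stimulatory).
    if hill < 0:
        zero, inf_, hill = inf_, zero, -hill
    pred = logistic4(log_c, zero, inf_, lac50_um, hill)
    r2 = r_squared(resp, pred)
    fit = CurveFit4PL(
        asym_zero=zero,
        asym_inf=inf_,
        lac50=lac50_um - 6.0,  # report log10 molar
        hill_slope=hill,
        r2=r2,
        auc=None,
        converged=True,
        n_points=n,
    )
    auc = auc_from_curve(fit, float(log_c.min()), float(log_c.max()), n_grid=auc_n_grid)
    return CurveFit4PL(**{**fit.__dict__, "auc": auc})


def fit_screen(table: ScreenTable, **kwargs) -> list[tuple[DoseResponseSeries, CurveFit4PL]]:
    """Fit every raw series in a raw-dialect screen table, in key order."""
    if table.dialect != "raw":
        raise ValueError("fit_screen expects a raw-dialect table")
    out = []
    for key in table.records:
        series = table.records[key]
        out.append((series, fit_4pl(series, **kwargs)))
    return out
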