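"""Population-level trend estimation.

Each population's sparse abundance series is turned into a complete sequence
of annual log10 rates of change ("lambdas", d_t = log10(N_t / N_{t-1})).
Series with at least ``gam_min_points`` observations are smoothed with a
penalized cubic B-spline regression of log10 abundance on year (a GAM with a
single smooth term); shorter series, or series where the smooth fit is poor,
fall back to the chain method: log-linear interpolation between consecutive
observations followed by direct log-ratios.

Population lambdas are then averaged per year within species with equal
weight, giving one trend per species regardless of how intensively it was
monitored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .types import LambdaSeries, SpeciesTrend, ValidationWarning

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs for the population -> species trend pipeline.

    gam_min_points
        minimum observed years for the spline smoother (below: chain method).
    cap
        absolute bound on any annual lambda, in log10 units per year
        (1.0 = one order of magnitude); ``None`` or ``inf`` disables capping.
    zero_adjust_fraction
        fraction of the series mean added to every observation when a zero
        count is present, so log ratios stay defined.
    gam_fit_margin
        a smooth fit whose fitted log10 values stray beyond the observed
        log10 range by more than this is declared poor and chained instead.
    """

    gam_min_points: int = 6
    cap: float | None = 1.0
    zero_adjust_fraction: float = 0.01
    gam_fit_margin: float = 1.0


def zero_adjust(series: dict[int, float], fraction: float = 0.01) -> dict[int, float] | None:
    """Shift a series containing zero counts so log ratios are defined.

    If any observed value is 0, a constant equal to ``fraction`` of the mean
    of the observed values is added to every observation. Series that are
    zero throughout cannot be rescued and return None (caller drops them
    with a warning).
    """
    if not series:
        raise ValueError("empty series")
    values = np.array(list(series.values()), dtype=float)
    if not np.any(values == 0):
        return dict(series)
    constant = fraction * values.mean()
    if constant <= 0:
        return None
    return {y: v + constant for y, v in series.items()}


def interpolate_log_linear(series: dict[int, float]) -> dict[int, float]:
    """Fill interior years by linear interpolation of log10 abundance.

    Endpoints are untouched and no extrapolation happens outside the
    observed span. All observed values must be positive.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 observed years to interpolate")
    years = np.array(sorted(series), dtype=int)
    values = np.array([series[int(y)] for y in years], dtype=float)
    if np.any(values <= 0):
        raise ValueError("all values must be > 0 (zero-adjust the series first)")
    full_years = np.arange(years[0], years[-1] + 1)
    full_log = np.interp(full_years, years, np.log10(values))
    out = {int(y): float(10.0 ** v) for y, v in zip(full_years, full_log)}
    out.update({int(y): float(series[int(y)]) for y in years})  # keep observations exact
    return out


def _bspline_design(x: np.ndarray, n_basis: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray, int]:
    """Clamped uniform-knot B-spline design matrix over the span of x."""
    degree = min(degree, n_basis - 1)
    n_interior = n_basis - degree - 1
    lo, hi = float(x.min()), float(x.max())
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    design = BSpline.design_matrix(x, knots, degree).toarray()
    return design, knots, degree


def fit_gam_trend(
    series: dict[int, float],
    min_points: int = 6,
    fit_margin: float = 1.0,
) -> tuple[dict[int, float], bool]:
    """Smooth a positive abundance series on the log10 scale.

    A penalized cubic B-spline regression (basis dimension ceil(n/2), at
    least 3; second-difference coefficient penalty; penalty weight chosen by
    generalized cross-validation) is fitted to log10 abundance against year
    and evaluated at every year from the first to the last observation.

    Returns ``(fitted_series, ok)``. ``ok`` is False when there are fewer
    than ``min_points`` observations, the fit fails, any fitted value is
    non-finite, or fitted log10 values leave the observed range by more than
    ``fit_margin`` orders of magnitude — in all cases the caller should use
    the chain method instead.
    """
    years = np.array(sorted(series), dtype=float)
    n = len(years)
    if n < min_points:
        return {}, False
    values = np.array([series[int(y)] for y in years], dtype=float)
    if np.any(values <= 0):
        raise ValueError("all values must be > 0 (zero-adjust the series first)")
    y_log = np.log10(values)

    n_basis = max(3, int(np.ceil(n / 2)))
    try:
        design, knots, degree = _bspline_design(years, n_basis)
        # second-difference penalty on adjacent basis coefficients (P-spline)
        d2 = np.diff(np.eye(n_basis), n=min(2, n_basis - 1), axis=0)
        penalty = d2.T @ d2
        xtx = design.T @ design
        xty = design.T @ y_log

        best = None
        for alpha in np.concatenate(([0.0], np.logspace(-5, 5, 31))):
            try:
                a = xtx + alpha * penalty
                coef = np.linalg.solve(a, xty)
                hat_diag = np.einsum(
                    "ij,jk,ik->i", design, np.linalg.inv(a), design
                )
                edf = float(hat_diag.sum())
            except np.linalg.LinAlgError:
                continue
            resid = y_log - design @ coef
            denom = max(n - edf, 1e-8)
            gcv = n * float(resid @ resid) / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, coef)
        if best is None:
            return {}, False
        coef = best[1]
        eval_years = np.arange(years[0], years[-1] + 1)
        spline = BSpline(knots, coef, degree)
        fitted_log = spline(eval_years)
    except Exception:  # fit failure of any kind -> chain fallback
        log.info("GAM fit failed for a %d-point series; falling back to chain", n)
        return {}, False

    if not np.all(np.isfinite(fitted_log)):
        return {}, False
    if fitted_log.max() > y_log.max() + fit_margin or fitted_log.min() < y_log.min() - fit_margin:
        return {}, False
    return {int(y): float(10.0 ** v) for y, v in zip(eval_years, fitted_log)}, True


def series_lambdas(values: dict[int, float]) -> dict[int, float]:
    """Annual log10 rates of change of a complete, positive series.

    ``result[t] = log10(values[t] / values[t-1])`` for every consecutive
    year pair; keys are the later year of each pair.
    """
    years = sorted(values)
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    if any(years[i + 1] - years[i] != 1 for i in range(len(years) - 1)):
        raise ValueError("years must be consecutive (interpolate first)")
    if any(values[y] <= 0 for y in years):
        raise ValueError("all values must be > 0")
    return {
        y: float(np.log10(values[y] / values[y - 1])) for y in years[1:]
    }


def cap_lambdas(lambdas: dict[int, float], cap: float | None = 1.0) -> dict[int, float]:
    """Clip each annual rate to [-cap, +cap]; ``None``/inf disables."""
    if cap is None or np.isinf(cap):
        return dict(lambdas)
    if cap <= 0:
        raise ValueError("cap must be > 0")
    clipped = {y: float(np.clip(v, -cap, cap)) for y, v in lambdas.items()}
    n_clipped = sum(1 for y in lambdas if clipped[y] != lambdas[y])
    if n_clipped:
        log.info("capped %d lambda values at ±%g", n_clipped, cap)
    return clipped


def population_lambdas(
    record,
    window: tuple[int, int],
    config: PipelineConfig | None = None,
) -> LambdaSeries | None:
    """Full per-population pipeline: zero-adjust, smooth or chain, cap.

    Returns a window-aligned LambdaSeries, or None when the series is
    degenerate (all-zero counts) — a warning is emitted in that case.
    """
    config = config or PipelineConfig()
    series = {y: v for y, v in record.series.items() if window[0] <= y <= window[1]}
    if len(series) < 2:
        warnings.warn(
            f"population {record.population_id!r}: fewer than 2 observations "
            "inside the index window; dropped",
            ValidationWarning,
            stacklevel=2,
        )
        return None
    adjusted = zero_adjust(series, config.zero_adjust_fraction)
    if adjusted is None:
        warnings.warn(
            f"population {record.population_id!r}: all observed counts are zero; dropped",
            ValidationWarning,
            stacklevel=2,
        )
        return None

    method = "chain"
    fitted, ok = fit_gam_trend(
        adjusted, min_points=config.gam_min_points, fit_margin=config.gam_fit_margin
    )
    if ok:
        method = "gam"
        complete = fitted
    else:
        complete = interpolate_log_linear(adjusted)
    lam = cap_lambdas(series_lambdas(complete), config.cap)

    base, final = window
    years = np.arange(base, final + 1)
    arr = np.full(years.shape, np.nan)
    for y, v in lam.items():
        arr[y - base] = v
    return LambdaSeries(
        label=str(record.population_id), years=years, lambdas=arr, method=method
    )


def species_mean_lambdas(populations: list[LambdaSeries], binomial: str = "") -> SpeciesTrend:
    """Average population lambdas per year with equal weight (one trend per species)."""
    if not populations:
        raise ValueError("need at least one population series")
    years = populations[0].years
    stack = np.vstack([p.lambdas for p in populations])
    counts = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(stack, axis=0)
    means[counts == 0] = np.nan
    return SpeciesTrend(
        binomial=binomial or populations[0].label,
        years=years,
        lambdas=means,
        n_populations=counts,
    )
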