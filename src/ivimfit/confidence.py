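"""Identifiability analysis: F-test confidence grids and multi-start
local-minima census.

Confidence grids
----------------
Standard errors from the covariance matrix can misrepresent uncertainty
when the bi-exponential model is weakly identified, so parameter-pair
confidence regions are mapped directly: two parameters are fixed on a 2D
grid, any remaining free parameters are re-optimized at every node, and
the increase in the residual sum of squares over the best fit is converted
to a confidence level with a fixed-parameter F-test:

    F = ((chi2_fixed / chi2_best) - 1) * (N - P) / P_fixed

with N the number of b-values, P the number of solver-free parameters in
the unconstrained (null) fit and P_fixed the number of grid-fixed
parameters (2).  The confidence level is the CDF of F(P_fixed, N - P).

Minima census
-------------
A multi-start sweep of a fitting cascade from a log-spaced grid of initial
values; well-conditioned converged solutions are merged when all free
parameters agree within a relative tolerance, giving the number of
distinct local minima on a curve's cost surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import IVIMParams, SignalCurve, ValidationError
from .fitting import (
    FREE_PARAMS,
    PARAM_NAMES,
    FitInfeasibleError,
    FitResult,
    MethodSpec,
    _FITTERS,
    _solve,
)


#: residual sums of squares below this are numerically zero (a perfect,
#: noiseless fit): the relative F-test surface is undefined there
RSS_FLOOR = 1e-20


class DegenerateSurfaceError(ValidationError):
    """The best fit has zero residual (noiseless perfect fit); the F-test
    surface is undefined.  Add noise or jitter the curve."""


class EmptyCensusError(ValidationError):
    """No start of the multi-start sweep produced a usable solution."""


def ftest_probability(
    chi2_alt: float, chi2_best: float, n_obs: int, n_free: int, n_fixed: int
) -> float:
    """Confidence level that the fixed-parameter alternative is rejected.

    Returns the CDF of F(n_fixed, n_obs - n_free) evaluated at
    ``((chi2_alt / chi2_best) - 1) * (n_obs - n_free) / n_fixed``; cost
    decreases (possible numerically) are clipped to zero.
    """
    if chi2_best <= RSS_FLOOR:
        raise DegenerateSurfaceError(
            "best-fit residual sum of squares is zero; the relative F-test "
            "surface is undefined (add noise or jitter)"
        )
    dof = n_obs - n_free
    if dof <= 0:
        raise ValidationError("no residual degrees of freedom")
    f_stat = max(chi2_alt / chi2_best - 1.0, 0.0) * dof / n_fixed
    return float(stats.f.cdf(f_stat, n_fixed, dof))


@dataclass(frozen=True)
class ConfidenceGrid:
    """2D confidence surface over a fixed parameter pair."""

    param_pair: tuple[str, str]
    axes: tuple[np.ndarray, np.ndarray]
    probability: np.ndarray  # shape (len(axes[0]), len(axes[1])), in [0, 1]
    best_fit: IVIMParams
    rss_best: float

    def contour_mask(self, level: float = 0.95) -> np.ndarray:
        """Boolean mask of grid nodes inside the given confidence level."""
        return self.probability <= level


def _axis(
    center: float, stderr: float, bounds: tuple[float, float],
    n_points: int, sigmas: float, fallback_frac: float,
) -> np.ndarray:
    half = sigmas * stderr if math.isfinite(stderr) and stderr > 0 else abs(center) * fallback_frac
    lo = max(center - half, bounds[0] if bounds[0] > 0 else 1e-12)
    hi = min(center + half, bounds[1])
    if hi <= lo:
        lo, hi = bounds[0] if bounds[0] > 0 else 1e-12, bounds[1]
    return np.linspace(lo, hi, n_points)


def confidence_grid(
    curve: SignalCurve,
    best_fit: FitResult,
    pair: tuple[str, str],
    method: MethodSpec | None = None,
    n_points: int = 41,
    sigmas: float = 5.0,
    fallback_frac: float = 0.5,
    axes: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConfidenceGrid:
    """Map the F-test confidence surface over a parameter pair.

    At each node the two paired parameters are held at the node values, any
    parameters the cascade leaves free (beyond the pair) are re-optimized,
    and the resulting cost is compared with the best fit.  Axes default to
    best-fit +/- ``sigmas`` standard errors (falling back to +/-50% of the
    estimate when no standard error is available), clipped to the method
    bounds.
    """
    method = method or MethodSpec(best_fit.method_id)
    if pair[0] == pair[1] or any(p not in PARAM_NAMES for p in pair):
        raise ValidationError(f"pair must be two distinct parameters, got {pair}")
    if not best_fit.converged:
        raise ValidationError("best_fit must be a converged fit")
    if best_fit.rss <= RSS_FLOOR:
        raise DegenerateSurfaceError(
            "best fit has zero residual; add noise or jitter the curve"
        )
    est = {p: getattr(best_fit.estimate, p) for p in PARAM_NAMES}
    if axes is None:
        axes = tuple(
            _axis(
                est[p], best_fit.stderr.get(p, math.nan), method.bounds[p],
                n_points, sigmas, fallback_frac,
            )
            for p in pair
        )
    n_obs = len(curve)
    n_free_null = len(FREE_PARAMS[method.method_id])
    refit = tuple(p for p in FREE_PARAMS[method.method_id] if p not in pair)
    prob = np.empty((len(axes[0]), len(axes[1])))
    for i, v0 in enumerate(axes[0]):
        for j, v1 in enumerate(axes[1]):
            fixed = dict(est)
            fixed[pair[0]] = float(v0)
            fixed[pair[1]] = float(v1)
            if refit:
                sol = _solve(
                    curve, method, free=refit,
                    fixed={k: v for k, v in fixed.items() if k not in refit},
                    x0=[est[p] for p in refit],
                )
                chi2 = sol["rss"]
            else:
                from .core import ivim_model

                r = ivim_model(curve.scheme.b, fixed["D"], fixed["D_star"], fixed["f"]) - curve.values
                chi2 = float(r @ r)
            prob[i, j] = ftest_probability(
                chi2, best_fit.rss, n_obs, n_free_null, n_fixed=2
            )
    return ConfidenceGrid(
        param_pair=tuple(pair),
        axes=axes,
        probability=prob,
        best_fit=best_fit.estimate,
        rss_best=best_fit.rss,
    )


def export_grid_csv(grid: ConfidenceGrid, out_dir, prefix: str = "grid") -> list:
    """Write the surface as a CSV matrix plus one CSV per axis vector."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, ax in zip(grid.param_pair, grid.axes):
        p = out_dir / f"{prefix}_axis_{name}.csv"
        np.savetxt(p, ax, delimiter=",")
        paths.append(p)
    p = out_dir / f"{prefix}_probability.csv"
    np.savetxt(p, grid.probability, delimiter=",")
    paths.append(p)
    return paths


# --------------------------------------------------------------------------
# Multi-start census
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CensusSolution:
    params: IVIMParams
    cost: float
    n_starts: int  # how many starts converged into this cluster


@dataclass(frozen=True)
class MinimaCensus:
    """Distinct well-conditioned local minima found by a multi-start sweep."""

    solutions: tuple[CensusSolution, ...]  # sorted by cost, ascending
    merge_tol: float
    truth: IVIMParams | None = None

    @property
    def count(self) -> int:
        return len(self.solutions)

    @property
    def is_multi_minimum(self) -> bool:
        return self.count > 1

    def _distance(self, p: IVIMParams) -> float:
        if self.truth is None:
            return math.nan
        t = self.truth
        return math.sqrt(
            sum(
                ((getattr(p, n) - getattr(t, n)) / getattr(t, n)) ** 2
                for n in PARAM_NAMES
            )
        )

    @property
    def global_minimum_correct(self) -> bool | None:
        """Whether the lowest-cost solution is the one nearest ground truth
        (None when truth is unknown or only one minimum exists)."""
        if self.truth is None or self.count == 0:
            return None
        if self.count == 1:
            return True
        dists = [self._distance(s.params) for s in self.solutions]
        return bool(np.argmin(dists) == 0)


def default_start_grid(
    method: MethodSpec, n_per_param: int = 3
) -> list[tuple[float, ...]]:
    """Log-spaced start grid spanning the bounds box of a cascade's free
    parameters (interior points of a finer geometric ladder, so no start
    sits on a bound)."""
    free = FREE_PARAMS[method.method_id]
    axes = []
    for p in free:
        lb, ub = method.bounds[p]
        lo = lb if lb > 0 else ub * 1e-3
        axes.append(np.geomspace(lo, ub, n_per_param + 2)[1:-1])
    return list(itertools.product(*axes))


def minima_census(
    curve: SignalCurve,
    method: MethodSpec,
    starts: list[tuple[float, ...]] | None = None,
    merge_tol: float = 1e-3,
    truth: IVIMParams | None = None,
) -> MinimaCensus:
    """Run a cascade from every start and merge the solutions.

    Solutions are kept when the solver converged to a well-conditioned
    interior point (ill-conditioned or bound-pinned terminations are not
    genuine minima of the model surface) and merged when every free
    parameter agrees within ``merge_tol`` relative tolerance.
    """
    if starts is None:
        starts = default_start_grid(method)
    if len(starts) == 0:
        raise ValidationError("need at least one start")
    fitter = _FITTERS[method.method_id]
    free = FREE_PARAMS[method.method_id]
    candidates: list[tuple[np.ndarray, float]] = []
    for x0 in starts:
        try:
            fr = fitter(curve, method, x0=x0)
        except FitInfeasibleError:
            continue
        if fr.converged and not fr.outlier:
            vec = np.array([getattr(fr.estimate, p) for p in free])
            candidates.append((vec, fr.rss, fr.estimate))
    if not candidates:
        raise EmptyCensusError("no start converged to a well-conditioned solution")
    candidates.sort(key=lambda c: c[1])
    clusters: list[list] = []  # [rep_vec, cost, params, n_starts]
    for vec, cost, params in candidates:
        merged = False
        for cl in clusters:
            rel = np.abs(vec - cl[0]) / np.maximum(np.abs(vec), np.abs(cl[0]))
            if np.all(rel <= merge_tol):
                cl[3] += 1
                merged = True
                break
        if not merged:
            clusters.append([vec, cost, params, 1])
    sols = tuple(
        CensusSolution(params=cl[2], cost=float(cl[1]), n_starts=int(cl[3]))
        for cl in clusters
    )
    return MinimaCensus(solutions=sols, merge_tol=merge_tol, truth=truth)


def multi_minimum_fraction(
    curves,
    method: MethodSpec,
    truth: IVIMParams | None = None,
    merge_tol: float = 1e-3,
    starts: list[tuple[float, ...]] | None = None,
) -> dict:
    """Census over an ensemble of curves.

    Returns the percentage of curves whose surface shows more than one
    distinct minimum, the number of censused curves, and — among the
    multi-minimum cases — how often the lowest-cost solution is nearest
    truth.  Curves where no start yields a usable solution are counted as
    censused with zero interior minima (not multi-minimum).
    """
    if starts is None:
        starts = default_start_grid(method)
    n_multi = 0
    n_total = 0
    n_global_correct = 0
    for curve in curves:
        n_total += 1
        try:
            census = minima_census(
                curve, method, starts=starts, merge_tol=merge_tol, truth=truth
            )
        except EmptyCensusError:
            continue
        if census.is_multi_minimum:
            n_multi += 1
            if census.global_minimum_correct:
                n_global_correct += 1
    return {
        "n_curves": n_total,
        "n_multi_minimum": n_multi,
        "multi_minimum_percent": 100.0 * n_multi / n_total if n_total else math.nan,
        "n_multi_with_correct_global": n_global_correct,
        "global_correct_fraction": (
            n_global_correct / n_multi if n_multi else math.nan
        ),
    }
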