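"""The three bi-exponential IVIM fitting cascades.

All three methods minimize squared residuals of the bi-exponential model
against a normalized signal curve with a damped least-squares solver
(trust-region reflective, the bounded member of the Levenberg-Marquardt
family), differing in how many parameters are fixed beforehand:

``three_parameter``
    Simultaneous: D, D* and f estimated jointly from the full curve.
``two_parameter``
    Segmented: D fixed from a mono-exponential fit of the high-b portion
    (where perfusion is negligible), then (f, D*) estimated jointly.
``one_parameter``
    Fully constrained: D fixed as above, f fixed from the y-intercept of
    the same high-b fit extrapolated to b = 0, then D* estimated alone.

Fits whose solution carries no usable parameter information are flagged as
outliers and excluded from downstream summary statistics.  The flag
operationalizes "ill-conditioned" for this model as any of: solver
non-convergence; a rank-deficient Jacobian at the solution (a parameter
with no effect, e.g. D* when f = 0); condition number above a threshold;
an estimate pinned at a bound; a D* standard error exceeding the estimate
itself (the single-parameter face of a flat cost surface on
near-mono-exponential data); or a perfusion fraction above the
physiological ceiling (the amplitude-swap valley, where the pseudo-
diffusion term has captured the tissue compartment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    AcquisitionScheme,
    IVIMParams,
    SignalCurve,
    ValidationError,
    ivim_jacobian,
    ivim_model,
)
from .simulate import EnsembleRecord

PARAM_NAMES = ("D", "D_star", "f")

METHOD_IDS = ("one_parameter", "two_parameter", "three_parameter")

#: Free parameters per cascade, in solver order.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "one_parameter": ("D_star",),
    "two_parameter": ("f", "D_star"),
    "three_parameter": ("D", "D_star", "f"),
}


class FitInfeasibleError(ValidationError):
    """The segmented high-b sub-fit cannot be performed on this curve."""


@dataclass(frozen=True)
class MethodSpec:
    """Configuration of one fitting cascade.

    The default initial values bracket both gray-matter-like and
    tumor-like tissue without imposing D* > D; bounds keep the diffusion
    coefficients positive and f physical.  ``b_threshold`` separates the
    perfusion-sensitive low-b regime from the high-b regime where the
    mono-exponential tissue model holds (strictly b > threshold by
    default; set ``strict_threshold=False`` for b >= threshold).
    """

    method_id: str
    b_threshold: float = 200.0
    strict_threshold: bool = True
    initial: dict[str, float] = field(
        default_factory=lambda: {"D": 1.0e-3, "D_star": 1.0e-2, "f": 0.1}
    )
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "D": (1.0e-5, 5.0e-3),
            "D_star": (1.0e-4, 5.0e-1),
            "f": (0.0, 1.0),
        }
    )
    cond_threshold: float = 1.0e8
    #: perfusion fractions above this are non-physiological in brain tissue
    #: (CSF partial-volume scale); such fits are flagged, not clipped
    f_max: float = 0.3
    #: relative solver tolerances on parameters and cost
    xtol: float = 1.0e-8
    ftol: float = 1.0e-8

    def __post_init__(self) -> None:
        if self.method_id not in METHOD_IDS:
            raise ValidationError(
                f"method_id must be one of {METHOD_IDS}, got {self.method_id!r}"
            )

    def validate_scheme(self, scheme: AcquisitionScheme) -> None:
        b = scheme.b
        if not (b.min() < self.b_threshold < b.max()):
            raise ValidationError(
                f"b_threshold {self.b_threshold} must lie strictly between the "
                f"scheme's min ({b.min()}) and max ({b.max()}) b-values"
            )


@dataclass(frozen=True)
class FitResult:
    """Outcome of one fitting cascade on one curve.

    Fixed parameters of the constrained cascades are carried through
    bit-identically; their standard errors are NaN.  ``outlier`` marks
    fits to be excluded from downstream summaries.
    """

    estimate: IVIMParams
    stderr: dict[str, float]
    rss: float
    n_function_evals: int
    converged: bool
    outlier: bool
    method_id: str
    free_params: tuple[str, ...]
    cond: float = math.nan
    at_bound: bool = False
    f_clamped: bool = False
    n_dropped_high_b: int = 0
    #: why the fit was flagged (empty when outlier is False)
    outlier_reasons: tuple[str, ...] = ()

    @property
    def f_nonphysiological(self) -> bool:
        """True when the only defect is a perfusion fraction above the
        physiological ceiling (voxelwise mapping treats these as CSF
        contamination rather than fit failures)."""
        return self.outlier_reasons == ("f_nonphysiological",)


# --------------------------------------------------------------------------
# Segmented high-b sub-fit
# --------------------------------------------------------------------------


def fit_high_b_segment(
    curve: SignalCurve, method: MethodSpec
) -> tuple[float, float, int]:
    """Mono-exponential fit of the high-b portion of a curve.

    Ordinary least squares of log(signal) on b over the samples above the
    perfusion threshold: the negated slope is the tissue diffusion
    coefficient D and the exponentiated intercept is the extrapolated
    S(int).  Non-positive signal values (possible under noise) are dropped
    before the log transform and counted.

    Returns ``(D, S_int, n_dropped)``.
    """
    method.validate_scheme(curve.scheme)
    idx = curve.scheme.high_b_indices(method.b_threshold, method.strict_threshold)
    if idx.size < 2:
        raise FitInfeasibleError(
            f"need >= 2 b-values above threshold {method.b_threshold}, have {idx.size}"
        )
    b = curve.scheme.b[idx]
    s = curve.values[idx]
    usable = s > 0
    n_dropped = int((~usable).sum())
    if usable.sum() < 2:
        raise FitInfeasibleError(
            "fewer than 2 positive high-b signal values after dropping "
            f"{n_dropped} non-positive samples"
        )
    slope, log_intercept = np.polyfit(b[usable], np.log(s[usable]), 1)
    return float(-slope), float(np.exp(log_intercept)), n_dropped


# --------------------------------------------------------------------------
# Damped least-squares engine
# --------------------------------------------------------------------------


def _solve(
    curve: SignalCurve,
    method: MethodSpec,
    free: Sequence[str],
    fixed: dict[str, float],
    x0: Sequence[float] | None = None,
) -> dict:
    """Bounded damped least squares of the IVIM model with the given
    parameters free and the rest fixed.  Returns raw solver internals."""
    b = curve.scheme.b
    y = curve.values
    free = tuple(free)
    free_idx = [PARAM_NAMES.index(p) for p in free]

    def full(x: np.ndarray) -> dict[str, float]:
        p = dict(fixed)
        for name, v in zip(free, x):
            p[name] = v
        return p

    def residuals(x: np.ndarray) -> np.ndarray:
        p = full(x)
        return ivim_model(b, p["D"], p["D_star"], p["f"]) - y

    def jac(x: np.ndarray) -> np.ndarray:
        p = full(x)
        return ivim_jacobian(b, p["D"], p["D_star"], p["f"])[:, free_idx]

    lb = np.array([method.bounds[p][0] for p in free])
    ub = np.array([method.bounds[p][1] for p in free])
    if x0 is None:
        x0 = np.array([method.initial[p] for p in free])
    x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)

    res = least_squares(
        residuals,
        x0,
        jac=jac,
        bounds=(lb, ub),
        method="trf",
        xtol=method.xtol,
        ftol=method.ftol,
        gtol=1e-10,
        x_scale=np.array([method.initial[p] for p in free]),
        max_nfev=400,
    )
    estimate = full(res.x)
    return {
        "estimate": estimate,
        "x": res.x,
        "jac": res.jac,
        "rss": float(2.0 * res.cost),
        "nfev": int(res.nfev),
        "converged": bool(res.status > 0),
        "lb": lb,
        "ub": ub,
        "free": free,
    }


def detect_outlier(
    jac: np.ndarray,
    converged: bool,
    x: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    cond_threshold: float = 1.0e8,
) -> tuple[bool, float, bool]:
    """Flag an ill-conditioned fit.

    A fit is an outlier when the solver did not converge, the Jacobian at
    the solution is rank-deficient (a zero column: some free parameter has
    no effect on the model) or its condition number exceeds the threshold,
    or any estimate is pinned at a bound.  Returns
    ``(outlier, condition_number, at_bound)``.
    """
    jac = np.atleast_2d(np.asarray(jac, dtype=float))
    col_scale = np.linalg.norm(jac, axis=0)
    rank_deficient = bool(np.any(col_scale < 1e-12)) or not np.all(np.isfinite(jac))
    cond = math.inf if rank_deficient else float(np.linalg.cond(jac))
    span = ub - lb
    # trust-region solvers stop a small step inside an active bound, so the
    # pinned-at-bound test uses a tolerance relative to the box width
    tol = 1e-3 * np.where(span > 0, span, 1.0)
    at_bound = bool(np.any(x - lb <= tol) or np.any(ub - x <= tol))
    outlier = (not converged) or rank_deficient or cond > cond_threshold or at_bound
    return outlier, cond, at_bound


def _finish(
    sol: dict,
    curve: SignalCurve,
    method: MethodSpec,
    f_clamped: bool = False,
    n_dropped: int = 0,
    force_outlier: bool = False,
) -> FitResult:
    base_outlier, cond, at_bound = detect_outlier(
        sol["jac"], sol["converged"], sol["x"], sol["lb"], sol["ub"],
        method.cond_threshold,
    )
    reasons: list[str] = []
    if not sol["converged"]:
        reasons.append("non_convergence")
    if not math.isfinite(cond):
        reasons.append("rank_deficient")
    elif cond > method.cond_threshold:
        reasons.append("ill_conditioned")
    if at_bound:
        reasons.append("at_bound")
    if force_outlier:
        reasons.append("segment_out_of_bounds")
    n = len(curve)
    n_free = len(sol["free"])
    stderr = {p: math.nan for p in PARAM_NAMES}
    if math.isfinite(cond) and n > n_free:
        # Gauss-Newton covariance: s^2 (J^T J)^-1
        s2 = sol["rss"] / (n - n_free)
        try:
            cov = s2 * np.linalg.inv(sol["jac"].T @ sol["jac"])
            for p, v in zip(sol["free"], np.sqrt(np.clip(np.diag(cov), 0, None))):
                stderr[p] = float(v)
        except np.linalg.LinAlgError:
            pass
    est = sol["estimate"]
    # the pseudo-diffusion coefficient is the weakly identified parameter of
    # this model: a standard error exceeding the estimate itself means the
    # curvature in D* at the solution carries no information (the practical
    # face of an ill-conditioned Jacobian for near-mono-exponential data)
    if (
        "D_star" in sol["free"]
        and math.isfinite(stderr["D_star"])
        and stderr["D_star"] > abs(est["D_star"])
    ):
        reasons.append("stderr_exceeds_dstar")
    if est["f"] > method.f_max:
        reasons.append("f_nonphysiological")
    try:
        params = IVIMParams(D=est["D"], D_star=est["D_star"], f=est["f"])
    except ValidationError:
        # solver pinned a parameter in an unphysical spot; keep values but flag
        params = IVIMParams(
            D=max(est["D"], 1e-12),
            D_star=max(est["D_star"], 1e-12),
            f=float(np.clip(est["f"], 0.0, 1.0)),
        )
        reasons.append("invalid_params")
    return FitResult(
        estimate=params,
        stderr=stderr,
        rss=sol["rss"],
        n_function_evals=sol["nfev"],
        converged=sol["converged"],
        outlier=bool(reasons),
        method_id=method.method_id,
        free_params=sol["free"],
        cond=cond,
        at_bound=at_bound,
        f_clamped=f_clamped,
        n_dropped_high_b=n_dropped,
        outlier_reasons=tuple(reasons),
    )


# --------------------------------------------------------------------------
# The three cascades
# --------------------------------------------------------------------------


def _check_segment_D(D_seg: float, method: MethodSpec) -> tuple[float, bool]:
    """Keep the segmented D inside the physical bounds; an out-of-bounds
    segment slope (possible under heavy noise) marks the whole cascade as
    an outlier rather than being silently accepted."""
    lb, ub = method.bounds["D"]
    if lb <= D_seg <= ub:
        return float(D_seg), False
    return float(np.clip(D_seg, lb, ub)), True


def fit_one_parameter(
    curve: SignalCurve,
    method: MethodSpec | None = None,
    x0: Sequence[float] | None = None,
) -> FitResult:
    """Fully constrained cascade: D and f fixed from the high-b segment,
    D* alone estimated on the full curve.

    f is derived from the extrapolated intercept via f = (S(0) - S(int)) / S(0)
    with S(0) = 1 (the normalization convention), clamped to [0, 1] when the
    noisy intercept strays outside (0, 1].  A clamped f of 0 leaves the
    pseudo-diffusion term with zero amplitude, which surfaces downstream as
    a rank-deficient Jacobian and an outlier flag.
    """
    method = method or MethodSpec("one_parameter")
    D_seg, S_int, n_dropped = fit_high_b_segment(curve, method)
    f_seg = 1.0 - S_int
    f_clamped = not (0.0 < S_int <= 1.0)
    if f_clamped:
        f_seg = float(np.clip(f_seg, 0.0, 1.0))
    D_seg, seg_oob = _check_segment_D(D_seg, method)
    sol = _solve(
        curve, method, free=("D_star",), fixed={"D": D_seg, "f": f_seg}, x0=x0
    )
    return _finish(
        sol, curve, method, f_clamped=f_clamped, n_dropped=n_dropped,
        force_outlier=seg_oob,
    )


def fit_two_parameter(
    curve: SignalCurve,
    method: MethodSpec | None = None,
    x0: Sequence[float] | None = None,
) -> FitResult:
    """Segmented cascade: D fixed from the high-b segment, (f, D*) estimated
    jointly on the full curve (solver order of ``x0``: (f, D*))."""
    method = method or MethodSpec("two_parameter")
    D_seg, _S_int, n_dropped = fit_high_b_segment(curve, method)
    D_seg, seg_oob = _check_segment_D(D_seg, method)
    sol = _solve(curve, method, free=("f", "D_star"), fixed={"D": D_seg}, x0=x0)
    return _finish(sol, curve, method, n_dropped=n_dropped, force_outlier=seg_oob)


def fit_three_parameter(
    curve: SignalCurve,
    method: MethodSpec | None = None,
    x0: Sequence[float] | None = None,
) -> FitResult:
    """Simultaneous cascade: (D, D*, f) estimated jointly from the full
    curve, starting from the configured initial values (or ``x0`` in solver
    order (D, D*, f), as used by the multi-start census)."""
    method = method or MethodSpec("three_parameter")
    sol = _solve(
        curve, method, free=("D", "D_star", "f"), fixed={}, x0=x0
    )
    return _finish(sol, curve, method)


_FITTERS = {
    "one_parameter": fit_one_parameter,
    "two_parameter": fit_two_parameter,
    "three_parameter": fit_three_parameter,
}


def fit_curve(curve: SignalCurve, method: MethodSpec) -> FitResult:
    """Dispatch a curve to the cascade named by ``method.method_id``."""
    return _FITTERS[method.method_id](curve, method)


# --------------------------------------------------------------------------
# Batch interface
# --------------------------------------------------------------------------


def fit_ensemble(
    records: Iterable[EnsembleRecord],
    method: MethodSpec,
    model: str = "model",
) -> pd.DataFrame:
    """Fit every curve of an ensemble with one cascade.

    Returns one row per iteration with columns (model, snr, iteration,
    method, D, D_star, f, stderr_D, stderr_D_star, stderr_f, rss,
    converged, outlier).  Curves whose segmented sub-fit is infeasible are
    recorded as outlier rows with NaN estimates.
    """
    rows = []
    for rec in records:
        try:
            fr = fit_curve(rec.curve, method)
            rows.append(
                (
                    model, rec.snr, rec.iteration, method.method_id,
                    fr.estimate.D, fr.estimate.D_star, fr.estimate.f,
                    fr.stderr["D"], fr.stderr["D_star"], fr.stderr["f"],
                    fr.rss, fr.converged, fr.outlier,
                )
            )
        except FitInfeasibleError:
            rows.append(
                (
                    model, rec.snr, rec.iteration, method.method_id,
                    math.nan, math.nan, math.nan,
                    math.nan, math.nan, math.nan,
                    math.nan, False, True,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "snr", "iteration", "method",
            "D", "D_star", "f",
            "stderr_D", "stderr_D_star", "stderr_f",
            "rss", "converged", "outlier",
        ],
    )
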