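"""Forward models and shared types for bi-exponential IVIM analysis.

The intravoxel incoherent motion (IVIM) model decomposes the normalized
diffusion-weighted signal into a tissue-diffusion compartment and a
capillary pseudo-diffusion compartment:

    S(b)/S(0) = f * exp(-b * D*) + (1 - f) * exp(-b * D)

with ``D`` the tissue diffusion coefficient (mm²/s), ``D*`` the
pseudo-diffusion coefficient of blood in randomly oriented capillaries
(mm²/s), and ``f`` the perfusion fraction in [0, 1].  Signals are carried
normalized (S(0) = 1 by construction); absolute signal is never modeled.
All b-values are in s/mm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class ValidationError(ValueError):
    """An input violates a documented invariant."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IVIMParams:
    """The IVIM parameter triplet (D, D*, f).

    Used both as ground truth for signal generation and as an estimate
    produced by fitting.  Construction enforces positivity of the diffusion
    coefficients and f in [0, 1]; it does not require D* > D, because noisy
    fits may legitimately land outside the bi-exponential regime —
    :meth:`is_biexponential` reports whether the regime holds.
    """

    D: float
    D_star: float
    f: float

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValidationError(f"D must be > 0, got {self.D}")
        if not (self.D_star > 0):
            raise ValidationError(f"D_star must be > 0, got {self.D_star}")
        if not (0.0 <= self.f <= 1.0):
            raise ValidationError(f"f must lie in [0, 1], got {self.f}")

    def is_biexponential(self) -> bool:
        """True when D* > D, i.e. the two compartments are ordered as the
        model intends (pseudo-diffusion faster than tissue diffusion)."""
        return self.D_star > self.D

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.D_star, self.f], dtype=float)


#: Gray-matter study model: population-average parameters for healthy
#: gray matter (moderate perfusion fraction, strongly separated D and D*).
GM_PARAMS = IVIMParams(D=8.32e-4, D_star=2.68e-2, f=0.115)

#: Low-perfused tumor study model: subtle bi-exponential behavior
#: (D* only ~4.4x D, small perfusion fraction).
TUMOR_PARAMS = IVIMParams(D=1.63e-3, D_star=7.23e-3, f=0.0953)

#: Named study models, keyed as they appear in configs and output tables.
STUDY_MODELS: dict[str, IVIMParams] = {
    "gray_matter": GM_PARAMS,
    "tumor": TUMOR_PARAMS,
}


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered b-value schedule (s/mm²) at which the signal is sampled."""

    b_values: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size == 0 or b[0] != 0.0:
            raise ValidationError("b_values must start at b = 0")
        if np.any(b < 0):
            raise ValidationError("b_values must all be >= 0")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("b_values must be strictly increasing (no duplicates)")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def high_b_indices(self, threshold: float, strict: bool = True) -> np.ndarray:
        """Indices of the b-values above the perfusion threshold.

        ``strict=True`` selects b > threshold (the default reading of the
        high-b regime); ``strict=False`` selects b >= threshold.
        """
        b = self.b
        return np.nonzero(b > threshold if strict else b >= threshold)[0]

    def supports_segmented(self, threshold: float, strict: bool = True) -> bool:
        """Whether >= 2 samples lie above the threshold, as the segmented
        (high-b mono-exponential) sub-fit requires."""
        return self.high_b_indices(threshold, strict).size >= 2


#: The 11-point b-value schedule of the study protocol (s/mm²).
DEFAULT_SCHEME = AcquisitionScheme(
    b_values=(0, 20, 40, 80, 110, 140, 170, 200, 300, 500, 1000)
)


@dataclass(frozen=True)
class SignalCurve:
    """Normalized signal S(b)/S(0) sampled on an acquisition scheme.

    Noiseless curves generated from valid parameters start at exactly 1 and
    decrease in b; noisy curves carry no such guarantee and may stray above
    1 or below 0.
    """

    scheme: AcquisitionScheme
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.scheme):
            raise ValidationError(
                f"values length {v.size} does not match scheme length {len(self.scheme)}"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.scheme)


# --------------------------------------------------------------------------
# Forward models
# --------------------------------------------------------------------------


def ivim_model(b: np.ndarray, D: float, D_star: float, f: float) -> np.ndarray:
    """Bi-exponential IVIM decay evaluated at raw b-values (array in, array out)."""
    b = np.asarray(b, dtype=float)
    return f * np.exp(-b * D_star) + (1.0 - f) * np.exp(-b * D)


def ivim_jacobian(b: np.ndarray, D: float, D_star: float, f: float) -> np.ndarray:
    """Analytic Jacobian of :func:`ivim_model` with columns (dD, dD*, df)."""
    b = np.asarray(b, dtype=float)
    e_tissue = np.exp(-b * D)
    e_perf = np.exp(-b * D_star)
    return np.column_stack(
        [-(1.0 - f) * b * e_tissue, -f * b * e_perf, e_perf - e_tissue]
    )


def ivim_signal(params: IVIMParams, scheme: AcquisitionScheme) -> SignalCurve:
    """Noiseless IVIM signal curve S(b)/S(0) for the given parameters.

    The value at b = 0 is exactly 1 by construction of the normalized model.
    """
    if not isinstance(params, IVIMParams):
        raise ValidationError("params must be an IVIMParams instance")
    if not isinstance(scheme, AcquisitionScheme):
        raise ValidationError("scheme must be an AcquisitionScheme instance")
    return SignalCurve(scheme, ivim_model(scheme.b, params.D, params.D_star, params.f))


def mono_exp_signal(
    D: float, intercept: float, scheme: AcquisitionScheme
) -> SignalCurve:
    """Mono-exponential decay ``intercept * exp(-b D)``.

    With intercept 1 this is the high-b tissue model; a free intercept below
    1 represents the tissue compartment extrapolated back to b = 0, whose
    deficit from 1 is the perfusion fraction.
    """
    if not (D > 0):
        raise ValidationError(f"D must be > 0, got {D}")
    if not (intercept > 0):
        raise ValidationError(f"intercept must be > 0, got {intercept}")
    return SignalCurve(scheme, intercept * np.exp(-scheme.b * D))


def perfusion_fraction_from_intercept(S0: float, S_int: float) -> float:
    """Perfusion fraction from the high-b extrapolated intercept.

    f = (S(0) - S(int)) / S(0).  When no vascular component is present the
    extrapolated intercept equals S(0) and f = 0.  Results falling outside
    [0, 1] (intercept non-positive or above S(0), as noise can produce) are
    clamped with a warning.
    """
    if not (S0 > 0):
        raise ValidationError(f"S0 must be > 0, got {S0}")
    f = (S0 - S_int) / S0
    if not (0.0 < S_int <= S0):
        warnings.warn(
            f"intercept {S_int} outside (0, S0={S0}]; perfusion fraction "
            f"clamped from {f:.4g} to [0, 1]",
            stacklevel=2,
        )
        f = float(np.clip(f, 0.0, 1.0))
    return float(f)
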