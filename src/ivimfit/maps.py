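"""Voxel-by-voxel IVIM parameter mapping on 4D multi-b-value volumes.

Each in-mask voxel's decay is normalized by its own b = 0 sample and fitted
with one of the three cascades, producing 3D maps of D, D* and f.  Voxels
whose fitted perfusion fraction exceeds a threshold (default 0.3) are
masked as non-physiological — in brain data such values arise from
cerebrospinal-fluid partial-volume contamination rather than perfusion.
The threshold acts as a post-fit mask, not a fit bound, so it never biases
the estimates of retained voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .core import AcquisitionScheme, SignalCurve, ValidationError
from .fitting import FitInfeasibleError, MethodSpec, fit_curve

#: perfusion fractions above this are treated as CSF contamination.
DEFAULT_F_MAX = 0.3


@dataclass(frozen=True)
class ParameterMaps:
    """Voxelwise fit output.

    ``fitted_mask``, ``csf_mask`` and the background (all-False remainder)
    partition the in-brain volume; outlier voxels are inside ``fitted_mask``
    but flagged in ``outlier_mask`` with their map values withheld (NaN).
    """

    D: np.ndarray
    D_star: np.ndarray
    f: np.ndarray
    fitted_mask: np.ndarray
    csf_mask: np.ndarray
    outlier_mask: np.ndarray


def fit_volume(
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    method: MethodSpec,
    brain_mask: np.ndarray | None = None,
    f_max: float = DEFAULT_F_MAX,
) -> ParameterMaps:
    """Fit every in-mask voxel of a 4D (x, y, z, b) volume.

    The 4th dimension must match the scheme; every in-mask voxel must have
    a positive b = 0 sample (used for per-voxel normalization).  Voxels
    with fitted f above ``f_max`` land in the CSF mask with values
    withheld; outlier fits are flagged and withheld likewise.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValidationError(f"volume must be 4D, got {volume.ndim}D")
    if volume.shape[3] != len(scheme):
        raise ValidationError(
            f"volume has {volume.shape[3]} b-samples but scheme has {len(scheme)}"
        )
    shape = volume.shape[:3]
    if brain_mask is None:
        brain_mask = volume[..., 0] != 0
    else:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != shape:
            raise ValidationError(
                f"brain_mask shape {brain_mask.shape} does not match volume {shape}"
            )
    s0 = volume[..., 0]
    if np.any(brain_mask & (s0 <= 0)):
        raise ValidationError("non-positive b=0 samples inside the brain mask")

    D = np.full(shape, np.nan)
    D_star = np.full(shape, np.nan)
    f = np.full(shape, np.nan)
    fitted = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    outlier = np.zeros(shape, dtype=bool)

    # align the fit-level physiological ceiling with the mapping threshold
    method = replace(method, f_max=f_max)
    for idx in np.argwhere(brain_mask):
        i, j, k = idx
        signal = volume[i, j, k, :] / s0[i, j, k]
        curve = SignalCurve(scheme, signal)
        try:
            fr = fit_curve(curve, method)
        except FitInfeasibleError:
            fitted[i, j, k] = True
            outlier[i, j, k] = True
            continue
        if fr.f_nonphysiological or (not fr.outlier and fr.estimate.f > f_max):
            csf[i, j, k] = True
        elif fr.outlier:
            fitted[i, j, k] = True
            outlier[i, j, k] = True
        else:
            fitted[i, j, k] = True
            D[i, j, k] = fr.estimate.D
            D_star[i, j, k] = fr.estimate.D_star
            f[i, j, k] = fr.estimate.f
    return ParameterMaps(
        D=D, D_star=D_star, f=f,
        fitted_mask=fitted, csf_mask=csf, outlier_mask=outlier,
    )


# --------------------------------------------------------------------------
# NIfTI / sidecar I/O
# --------------------------------------------------------------------------


def read_bvals(path: str | Path) -> AcquisitionScheme:
    """Read a b-value sidecar file: one value per line, in volume order."""
    values = [float(line) for line in Path(path).read_text().split() if line.strip()]
    return AcquisitionScheme(tuple(values))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_maps(
    maps: ParameterMaps, out_dir: str | Path, affine: np.ndarray | None = None
) -> dict[str, Path]:
    """Write one NIfTI per parameter map plus the fitted/CSF/outlier masks."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    out: dict[str, Path] = {}
    for name, data, dtype in [
        ("D", maps.D, np.float64),
        ("D_star", maps.D_star, np.float64),
        ("f", maps.f, np.float64),
        ("fitted_mask", maps.fitted_mask, np.uint8),
        ("csf_mask", maps.csf_mask, np.uint8),
        ("outlier_mask", maps.outlier_mask, np.uint8),
    ]:
        path = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), path)
        out[name] = path
    return out
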