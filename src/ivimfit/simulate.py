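"""Monte-Carlo input generation: noise injection, iteration ensembles and
digital phantoms.

Noise model
-----------
Additive zero-mean white Gaussian noise on the normalized magnitude signal,
independently per b-value.  The noise level is set through the
signal-to-noise ratio SNR = mu / sigma with mu the maximum signal; since
curves are normalized and decreasing, mu = 1 and sigma = 1 / SNR.  No
Rician correction is applied.

Seeding
-------
A master seed spawns one independent child stream per SNR level (and per
model, when several are simulated), so iteration streams at different
levels are statistically independent and any single iteration can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    STUDY_MODELS,
    AcquisitionScheme,
    DEFAULT_SCHEME,
    IVIMParams,
    SignalCurve,
    ValidationError,
    ivim_signal,
)

#: SNR levels of the study design.
DEFAULT_SNR_LEVELS: tuple[float, ...] = (20, 30, 40, 50, 60, 70)

#: Iterations per (model, SNR) cell of the study design.
DEFAULT_N_ITERATIONS = 1000


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level, specified through SNR on the normalized scale."""

    snr: float

    def __post_init__(self) -> None:
        if not (self.snr > 0):
            raise ValidationError(f"snr must be > 0, got {self.snr}")

    @property
    def sigma(self) -> float:
        """Noise standard deviation: sigma = mu / SNR with mu = 1."""
        return 1.0 / self.snr


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one model's Monte-Carlo ensemble."""

    model_params: IVIMParams
    scheme: AcquisitionScheme = DEFAULT_SCHEME
    snr_levels: tuple[float, ...] = DEFAULT_SNR_LEVELS
    n_iterations: int = DEFAULT_N_ITERATIONS
    seed: int = 0
    model_name: str = "model"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if any(s <= 0 for s in self.snr_levels):
            raise ValidationError("snr_levels must all be > 0")
        object.__setattr__(self, "snr_levels", tuple(float(s) for s in self.snr_levels))

    @classmethod
    def from_dict(cls, cfg: Mapping, seed: int | None = None) -> "SimulationConfig":
        """Build from a configuration mapping.

        The model is given either by name (``model: tumor``) or by explicit
        coefficients (``D``, ``D_star``, ``f``).
        """
        if "model" in cfg:
            name = str(cfg["model"])
            try:
                params = STUDY_MODELS[name]
            except KeyError:
                raise ValidationError(
                    f"unknown model {name!r}; known: {sorted(STUDY_MODELS)}"
                ) from None
        else:
            params = IVIMParams(
                D=float(cfg["D"]), D_star=float(cfg["D_star"]), f=float(cfg["f"])
            )
            name = str(cfg.get("name", "custom"))
        scheme = (
            AcquisitionScheme(tuple(cfg["b_values"]))
            if "b_values" in cfg
            else DEFAULT_SCHEME
        )
        return cls(
            model_params=params,
            scheme=scheme,
            snr_levels=tuple(cfg.get("snr_levels", DEFAULT_SNR_LEVELS)),
            n_iterations=int(cfg.get("n_iterations", DEFAULT_N_ITERATIONS)),
            seed=int(seed if seed is not None else cfg.get("seed", 0)),
            model_name=name,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), seed=seed)


@dataclass(frozen=True)
class EnsembleRecord:
    """One noisy realization: (snr, iteration index, curve)."""

    snr: float
    iteration: int
    curve: SignalCurve


def add_noise(
    curve: SignalCurve, noise: NoiseSpec, rng: np.random.Generator
) -> SignalCurve:
    """Return a new curve with i.i.d. zero-mean Gaussian deviates of standard
    deviation ``noise.sigma`` added independently at each b-value.

    The input curve is left unmodified; noisy curves compose (noise can be
    added to an already-noisy curve).
    """
    deviates = rng.normal(loc=0.0, scale=noise.sigma, size=len(curve))
    return SignalCurve(curve.scheme, curve.values + deviates)


def snr_rng(seed: int, level_index: int, n_levels: int) -> np.random.Generator:
    """Independent child generator for one SNR level under a master seed."""
    children = np.random.SeedSequence(seed).spawn(n_levels)
    return np.random.default_rng(children[level_index])


def generate_ensemble(config: SimulationConfig) -> list[EnsembleRecord]:
    """Generate the full iteration ensemble for one model.

    Returns ``n_iterations`` noisy curves per SNR level, in (level, iteration)
    order.  Deterministic under a fixed seed; each SNR level draws from its
    own spawned substream so levels are mutually independent.
    """
    clean = ivim_signal(config.model_params, config.scheme)
    records: list[EnsembleRecord] = []
    for li, snr in enumerate(config.snr_levels):
        rng = snr_rng(config.seed, li, len(config.snr_levels))
        noise = NoiseSpec(snr=snr)
        for it in range(config.n_iterations):
            records.append(EnsembleRecord(snr, it, add_noise(clean, noise, rng)))
    return records


def ensemble_to_frame(
    records: Iterable[EnsembleRecord], model: str = "model"
) -> pd.DataFrame:
    """Long-format view of an ensemble: one row per iteration x b-value."""
    rows = []
    for rec in records:
        for b, s in zip(rec.curve.scheme.b_values, rec.curve.values):
            rows.append((model, rec.snr, rec.iteration, b, s))
    return pd.DataFrame(rows, columns=["model", "snr", "iteration", "b", "signal"])


def frame_to_curves(frame: pd.DataFrame) -> list[EnsembleRecord]:
    """Inverse of :func:`ensemble_to_frame` (b-values must be consistent)."""
    records = []
    for (snr, it), grp in frame.groupby(["snr", "iteration"], sort=True):
        grp = grp.sort_values("b")
        scheme = AcquisitionScheme(tuple(grp["b"].to_numpy()))
        records.append(
            EnsembleRecord(float(snr), int(it), SignalCurve(scheme, grp["signal"].to_numpy()))
        )
    return records


# --------------------------------------------------------------------------
# Digital phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """A labeled multi-compartment digital phantom.

    ``labels`` is a 3D integer volume; every nonzero label must have an
    entry in ``region_params``.  Label 0 is background and stays zero in
    the generated signal.  Stands in for a patient acquisition: each voxel
    carries a full multi-b-value decay for its compartment, plus noise.
    """

    labels: np.ndarray
    region_params: Mapping[int, IVIMParams]
    scheme: AcquisitionScheme = DEFAULT_SCHEME
    noise: NoiseSpec | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3 or lab.size == 0:
            raise ValidationError("labels must be a non-empty 3D volume")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(self.region_params)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} have no region parameters")
        object.__setattr__(self, "labels", lab.astype(int))


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """4D signal volume (x, y, z, b) from a phantom specification.

    Each labeled voxel holds its region's noiseless decay plus (optionally)
    i.i.d. Gaussian noise; background voxels are zero at every b.
    """
    nx, ny, nz = spec.labels.shape
    nb = len(spec.scheme)
    vol = np.zeros((nx, ny, nz, nb), dtype=float)
    for label, params in spec.region_params.items():
        mask = spec.labels == label
        if not mask.any():
            continue
        vol[mask, :] = ivim_signal(params, spec.scheme).values
    if spec.noise is not None:
        fg = spec.labels > 0
        vol[fg, :] += rng.normal(0.0, spec.noise.sigma, size=(int(fg.sum()), nb))
    return vol


def save_phantom_nifti(
    volume: np.ndarray, labels: np.ndarray, out_dir: str | Path, prefix: str = "phantom"
) -> tuple[Path, Path]:
    """Write the 4D signal and 3D label volumes as NIfTI files."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    sig_path = out_dir / f"{prefix}_dwi.nii"
    lab_path = out_dir / f"{prefix}_labels.nii"
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), sig_path)
    nib.save(
        nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), lab_path
    )
    return sig_path, lab_path
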