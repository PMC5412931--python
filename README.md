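# ivimfit

Bi-exponential intravoxel incoherent motion (IVIM) model fitting for
low-perfused tissue, with a Monte-Carlo harness for evaluating how well the
three standard fitting cascades recover the model parameters as a function
of signal-to-noise ratio.

## Who this is for

Diffusion-MRI researchers who fit the IVIM model in brain or other
low-perfusion tissue and need to know which fitting strategy to trust —
and at what SNR the perfusion parameters stop being meaningful.

## The model

The normalized diffusion-weighted signal is modeled as a two-compartment
decay over the b-value (diffusion weighting, s/mm²):

    S(b)/S(0) = f · exp(−b·D*) + (1 − f) · exp(−b·D)

- **D** — tissue diffusion coefficient (mm²/s),
- **D\*** — pseudo-diffusion coefficient of blood in randomly oriented
  capillaries (mm²/s), normally ≫ D,
- **f** — perfusion fraction, the share of voxel signal from the vascular
  compartment.

Three estimation cascades are implemented, all damped nonlinear least
squares on the full curve:

| cascade | fixed beforehand | estimated |
|---|---|---|
| `three_parameter` (simultaneous) | — | D, D\*, f |
| `two_parameter` (segmented) | D from a log-linear fit of b > 200 s/mm² | f, D\* |
| `one_parameter` (fully constrained) | D as above; f = 1 − S(int) from the same fit's extrapolated intercept | D\* |

Fits whose solution carries no parameter information (solver failure,
rank-deficient or ill-conditioned Jacobian, estimate pinned at a bound, D\*
standard error exceeding the estimate, non-physiological f > 0.3) are
flagged as outliers and excluded from summaries — weak bi-exponential decay
plus noise routinely produces such fits, and counting them is itself one of
the evaluation's outputs.

Around the cascades the package provides: Gaussian-noise ensemble
simulation at controlled SNR (σ = 1/SNR on the normalized scale);
accuracy (mean error %), reproducibility (CV%), and Bland-Altman
bias/limits-of-agreement summaries with ANOVA + Tukey HSD cross-method
comparison; F-test confidence-region grids over parameter pairs; a
multi-start census of local minima; and voxelwise parameter mapping of 4D
NIfTI volumes with CSF masking (f > 0.3).

## Worked example

```python
import ivimfit as iv

# the gray-matter study model on the 11-point b-value schedule
curve = iv.ivim_signal(iv.GM_PARAMS, iv.DEFAULT_SCHEME)
print(curve.values[[0, 7, 10]])   # S/S0 at b = 0, 200, 1000

r = iv.fit_one_parameter(curve)   # noiseless recovery
print(r.estimate)

# Monte-Carlo at SNR 40: 1000 noisy curves, constrained cascade
cfg = iv.SimulationConfig(model_params=iv.GM_PARAMS, snr_levels=(40.0,),
                          n_iterations=1000, seed=1)
fits = iv.fit_ensemble(iv.generate_ensemble(cfg),
                       iv.MethodSpec("one_parameter"))
used = fits[~fits.outlier]
print(f"outliers: {100 * fits.outlier.mean():.1f}%")
print(f"mean D:   {used.D.mean():.4g}  (truth {iv.GM_PARAMS.D:.4g})")
```

prints

```
[1.     0.7499 0.3851]
IVIMParams(D=0.000832062..., D_star=0.0268257..., f=0.114951...)
outliers: 21.1%
mean D:   0.000799  (truth 0.000832)
```

Read: at b = 1000 s/mm² the gray-matter signal has decayed to 0.385 of its
b = 0 value; with no noise the constrained cascade recovers (D, D\*, f) to
better than 0.1%; at SNR 40, 21% of iterations are discarded as
ill-conditioned, and the surviving mean D underestimates truth by ~4% —
the flip side of excluding fits in which noise flattened the perfusion
shoulder.

The full study (both tissue models × 6 SNR levels × 3 cascades × 1000
iterations) runs from a config file and writes the summary tables:

```bash
ivim simulate --config study.yaml --out results/
ivim fit-volume --dwi phantom_dwi.nii --bvals bvals.txt --method 1p --out maps/
```

## Layout

| module | contents |
|---|---|
| `ivimfit.core` | parameter/scheme/signal types, forward models |
| `ivimfit.simulate` | noise model, Monte-Carlo ensembles, digital phantoms |
| `ivimfit.fitting` | the three cascades, segment sub-fit, outlier flagging |
| `ivimfit.metrics` | CV%, mean error, Bland-Altman, ANOVA/Tukey, tables |
| `ivimfit.confidence` | F-test confidence grids, multi-start minima census |
| `ivimfit.maps` | voxelwise mapping of 4D volumes, NIfTI I/O |
| `ivimfit.study` | end-to-end orchestration, manifests |
| `ivimfit.cli` | the `ivim` command-line tool |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
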