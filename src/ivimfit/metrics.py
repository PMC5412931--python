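"""Summary statistics for the Monte-Carlo evaluation.

Per (model, SNR, method, parameter) cell the study reports:

- reproducibility as the coefficient of variation, CV% = 100 * SD / mean;
- accuracy as the mean error %, 100 * |mean - truth| / truth;
- Bland-Altman bias and 95% limits of agreement on per-iteration relative
  differences d_i = 100 * (estimate_i - truth) / truth;
- the outlier percentage of the fitting cascade;
- a one-way ANOVA with Tukey HSD post-hoc comparison across the three
  cascades.

All statistics use the sample (n-1) standard deviation and are computed on
the non-outlier subset only; outliers are reported as their own column,
never silently mixed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import IVIMParams
from .fitting import PARAM_NAMES

#: z-quantile for 95% limits of agreement.
LOA_MULTIPLIER = 1.96

#: significance threshold for the cross-method comparison.
ALPHA = 0.05


class UndefinedMetricError(ValueError):
    """Too few values, or a degenerate configuration, for the metric."""


def _clean(estimates: Iterable[float]) -> np.ndarray:
    x = np.asarray(list(estimates), dtype=float)
    return x[np.isfinite(x)]


def cv_percent(estimates: Iterable[float]) -> float:
    """Coefficient of variation: 100 * sample SD / mean."""
    x = _clean(estimates)
    if x.size < 2:
        raise UndefinedMetricError(f"need >= 2 values, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise UndefinedMetricError("mean is zero; CV undefined")
    return float(100.0 * x.std(ddof=1) / mean)


def mean_error_percent(estimates: Iterable[float], truth: float) -> float:
    """Accuracy of the ensemble mean: 100 * |mean - truth| / truth."""
    x = _clean(estimates)
    if x.size < 1:
        raise UndefinedMetricError("need >= 1 value")
    if truth == 0:
        raise UndefinedMetricError("truth is zero; relative error undefined")
    return float(100.0 * abs(x.mean() - truth) / truth)


@dataclass(frozen=True)
class BlandAltman:
    bias_percent: float
    loa_low_percent: float
    loa_high_percent: float


def bland_altman(estimates: Iterable[float], truth: float) -> BlandAltman:
    """Bland-Altman agreement with ground truth on the relative scale.

    Per-iteration relative difference d_i = 100 * (estimate_i - truth) / truth;
    bias = mean(d), limits of agreement = bias +/- 1.96 * SD(d).  The sign
    convention (estimate minus truth) makes overestimation positive.
    """
    x = _clean(estimates)
    if x.size < 2:
        raise UndefinedMetricError(f"need >= 2 values, got {x.size}")
    if truth == 0:
        raise UndefinedMetricError("truth is zero")
    d = 100.0 * (x - truth) / truth
    bias = d.mean()
    half = LOA_MULTIPLIER * d.std(ddof=1)
    return BlandAltman(float(bias), float(bias - half), float(bias + half))


def outlier_percent(outlier_flags: Iterable[bool]) -> float:
    """Percentage of fits flagged as outliers."""
    flags = np.asarray(list(outlier_flags), dtype=bool)
    if flags.size == 0:
        raise UndefinedMetricError("need >= 1 fit result")
    return float(100.0 * flags.sum() / flags.size)


@dataclass(frozen=True)
class MethodComparison:
    """One-way ANOVA across fitting methods with Tukey HSD post hoc."""

    parameter: str
    snr: float
    f_statistic: float
    p_value: float
    tukey_p: dict[tuple[str, str], float]

    def significant_pairs(self, alpha: float = ALPHA) -> list[tuple[str, str]]:
        return [pair for pair, p in self.tukey_p.items() if p < alpha]


def compare_methods(
    groups: Mapping[str, Sequence[float]],
    parameter: str = "",
    snr: float = float("nan"),
) -> MethodComparison:
    """ANOVA + Tukey HSD on per-method estimate collections.

    ``groups`` maps a method label to its (non-outlier) estimates of one
    parameter at one SNR.  Requires >= 2 groups with >= 2 values each and
    some within-group variance.
    """
    labels = list(groups)
    arrays = [_clean(groups[k]) for k in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise UndefinedMetricError("need >= 2 groups with >= 2 values each")
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise UndefinedMetricError("zero within-group variance everywhere")
    f_stat, p_val = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    tukey_p: dict[tuple[str, str], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            tukey_p[(labels[i], labels[j])] = float(tukey.pvalue[i, j])
    return MethodComparison(
        parameter=parameter,
        snr=snr,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        tukey_p=tukey_p,
    )


# --------------------------------------------------------------------------
# Table builders over batch fit output
# --------------------------------------------------------------------------


def summarize_fits(
    fits: pd.DataFrame, truths: Mapping[str, IVIMParams]
) -> pd.DataFrame:
    """Per-cell summary table over batch fit output.

    ``fits`` is the long-format frame emitted by ``fit_ensemble`` (possibly
    concatenated over models and methods); ``truths`` maps model id to its
    ground-truth parameters.  Returns one row per (model, snr, method,
    parameter) with n_used, mean, sd, cv_percent, mean_error_percent,
    bias_percent, loa_low/high_percent and outlier_percent.
    """
    rows = []
    for (model, snr, method), grp in fits.groupby(
        ["model", "snr", "method"], sort=True
    ):
        truth = truths[model]
        out_pct = outlier_percent(grp["outlier"])
        used = grp[~grp["outlier"]]
        for param in PARAM_NAMES:
            vals = used[param].to_numpy()
            truth_val = getattr(truth, param)
            if vals.size >= 2 and np.isfinite(vals).sum() >= 2:
                ba = bland_altman(vals, truth_val)
                row = dict(
                    model=model, snr=snr, method=method, parameter=param,
                    n_used=int(np.isfinite(vals).sum()),
                    mean=float(np.nanmean(vals)),
                    sd=float(np.nanstd(vals, ddof=1)),
                    cv_percent=cv_percent(vals),
                    mean_error_percent=mean_error_percent(vals, truth_val),
                    bias_percent=ba.bias_percent,
                    loa_low_percent=ba.loa_low_percent,
                    loa_high_percent=ba.loa_high_percent,
                    outlier_percent=out_pct,
                )
            else:
                row = dict(
                    model=model, snr=snr, method=method, parameter=param,
                    n_used=int(np.isfinite(vals).sum()),
                    mean=np.nan, sd=np.nan, cv_percent=np.nan,
                    mean_error_percent=np.nan, bias_percent=np.nan,
                    loa_low_percent=np.nan, loa_high_percent=np.nan,
                    outlier_percent=out_pct,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def reproducibility_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Reproducibility view: CV% and outlier% per cell."""
    return summary[
        ["model", "snr", "method", "parameter", "n_used", "cv_percent",
         "outlier_percent"]
    ].copy()


def bias_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman view: bias and limits of agreement per cell."""
    return summary[
        ["model", "snr", "method", "parameter", "n_used", "bias_percent",
         "loa_low_percent", "loa_high_percent"]
    ].copy()


def accuracy_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Accuracy view: ensemble mean +/- SD and mean error % per cell."""
    return summary[
        ["model", "snr", "method", "parameter", "n_used", "mean", "sd",
         "mean_error_percent"]
    ].copy()


def compare_methods_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Cross-method ANOVA/Tukey for every (model, snr, parameter) cell.

    Cells where the comparison is undefined (too few usable fits) are
    skipped.
    """
    rows = []
    for (model, snr), grp in fits.groupby(["model", "snr"], sort=True):
        used = grp[~grp["outlier"]]
        for param in PARAM_NAMES:
            groups = {
                m: sub[param].to_numpy()
                for m, sub in used.groupby("method", sort=True)
            }
            try:
                cmp = compare_methods(groups, parameter=param, snr=snr)
            except UndefinedMetricError:
                continue
            row = dict(
                model=model, snr=snr, parameter=param,
                anova_f=cmp.f_statistic, anova_p=cmp.p_value,
            )
            for (a, b), p in cmp.tukey_p.items():
                row[f"tukey_p_{a}_vs_{b}"] = p
            rows.append(row)
    return pd.DataFrame(rows)
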