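"""First-order statistics of the lesion HU distribution.

Forty-four statistics computed on the raw (undiscretized) voxel values,
describing location, dispersion, shape and robust summaries of the marginal
Hounsfield-unit distribution.  Spatial arrangement is ignored entirely.

Catalog (44 names, fixed order):

* core (16): mean, median, mode, sample sd, variance, Fisher skewness,
  excess kurtosis, min, max, range, IQR, mean absolute deviation about the
  mean, median absolute deviation about the median, root mean square, mean
  of squares (energy density), coefficient of variation;
* percentiles (14): p1, p5, p10, p20, p25, p30, p40, p60, p70, p75, p80,
  p90, p95, p99 (linear interpolation between order statistics);
* robust (4): 5% and 10% trimmed means, 5% winsorized mean, midhinge;
* shape (10): entropy and uniformity of equal-width bin occupancies at
  B = 16/32/64, quartile skewness, quartile coefficient of dispersion,
  standard error of the mean, interdecile range.

Degenerate lesions (single voxel or constant values) return 0 for the
dispersion/shape terms that are otherwise undefined, keeping downstream
feature matrices finite; such zero-variance columns are removed by the
model-building preprocessing anyway.
"""

from __future__ import annotations

import numpy as np

from .discretize import equal_width_labels
from .io import VoxelLesion

__all__ = ["FIRSTORDER_NAMES", "compute_firstorder"]

_PERCENTILES = (1, 5, 10, 20, 25, 30, 40, 60, 70, 75, 80, 90, 95, 99)

FIRSTORDER_NAMES: tuple[str, ...] = (
    "fo_mean", "fo_median", "fo_mode", "fo_sd", "fo_variance",
    "fo_skewness", "fo_kurtosis", "fo_min", "fo_max", "fo_range",
    "fo_iqr", "fo_mad_mean", "fo_mad_median", "fo_rms", "fo_energy_density",
    "fo_cv",
    *(f"fo_p{p}" for p in _PERCENTILES),
    "fo_trimmed_mean_5", "fo_trimmed_mean_10", "fo_winsorized_mean_5",
    "fo_midhinge",
    "fo_entropy_b16", "fo_uniformity_b16",
    "fo_entropy_b32", "fo_uniformity_b32",
    "fo_entropy_b64", "fo_uniformity_b64",
    "fo_quartile_skewness", "fo_quartile_dispersion", "fo_sem",
    "fo_interdecile_range",
)


def _mode_smallest(values: np.ndarray) -> float:
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])  # argmax -> first, i.e. smallest value


def _trimmed_mean(sorted_values: np.ndarray, proportion: float) -> float:
    n = len(sorted_values)
    k = int(np.floor(proportion * n))
    return float(sorted_values[k:n - k].mean())


def _winsorized_mean(sorted_values: np.ndarray, proportion: float) -> float:
    n = len(sorted_values)
    k = int(np.floor(proportion * n))
    w = sorted_values.astype(np.float64).copy()
    w[:k] = w[k]
    w[n - k:] = w[n - 1 - k]
    return float(w.mean())


def _bin_entropy_uniformity(values: np.ndarray, n_bins: int) -> tuple[float, float]:
    labels = equal_width_labels(values, n_bins)
    counts = np.bincount(labels, minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / len(values)
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    return entropy, uniformity


def compute_firstorder(lesion: VoxelLesion) -> dict[str, float]:
    """Compute the 44-statistic first-order block for one lesion."""
    v = np.asarray(lesion.values, dtype=np.float64)
    n = len(v)
    s = np.sort(v)
    out: dict[str, float] = {}

    mean = float(v.mean())
    median = float(np.median(v))
    constant = bool(s[0] == s[-1])
    if n > 1 and not constant:
        variance = float(v.var(ddof=1))
        sd = float(np.sqrt(variance))
        m2 = float(((v - mean) ** 2).mean())
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skewness = m3 / m2 ** 1.5
        kurtosis = m4 / m2 ** 2 - 3.0
        cv = sd / mean if mean != 0 else 0.0
        sem = sd / np.sqrt(n)
    else:
        variance = sd = skewness = kurtosis = cv = sem = 0.0

    q1, q3 = np.percentile(v, (25, 75))
    p10, p90 = np.percentile(v, (10, 90))
    iqr = float(q3 - q1)

    out["fo_mean"] = mean
    out["fo_median"] = median
    out["fo_mode"] = _mode_smallest(v)
    out["fo_sd"] = sd
    out["fo_variance"] = variance
    out["fo_skewness"] = float(skewness)
    out["fo_kurtosis"] = float(kurtosis)
    out["fo_min"] = float(s[0])
    out["fo_max"] = float(s[-1])
    out["fo_range"] = float(s[-1] - s[0])
    out["fo_iqr"] = iqr
    out["fo_mad_mean"] = float(np.abs(v - mean).mean())
    out["fo_mad_median"] = float(np.median(np.abs(v - median)))
    out["fo_rms"] = float(np.sqrt((v ** 2).mean()))
    out["fo_energy_density"] = float((v ** 2).mean())
    out["fo_cv"] = float(cv)

    for p in _PERCENTILES:
        out[f"fo_p{p}"] = float(np.percentile(v, p))

    out["fo_trimmed_mean_5"] = _trimmed_mean(s, 0.05)
    out["fo_trimmed_mean_10"] = _trimmed_mean(s, 0.10)
    out["fo_winsorized_mean_5"] = _winsorized_mean(s, 0.05)
    out["fo_midhinge"] = float((q1 + q3) / 2.0)

    for b in (16, 32, 64):
        ent, uni = _bin_entropy_uniformity(v, b)
        out[f"fo_entropy_b{b}"] = ent
        out[f"fo_uniformity_b{b}"] = uni

    out["fo_quartile_skewness"] = (
        float((q3 + q1 - 2.0 * median) / (q3 - q1)) if q3 != q1 else 0.0
    )
    out["fo_quartile_dispersion"] = (
        float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0
    )
    out["fo_sem"] = float(sem)
    out["fo_interdecile_range"] = float(p90 - p10)

    assert tuple(out) == FIRSTORDER_NAMES
    return out
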