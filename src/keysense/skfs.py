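"""Statistical key feature selection (SKFS).

Each instance's selected-feature vector (the PKFS union columns, in
union order) is summarized by 13 statistics which are appended to the
matrix as extra columns, one set per instance.  Conventions, fixed once:

* population (not sample) moments; kurtosis is excess kurtosis;
  skewness and kurtosis are 0 for a constant vector;
* crossing rates count sign changes per step, so they lie in [0, 1];
* "pairwise correlation" is the lag-1 autocorrelation of the vector in
  its canonical feature order (a single row admits no feature-pair
  correlation), 0 when the variance is 0;
* spectral entropy is the Shannon entropy (natural log) of the
  DFT power spectrum of the mean-centered vector normalized to sum 1,
  and 0 when all power is 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from keysense.instances import FeatureMatrix
from keysense.pkfs import SelectionResult

__all__ = ["STAT_NAMES", "row_statistics", "augment"]

STAT_NAMES = (
    "rms",
    "std",
    "mean",
    "median",
    "variance",
    "avg_derivative",
    "zero_crossing_rate",
    "iqr",
    "mean_crossing_rate",
    "kurtosis",
    "skewness",
    "pairwise_correlation",
    "spectral_entropy",
)


def _crossing_rate(v: np.ndarray) -> float:
    # sign changes per step; a touch of exactly zero is not a crossing
    s = np.sign(v)
    return float(np.count_nonzero(s[:-1] * s[1:] < 0)) / (len(v) - 1)


def row_statistics(v) -> dict[str, float]:
    """The 13 summary statistics of one ordered numeric vector (n >= 2).

    Returns a dict keyed by :data:`STAT_NAMES`.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("row_statistics needs a 1-D vector of length >= 2")
    n = len(v)
    mean = float(v.mean())
    centered = v - mean
    variance = float(np.mean(centered**2))
    std = float(np.sqrt(variance))
    rms = float(np.sqrt(np.mean(v**2)))
    median = float(np.median(v))
    q75, q25 = np.percentile(v, [75, 25])  # linear-interpolation quantiles
    iqr = float(q75 - q25)
    avg_derivative = float(np.mean(np.diff(v)))
    zcr = _crossing_rate(v)
    mcr = _crossing_rate(centered)
    if variance > 0:
        m2 = variance
        m3 = float(np.mean(centered**3))
        m4 = float(np.mean(centered**4))
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2 - 3.0
        autocorr = float(np.sum(centered[:-1] * centered[1:]) / np.sum(centered**2))
    else:
        skewness = kurtosis = autocorr = 0.0
    power = np.abs(np.fft.fft(centered)) ** 2
    total = power.sum()
    if total > 0:
        p = power / total
        p = p[p > 0]
        spectral_entropy = float(-np.sum(p * np.log(p)))
    else:
        spectral_entropy = 0.0
    return {
        "rms": rms,
        "std": std,
        "mean": mean,
        "median": median,
        "variance": variance,
        "avg_derivative": avg_derivative,
        "zero_crossing_rate": zcr,
        "iqr": iqr,
        "mean_crossing_rate": mcr,
        "kurtosis": kurtosis,
        "skewness": skewness,
        "pairwise_correlation": autocorr,
        "spectral_entropy": spectral_entropy,
    }


def augment(matrix: FeatureMatrix, selection: SelectionResult) -> FeatureMatrix:
    """Append the 13 statistics of each row's selected-feature vector.

    Output columns are the union-set columns (in union order, values
    passed through untouched) followed by the ``skfs_<name>`` statistic
    columns.  Labels and cohorts are preserved.  In the recognition
    pipeline this runs on the rescaled matrix, so the statistics
    summarize values on a common [0, 1] scale.

    Raises
    ------
    ValueError
        If the matrix lacks a union feature or the union has < 2
        features (the statistics are undefined on shorter vectors).
    """
    union = selection.union_set
    missing = [f for f in union if f not in matrix.data.columns]
    if missing:
        raise ValueError(f"matrix lacks selected features: {missing}")
    if len(union) < 2:
        raise ValueError("need >= 2 selected features to compute row statistics")
    sub = matrix.data[union]
    stats = np.empty((len(sub), len(STAT_NAMES)))
    values = sub.to_numpy(dtype=float)
    for i in range(len(sub)):
        row = row_statistics(values[i])
        stats[i] = [row[name] for name in STAT_NAMES]
    stat_df = pd.DataFrame(stats, columns=[f"skfs_{s}" for s in STAT_NAMES])
    out = pd.concat([sub.reset_index(drop=True), stat_df], axis=1)
    return matrix.with_data(out)
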