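"""The 31-dimensional per-window feature vector.

For each axis (X, Y, Z) ten statistics are computed over the window —
skewness, kurtosis, mean, standard deviation, variance, minimum, maximum,
entropy, energy, covariance — and a 31st feature, the average signal
magnitude, summarises all three axes.

Conventions (all configurable where the field has no single standard):

* moments use population normalisation (divide by n); kurtosis is
  non-excess (a normal population scores 3);
* energy is the time-domain mean squared amplitude;
* entropy is the Shannon entropy (bits) of a 16-bin histogram over the
  axis's own [min, max] range within the window;
* the "covariance" feature of an axis is the cross-covariance of the two
  *other* axes: covariance_x = cov(Y, Z), covariance_y = cov(X, Z),
  covariance_z = cov(X, Y), population-normalised — the assignment of each
  pairwise covariance to the axis not in the pair is what yields exactly
  31 features together with the magnitude term;
* degenerate (zero-variance) axes score 0 for skewness, kurtosis and
  entropy rather than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .windowing import LabeledWindow, WindowSet

__all__ = [
    "FeatureConfig",
    "FEATURE_NAMES",
    "extract_features",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

_AXIS_STATS = (
    "skewness",
    "kurtosis",
    "mean",
    "std",
    "variance",
    "min",
    "max",
    "entropy",
    "energy",
    "covariance",
)
_AXES = ("x", "y", "z")

#: the stable public feature order: ten stats per axis, then the magnitude
FEATURE_NAMES: list[str] = [
    f"{stat}_{ax}" for ax in _AXES for stat in _AXIS_STATS
] + ["magnitude_avg"]


@dataclass(frozen=True)
class FeatureConfig:
    entropy_bins: int = 16
    #: report excess kurtosis (normal -> 0) instead of non-excess (normal -> 3)
    excess_kurtosis: bool = False
    #: delta degrees of freedom for variance/covariance (0 = population)
    ddof: int = 0


def _batch_features(samples: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """(n, w, 3) sample block -> (n, 31) feature block."""
    n, w, _ = samples.shape
    if w < 2:
        raise ValueError("windows need at least 2 samples")
    denom = w - cfg.ddof
    cols = []
    means = samples.mean(axis=1)  # (n, 3)
    for a in range(3):
        x = samples[:, :, a]
        mu = means[:, a]
        xc = x - mu[:, None]
        var_pop = (xc**2).mean(axis=1)
        var = (xc**2).sum(axis=1) / denom
        sd = np.sqrt(var)
        sd_pop = np.sqrt(var_pop)
        nz = sd_pop > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(nz, (xc**3).mean(axis=1) / np.where(nz, sd_pop, 1) ** 3, 0.0)
            kurt = np.where(
                nz, (xc**4).mean(axis=1) / np.where(nz, var_pop, 1) ** 2, 0.0
            )
        if cfg.excess_kurtosis:
            kurt = np.where(nz, kurt - 3.0, 0.0)
        mn = x.min(axis=1)
        mx = x.max(axis=1)
        energy = (x**2).mean(axis=1)
        entropy = _histogram_entropy(x, mn, mx, cfg.entropy_bins)
        b, c = [ax for ax in range(3) if ax != a]
        cov = ((samples[:, :, b] - means[:, b, None]) * (samples[:, :, c] - means[:, c, None])).sum(axis=1) / denom
        cols.extend([skew, kurt, mu, sd, var, mn, mx, entropy, energy, cov])
    magnitude = np.sqrt((samples**2).sum(axis=2)).mean(axis=1)
    cols.append(magnitude)
    return np.stack(cols, axis=1)


def _histogram_entropy(x: np.ndarray, mn: np.ndarray, mx: np.ndarray, bins: int) -> np.ndarray:
    """Shannon entropy (bits) of the per-row histogram over [min, max]."""
    n, w = x.shape
    rng = mx - mn
    safe = np.where(rng > 0, rng, 1.0)
    u = (x - mn[:, None]) / safe[:, None]
    b = np.clip((u * bins).astype(int), 0, bins - 1)
    flat = b + np.arange(n)[:, None] * bins
    counts = np.bincount(flat.ravel(), minlength=n * bins).reshape(n, bins)
    p = counts / w
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ent = -terms.sum(axis=1)
    return np.where(rng > 0, ent, 0.0)


def extract_features(
    window: LabeledWindow, config: FeatureConfig | None = None
) -> pd.Series:
    """Feature vector of a single window, as a named 31-entry series."""
    cfg = config or FeatureConfig()
    samples = np.asarray(window.samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("window samples must be (n, 3)")
    if samples.shape[0] < 2:
        raise ValueError("window needs at least 2 samples")
    values = _batch_features(samples[None, :, :], cfg)[0]
    return pd.Series(values, index=FEATURE_NAMES)


def build_feature_matrix(
    windows: WindowSet | Iterable[LabeledWindow],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature matrix of a window collection; rows preserve window order.

    Returns a DataFrame with the 31 feature columns plus a ``label`` column.
    """
    cfg = config or FeatureConfig()
    if isinstance(windows, WindowSet):
        if len(windows) == 0:
            raise ValueError("empty window list")
        values = _batch_features(np.asarray(windows.samples, dtype=float), cfg)
        labels = windows.labels
    else:
        windows = list(windows)
        if not windows:
            raise ValueError("empty window list")
        samples = np.stack([np.asarray(w.samples, dtype=float) for w in windows])
        values = _batch_features(samples, cfg)
        labels = np.array([w.label for w in windows], dtype=int)
    df = pd.DataFrame(values, columns=FEATURE_NAMES)
    df["label"] = labels
    return df


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES + ["label"] if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    return df
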