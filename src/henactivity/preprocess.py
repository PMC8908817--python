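"""Feature standardization, correlation screening, PCA at 95% variance.

All fit functions learn from a training matrix only and are applied to any
matrix with the same schema, so cross-validation can keep test folds out of
the fit (the statistically correct default).  A global "paper mode" fit —
standardizing the full dataset before splitting — is available upstream by
simply fitting on the full matrix.

Features have wildly different natural scales (m/s^2 vs bits vs m^2/s^4),
so PCA operates on standardized features (correlation-matrix PCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "StandardizationParams",
    "PcaModel",
    "CorrelatedPair",
    "fit_standardizer",
    "apply_standardizer",
    "find_correlated",
    "drop_correlated",
    "fit_pca",
    "apply_pca",
    "FIT_LOG",
]

#: (kind, n_rows) record of every fit performed; lets tests assert that
#: cross-validation never fits preprocessing on test rows.
FIT_LOG: list[tuple[str, int]] = []

LABEL_COL = "label"


def _feature_columns(m: pd.DataFrame) -> list[str]:
    return [c for c in m.columns if c != LABEL_COL]


@dataclass
class StandardizationParams:
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    #: features with zero spread in the training data (mapped to 0)
    constant: np.ndarray


@dataclass
class PcaModel:
    feature_names: list[str]
    components: np.ndarray  #: (p, p) loadings, rows ordered by variance
    explained_variance_ratio: np.ndarray  #: all p fractions, descending
    k: int
    var_threshold: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass(frozen=True)
class CorrelatedPair:
    a: str
    b: str
    r: float


def fit_standardizer(train: pd.DataFrame) -> StandardizationParams:
    """Learn per-feature mean and population SD from a training matrix."""
    if len(train) == 0:
        raise ValueError("cannot fit standardizer on an empty matrix")
    cols = _feature_columns(train)
    x = train[cols].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population normalisation
    constant = sd == 0
    FIT_LOG.append(("standardizer", len(train)))
    return StandardizationParams(cols, mean, sd, constant)


def apply_standardizer(params: StandardizationParams, m: pd.DataFrame) -> pd.DataFrame:
    x = m[params.feature_names].to_numpy(dtype=float)
    safe_sd = np.where(params.constant, 1.0, params.sd)
    z = (x - params.mean) / safe_sd
    z[:, params.constant] = 0.0
    out = pd.DataFrame(z, columns=params.feature_names, index=m.index)
    if LABEL_COL in m.columns:
        out[LABEL_COL] = m[LABEL_COL].to_numpy()
    return out


def find_correlated(m: pd.DataFrame, threshold: float = 0.7) -> list[CorrelatedPair]:
    """All unordered feature pairs with |Pearson r| > threshold.

    Constant features are excluded (their correlation is undefined).
    """
    cols = _feature_columns(m)
    if len(m) < 3:
        raise ValueError("need at least 3 rows for a meaningful correlation")
    x = m[cols].to_numpy(dtype=float)
    keep = [i for i, c in enumerate(cols) if x[:, i].std() > 0]
    if len(keep) < 2:
        return []
    r = np.corrcoef(x[:, keep], rowvar=False)
    pairs = []
    for ii in range(len(keep)):
        for jj in range(ii + 1, len(keep)):
            if abs(r[ii, jj]) > threshold:
                pairs.append(CorrelatedPair(cols[keep[ii]], cols[keep[jj]], float(r[ii, jj])))
    return pairs


def drop_correlated(m: pd.DataFrame, pairs: list[CorrelatedPair]) -> pd.DataFrame:
    """Greedy removal: repeatedly drop the feature in the most unresolved
    flagged pairs (ties broken toward the later column) until none remain."""
    cols = _feature_columns(m)
    order = {c: i for i, c in enumerate(cols)}
    active = [(p.a, p.b) for p in pairs]
    dropped: set[str] = set()
    while active:
        counts: dict[str, int] = {}
        for a, b in active:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = max(counts, key=lambda c: (counts[c], order[c]))
        dropped.add(worst)
        active = [(a, b) for a, b in active if worst not in (a, b)]
    keep = [c for c in m.columns if c not in dropped]
    return m[keep]


def fit_pca(train: pd.DataFrame, var_threshold: float = 0.95) -> PcaModel:
    """Principal components of a standardized training matrix; keeps the
    smallest leading set reaching the cumulative-variance threshold."""
    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must be in (0, 1]")
    cols = _feature_columns(train)
    x = train[cols].to_numpy(dtype=float)
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    FIT_LOG.append(("pca", len(train)))
    return PcaModel(
        feature_names=cols,
        components=pca.components_,
        explained_variance_ratio=ratios,
        k=k,
        var_threshold=var_threshold,
        center=pca.mean_,
    )


def apply_pca(model: PcaModel, m: pd.DataFrame) -> pd.DataFrame:
    """Project onto the first k components (input must be standardized
    with the same training parameters)."""
    x = m[model.feature_names].to_numpy(dtype=float)
    z = (x - model.center) @ model.components[: model.k].T
    out = pd.DataFrame(z, columns=[f"pc{i + 1}" for i in range(model.k)], index=m.index)
    if LABEL_COL in m.columns:
        out[LABEL_COL] = m[LABEL_COL].to_numpy()
    return out
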