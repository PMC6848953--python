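"""Principal component analysis of compound-class relative abundances.

Samples are rows of compositional class-abundance fractions (each row sums
to 1 over the classes plus "unclassified").  PCA is performed on the
column-mean-centered matrix (no unit-variance scaling by default —
compositional fractions already share a scale) with a deterministic sign
convention: within each component the largest-magnitude loading is made
positive.  Group structure (e.g. target species vs medicinal vs control
plants) is summarized by ranked Euclidean distances between group
centroids in score space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

__all__ = ["PCAResult", "pca", "group_distances"]


@dataclass
class PCAResult:
    """Scores (samples x k), loadings (classes x k), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    scale: bool = False,
) -> PCAResult:
    """Centered PCA of a samples x classes abundance matrix.

    ``scale=True`` additionally divides columns by their standard
    deviation (opt-in).  Raises on constant (zero-variance) input and when
    ``n_components`` exceeds min(samples - 1, classes).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 classes")
    max_k = min(matrix.shape[0] - 1, matrix.shape[1])
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}]")
    x = matrix.to_numpy(dtype=float)
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("abundance matrix has zero variance; PCA undefined")
    mean = x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - mean) / sd + mean  # keep mean handling inside sklearn

    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # classes x k, orthonormal columns

    # deterministic sign: largest |loading| per component is positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
        mean=pd.Series(mean, index=matrix.columns),
    )


def group_distances(
    result: PCAResult,
    groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Ranked Euclidean distances between group centroids in score space.

    ``groups`` maps sample id -> group label; at least two groups are
    required.  Returns rows (group_a, group_b, distance, rank).
    """
    labels = pd.Series(groups)
    labels = labels.reindex(result.scores.index)
    if labels.isna().any():
        missing = list(result.scores.index[labels.isna()])
        raise ValueError(f"samples without group label: {missing}")
    centroids = result.scores.groupby(labels).mean()
    names = list(centroids.index)
    if len(names) < 2:
        raise ValueError("at least two groups are required")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
            rows.append({"group_a": a, "group_b": b, "distance": d})
    df = pd.DataFrame(rows).sort_values("distance").reset_index(drop=True)
    df["rank"] = df["distance"].rank(method="min").astype(int)
    return df
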