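"""PCA reduction of deep features and fusion with handcrafted blocks.

Deep descriptors (4096 per image) are compressed to k principal
components (default 1024) and concatenated with the 244 handcrafted
values, giving 1268-wide fused vectors at the default widths. The PCA
model is fitted on training-phase rows only so no information from
validation or test images leaks into the projection; a flag restores the
fit-on-everything variant for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .handcrafted import TOTAL_FEATURES

__all__ = ["PCAModel", "FusedMatrix", "pca_fit", "pca_transform", "fuse",
           "DEFAULT_PCA_COMPONENTS"]

DEFAULT_PCA_COMPONENTS = 1024


@dataclass
class PCAModel:
    """Training mean, orthonormal component rows (k×d) and
    explained-variance shares."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def d(self) -> int:
        return self.components.shape[1]


def pca_fit(train_features: np.ndarray, k: int = DEFAULT_PCA_COMPONENTS) -> PCAModel:
    """Fit PCA on training rows; k is silently lowered to
    min(k, n_train − 1, d).

    Component signs follow a fixed convention — the largest-magnitude
    coordinate of each component is made positive — so repeated fits are
    bitwise comparable.
    """
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("train_features must be a 2-D matrix")
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 training rows")
    k_eff = min(k, n - 1, d)
    model = PCA(n_components=k_eff, random_state=0)
    model.fit(X)
    comps = model.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        mean=model.mean_.copy(),
        components=comps,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def pca_transform(model: PCAModel, features: np.ndarray) -> np.ndarray:
    """Project centered rows onto the component basis (n × k)."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.d:
        raise ValueError(f"feature width {X.shape[1]} != model width {model.d}")
    return (X - model.mean) @ model.components.T


@dataclass
class FusedMatrix:
    """Concatenated deep-PCA and handcrafted blocks with row ids."""

    values: np.ndarray
    k: int
    ids: list[str]

    @property
    def deep_block(self) -> np.ndarray:
        return self.values[:, :self.k]

    @property
    def handcrafted_block(self) -> np.ndarray:
        return self.values[:, self.k:]


def fuse(deep_reduced: np.ndarray, handcrafted: np.ndarray,
         ids: Sequence[str] | None = None,
         handcrafted_ids: Sequence[str] | None = None) -> FusedMatrix:
    """Column-wise concatenation deep_pca ∥ handcrafted.

    Row counts must match; when both id sequences are given they must be
    aligned element-wise.
    """
    D = np.asarray(deep_reduced, dtype=np.float64)
    H = np.asarray(handcrafted, dtype=np.float64)
    if D.ndim != 2 or H.ndim != 2:
        raise ValueError("both inputs must be 2-D matrices")
    if D.shape[0] != H.shape[0]:
        raise ValueError(f"row counts differ: {D.shape[0]} vs {H.shape[0]}")
    if H.shape[1] != TOTAL_FEATURES:
        raise ValueError(f"handcrafted block must be {TOTAL_FEATURES} wide")
    if ids is not None and handcrafted_ids is not None and list(ids) != list(handcrafted_ids):
        raise ValueError("row ids of the two blocks are not aligned")
    row_ids = list(ids) if ids is not None else [f"row{i:05d}" for i in range(D.shape[0])]
    return FusedMatrix(values=np.hstack([D, H]), k=D.shape[1], ids=row_ids)
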