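"""SVD-based PCA compression of embedding matrices.

A p x n matrix X is factored X = U S V^T and truncated to the smallest r
whose cumulative squared-singular-value fraction reaches the variance
threshold (default 0.99); the reduced coordinates are Y_r = U S_r.  Columns
are mean-centered first so "fraction of variance retained" means what it
says; ``center=False`` reproduces the raw-SVD variant.  Each component's
sign is fixed so its largest-magnitude loading is positive, removing the
SVD sign ambiguity for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._errors import DataError
from .gcn import EmbeddingMatrix

DEFAULT_VARIANCE_THRESHOLD = 0.99


@dataclass
class ReducedFeatures:
    """PCA scores with the retained-variance bookkeeping."""

    node_ids: list[str]
    values: np.ndarray          # p x r scores, columns by decreasing singular value
    r: int
    explained_fraction: float
    singular_values: np.ndarray  # full spectrum

    def row(self, node_id: str) -> np.ndarray:
        try:
            return self.values[self.node_ids.index(node_id)]
        except ValueError:
            raise DataError(f"node {node_id!r} has no reduced feature row") from None


class VariancePCA(BaseEstimator, TransformerMixin):
    """PCA via SVD keeping enough components for a target variance fraction.

    Parameters
    ----------
    variance_threshold : float in (0, 1]
        Smallest r with cumulative squared-singular-value fraction >= this
        is retained.
    center : bool
        Subtract column means before the SVD (default).  Without centering
        the decomposition is a plain truncated SVD of the raw matrix.

    Attributes
    ----------
    n_components_ : retained component count r
    explained_fraction_ : achieved cumulative fraction (>= threshold)
    singular_values_ : full singular spectrum
    components_ : r x n right singular vectors (rows)
    mean_ : column means subtracted (zeros when ``center=False``)
    """

    def __init__(self, variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                 center: bool = True):
        self.variance_threshold = variance_threshold
        self.center = center

    def fit(self, X, y=None):
        self._fit(X)
        return self

    def _fit(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise DataError("PCA input must be 2-D with at least 2 rows")
        if not (0.0 < self.variance_threshold <= 1.0):
            raise DataError(
                f"variance_threshold must be in (0, 1], got {self.variance_threshold}"
            )
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float(np.sum(s**2))
        if total == 0.0:
            raise DataError("matrix has zero total variance (constant rows)")
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        U = U * flip
        Vt = Vt * flip[:, None]
        frac = np.cumsum(s**2) / total
        r = int(np.searchsorted(frac, self.variance_threshold - 1e-12) + 1)
        r = min(r, len(s))
        self.singular_values_ = s
        self.n_components_ = r
        self.explained_fraction_ = float(frac[r - 1])
        self.components_ = Vt[:r]
        return U[:, :r] * s[:r]

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the scores Y_r = U S_r."""
        return self._fit(X)

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise DataError("VariancePCA is not fitted")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Y) -> np.ndarray:
        return np.asarray(Y, float) @ self.components_ + self.mean_


def pca_reduce(
    emb: EmbeddingMatrix,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    center: bool = True,
) -> ReducedFeatures:
    """Reduce an embedding matrix, keeping ``variance_threshold`` of the
    (squared-singular-value) variance."""
    pca = VariancePCA(variance_threshold=variance_threshold, center=center)
    Y = pca.fit_transform(emb.values)
    return ReducedFeatures(
        node_ids=list(emb.node_ids),
        values=Y,
        r=pca.n_components_,
        explained_fraction=pca.explained_fraction_,
        singular_values=pca.singular_values_,
    )


def write_reduced(rf: ReducedFeatures, tsv_path, sidecar_path=None) -> None:
    """TSV of scores plus a JSON sidecar with the spectrum and the achieved
    explained fraction."""
    cols = [f"pc{i+1}" for i in range(rf.r)]
    pd.DataFrame(rf.values, index=rf.node_ids, columns=cols).rename_axis(
        "node_id"
    ).to_csv(tsv_path, sep="\t", float_format="%.12g")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "r": rf.r,
                    "explained_fraction": rf.explained_fraction,
                    "singular_values": [float(s) for s in rf.singular_values],
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def read_reduced(tsv_path, sidecar_path=None) -> ReducedFeatures:
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    r = values.shape[1]
    explained, spectrum = float("nan"), np.array([])
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        r = int(meta["r"])
        explained = float(meta["explained_fraction"])
        spectrum = np.asarray(meta["singular_values"], dtype=float)
    return ReducedFeatures(
        [str(i) for i in df.index], values, r, explained, spectrum
    )
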