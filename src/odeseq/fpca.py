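"""Functional principal component analysis on a common evaluation grid.

Curves are centered by their mean function and the quadrature-weighted
sample covariance operator is eigendecomposed; eigenfunctions are
orthonormal under the same quadrature and scores are quadrature inner
products of centered curves with the eigenfunctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import simpson_weights

__all__ = ["FpcaModel", "FeatureMatrix", "quad_weights", "fit_fpca", "score_features"]


def quad_weights(t: np.ndarray) -> np.ndarray:
    """Quadrature weights for an equispaced grid: Simpson when the point
    count is odd, trapezoid otherwise."""
    t = np.asarray(t, dtype=float)
    if t.size % 2 == 1:
        return simpson_weights(t.size, t[0], t[-1])
    h = (t[-1] - t[0]) / (t.size - 1)
    w = np.full(t.size, h)
    w[0] = w[-1] = h / 2.0
    return w


@dataclass
class FpcaModel:
    t: np.ndarray
    weights: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray  # (len(t), n_components)
    eigenvalues: np.ndarray  # descending, >= 0
    var_explained: np.ndarray  # cumulative fraction per component

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[1]

    def scores(self, curves: np.ndarray) -> np.ndarray:
        """Project curves (n, len(t)) onto the eigenfunctions by quadrature."""
        curves = np.atleast_2d(np.asarray(curves, dtype=float))
        if curves.shape[1] != self.t.size:
            raise ValueError(
                f"curves on a grid of {curves.shape[1]} points; model grid "
                f"has {self.t.size}"
            )
        centered = curves - self.mean
        return (centered * self.weights) @ self.eigenfunctions

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.mean + scores @ self.eigenfunctions.T


def _fix_signs(B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: integral >= 0, tie-broken by the first
    non-negligible grid value being positive."""
    B = B.copy()
    for j in range(B.shape[1]):
        integral = float(w @ B[:, j])
        if abs(integral) > 1e-10:
            if integral < 0:
                B[:, j] *= -1.0
            continue
        nz = np.nonzero(np.abs(B[:, j]) > 1e-10)[0]
        if nz.size and B[nz[0], j] < 0:
            B[:, j] *= -1.0
    return B


def fit_fpca(
    curves: np.ndarray,
    t: np.ndarray,
    n_components: int | None = None,
    var_target: float = 0.9,
    max_components: int = 10,
) -> FpcaModel:
    """Fit FPCA to ``curves`` (n_samples x n_grid) evaluated at ``t``.

    When ``n_components`` is None, the smallest number of components
    explaining at least ``var_target`` of the variance is kept, capped at
    ``max_components``.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    t = np.asarray(t, dtype=float)
    n, m = curves.shape
    if n < 2:
        raise ValueError(f"FPCA needs at least 2 curves, got {n}")
    if m != t.size:
        raise ValueError("curve grid length does not match t")
    w = quad_weights(t)
    mean = curves.mean(axis=0)
    centered = curves - mean
    # SVD of the weighted data matrix: right singular vectors of
    # Xc * sqrt(w) / sqrt(n-1) are eigenvectors of the discretized operator.
    sw = np.sqrt(w)
    _, s, Vt = np.linalg.svd(centered * sw / np.sqrt(n - 1), full_matrices=False)
    eigenvalues = s**2
    eigenfunctions = (Vt / sw).T  # orthonormal under quadrature

    total = float(eigenvalues.sum())
    frac = np.cumsum(eigenvalues) / total if total > 0 else np.ones_like(eigenvalues)
    if n_components is None:
        n_components = int(np.searchsorted(frac, var_target) + 1)
        n_components = min(n_components, max_components, eigenvalues.size)
    if n_components < 1 or n_components > eigenvalues.size:
        raise ValueError(
            f"n_components must be in [1, {eigenvalues.size}], got {n_components}"
        )
    B = _fix_signs(eigenfunctions[:, :n_components], w)
    return FpcaModel(
        t=t,
        weights=w,
        mean=mean,
        eigenfunctions=B,
        eigenvalues=eigenvalues[:n_components],
        var_explained=frac[:n_components],
    )


@dataclass
class FeatureMatrix:
    """Interleaved FPCA scores of the two operator weight functions.

    Column order follows the pattern w0_pc1, w1_pc1, w0_pc2, w1_pc2, ...
    """

    Z: np.ndarray
    sample_ids: list[str]
    columns: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.sample_ids, columns=self.columns)


def score_features(
    model_w0: FpcaModel,
    model_w1: FpcaModel,
    w0_curves: np.ndarray,
    w1_curves: np.ndarray,
    sample_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble the per-sample feature matrix from both coefficient curves."""
    w0_curves = np.atleast_2d(np.asarray(w0_curves, dtype=float))
    w1_curves = np.atleast_2d(np.asarray(w1_curves, dtype=float))
    if w0_curves.shape[0] != w1_curves.shape[0]:
        raise ValueError("w0 and w1 curve collections differ in sample count")
    z0 = model_w0.scores(w0_curves)
    z1 = model_w1.scores(w1_curves)
    n = w0_curves.shape[0]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for j in range(max(z0.shape[1], z1.shape[1])):
        if j < z0.shape[1]:
            cols.append(z0[:, j])
            names.append(f"w0_pc{j + 1}")
        if j < z1.shape[1]:
            cols.append(z1[:, j])
            names.append(f"w1_pc{j + 1}")
    Z = np.column_stack(cols)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if len(sample_ids) != n:
        raise ValueError("sample_ids length mismatch")
    return FeatureMatrix(Z=Z, sample_ids=list(sample_ids), columns=names)
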