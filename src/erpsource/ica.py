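"""FastICA blind source separation of multi-channel ERP data.

Components are estimated by the fixed-point FastICA algorithm (symmetric
decorrelation, tanh contrast by default) on PCA-whitened data.  ICA is
identifiable only up to permutation, sign and scale, so each component's
scalp map is reported unit-normalized with the sign fixed so that its
largest-magnitude electrode is positive; the absolute magnitude lives in the
source timecourse.  Explained-variance fractions order the components and
drive retention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "WhiteningTransform",
    "Decomposition",
    "ScalpICA",
    "whiten",
    "fastica",
    "normalize_component",
    "select_components",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WhiteningTransform:
    """Mean removal + linear map giving identity covariance."""

    mean: np.ndarray  # (channels,)
    matrix: np.ndarray  # (retained, channels)
    n_retained: int

    def apply(self, data: np.ndarray) -> np.ndarray:
        return self.matrix @ (data - self.mean[:, None])


def whiten(data: np.ndarray, rank_tol: float = 1e-10) -> tuple[np.ndarray, WhiteningTransform]:
    """PCA-whiten channels x samples data.

    Rank-deficient inputs are reduced to their effective dimensionality
    (eigenvalues above ``rank_tol`` times the largest) with a logged warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 channels of 2-D data")
    n_channels, n_samples = data.shape
    if n_samples <= n_channels:
        raise ValueError(f"need more samples ({n_samples}) than channels ({n_channels})")
    mean = data.mean(axis=1)
    centered = data - mean[:, None]
    cov = centered @ centered.T / (n_samples - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > rank_tol * eigvals[0]
    n_retained = int(keep.sum())
    if n_retained < n_channels:
        logger.warning("whiten: rank-deficient data, retaining %d of %d dimensions", n_retained, n_channels)
    matrix = eigvecs[:, :n_retained].T / np.sqrt(eigvals[:n_retained])[:, None]
    transform = WhiteningTransform(mean=mean, matrix=matrix, n_retained=n_retained)
    return transform.apply(data), transform


@dataclass(frozen=True)
class Decomposition:
    """ICA result: unmixing/mixing matrices, sources and scalp maps.

    ``mixing @ sources + mean`` reconstructs the input on the retained
    subspace; scalp map i is column i of the mixing matrix, unit-normalized
    with a positive largest-magnitude entry.
    """

    unmixing: np.ndarray  # (components, channels)
    mixing: np.ndarray  # (channels, components)
    sources: np.ndarray  # (components, samples)
    scalp_maps: np.ndarray  # (channels, components), unit columns
    explained_variance: np.ndarray  # (components,) fractions in [0, 1]
    mean: np.ndarray  # (channels,)
    converged: bool
    n_iter: int
    channels: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.sources + self.mean[:, None]


class ScalpICA(BaseEstimator, TransformerMixin):
    """FastICA over channels x samples EEG with scalp-map bookkeeping.

    Thin estimator around :class:`sklearn.decomposition.FastICA` (fixed-point
    iteration, symmetric or deflation decorrelation) adding automatic rank
    detection, per-component explained variance, unit-norm sign-fixed scalp
    maps and an explicit convergence flag.  Data orientation follows the EEG
    convention (channels x samples).
    """

    def __init__(
        self,
        n_components: int | None = None,
        contrast: str = "logcosh",
        tol: float = 1e-6,
        max_iter: int = 500,
        algorithm: str = "parallel",
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.contrast = contrast
        self.tol = tol
        self.max_iter = max_iter
        self.algorithm = algorithm
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] <= X.shape[0]:
            raise ValueError("expected channels x samples data with samples > channels")
        n_components = self.n_components
        if n_components is None:
            _, wt = whiten(X)
            n_components = wt.n_retained
        model = FastICA(
            n_components=n_components,
            algorithm=self.algorithm,
            fun=self.contrast,
            tol=self.tol,
            max_iter=self.max_iter,
            whiten="unit-variance",
            random_state=self.random_state,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = model.fit_transform(X.T).T  # (components, samples)
        self.converged_ = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        self.n_iter_ = int(model.n_iter_)

        mixing = model.mixing_  # (channels, components)
        unmixing = model.components_
        mean = model.mean_

        # Fix the scale/sign ambiguity: unit-norm maps, dominant entry positive.
        norms = np.linalg.norm(mixing, axis=0)
        if np.any(norms == 0):
            raise ValueError("degenerate all-zero mixing column")
        signs = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(mixing.shape[1])])
        signs[signs == 0] = 1.0
        scale = norms * signs
        mixing = mixing / scale
        sources = sources * scale[:, None]
        unmixing = unmixing * scale[:, None]

        total_var = float(((X - X.mean(axis=1, keepdims=True)) ** 2).sum())
        explained = np.empty(mixing.shape[1])
        for i in range(mixing.shape[1]):
            contribution = np.outer(mixing[:, i], sources[i])
            explained[i] = ((contribution - contribution.mean(axis=1, keepdims=True)) ** 2).sum()
        explained = explained / total_var if total_var > 0 else explained * 0.0

        self.mixing_ = mixing
        self.unmixing_ = unmixing
        self.mean_ = mean
        self.sources_ = sources
        self.scalp_maps_ = mixing.copy()
        self.explained_variance_ratio_ = explained
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.unmixing_ @ (X - self.mean_[:, None])

    def to_decomposition(self, channels: tuple[str, ...] = ()) -> Decomposition:
        return Decomposition(
            unmixing=self.unmixing_,
            mixing=self.mixing_,
            sources=self.sources_,
            scalp_maps=self.scalp_maps_,
            explained_variance=self.explained_variance_ratio_,
            mean=self.mean_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            channels=tuple(channels),
        )


def fastica(
    data: np.ndarray,
    n_components: int | None = None,
    contrast: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = 0,
    algorithm: str = "parallel",
    channels: tuple[str, ...] = (),
) -> Decomposition:
    """Fixed-point ICA of channels x samples data; see :class:`ScalpICA`."""
    est = ScalpICA(
        n_components=n_components,
        contrast=contrast,
        tol=tol,
        max_iter=max_iter,
        algorithm=algorithm,
        random_state=seed,
    )
    est.fit(data)
    if not est.converged_:
        logger.warning("fastica: not converged after %d iterations", est.n_iter_)
    return est.to_decomposition(channels)


def normalize_component(decomposition: Decomposition, i: int) -> Decomposition:
    """Re-apply the unit-norm/positive-sign convention to component ``i``.

    The map (x) source outer product is invariant; applying twice equals
    applying once.
    """
    mixing = decomposition.mixing.copy()
    sources = decomposition.sources.copy()
    unmixing = decomposition.unmixing.copy()
    maps = decomposition.scalp_maps.copy()
    column = mixing[:, i]
    norm = float(np.linalg.norm(column))
    if norm == 0:
        raise ValueError(f"component {i} has an all-zero scalp map")
    sign = float(np.sign(column[np.abs(column).argmax()])) or 1.0
    factor = norm * sign
    mixing[:, i] = column / factor
    maps[:, i] = mixing[:, i]
    sources[i] = sources[i] * factor
    unmixing[i] = unmixing[i] * factor
    return replace(
        decomposition, mixing=mixing, sources=sources, unmixing=unmixing, scalp_maps=maps
    )


def select_components(
    decomposition: Decomposition, min_variance_fraction: float = 0.01
) -> list[int]:
    """Component indices sorted by explained variance, low ones dropped.

    The default 1% retention threshold reflects that a handful of spike-like
    components dominate schedule-driven data.  Ordering is stable for ties.
    """
    if not 0.0 <= min_variance_fraction <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {min_variance_fraction}")
    ev = decomposition.explained_variance
    order = sorted(range(len(ev)), key=lambda i: (-ev[i], i))
    return [i for i in order if ev[i] >= min_variance_fraction]
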