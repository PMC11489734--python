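"""Conformational-symmetry metrics from subIC projections.

The minimum-over-rolls distance (Algorithm-1 style) makes two asymmetric
conformations that differ only in *which* subunit deviates compare as equal;
classical MDS on that distance matrix embeds conformations modulo the cyclic
symmetry.  Per-frame subIC standard deviation and inter-subunit coupling
quantify how symmetric the sampled conformations are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .symtica import ProjectionResult

__all__ = [
    "sym_distance",
    "pairwise_sym_distances",
    "SymmetryAwareMDS",
    "symmetry_aware_mds",
    "symmetry_metrics",
    "SymmetryMetrics",
]


def _as_blocks(s, n_fold: int) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim == 1:
        if s.size % n_fold:
            raise ValueError("length not divisible by n_fold")
        s = s.reshape(n_fold, -1)
    if s.shape[0] != n_fold:
        raise ValueError(f"expected {n_fold} blocks, got {s.shape[0]}")
    return s


def sym_distance(s_i, s_j, n_fold: int = 5) -> float:
    """Minimum Euclidean distance over all cyclic rolls of the second sample.

    Inputs are subIC tuples, either flat (n_fold·d,) grouped by subunit or
    already shaped (n_fold, d).  The result is a pseudometric: it vanishes on
    roll-equivalent pairs, is symmetric, and obeys the triangle inequality.
    """
    a = _as_blocks(s_i, n_fold)
    b = _as_blocks(s_j, n_fold)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    best = np.inf
    for r in range(n_fold):
        best = min(best, float(np.linalg.norm(a - np.roll(b, r, axis=0))))
    return best


def pairwise_sym_distances(samples: np.ndarray, n_fold: int = 5) -> np.ndarray:
    """All-pairs minimum-over-rolls distance matrix (vectorized over rolls)."""
    x = np.asarray(samples, dtype=float)
    n = x.shape[0]
    blocks = x.reshape(n, n_fold, -1)
    best = np.full((n, n), np.inf)
    for r in range(n_fold):
        rolled = np.roll(blocks, r, axis=1).reshape(n, -1)
        d2 = (
            np.sum(x**2, axis=1)[:, None]
            + np.sum(rolled**2, axis=1)[None, :]
            - 2.0 * x @ rolled.T
        )
        np.minimum(best, np.sqrt(np.maximum(d2, 0.0)), out=best)
    best = 0.5 * (best + best.T)
    np.fill_diagonal(best, 0.0)
    return best


class SymmetryAwareMDS(BaseEstimator):
    """Classical MDS on the minimum-over-rolls distance matrix.

    The double-centered Gram matrix of squared distances is eigendecomposed;
    negative eigenvalues (the metric need not be Euclidean) are clamped to
    zero.  For more than ``max_exact`` samples a seeded landmark subset is
    embedded exactly and the rest placed by Nyström triangulation.

    Attributes
    ----------
    embedding_ : (n, m) coordinates.
    eigenvalues_ : spectrum of the centered Gram matrix (before clamping).
    stress_ : relative distance-reconstruction error
        sqrt(Σ(d_emb − d)² / Σ d²).
    """

    def __init__(self, n_components: int = 2, n_fold: int = 5,
                 max_exact: int = 5000, landmark_seed: int = 0):
        self.n_components = n_components
        self.n_fold = n_fold
        self.max_exact = max_exact
        self.landmark_seed = landmark_seed

    def fit_transform(self, samples, y=None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(samples, dtype=float))
        n = x.shape[0]
        if n < self.n_components + 1:
            raise ValueError("need at least n_components + 1 samples")
        if n <= self.max_exact:
            d = pairwise_sym_distances(x, self.n_fold)
            coords, w = self._classical_mds(d)
            self.eigenvalues_ = w
            self.embedding_ = coords
            self.stress_ = self._stress(d, coords)
            return coords
        # landmark MDS
        rng = np.random.default_rng(self.landmark_seed)
        lm = np.sort(rng.choice(n, size=self.max_exact, replace=False))
        d_lm = pairwise_sym_distances(x[lm], self.n_fold)
        coords_lm, w = self._classical_mds(d_lm)
        self.eigenvalues_ = w
        self.landmarks_ = lm
        # Nyström: place every sample from its distances to the landmarks
        blocks_lm = x[lm].reshape(len(lm), self.n_fold, -1)
        d_all = np.full((n, len(lm)), np.inf)
        for r in range(self.n_fold):
            rolled = np.roll(blocks_lm, r, axis=1).reshape(len(lm), -1)
            d2 = (
                np.sum(x**2, axis=1)[:, None]
                + np.sum(rolled**2, axis=1)[None, :]
                - 2.0 * x @ rolled.T
            )
            np.minimum(d_all, np.sqrt(np.maximum(d2, 0.0)), out=d_all)
        mean_sq = (d_lm**2).mean(axis=0)
        pinv = np.linalg.pinv(coords_lm[:, : self.n_components])
        coords = -0.5 * (d_all**2 - mean_sq[None, :]) @ pinv.T
        self.embedding_ = coords
        self.stress_ = self._stress(d_lm, coords[lm])
        return coords

    fit = fit_transform

    def _classical_mds(self, d: np.ndarray):
        n = d.shape[0]
        if np.allclose(d, 0.0):
            warnings.warn("all samples are roll-equivalent: zero embedding",
                          stacklevel=2)
            return np.zeros((n, self.n_components)), np.zeros(n)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        w, v = scipy.linalg.eigh(0.5 * (b + b.T))
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        wc = np.clip(w[: self.n_components], 0.0, None)
        coords = v[:, : self.n_components] * np.sqrt(wc)
        return coords, w

    @staticmethod
    def _stress(d: np.ndarray, coords: np.ndarray) -> float:
        d_emb = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        denom = np.sum(d**2)
        if denom == 0:
            return 0.0
        return float(np.sqrt(np.sum((d_emb - d) ** 2) / denom))


def symmetry_aware_mds(samples, n_components: int = 2, n_fold: int = 5,
                       **kwargs) -> SymmetryAwareMDS:
    """Fit a :class:`SymmetryAwareMDS` and return the fitted estimator."""
    est = SymmetryAwareMDS(n_components=n_components, n_fold=n_fold, **kwargs)
    est.fit_transform(samples)
    return est


@dataclass
class SymmetryMetrics:
    """Per-frame symmetry deviation and inter-subunit coupling."""

    deviation: np.ndarray  # (frames,) std of the component across subunits
    coupling_matrix: np.ndarray  # (n_fold, n_fold) pairwise Pearson r
    coupling: float  # mean over unordered subunit pairs
    undefined_pairs: int  # pairs with zero-variance series (flagged NaN)


def symmetry_metrics(subics, component: int = 0) -> SymmetryMetrics:
    """Symmetry summary of one subIC component.

    ``deviation[t]`` is the standard deviation of the component across the
    n_fold subunits in frame ``t`` (zero for a perfectly symmetric frame).
    ``coupling`` is the mean pairwise Pearson correlation between the
    per-subunit time series; the full pairwise matrix is also returned.
    Constant series yield NaN entries and are counted in
    ``undefined_pairs``.
    """
    if isinstance(subics, ProjectionResult):
        subics = subics.subics
    s = np.asarray(subics, dtype=float)
    if s.ndim != 3:
        raise ValueError("expected (frames, n_fold, k) subIC array")
    n_fold = s.shape[1]
    if n_fold < 2:
        raise ValueError("need at least two subunits")
    series = s[:, :, component]  # (frames, n_fold)
    deviation = series.std(axis=1)
    sd = series.std(axis=0)
    corr = np.full((n_fold, n_fold), np.nan)
    defined = sd > 0
    if defined.any():
        with np.errstate(invalid="ignore"):
            full = np.corrcoef(series.T)
        corr[np.ix_(defined, defined)] = full[np.ix_(defined, defined)]
    np.fill_diagonal(corr, 1.0)
    iu = np.triu_indices(n_fold, k=1)
    vals = corr[iu]
    n_undef = int(np.isnan(vals).sum())
    coupling = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return SymmetryMetrics(
        deviation=deviation, coupling_matrix=corr, coupling=coupling,
        undefined_pairs=n_undef,
    )
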