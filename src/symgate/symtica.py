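"""Symmetry-adapted time-lagged independent component analysis (SymTICA).

For a Cn-symmetric assembly whose features are arranged in ``n_fold`` blocks,
the instantaneous and time-lagged covariance matrices are block-circulant:
they are built from a diagonal block ``C_d`` and off-diagonal blocks ``C_o1``
(neighbouring subsystems), ``C_o2`` (next-nearest), and so on.  Restricting
the Koopman eigenproblem to the permutation-symmetric subspace (eigenvector
ν repeated over all blocks) collapses the n·b-dimensional problem to a
b-dimensional one on the *summed* blocks:

    S0 = Σ_o C0^(o),     Sτ = Σ_o Cτ^(o),

and the symmetric generalized eigenproblem ``Sτ ν = λ S0 ν`` — equivalent to
the summed-Koopman form ``K_sum ν = λ ν`` because restriction to the
symmetric subspace commutes with whitening.  Projections of single blocks on
ν give per-subunit *subICs*; their sum over blocks gives the global,
roll-invariant *ICs*.

``TICA`` is the conventional (symmetry-agnostic) estimator with identical
numerical conventions; it serves as the reference the symmetric solution can
be checked against on fully augmented data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .features import BlockFeatureSet, roll_blocks

__all__ = [
    "BlockCovariances",
    "ProjectionResult",
    "SymTICA",
    "TICA",
    "fit_symtica",
    "fit_standard_tica",
]


@dataclass
class BlockCovariances:
    """Instantaneous and time-lagged b×b covariance blocks by subunit offset.

    ``c0[o]`` is the covariance between a block and the block ``o`` positions
    further around the ring, averaged over all block positions; ``ct[o]`` is
    the same at lag ``lag`` frames.  Offsets ``o`` and ``n_fold - o`` are
    mutual transposes of each other's instantaneous blocks.
    """

    c0: dict
    ct: dict
    mean: np.ndarray  # length-b block mean
    lag: int  # frames
    n_fold: int
    n_samples_c0: int
    n_samples_ct: int

    @property
    def c0_d(self) -> np.ndarray:
        return self.c0[0]

    @property
    def c0_o1(self) -> np.ndarray:
        return self.c0[1]

    @property
    def c0_o2(self) -> np.ndarray:
        return self.c0.get(2)

    def summed(self) -> tuple[np.ndarray, np.ndarray]:
        """(S0, Sτ): blocks summed over all offsets, S0 symmetrized."""
        s0 = sum(self.c0.values())
        st = sum(self.ct.values())
        return 0.5 * (s0 + s0.T), st

    def assemble_full(self, which: str = "c0") -> np.ndarray:
        """The full n·b × n·b block-circulant matrix (for checks/plots)."""
        blocks = self.c0 if which == "c0" else self.ct
        n, b = self.n_fold, len(self.mean)
        full = np.zeros((n * b, n * b))
        for i in range(n):
            for j in range(n):
                full[i * b : (i + 1) * b, j * b : (j + 1) * b] = blocks[(j - i) % n]
        return full


@dataclass
class ProjectionResult:
    """SubIC / IC projections of one trajectory.

    ``subics`` has shape (frames, n_fold, k); ``ics`` is their exact sum over
    the subunit axis.
    """

    subics: np.ndarray

    @property
    def ics(self) -> np.ndarray:
        return self.subics.sum(axis=1)

    @property
    def n_fold(self) -> int:
        return self.subics.shape[1]


def _as_array_list(data, n_fold=None):
    if isinstance(data, BlockFeatureSet):
        return data.arrays(), data.n_fold
    if isinstance(data, np.ndarray):
        return [np.atleast_2d(data)], n_fold
    return [np.atleast_2d(np.asarray(x, dtype=float)) for x in data], n_fold


def estimate_block_covariances(
    data, lag: int, n_fold: int | None = None
) -> BlockCovariances:
    """Accumulate block covariances over all trajectories and block positions.

    Covariance pairs are taken from every frame ``t`` with ``t + lag`` inside
    the same trajectory (no sliding-window weighting).  Averaging over the
    block position is mathematically identical to averaging over the
    block-rolled pseudo-trajectories, so un-augmented input gives the same
    result as explicitly augmented input.
    """
    arrays, n_fold = _as_array_list(data, n_fold)
    if n_fold is None:
        raise ValueError("n_fold required for raw array input")
    n_feat = arrays[0].shape[1]
    if n_feat % n_fold:
        raise ValueError("feature count not divisible by n_fold")
    b = n_feat // n_fold

    # pooled block mean (equal over block positions by construction)
    total = np.zeros(b)
    n_frames = 0
    for x in arrays:
        total += x.reshape(-1, n_fold, b).sum(axis=(0, 1))
        n_frames += x.shape[0]
    if n_frames == 0:
        raise ValueError("no frames")
    mean = total / (n_frames * n_fold)

    c0 = {o: np.zeros((b, b)) for o in range(n_fold)}
    ct = {o: np.zeros((b, b)) for o in range(n_fold)}
    n_ct = 0
    for x in arrays:
        if x.shape[0] <= lag:
            raise ValueError(
                f"trajectory of {x.shape[0]} frames is not longer than lag={lag}"
            )
        xb = x.reshape(-1, n_fold, b) - mean
        for o in range(n_fold):
            xro = np.roll(xb, -o, axis=1)
            c0[o] += np.einsum("tsa,tsb->ab", xb, xro)
            ct[o] += np.einsum("tsa,tsb->ab", xb[:-lag], xro[lag:])
        n_ct += x.shape[0] - lag
    for o in range(n_fold):
        c0[o] /= n_frames * n_fold
        ct[o] /= n_ct * n_fold
    return BlockCovariances(
        c0=c0, ct=ct, mean=mean, lag=lag, n_fold=n_fold,
        n_samples_c0=n_frames, n_samples_ct=n_ct,
    )


def _solve_reversible_eig(c0, ct, reg, n_components):
    """Solve Cτ ν = λ C0 ν with symmetrized Cτ and rank-regularized C0.

    Returns (eigenvalues desc, eigenvectors as columns, rank kept).
    Eigenvectors are normalized to unit length under the C0 metric and
    sign-fixed so each column's largest-magnitude entry is positive.
    """
    zero_var = np.flatnonzero(np.diag(c0) <= 0)
    if len(zero_var):
        raise ValueError(
            f"zero-variance feature columns after mean removal: {zero_var.tolist()}"
        )
    ct = 0.5 * (ct + ct.T)  # reversibility enforced numerically
    w, u = scipy.linalg.eigh(c0)
    keep = w > reg * w.max()
    rank = int(keep.sum())
    if rank == 0:
        raise ValueError("C0 numerically singular beyond regularization")
    whiten = u[:, keep] / np.sqrt(w[keep])
    m = whiten.T @ ct @ whiten
    lam, y = scipy.linalg.eigh(0.5 * (m + m.T))
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = whiten @ y[:, order]
    if n_components is not None:
        lam = lam[:n_components]
        vec = vec[:, : n_components]
    # fix sign: largest-|entry| positive
    flip = vec[np.abs(vec).argmax(axis=0), np.arange(vec.shape[1])] < 0
    vec[:, flip] *= -1
    return lam, vec, rank


class SymTICA(TransformerMixin, BaseEstimator):
    """Symmetry-adapted TICA estimator (scikit-learn style).

    Parameters
    ----------
    lag : int
        Lag time in frames.
    n_components : int
        Number of eigenpairs to keep.
    n_fold : int, optional
        Cyclic symmetry order; inferred from a BlockFeatureSet input.
    reg : float
        Relative eigenvalue floor for the rank regularization of S0.

    Attributes
    ----------
    eigenvalues_ : (k,) autocorrelation eigenvalues, descending.
    components_ : (k, b) block eigenvectors ν (rows), C0-metric normalized.
    mean_ : (b,) pooled block mean removed before projection.
    covariances_ : the fitted BlockCovariances.
    rank_ : retained rank of S0 after regularization.
    """

    def __init__(self, lag: int = 1, n_components: int = 6,
                 n_fold: int | None = None, reg: float = 1e-10):
        self.lag = lag
        self.n_components = n_components
        self.n_fold = n_fold
        self.reg = reg

    def fit(self, X, y=None):
        cov = (
            X
            if isinstance(X, BlockCovariances)
            else estimate_block_covariances(X, lag=self.lag, n_fold=self.n_fold)
        )
        s0, st = cov.summed()
        lam, vec, rank = _solve_reversible_eig(s0, st, self.reg, self.n_components)
        self.covariances_ = cov
        self.n_fold_ = cov.n_fold
        self.b_ = len(cov.mean)
        self.eigenvalues_ = lam
        self.components_ = vec.T
        self.mean_ = cov.mean
        self.rank_ = rank
        self.lag_ = cov.lag
        return self

    def _check_fitted(self):
        if not hasattr(self, "components_"):
            raise RuntimeError("SymTICA instance is not fitted")

    def timescales(self, frame_interval: float = 1.0) -> np.ndarray:
        """Implied timescales −τ/ln λ in units of ``frame_interval``."""
        self._check_fitted()
        lam = self.eigenvalues_
        out = np.full(lam.shape, np.nan)
        ok = (lam > 0) & (lam < 1)
        out[ok] = -self.lag_ * frame_interval / np.log(lam[ok])
        return out

    def project(self, X) -> ProjectionResult | list:
        """SubIC projection; a list input returns one result per trajectory."""
        self._check_fitted()
        arrays, _ = _as_array_list(X, self.n_fold_)
        results = []
        for x in arrays:
            if x.shape[1] != self.n_fold_ * self.b_:
                raise ValueError(
                    f"expected {self.n_fold_ * self.b_} features, got {x.shape[1]}"
                )
            xb = x.reshape(-1, self.n_fold_, self.b_) - self.mean_
            subics = np.einsum("tsb,kb->tsk", xb, self.components_)
            results.append(ProjectionResult(subics=subics))
        if isinstance(X, np.ndarray):
            return results[0]
        return results

    def transform(self, X) -> np.ndarray:
        """Global ICs (frames × k) of a single feature matrix."""
        if isinstance(X, (BlockFeatureSet, list)):
            return [p.ics for p in self.project(X)]
        return self.project(X).ics


class TICA(TransformerMixin, BaseEstimator):
    """Conventional reversible TICA with the same numerical conventions.

    Serves as the symmetry-agnostic reference: on fully augmented block data
    its permutation-invariant eigenpairs coincide with SymTICA's.
    """

    def __init__(self, lag: int = 1, n_components: int | None = None,
                 reg: float = 1e-10):
        self.lag = lag
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y=None):
        arrays, _ = _as_array_list(X)
        n = arrays[0].shape[1]
        total = np.zeros(n)
        n_frames = 0
        for x in arrays:
            total += x.sum(axis=0)
            n_frames += x.shape[0]
        mean = total / n_frames
        c0 = np.zeros((n, n))
        ct = np.zeros((n, n))
        n_ct = 0
        for x in arrays:
            if x.shape[0] <= self.lag:
                raise ValueError("trajectory not longer than lag")
            xc = x - mean
            c0 += xc.T @ xc
            ct += xc[: -self.lag].T @ xc[self.lag :]
            n_ct += x.shape[0] - self.lag
        c0 /= n_frames
        ct /= n_ct
        lam, vec, rank = _solve_reversible_eig(
            0.5 * (c0 + c0.T), ct, self.reg, self.n_components
        )
        self.eigenvalues_ = lam
        self.components_ = vec.T
        self.mean_ = mean
        self.rank_ = rank
        self.lag_ = self.lag
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, list):
            return [(np.atleast_2d(x) - self.mean_) @ self.components_.T for x in X]
        return (np.atleast_2d(X) - self.mean_) @ self.components_.T

    def symmetric_subspace_eigenpairs(self, n_fold: int, tol: float = 1e-6):
        """Eigenpairs whose eigenvectors are invariant under block rolls.

        Returns (eigenvalues, eigenvectors as columns) restricted to the
        permutation-symmetric subspace.
        """
        lam, vecs = [], []
        for i, ev in enumerate(self.eigenvalues_):
            v = self.components_[i]
            if np.linalg.norm(roll_blocks(v[None], n_fold, 1)[0] - v) <= tol * (
                np.linalg.norm(v) + 1e-300
            ):
                lam.append(ev)
                vecs.append(v)
        return np.array(lam), np.array(vecs).T if vecs else np.empty((0, 0))


def fit_symtica(data, lag: int, n_components: int = 6, reg: float = 1e-10,
                n_fold: int | None = None) -> SymTICA:
    """Functional wrapper over :class:`SymTICA`."""
    return SymTICA(lag=lag, n_components=n_components, n_fold=n_fold, reg=reg).fit(data)


def fit_standard_tica(data, lag: int, n_components: int | None = None,
                      reg: float = 1e-10) -> TICA:
    """Functional wrapper over :class:`TICA`."""
    return TICA(lag=lag, n_components=n_components, reg=reg).fit(data)
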