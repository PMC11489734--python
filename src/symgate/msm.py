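"""Markov state modelling: microstates, estimation, validation, kinetics.

The workflow mirrors standard practice for conformational kinetics: k-means
microstates in IC space (VAMP-2 cross-validated), a reversible
maximum-likelihood MSM at a validated lag time (implied timescales,
Chapman-Kolmogorov test), PCCA+ coarse-graining into metastable macrostates,
and derived quantities — stationary free energies, mean first passage times,
Bayesian posterior uncertainty, and open-burst durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from ._markov import simulate_chain, stationary_distribution, validate_transition_matrix

__all__ = [
    "DiscreteTrajectorySet",
    "MarkovStateModel",
    "MacrostateModel",
    "cluster_microstates",
    "count_matrix",
    "estimate_msm",
    "implied_timescales",
    "ck_test",
    "score_vamp2",
    "pcca_coarse_grain",
    "free_energies",
    "mfpt",
    "sample_posterior",
    "open_burst_durations",
    "KB_KCAL_PER_MOL_K",
]

#: Boltzmann constant in kcal/(mol·K); k_B·T = 0.59616 kcal/mol at 300 K.
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass
class DiscreteTrajectorySet:
    """Microstate label sequences with their cluster centers."""

    sequences: list
    n_states: int
    centers: np.ndarray | None = None
    frame_interval: float = 1.0  # ns

    def __post_init__(self) -> None:
        self.sequences = [np.asarray(s, dtype=np.int64) for s in self.sequences]
        for s in self.sequences:
            if s.min() < 0 or s.max() >= self.n_states:
                raise ValueError("labels outside [0, n_states)")


def cluster_microstates(
    ic_data, k: int, seed: int, frame_interval: float = 1.0
) -> DiscreteTrajectorySet:
    """k-means microstates (k-means++ init, fixed seed) in IC space.

    ``ic_data``: (frames × d) array or list of such arrays (one per
    trajectory).  Deterministic for a fixed seed.
    """
    arrays = [np.atleast_2d(np.asarray(x, dtype=float))
              for x in (ic_data if isinstance(ic_data, list) else [ic_data])]
    lengths = [x.shape[0] for x in arrays]
    stacked = np.vstack(arrays)
    if stacked.size == 0:
        raise ValueError("empty input")
    if k > stacked.shape[0]:
        raise ValueError(f"k={k} exceeds {stacked.shape[0]} frames")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    labels = km.fit_predict(stacked)
    seqs = np.split(labels, np.cumsum(lengths)[:-1])
    return DiscreteTrajectorySet(
        sequences=list(seqs), n_states=k, centers=km.cluster_centers_,
        frame_interval=frame_interval,
    )


def count_matrix(sequences, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding transition counts at ``lag`` frames."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    seqs = [np.asarray(s, dtype=np.int64)
            for s in (sequences if isinstance(sequences, list) else [sequences])]
    if n_states is None:
        n_states = max(int(s.max()) for s in seqs) + 1
    c = np.zeros((n_states, n_states))
    for s in seqs:
        if len(s) > lag:
            np.add.at(c, (s[:-lag], s[lag:]), 1.0)
    return c


def largest_connected_set(c: np.ndarray) -> np.ndarray:
    """Largest strongly connected set of the count graph (most states;
    ties broken by total counts)."""
    adj = scipy.sparse.csr_matrix(c > 0)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        key = (len(members), c[np.ix_(members, members)].sum())
        if best_key is None or key > best_key:
            best, best_key = members, key
    return best


def reversible_mle(
    c: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood reversible transition matrix.

    Detailed-balance fixed-point iteration on the symmetric edge weights
    x_ij: ``x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)``.  Returns (T, π).
    """
    c = np.asarray(c, dtype=float)
    csym = c + c.T
    ci = c.sum(axis=1)
    if np.any(ci == 0):
        raise ValueError("count matrix has empty rows; restrict to connected set")
    x = csym / csym.sum()
    support = csym > 0
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
        x_new = np.where(support, csym / denom, 0.0)
        x_new /= x_new.sum()
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge: residual {delta:.3e} after "
            f"{max_iter} sweeps"
        )
    pi = x.sum(axis=1)
    t = x / pi[:, None]
    return t, pi


class MarkovStateModel(BaseEstimator):
    """Reversible maximum-likelihood MSM estimator (scikit-learn style).

    Parameters
    ----------
    lag : int
        Lag time in frames.
    reversible : bool
        Enforce detailed balance in the estimate.
    n_states : int, optional
        Total microstate count (inferred from data when omitted).

    Attributes
    ----------
    count_matrix_full_ : counts over all input states at ``lag``.
    active_set_ : indices of the largest strongly connected set.
    count_matrix_ : counts restricted to the active set.
    transition_matrix_ : row-stochastic T on the active set.
    stationary_distribution_ : π with πT = π.
    """

    def __init__(self, lag: int = 1, reversible: bool = True,
                 n_states: int | None = None):
        self.lag = lag
        self.reversible = reversible
        self.n_states = n_states

    def fit(self, sequences, y=None):
        c_full = count_matrix(sequences, self.lag, self.n_states)
        if c_full.sum() == 0:
            raise ValueError("no transitions at this lag")
        active = largest_connected_set(c_full)
        if len(active) < 2:
            raise ValueError("fewer than 2 states in the connected set")
        c = c_full[np.ix_(active, active)]
        if self.reversible:
            t, pi = reversible_mle(c)
        else:
            t = c / c.sum(axis=1, keepdims=True)
            pi = stationary_distribution(t)
        self.count_matrix_full_ = c_full
        self.active_set_ = active
        self.count_matrix_ = c
        self.transition_matrix_ = t
        self.stationary_distribution_ = pi
        return self

    @property
    def n_states_(self) -> int:
        return len(self.active_set_)

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real-part-sorted eigenvalues of T (real for reversible T)."""
        t = self.transition_matrix_
        if self.reversible:
            pi = self.stationary_distribution_
            s = np.sqrt(pi)
            lam = scipy.linalg.eigvalsh(0.5 * ((w := s[:, None] * t / s[None, :]) + w.T))
        else:
            lam = np.real(np.linalg.eigvals(t))
        lam = np.sort(lam)[::-1]
        return lam if k is None else lam[:k]

    def timescales(self, k: int | None = None, frame_interval: float = 1.0):
        """Implied timescales −τ/ln λ (NaN where λ ≤ 0, i.e. undefined)."""
        lam = self.eigenvalues(None if k is None else k + 1)[1:]
        out = np.full(lam.shape, np.nan)
        ok = (lam > 0) & (lam < 1)
        out[ok] = -self.lag * frame_interval / np.log(lam[ok])
        return out

    def map_to_active(self, sequences):
        """Relabel sequences onto active-set indices (-1 outside)."""
        mapping = np.full(self.count_matrix_full_.shape[0], -1, dtype=np.int64)
        mapping[self.active_set_] = np.arange(len(self.active_set_))
        seqs = sequences if isinstance(sequences, list) else [sequences]
        return [mapping[np.asarray(s, dtype=np.int64)] for s in seqs]


def estimate_msm(
    dtrajs, lag, reversible: bool = True, lag_in_frames: bool = True
) -> MarkovStateModel:
    """Estimate an MSM from a DiscreteTrajectorySet or raw label sequences.

    With ``lag_in_frames=False``, ``lag`` is interpreted in the trajectory
    time unit (ns) and must be a multiple of the frame interval.
    """
    if isinstance(dtrajs, DiscreteTrajectorySet):
        seqs, n_states = dtrajs.sequences, dtrajs.n_states
        if not lag_in_frames:
            ratio = lag / dtrajs.frame_interval
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError("lag must be a multiple of the frame interval")
            lag = int(round(ratio))
    else:
        seqs, n_states = dtrajs, None
    return MarkovStateModel(lag=int(lag), reversible=reversible,
                            n_states=n_states).fit(seqs)


def implied_timescales(
    dtrajs, lags, n_timescales: int = 5, reversible: bool = True,
    frame_interval: float = 1.0,
):
    """Implied timescales t_i(τ) = −τ/ln λ_{i+1}(T(τ)) over a set of lags.

    Returns a pandas DataFrame (index: lag in frames; columns t1..tn, in
    ``frame_interval`` units).  Undefined timescales (λ ≤ 0 or state lost
    from the connected set) are NaN.
    """
    import pandas as pd

    rows = []
    for lag in lags:
        try:
            m = estimate_msm(dtrajs, lag, reversible=reversible)
            ts = m.timescales(n_timescales, frame_interval)
        except (ValueError, RuntimeError):
            ts = np.full(n_timescales, np.nan)
        if len(ts) < n_timescales:
            ts = np.concatenate([ts, np.full(n_timescales - len(ts), np.nan)])
        rows.append(ts[:n_timescales])
    return pd.DataFrame(
        rows, index=pd.Index(list(lags), name="lag"),
        columns=[f"t{i + 2}" for i in range(n_timescales)],
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class CKTestResult:
    """Chapman-Kolmogorov comparison: T(τ)^k vs re-estimated T(kτ)."""

    steps: np.ndarray  # multiples k
    predicted: np.ndarray  # (n_sets, n_steps) set-stay probabilities
    estimated: np.ndarray
    estimated_std: np.ndarray
    insufficient: np.ndarray  # bool flags (n_steps,) — too little data at kτ

    def max_deviation_sigmas(self) -> float:
        ok = ~self.insufficient
        dev = np.abs(self.predicted[:, ok] - self.estimated[:, ok])
        return float(np.nanmax(dev / np.maximum(self.estimated_std[:, ok], 1e-12)))


def ck_test(
    msm: MarkovStateModel, macro_assignments: np.ndarray, steps: int,
    sequences, n_error_samples: int = 25, seed: int = 0,
) -> CKTestResult:
    """Chapman-Kolmogorov test on macrostate sets.

    For each set A, the predicted probability of remaining in A after k·τ
    under T(τ)^k is compared with the probability under a model re-estimated
    at lag k·τ; error bars come from Dirichlet posterior samples of the
    re-estimated transition matrix.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    rng = np.random.default_rng(seed)
    assign = np.asarray(macro_assignments, dtype=int)
    m = assign.max() + 1
    t, pi = msm.transition_matrix_, msm.stationary_distribution_
    n_active = len(msm.active_set_)
    seqs_active = msm.map_to_active(sequences)

    predicted = np.zeros((m, steps))
    estimated = np.zeros((m, steps))
    est_std = np.zeros((m, steps))
    insufficient = np.zeros(steps, dtype=bool)

    sets = [np.flatnonzero(assign == a) for a in range(m)]
    weights = []
    for members in sets:
        w = np.zeros(n_active)
        w[members] = pi[members]
        weights.append(w / w.sum())

    tk = np.eye(n_active)
    for k in range(1, steps + 1):
        tk = tk @ t
        c_k = count_matrix(
            [s[s >= 0] for s in seqs_active], msm.lag * k, n_active
        )
        if c_k.sum() < 10 or np.any(c_k.sum(axis=1) == 0):
            insufficient[k - 1] = True
        # re-estimate with the same estimator as the base model so that the
        # k = 1 comparison is an identity
        if msm.reversible and not insufficient[k - 1] and len(
            largest_connected_set(c_k)
        ) == n_active:
            t_est, _ = reversible_mle(c_k)
        else:
            rowsum = np.maximum(c_k.sum(axis=1, keepdims=True), 1e-300)
            t_est = c_k / rowsum
        # posterior samples for error bars
        stay_samples = np.zeros((n_error_samples, m))
        for s_i in range(n_error_samples):
            t_s = np.zeros_like(c_k)
            for i in range(n_active):
                row = c_k[i]
                nz = row > 0
                if not nz.any():
                    t_s[i, i] = 1.0
                    continue
                g = rng.gamma(row[nz])
                t_s[i, nz] = g / g.sum()
            for a, members in enumerate(sets):
                ind = np.zeros(n_active)
                ind[members] = 1.0
                stay_samples[s_i, a] = weights[a] @ t_s @ ind
        for a, members in enumerate(sets):
            ind = np.zeros(n_active)
            ind[members] = 1.0
            predicted[a, k - 1] = weights[a] @ tk @ ind
            estimated[a, k - 1] = weights[a] @ t_est @ ind
            est_std[a, k - 1] = stay_samples[:, a].std(ddof=1)
    return CKTestResult(
        steps=np.arange(1, steps + 1), predicted=predicted,
        estimated=estimated, estimated_std=est_std, insufficient=insufficient,
    )


# ---------------------------------------------------------------------------
# VAMP-2 scoring
# ---------------------------------------------------------------------------

def _discrete_covariances(sequences, lag: int, n_states: int):
    c0t = count_matrix(sequences, lag, n_states)
    n = c0t.sum()
    if n == 0:
        raise ValueError("no transitions at this lag")
    c00 = c0t.sum(axis=1) / n
    ctt = c0t.sum(axis=0) / n
    return c00, c0t / n, ctt


def vamp2_from_counts(c00_diag, c0t, ctt_diag, dim: int | None = None) -> float:
    """VAMP-2 score (sum of squared propagator singular values) from
    one-hot covariances of a discrete process."""
    s0 = np.where(c00_diag > 0, 1.0 / np.sqrt(np.maximum(c00_diag, 1e-300)), 0.0)
    st = np.where(ctt_diag > 0, 1.0 / np.sqrt(np.maximum(ctt_diag, 1e-300)), 0.0)
    k = s0[:, None] * c0t * st[None, :]
    sv = np.linalg.svd(k, compute_uv=False)
    sv = np.minimum(sv, 1.0)
    if dim is not None:
        sv = sv[:dim]
    return float(np.sum(sv**2))


def score_vamp2(
    dtrajs, lag: int, n_splits: int | None = 5, seed: int = 0,
    dim: int | None = None,
) -> float:
    """Cross-validated VAMP-2 score of a microstate discretization.

    Singular functions are estimated on the training split and scored on the
    held-out split.  ``n_splits=None`` scores the full data without
    cross-validation (deterministic; useful for closed-form checks).
    """
    if isinstance(dtrajs, DiscreteTrajectorySet):
        seqs, n_states = dtrajs.sequences, dtrajs.n_states
    else:
        seqs = dtrajs if isinstance(dtrajs, list) else [dtrajs]
        seqs = [np.asarray(s, dtype=np.int64) for s in seqs]
        n_states = max(int(s.max()) for s in seqs) + 1

    if n_splits is None:
        return vamp2_from_counts(*_discrete_covariances(seqs, lag, n_states), dim=dim)

    # make at least n_splits pieces, chopping long sequences if needed
    pieces = list(seqs)
    while len(pieces) < n_splits:
        longest = max(range(len(pieces)), key=lambda i: len(pieces[i]))
        s = pieces.pop(longest)
        if len(s) < 2 * (lag + 2):
            raise ValueError("not enough data to split for cross-validation")
        pieces.extend([s[: len(s) // 2], s[len(s) // 2 :]])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pieces))
    folds = np.array_split(order, n_splits)

    scores = []
    for fold in folds:
        test = [pieces[i] for i in fold]
        train = [pieces[i] for i in order if i not in set(fold)]
        c00, c0t, ctt = _discrete_covariances(train, lag, n_states)
        s0 = np.where(c00 > 0, 1.0 / np.sqrt(np.maximum(c00, 1e-300)), 0.0)
        st = np.where(ctt > 0, 1.0 / np.sqrt(np.maximum(ctt, 1e-300)), 0.0)
        u, sv, vt = np.linalg.svd(s0[:, None] * c0t * st[None, :])
        d = dim if dim is not None else len(sv)
        a = (s0[:, None] * u)[:, :d]  # left singular functions
        b = (st[:, None] * vt.T)[:, :d]
        c00_t, c0t_t, ctt_t = _discrete_covariances(test, lag, n_states)
        m00 = a.T @ np.diag(c00_t) @ a
        mtt = b.T @ np.diag(ctt_t) @ b
        m0t = a.T @ c0t_t @ b
        k = _inv_sqrt_psd(m00) @ m0t @ _inv_sqrt_psd(mtt)
        scores.append(float(np.sum(np.linalg.svd(k, compute_uv=False) ** 2)))
    return float(np.mean(scores))


def _inv_sqrt_psd(m: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    w, u = scipy.linalg.eigh(0.5 * (m + m.T))
    keep = w > eps * max(w.max(), eps)
    return (u[:, keep] / np.sqrt(w[keep])) @ u[:, keep].T


# ---------------------------------------------------------------------------
# PCCA+ coarse-graining and kinetics
# ---------------------------------------------------------------------------

@dataclass
class MacrostateModel:
    """PCCA+ macrostates of a microstate MSM."""

    memberships: np.ndarray  # (k, m) fuzzy χ, rows sum to 1
    assignments: np.ndarray  # (k,) crisp argmax χ
    macro_pi: np.ndarray  # (m,) aggregated stationary probabilities
    micro_pi: np.ndarray
    labels: list | None = None

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]

    def free_energies(self, temperature: float = 300.0) -> np.ndarray:
        return free_energies(self.macro_pi, temperature)


def _pcca_memberships(t: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """PCCA+ memberships from the top-m right eigenvectors of T.

    Uses the inner-simplex vertex search followed by a feasibility projection
    (clip negatives, renormalize rows)."""
    n = t.shape[0]
    if m < 2 or m > n:
        raise ValueError("need 2 <= m <= n_states")
    s = np.sqrt(pi)
    sym = s[:, None] * t / s[None, :]
    asym = np.abs(sym - sym.T).max()
    if asym > 1e-8:
        raise ValueError(
            "transition matrix is not reversible (complex dominant spectrum "
            "possible); estimate with reversible=True before PCCA+"
        )
    w, y = scipy.linalg.eigh(0.5 * (sym + sym.T))
    order = np.argsort(w)[::-1][:m]
    psi = y[:, order] / s[:, None]  # right eigenvectors, π-orthonormal
    psi[:, 0] = 1.0

    # inner simplex algorithm: find m rows spanning the eigenvector simplex
    c = psi.copy()
    idx = np.zeros(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(c, axis=1)))
    ortho = c - c[idx[0]]
    for j in range(1, m):
        dist = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(dist))
        d = dist[idx[j]]
        if d <= 1e-12:
            raise ValueError("degenerate eigenvector simplex; reduce m")
        v = ortho[idx[j]] / d
        ortho = ortho - np.outer(ortho @ v, v)
    chi = psi @ np.linalg.inv(psi[idx])
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


def pcca_coarse_grain(
    msm: MarkovStateModel, m: int, fuzzy_populations: bool = False,
    labels: list | None = None,
) -> MacrostateModel:
    """Coarse-grain a reversible MSM into ``m`` metastable macrostates.

    Macrostate probabilities aggregate π over the crisp (argmax) assignment
    by default; ``fuzzy_populations=True`` uses membership-weighted sums.
    """
    chi = _pcca_memberships(msm.transition_matrix_,
                            msm.stationary_distribution_, m)
    assignments = chi.argmax(axis=1)
    if len(np.unique(assignments)) < m:
        warnings.warn("some macrostates received no microstate", stacklevel=2)
    pi = msm.stationary_distribution_
    if fuzzy_populations:
        macro_pi = chi.T @ pi
    else:
        macro_pi = np.array([pi[assignments == a].sum() for a in range(m)])
    return MacrostateModel(
        memberships=chi, assignments=assignments, macro_pi=macro_pi,
        micro_pi=pi, labels=labels,
    )


def free_energies(populations, temperature: float = 300.0) -> np.ndarray:
    """ΔG_i = −k_B·T·ln Π_i in kcal/mol, shifted so the minimum is 0.

    Zero populations give +inf (flagged sentinel, no exception).
    """
    p = np.asarray(populations, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("populations must be a valid distribution")
    kt = KB_KCAL_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        g = -kt * np.log(p)
    return g - g[np.isfinite(g)].min()


def mfpt(
    msm_or_t, source, target, pi: np.ndarray | None = None,
    lag_time: float = 1.0,
) -> float:
    """Mean first passage time from ``source`` to ``target`` (π-weighted).

    Solves m_i = τ + Σ_j T_ij m_j with m = 0 on the target set and returns
    the stationary-weighted average over the source set, in units of
    ``lag_time`` (the physical duration of one MSM step).
    """
    if isinstance(msm_or_t, MarkovStateModel):
        t = msm_or_t.transition_matrix_
        if pi is None:
            pi = msm_or_t.stationary_distribution_
    else:
        t = validate_transition_matrix(msm_or_t)
        if pi is None:
            pi = stationary_distribution(t)
    n = t.shape[0]
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if np.intersect1d(source, target).size:
        raise ValueError("source and target sets must be disjoint")
    rest = np.setdiff1d(np.arange(n), target)
    a = np.eye(len(rest)) - t[np.ix_(rest, rest)]
    try:
        m_rest = np.linalg.solve(a, np.full(len(rest), lag_time))
    except np.linalg.LinAlgError as err:
        raise ValueError("target set unreachable from some states") from err
    if np.any(m_rest < 0) or not np.all(np.isfinite(m_rest)):
        raise ValueError("target set unreachable: MFPT system is singular")
    m_full = np.zeros(n)
    m_full[rest] = m_rest
    w = pi[source]
    return float(w @ m_full[source] / w.sum())


# ---------------------------------------------------------------------------
# Bayesian posterior sampling
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrixEnsemble:
    """Posterior transition-matrix samples with derived-quantity mapping."""

    matrices: np.ndarray  # (n_samples, k, k)
    stationary: np.ndarray  # (n_samples, k)
    reversible: bool

    def map(self, fn) -> np.ndarray:
        """Evaluate fn(T, π) per sample; returns an array of results."""
        return np.array([fn(t, p) for t, p in zip(self.matrices, self.stationary)])


def sample_posterior(
    counts: np.ndarray, n_samples: int = 100, seed: int | None = None,
    reversible: bool = True, burn_in: int = 50, thin: int = 5,
    proposal_sigma: float = 0.2,
) -> TransitionMatrixEnsemble:
    """Posterior samples of the transition matrix given observed counts.

    Reversible sampling uses Metropolis moves on the symmetric edge weights
    x_ij (log-normal multiplicative proposals) under the likelihood
    Π_ij (x_ij / x_i)^{c_ij}; the non-reversible variant draws independent
    Dirichlet rows with the counts as concentration parameters.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c.sum(axis=1) == 0):
        raise ValueError("count matrix has empty rows; restrict to connected set")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    k = c.shape[0]

    if not reversible:
        mats = np.zeros((n_samples, k, k))
        for s in range(n_samples):
            for i in range(k):
                nz = c[i] > 0
                g = rng.gamma(c[i, nz])
                while g.sum() == 0:
                    g = rng.gamma(c[i, nz])
                mats[s, i, nz] = g / g.sum()
        pis = np.array([stationary_distribution(t) for t in mats])
        return TransitionMatrixEnsemble(matrices=mats, stationary=pis,
                                        reversible=False)

    # reversible Metropolis on symmetric weights
    t_mle, pi_mle = reversible_mle(c)
    x = pi_mle[:, None] * t_mle
    x = 0.5 * (x + x.T)
    ci = c.sum(axis=1)
    iu, ju = np.nonzero(np.triu(c + c.T) > 0)
    csym_e = (c + c.T)[iu, ju]
    xi = x.sum(axis=1)

    mats = np.zeros((n_samples, k, k))
    pis = np.zeros((n_samples, k))
    n_sweeps = burn_in + n_samples * thin
    taken = 0
    for sweep in range(n_sweeps):
        eps = rng.normal(0.0, proposal_sigma, size=len(iu))
        us = rng.random(len(iu))
        for e in range(len(iu)):
            i, j = int(iu[e]), int(ju[e])
            x_old = x[i, j]
            x_new = x_old * np.exp(eps[e])
            d = x_new - x_old
            if i == j:
                dlog = (
                    c[i, i] * (np.log(x_new) - np.log(x_old))
                    - ci[i] * (np.log(xi[i] + d) - np.log(xi[i]))
                )
            else:
                dlog = (
                    csym_e[e] * (np.log(x_new) - np.log(x_old))
                    - ci[i] * (np.log(xi[i] + d) - np.log(xi[i]))
                    - ci[j] * (np.log(xi[j] + d) - np.log(xi[j]))
                )
            # log-normal proposal Jacobian: q(x|x')/q(x'|x) = x_new/x_old
            if np.log(us[e]) < dlog + (np.log(x_new) - np.log(x_old)):
                x[i, j] = x_new
                xi[i] += d
                if i != j:
                    x[j, i] = x_new
                    xi[j] += d
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            mats[taken] = x / xi[:, None]
            pis[taken] = xi / xi.sum()
            taken += 1
    return TransitionMatrixEnsemble(matrices=mats[:taken], stationary=pis[:taken],
                                    reversible=True)


# ---------------------------------------------------------------------------
# open bursts
# ---------------------------------------------------------------------------

def _burst_lengths(macro_seq: np.ndarray, open_label: int,
                   merge_gap: int = 0) -> np.ndarray:
    """Lengths (steps) of maximal open runs, merging gaps <= merge_gap."""
    idx = np.flatnonzero(macro_seq == open_label)
    if idx.size == 0:
        return np.array([], dtype=np.int64)
    gaps = np.diff(idx) - 1
    breaks = np.flatnonzero(gaps > merge_gap)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return ends - starts + 1


def open_burst_durations(
    msm_or_t, macro_assignments: np.ndarray, open_label: int,
    n_steps: int, seed: int | None = None, merge_gap: int = 0,
    lag_time: float = 1.0, start: int | None = None,
) -> np.ndarray:
    """Durations of contiguous dwells in the open macrostate.

    A long microstate chain is simulated from T, projected onto macrostates,
    and maximal open runs are extracted; interruptions of at most
    ``merge_gap`` steps are absorbed into the surrounding burst (a burst's
    duration spans first to last open step inclusive).  Durations are in
    units of ``lag_time``.
    """
    t = (msm_or_t.transition_matrix_
         if isinstance(msm_or_t, MarkovStateModel) else msm_or_t)
    assign = np.asarray(macro_assignments, dtype=int)
    if not np.any(assign == open_label):
        raise ValueError("open macrostate is empty")
    chain = simulate_chain(t, n_steps, rng=seed, start=start)
    macro = assign[chain]
    lengths = _burst_lengths(macro, open_label, merge_gap)
    if lengths.size == 0:
        warnings.warn("open state never visited in the simulated chain",
                      stacklevel=2)
    return lengths * lag_time
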