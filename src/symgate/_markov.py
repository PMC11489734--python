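"""Shared low-level Markov-chain helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["validate_transition_matrix", "stationary_distribution", "simulate_chain"]


def validate_transition_matrix(t: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(t < -tol):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of transition matrix must sum to 1")
    return t


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary distribution from the dominant left eigenvector."""
    t = validate_transition_matrix(t)
    w, v = np.linalg.eig(t.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_chain(
    t: np.ndarray,
    n_steps: int,
    rng: np.random.Generator | int,
    start: int | None = None,
) -> np.ndarray:
    """Sample a discrete Markov chain of ``n_steps`` states (incl. start).

    ``start=None`` draws the initial state from the stationary distribution.
    """
    t = validate_transition_matrix(t)
    rng = np.random.default_rng(rng)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0
    if start is None:
        pi = stationary_distribution(t)
        state = int(rng.choice(len(pi), p=pi))
    else:
        state = int(start)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = state
    u = rng.random(n_steps - 1)
    for i in range(1, n_steps):
        state = int(np.searchsorted(cum[state], u[i - 1], side="right"))
        out[i] = state
    return out
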