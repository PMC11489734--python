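"""Cn-symmetric two-state toy kinetic models with exact ground truth.

Each of ``n_fold`` subunits switches between a closed (C) and an open (O)
conformation.  One uniformly chosen subunit attempts a flip per step
(random-scan Glauber-style update), with its switching probability amplified
by ``(1+g)`` per discordant nearest neighbour.  The full chain over all
``2^n_fold`` configurations is built exactly — stationary distribution and
relaxation spectrum come from dense diagonalization — which makes the model
a quantitative oracle for the whole feature → SymTICA → MSM pipeline.
Configurations that share a composition (e.g. CCCCO and CCCOC) are exactly
degenerate, reproducing the degeneracy structure of a symmetric pentamer.

Per-block Gaussian feature emissions mimic the contact-feature layout: block
*s* is drawn around μ_C or μ_O depending on the state of subunit *s*, so the
emitted features are block-roll equivariant in distribution (exactly so for
σ = 0 or with ``shared_noise=True``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._markov import simulate_chain, stationary_distribution
from .features import BlockFeatureSet, TrajectoryFeatures
from .structure_observables import StructureFrame

__all__ = [
    "ToyModelSpec",
    "ToyModelTruth",
    "build_toy_transition_matrix",
    "simulate_trajectories",
    "emit_block_features",
    "generate_ring_structure",
]


def _default_mu(b: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic emission-mean patterns with RMS contrast exactly 0.5."""
    j = np.arange(b)
    mu_c = 1.0 + 0.3 * np.cos(2 * np.pi * j / b)
    delta = 0.5 * np.sqrt(2.0) * np.cos(2 * np.pi * 3 * j / b + 0.7)
    return mu_c, mu_c + delta


@dataclass
class ToyModelSpec:
    """Parameters of the symmetric toy model.

    Defaults give a pentamer with per-subunit open probability 0.1
    (p_CO/(p_CO+p_OC)), uncoupled subunits, and a per-feature emission
    contrast-to-noise ratio of 2 (RMS |μ_O − μ_C| = 0.5, σ = 0.25).
    """

    n_fold: int = 5
    p_co: float = 0.02  # C -> O attempt probability per selected subunit
    p_oc: float = 0.18  # O -> C
    g: float = 0.0  # neighbour coupling: rate × (1+g)^(#discordant neighbours)
    b: int = 32  # features per block
    sigma: float = 0.25  # emission noise std
    mu_c: np.ndarray | None = None
    mu_o: np.ndarray | None = None
    step_ns: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.p_co < 1 and 0 < self.p_oc < 1):
            raise ValueError("p_co and p_oc must lie in (0, 1)")
        if self.g < 0:
            raise ValueError("coupling factor g must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mu_c is None or self.mu_o is None:
            mu_c, mu_o = _default_mu(self.b)
            if self.mu_c is None:
                self.mu_c = mu_c
            if self.mu_o is None:
                self.mu_o = mu_o
        self.mu_c = np.asarray(self.mu_c, dtype=float)
        self.mu_o = np.asarray(self.mu_o, dtype=float)
        if len(self.mu_c) != self.b or len(self.mu_o) != self.b:
            raise ValueError("emission means must have length b")


@dataclass
class ToyModelTruth:
    """Exact transition matrix and analytic summaries of a toy model."""

    spec: ToyModelSpec
    transition_matrix: np.ndarray  # (2^n, 2^n)
    configurations: np.ndarray  # (2^n, n) 0=C, 1=O
    pi: np.ndarray
    eigenvalues: np.ndarray  # real, descending

    @property
    def n_configurations(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def t2_steps(self) -> float:
        """Slowest relaxation time −1/ln λ₂ in steps."""
        lam2 = self.eigenvalues[1]
        return float(-1.0 / np.log(lam2))

    def state_index(self, labels) -> int:
        bits = np.asarray(labels, dtype=int)
        return int(bits @ (1 << np.arange(self.spec.n_fold)))

    def composition(self) -> np.ndarray:
        """Number of open subunits per configuration."""
        return self.configurations.sum(axis=1)

    def roll_permutation(self) -> np.ndarray:
        """P with P[s, roll(s)] = 1 for the cyclic relabeling s -> s+1."""
        n = self.n_configurations
        p = np.zeros((n, n))
        for s in range(n):
            rolled = np.roll(self.configurations[s], 1)
            p[s, self.state_index(rolled)] = 1.0
        return p


def build_toy_transition_matrix(spec: ToyModelSpec) -> ToyModelTruth:
    """Exact dense transition matrix over all subunit configurations.

    One subunit is selected uniformly per step and flips with probability
    p(label)·(1+g)^(#discordant nearest neighbours), clipped at 0.49 (with a
    warning) so rows stay stochastic for any coupling.
    """
    n = spec.n_fold
    if n > 12:
        raise ValueError("n_fold > 12 would build a > 4096-state dense chain")
    n_states = 2**n
    configs = ((np.arange(n_states)[:, None] >> np.arange(n)) & 1).astype(np.int64)
    t = np.zeros((n_states, n_states))
    clipped = False
    base = np.array([spec.p_co, spec.p_oc])
    for s in range(n_states):
        labels = configs[s]
        stay = 1.0
        for i in range(n):
            discordant = int(labels[i] != labels[(i - 1) % n]) + int(
                labels[i] != labels[(i + 1) % n]
            )
            q = base[labels[i]] * (1.0 + spec.g) ** discordant
            if q > 0.49:
                q = 0.49
                clipped = True
            flipped = labels.copy()
            flipped[i] ^= 1
            dest = int(flipped @ (1 << np.arange(n)))
            t[s, dest] = q / n
            stay -= q / n
        t[s, s] = stay
    if clipped:
        warnings.warn("switching probabilities clipped at 0.49", stacklevel=2)
    pi = stationary_distribution(t)
    # spectrum via similarity-symmetrization (chain is reversible by
    # construction: single-site updates with symmetric neighbour counts)
    d = np.sqrt(pi)
    sym = d[:, None] * t / d[None, :]
    eigenvalues = np.sort(np.linalg.eigvalsh(0.5 * (sym + sym.T)))[::-1]
    return ToyModelTruth(
        spec=spec, transition_matrix=t, configurations=configs, pi=pi,
        eigenvalues=eigenvalues,
    )


def simulate_trajectories(
    truth: ToyModelTruth, n_steps: int, n_traj: int = 1,
    seed: int | None = None, start: int | None = None,
):
    """Sample configuration chains; returns (state sequences, label arrays).

    Each element of the second list is the (n_steps, n_fold) per-subunit
    0/1 label series.  ``start=None`` draws initial states from the exact
    stationary distribution.
    """
    rng = np.random.default_rng(seed)
    states, labels = [], []
    for _ in range(n_traj):
        chain = simulate_chain(
            truth.transition_matrix, n_steps,
            rng=rng, start=start,
        )
        states.append(chain)
        labels.append(truth.configurations[chain])
    return states, labels


def emit_block_features(
    subunit_labels: np.ndarray, spec: ToyModelSpec,
    seed: int | None = None, shared_noise: bool = False,
    trajectory_id: str = "toy",
) -> TrajectoryFeatures:
    """Gaussian block emissions for a per-subunit label series.

    Block *s* of frame *t* is μ_C or μ_O (by the label of subunit *s*) plus
    N(0, σ²) noise.  With ``shared_noise=True`` the same noise draw is used
    for every block of a frame, which makes the emission exactly equivariant
    under subunit relabeling (rolled labels emit rolled features); the
    default independent noise is equivariant in distribution only.
    """
    labels = np.asarray(subunit_labels, dtype=int)
    if labels.ndim != 2:
        raise ValueError("subunit_labels must be (frames, n_fold)")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0 (C) or 1 (O)")
    n_frames, n_fold = labels.shape
    if n_fold != spec.n_fold:
        raise ValueError("label width does not match spec.n_fold")
    mu = np.stack([spec.mu_c, spec.mu_o])  # (2, b)
    values = mu[labels]  # (frames, n_fold, b)
    if spec.sigma > 0:
        rng = np.random.default_rng(seed)
        if shared_noise:
            noise = rng.normal(0.0, spec.sigma, size=(n_frames, 1, spec.b))
        else:
            noise = rng.normal(0.0, spec.sigma, size=(n_frames, n_fold, spec.b))
        values = values + noise
    return TrajectoryFeatures(
        values=values.reshape(n_frames, n_fold * spec.b),
        frame_interval=spec.step_ns,
        trajectory_id=trajectory_id,
    )


def emit_feature_set(
    label_trajectories, spec: ToyModelSpec, seed: int | None = None,
    shared_noise: bool = False,
) -> BlockFeatureSet:
    """Emit a (non-augmented) BlockFeatureSet for several label series."""
    rng = np.random.default_rng(seed)
    trajs = [
        emit_block_features(
            lab, spec, seed=rng.integers(2**31), shared_noise=shared_noise,
            trajectory_id=f"toy-{i}",
        )
        for i, lab in enumerate(label_trajectories)
    ]
    return BlockFeatureSet(trajectories=trajs, n_fold=spec.n_fold, augmented=False)


def generate_ring_structure(
    labels, radius_by_label=None, n_atoms: int = 4,
    z_by_label=None,
) -> StructureFrame:
    """Cn ring of subunit point clusters at label-dependent pore radius (Å).

    Subunit *s* is a rigid template cluster rotated to angle 2πs/n; its
    first atom sits exactly on the ring, so the first-atom positions form
    the pore polygon.  Rolling the labels and rotating by 2π/n produce the
    identical structure up to the subunit relabeling, which makes this a
    fixture with known symmetry-corrected alignment behaviour.
    """
    labels = np.asarray(labels, dtype=int)
    n_fold = len(labels)
    if radius_by_label is None:
        radius_by_label = {0: 10.0, 1: 12.0}
    if z_by_label is None:
        z_by_label = {0: 0.0, 1: 0.0}
    for lab in np.unique(labels):
        if radius_by_label[int(lab)] <= 0:
            raise ValueError("radii must be positive")
    # rigid local template (first atom at the origin of the template)
    template = np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.4, 0.8], [0.7, -1.2, 1.9], [-0.9, 0.8, 2.6],
         [1.1, 1.3, 3.4], [-1.4, -0.6, 4.1]]
    )[:n_atoms]
    coords = np.zeros((n_fold, n_atoms, 3))
    for s in range(n_fold):
        theta = 2 * np.pi * s / n_fold
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        r = radius_by_label[int(labels[s])]
        anchor = rot @ np.array([r, 0.0, z_by_label[int(labels[s])]])
        coords[s] = (rot @ template.T).T + anchor
    return StructureFrame(
        coords=coords, axis_point=np.zeros(3), axis_vector=np.array([0.0, 0.0, 1.0])
    )
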