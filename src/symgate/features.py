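"""Contact-map featurization for Cn-symmetric assemblies.

Features are Cα–Cα distances turned into reciprocal distances (nm⁻¹) and
arranged into ``n_fold`` symmetry blocks: block *s* holds the contacts within
subunit *s* plus the inter-subunit contacts (s, s+1) and (s, s+2), so that the
cyclic relabeling of subunits acts on the feature vector as a roll of whole
blocks.  Sampling is augmented by emitting, for every trajectory, the
``n_fold - 1`` block-rolled pseudo-trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactSpec",
    "TrajectoryFeatures",
    "BlockFeatureSet",
    "define_contacts",
    "compute_distances",
    "select_significant_contacts",
    "featurize_reciprocal",
    "arrange_and_augment",
    "roll_blocks",
]


@dataclass(frozen=True)
class ContactSpec:
    """Symmetry-blocked list of Cα contact pairs.

    Each pair is ``(atom_index_i, atom_index_j, subunit_i, subunit_j)`` where
    the atom indices are *within-subunit* positions.  ``block_id`` assigns the
    pair to one of ``n_fold`` blocks and ``within_block_index`` gives its slot
    inside the block; rotating every subunit label by +1 maps the pair at slot
    *w* of block *k* onto the pair at slot *w* of block *k+1 (mod n_fold)*.
    """

    pairs: np.ndarray  # (n_pairs, 4) int
    block_id: np.ndarray  # (n_pairs,) int
    within_block_index: np.ndarray  # (n_pairs,) int
    n_fold: int
    atoms_per_subunit: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", np.asarray(self.pairs, dtype=int))
        object.__setattr__(self, "block_id", np.asarray(self.block_id, dtype=int))
        object.__setattr__(
            self, "within_block_index", np.asarray(self.within_block_index, dtype=int)
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def block_length(self) -> int:
        if self.n_pairs % self.n_fold:
            raise ValueError("pair count not divisible by n_fold")
        return self.n_pairs // self.n_fold

    def validate(self) -> None:
        """Check the block-structure invariants."""
        counts = np.bincount(self.block_id, minlength=self.n_fold)
        if not np.all(counts == counts[0]):
            raise ValueError(f"unequal block lengths: {counts.tolist()}")
        b = counts[0]
        # key (block, slot) must be a bijection onto pairs
        key = self.block_id * b + self.within_block_index
        if len(np.unique(key)) != self.n_pairs:
            raise ValueError("(block, slot) assignment is not unique")
        # cyclic relabeling s -> s+1 maps block k slot w -> block k+1 slot w
        lookup = {}
        for p, (i, j, si, sj) in enumerate(self.pairs):
            lookup[(i, j, si, sj)] = (self.block_id[p], self.within_block_index[p])
        n = self.n_fold
        for p, (i, j, si, sj) in enumerate(self.pairs):
            rotated = (i, j, (si + 1) % n, (sj + 1) % n)
            if rotated not in lookup:
                raise ValueError(f"rotated image of pair {p} missing")
            bk, w = lookup[rotated]
            if bk != (self.block_id[p] + 1) % n or w != self.within_block_index[p]:
                raise ValueError(f"pair {p} breaks block-roll equivariance")

    def column_order(self) -> np.ndarray:
        """Permutation placing pairs in (block-major, slot-minor) order."""
        return np.lexsort((self.within_block_index, self.block_id))

    def to_table(self):
        """Contact table as a pandas DataFrame (CSV-exportable)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "atom_i": self.pairs[:, 0],
                "atom_j": self.pairs[:, 1],
                "subunit_i": self.pairs[:, 2],
                "subunit_j": self.pairs[:, 3],
                "block": self.block_id,
                "slot": self.within_block_index,
            }
        )


@dataclass
class TrajectoryFeatures:
    """Per-frame feature matrix for one (pseudo-)trajectory.

    ``values`` is frames × (n_fold · b), columns in block-major order.
    ``frame_interval`` is the time between frames in ns.
    """

    values: np.ndarray
    frame_interval: float = 1.0
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class BlockFeatureSet:
    """A collection of block-arranged feature trajectories.

    When ``augmented`` is true the list holds each source trajectory followed
    by its ``n_fold - 1`` block-rolled pseudo-copies.
    """

    trajectories: list
    n_fold: int
    augmented: bool = False
    spec: ContactSpec | None = None

    @property
    def n_features(self) -> int:
        return self.trajectories[0].n_features

    @property
    def block_length(self) -> int:
        if self.n_features % self.n_fold:
            raise ValueError("feature count not divisible by n_fold")
        return self.n_features // self.n_fold

    @property
    def n_frames_total(self) -> int:
        return sum(t.n_frames for t in self.trajectories)

    @property
    def frame_interval(self) -> float:
        return self.trajectories[0].frame_interval

    def arrays(self) -> list[np.ndarray]:
        return [t.values for t in self.trajectories]

    def augment(self) -> "BlockFeatureSet":
        if self.augmented:
            return self
        return arrange_and_augment(self.trajectories, self.n_fold, spec=self.spec)


def roll_blocks(values: np.ndarray, n_fold: int, shift: int) -> np.ndarray:
    """Roll the symmetry blocks of a (frames × n·b) matrix by ``shift``.

    Block ``k`` of the output equals block ``k - shift (mod n_fold)`` of the
    input, i.e. the feature image of relabeling subunits ``s -> s + shift``.
    """
    values = np.atleast_2d(values)
    n_frames, n_feat = values.shape
    if n_feat % n_fold:
        raise ValueError(f"feature count {n_feat} not divisible by n_fold={n_fold}")
    b = n_feat // n_fold
    rolled = np.roll(values.reshape(n_frames, n_fold, b), shift, axis=1)
    return rolled.reshape(n_frames, n_feat)


def _subunit_atom_index(subunit_ids: np.ndarray, n_fold: int) -> np.ndarray:
    """(n_fold, m) global atom indices, per-subunit order preserved."""
    subunit_ids = np.asarray(subunit_ids)
    sizes = np.bincount(subunit_ids, minlength=n_fold)
    if len(np.unique(subunit_ids)) != n_fold:
        raise ValueError("subunit labels must cover 0..n_fold-1")
    if not np.all(sizes == sizes[0]):
        bad = int(np.argmax(sizes != sizes[0]))
        raise ValueError(
            f"subunit {bad} has {sizes[bad]} atoms, expected {sizes[0]}: "
            "all subunits must have equal atom counts"
        )
    return np.stack([np.flatnonzero(subunit_ids == s) for s in range(n_fold)])


def define_contacts(
    seed_structures,
    subunit_ids: np.ndarray,
    n_fold: int,
    cutoff: float = 1.0,
) -> ContactSpec:
    """Build a symmetry-closed ContactSpec from seed structures.

    A candidate contact (canonical form in block 0: intra-subunit, or
    inter-subunit at offset +1 or +2) is included if *any* of its ``n_fold``
    rotated images is within ``cutoff`` (nm) in *any* seed structure; its full
    orbit is then included, so every block has the same length.

    ``seed_structures``: one (n_atoms, 3) array or a list of them, in nm.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if n_fold < 2:
        raise ValueError("n_fold must be >= 2")
    if n_fold % 2 == 0:
        # antipodal (offset n/2) contacts cannot be assigned to a unique block
        warnings.warn(
            "even n_fold: antipodal inter-subunit contacts are excluded",
            stacklevel=2,
        )
    structures = seed_structures
    if isinstance(structures, np.ndarray) and structures.ndim == 2:
        structures = [structures]
    structures = [np.asarray(c, dtype=float) for c in structures]
    if len(structures) == 0:
        raise ValueError("need at least one seed structure")

    atom_idx = _subunit_atom_index(subunit_ids, n_fold)
    m = atom_idx.shape[1]

    # canonical candidates anchored at subunit 0: (0,a)-(offset,a')
    candidates = []
    for a in range(m):
        for a2 in range(a + 1, m):
            candidates.append((a, a2, 0))  # intra-subunit
    max_offset = (n_fold - 1) // 2
    for off in range(1, max_offset + 1):
        for a in range(m):
            for a2 in range(m):
                candidates.append((a, a2, off))

    kept = []
    for a, a2, off in candidates:
        hit = False
        for coords in structures:
            for s in range(n_fold):
                gi = atom_idx[s, a]
                gj = atom_idx[(s + off) % n_fold, a2]
                d = np.linalg.norm(coords[gi] - coords[gj])
                if d <= cutoff:
                    hit = True
                    break
            if hit:
                break
        if hit:
            kept.append((a, a2, off))
    if not kept:
        raise ValueError("no contacts within cutoff: empty selection")

    pairs, block_id, wbi = [], [], []
    for k in range(n_fold):
        for w, (a, a2, off) in enumerate(kept):
            pairs.append((a, a2, k, (k + off) % n_fold))
            block_id.append(k)
            wbi.append(w)
    spec = ContactSpec(
        pairs=np.array(pairs),
        block_id=np.array(block_id),
        within_block_index=np.array(wbi),
        n_fold=n_fold,
        atoms_per_subunit=m,
    )
    spec.validate()
    return spec


def compute_distances(
    coords: np.ndarray, spec: ContactSpec, subunit_ids: np.ndarray
) -> np.ndarray:
    """Pairwise distances (frames × n_pairs) for a coordinate trajectory.

    Columns follow the spec's (block-major, slot-minor) order, so the output
    is directly block-arranged.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atom_idx = _subunit_atom_index(subunit_ids, spec.n_fold)
    order = spec.column_order()
    p = spec.pairs[order]
    gi = atom_idx[p[:, 2], p[:, 0]]
    gj = atom_idx[p[:, 3], p[:, 1]]
    return np.linalg.norm(coords[:, gi] - coords[:, gj], axis=2)


def select_significant_contacts(
    distance_series: np.ndarray,
    n_fold: int,
    ratio_threshold: float = 0.2,
    mode: str = "pooled",
) -> np.ndarray:
    """Mask of contacts whose peak-to-peak / mean ratio is >= threshold.

    Computed on raw distances (not reciprocals).  ``distance_series`` columns
    must be block-arranged.  Modes:

    - ``"pooled"`` (default): the n_fold rotated series of an equivalence
      class are pooled before the ratio is computed, so the mask is symmetric
      by construction.
    - ``"all"``: per-contact ratios; a class is kept iff every image passes.
    - ``"per_contact"``: per-contact ratios with no symmetry closure (the
      resulting mask may break the equal-block-length invariant).
    """
    d = np.atleast_2d(np.asarray(distance_series, dtype=float))
    if d.shape[0] < 2:
        raise ValueError("need at least two frames to assess variability")
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be strictly positive and finite")
    n_frames, n_pairs = d.shape
    if n_pairs % n_fold:
        raise ValueError("pair count not divisible by n_fold")
    b = n_pairs // n_fold

    if mode == "pooled":
        pooled = d.reshape(n_frames, n_fold, b)
        ratio = np.ptp(pooled, axis=(0, 1)) / pooled.mean(axis=(0, 1))
        keep_class = ratio >= ratio_threshold
        return np.tile(keep_class, n_fold)
    ratio = np.ptp(d, axis=0) / d.mean(axis=0)
    keep = ratio >= ratio_threshold
    if mode == "per_contact":
        return keep
    if mode == "all":
        keep_class = keep.reshape(n_fold, b).all(axis=0)
        return np.tile(keep_class, n_fold)
    raise ValueError(f"unknown mode {mode!r}")


def filter_contact_spec(spec: ContactSpec, mask: np.ndarray) -> ContactSpec:
    """Restrict a ContactSpec to the kept contacts (mask in column order)."""
    order = spec.column_order()
    mask = np.asarray(mask, dtype=bool)
    keep_sorted = order[mask]
    b_new = mask[: spec.n_pairs // spec.n_fold].sum()
    new = ContactSpec(
        pairs=spec.pairs[keep_sorted],
        block_id=np.repeat(np.arange(spec.n_fold), b_new),
        within_block_index=np.tile(np.arange(b_new), spec.n_fold),
        n_fold=spec.n_fold,
        atoms_per_subunit=spec.atoms_per_subunit,
    )
    new.validate()
    return new


def featurize_reciprocal(
    distances: np.ndarray,
    frame_interval: float = 1.0,
    trajectory_id: str = "",
) -> TrajectoryFeatures:
    """Element-wise reciprocal transform d -> 1/d (nm -> nm⁻¹).

    Reciprocal distances damp rare large-distance excursions that would
    otherwise dominate a TICA fit.
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    bad = ~(d > 0) | ~np.isfinite(d)
    if np.any(bad):
        t, p = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive or non-finite distance at frame {t}, pair {p}"
        )
    return TrajectoryFeatures(
        values=1.0 / d, frame_interval=frame_interval, trajectory_id=trajectory_id
    )


def arrange_and_augment(
    features,
    n_fold: int,
    spec: ContactSpec | None = None,
) -> BlockFeatureSet:
    """Emit the original trajectories plus their block-rolled pseudo-copies.

    The k-th pseudo-copy of a trajectory is the exact image of relabeling
    subunits s -> s+k, so the augmented set is closed under block rolls and
    effectively multiplies the sampling by ``n_fold``.  Pseudo-trajectory ids
    carry a ``@roll{k}`` suffix so downstream statistics can identify
    duplicated frames where needed.
    """
    if isinstance(features, TrajectoryFeatures):
        features = [features]
    if isinstance(features, BlockFeatureSet):
        if features.augmented:
            return features
        features = features.trajectories
    out = []
    for traj in features:
        if traj.n_features % n_fold:
            raise ValueError(
                f"feature count {traj.n_features} not divisible by n_fold={n_fold}"
            )
        out.append(traj)
    for k in range(1, n_fold):
        for traj in features:
            out.append(
                replace(
                    traj,
                    values=roll_blocks(traj.values, n_fold, k),
                    trajectory_id=f"{traj.trajectory_id}@roll{k}",
                )
            )
    return BlockFeatureSet(trajectories=out, n_fold=n_fold, augmented=True, spec=spec)
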