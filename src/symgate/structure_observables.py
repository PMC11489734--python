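"""Symmetry-corrected structural alignment and pore-geometry observables.

For a Cn-symmetric assembly, two frames belonging to the same conformational
state may differ only by which subunit carries the asymmetry; naive RMSD
alignment against a single reference then overestimates the deviation.  The
symmetry-corrected alignment searches all cyclic subunit relabelings for the
minimum Kabsch RMSD.  The module also provides the geometric observables
built on such alignments: pore-vertex polygon metrics, cylinder occupancy
counts (pore hydration), cylindrical density grids, and MSM-stationary-
weighted histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructureFrame",
    "WeightedEnsemble",
    "kabsch",
    "symmetry_corrected_align",
    "pore_polygon_metrics",
    "count_in_cylinder",
    "cylindrical_density",
    "reweighted_histogram",
]


@dataclass
class StructureFrame:
    """Cα coordinates (Å) grouped by subunit, plus an optional pore axis.

    ``coords`` has shape (n_fold, atoms_per_subunit, 3).  The axis is a
    (point, unit-vector) pair; when omitted it defaults to the z axis
    through the centroid.
    """

    coords: np.ndarray
    axis_point: np.ndarray | None = None
    axis_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_fold, atoms, 3)")
        if self.axis_point is None:
            self.axis_point = self.coords.reshape(-1, 3).mean(axis=0)
        if self.axis_vector is None:
            self.axis_vector = np.array([0.0, 0.0, 1.0])
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        v = np.asarray(self.axis_vector, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("axis vector must be nonzero")
        self.axis_vector = v / norm

    @property
    def n_fold(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)


@dataclass
class WeightedEnsemble:
    """Frames with microstate labels and the MSM stationary distribution.

    Each frame of microstate *s* carries weight π(s)/count(s), so ensemble
    averages reproduce the MSM stationary ensemble rather than the raw
    (possibly biased) sampling.
    """

    labels: np.ndarray  # per-frame microstate label
    pi: np.ndarray  # stationary distribution over active-set states
    active_set: np.ndarray | None = None  # valid labels; default: arange(len(pi))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.active_set is None:
            self.active_set = np.arange(len(self.pi))
        self.active_set = np.asarray(self.active_set, dtype=np.int64)

    def frame_weights(self) -> tuple[np.ndarray, int]:
        """(weights summing to 1 over valid frames, n_excluded).

        Frames whose label is outside the active set get weight 0.
        """
        state_to_pi = dict(zip(self.active_set.tolist(), self.pi.tolist()))
        valid = np.isin(self.labels, self.active_set)
        n_excluded = int((~valid).sum())
        w = np.zeros(len(self.labels))
        labels_valid = self.labels[valid]
        counts = {s: c for s, c in zip(*np.unique(labels_valid, return_counts=True))}
        w[valid] = [state_to_pi[s] / counts[s] for s in labels_valid]
        total = w.sum()
        if total <= 0:
            raise ValueError("no frames inside the active set")
        return w / total, n_excluded


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation and RMSD after centering both point sets.

    Returns (rotation matrix R, rmsd) with R applied to the centered mobile
    coordinates: ``ref_centered ≈ mobile_centered @ R.T``.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ValueError("need matching coordinate sets with >= 3 atoms")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if np.linalg.matrix_rank(pc, tol=1e-9) < 2 or np.linalg.matrix_rank(qc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ r.T - qc
    rmsd = float(np.sqrt((diff**2).sum() / p.shape[0]))
    return r, rmsd


def symmetry_corrected_align(mobile: StructureFrame, reference: StructureFrame):
    """Minimum Kabsch RMSD over all cyclic subunit relabelings.

    Returns ``(rotation, permutation_shift, rmsd)`` where the shift k means
    the mobile frame was compared with its subunit blocks rolled by k.  The
    returned RMSD never exceeds the identity-permutation RMSD.
    """
    if mobile.coords.shape != reference.coords.shape:
        raise ValueError("atom counts do not match")
    n_fold = mobile.n_fold
    best = None
    for k in range(n_fold):
        rolled = np.roll(mobile.coords, k, axis=0).reshape(-1, 3)
        r, rmsd = kabsch(rolled, reference.flat())
        if best is None or rmsd < best[2]:
            best = (r, k, rmsd)
    return best


def pore_polygon_metrics(vertices: np.ndarray):
    """Edge lengths and regularity of the pore polygon.

    ``vertices``: (n_fold, 3) positions of the pore-lining Cα atoms (e.g.
    the 9′ ring) in subunit order.  Returns ``(edges, regularity)`` with
    consecutive-vertex edge lengths (wrapping around) and regularity
    ``(max − min)/mean`` (0 for a regular polygon).
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 3:
        raise ValueError("need at least 3 vertices of dimension 3")
    edges = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
    if np.any(edges == 0):
        raise ValueError("coincident consecutive vertices")
    regularity = float(np.ptp(edges) / edges.mean())
    return edges, regularity


def _cylinder_coords(points, center, axis):
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, float)
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = p @ a
    radial = np.linalg.norm(p - np.outer(z, a), axis=1)
    return radial, z


def count_in_cylinder(points, center, axis, radius: float,
                      half_height: float = 2.0) -> int:
    """Number of points inside a finite cylinder.

    The cylinder is centered at ``center``, aligned with ``axis``, with the
    given radius and extending ±``half_height`` along the axis (Å).  This is
    the pore-hydration count when ``points`` are water oxygens and the
    center is a pore-lining residue.
    """
    if radius <= 0 or half_height <= 0:
        raise ValueError("radius and half_height must be positive")
    radial, z = _cylinder_coords(points, center, axis)
    return int(np.sum((np.abs(z) <= half_height) & (radial <= radius)))


def cylindrical_density(
    points, center, axis, r_edges, z_edges, slab: float | None = None,
):
    """2-D (r, z) histogram of points around an axis.

    ``slab`` optionally restricts to |z| <= slab before binning (a slice
    through the density).  Returns a dict with raw ``counts``, the
    shell-volume-normalized ``density`` (counts / (π(r₂²−r₁²)·Δz)), the bin
    edges, and ``n_dropped`` points outside the binned range.
    """
    r_edges = np.asarray(r_edges, dtype=float)
    z_edges = np.asarray(z_edges, dtype=float)
    if np.any(np.diff(r_edges) <= 0) or np.any(np.diff(z_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    radial, z = _cylinder_coords(points, center, axis)
    n_total = len(radial)
    if slab is not None:
        keep = np.abs(z) <= slab
        radial, z = radial[keep], z[keep]
    counts, _, _ = np.histogram2d(radial, z, bins=[r_edges, z_edges])
    n_dropped = n_total - int(counts.sum())
    shell = np.pi * np.diff(r_edges**2)
    volume = np.outer(shell, np.diff(z_edges))
    return {
        "counts": counts,
        "density": counts / volume,
        "r_edges": r_edges,
        "z_edges": z_edges,
        "n_dropped": n_dropped,
    }


def reweighted_histogram(values, ensemble: WeightedEnsemble, bins):
    """Histogram of a per-frame observable under MSM stationary weights.

    Each frame is weighted by π(label)/count(label); the result is
    normalized to unit total mass.  Returns ``(hist, edges, n_excluded)``
    where ``n_excluded`` counts frames whose label lies outside the MSM
    active set.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(ensemble.labels):
        raise ValueError("values and labels must have equal length")
    w, n_excluded = ensemble.frame_weights()
    hist, edges = np.histogram(values, bins=bins, weights=w)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, edges, n_excluded
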