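"""HDF5 / CSV persistence for the pipeline's typed objects.

All stores carry a ``symgate_layout`` version attribute; readers refuse
silently-incompatible files with an explicit :class:`StoreFormatError`.
Floats are stored as float64 so write → read round-trips are lossless.
"""

from __future__ import annotations

import numpy as np

from .features import BlockFeatureSet, ContactSpec, TrajectoryFeatures
from .msm import DiscreteTrajectorySet
from .symtica import SymTICA

LAYOUT_VERSION = 1

__all__ = [
    "StoreFormatError",
    "write_feature_set",
    "read_feature_set",
    "write_symtica_model",
    "read_symtica_model",
    "write_projections",
    "read_projections",
    "write_dtrajs",
    "read_dtrajs",
]


class StoreFormatError(RuntimeError):
    """Raised when a store is missing or has an incompatible layout."""


def _h5py():
    import h5py

    return h5py


def _check_layout(f, kind: str) -> None:
    version = f.attrs.get("symgate_layout")
    if version is None:
        raise StoreFormatError(f"{f.filename}: not a symgate store")
    if int(version) != LAYOUT_VERSION:
        raise StoreFormatError(
            f"{f.filename}: layout version {version}, expected {LAYOUT_VERSION}"
        )
    stored_kind = f.attrs.get("kind")
    if stored_kind != kind:
        raise StoreFormatError(
            f"{f.filename}: store holds {stored_kind!r}, expected {kind!r}"
        )


def _stamp(f, kind: str) -> None:
    f.attrs["symgate_layout"] = LAYOUT_VERSION
    f.attrs["kind"] = kind


def write_feature_set(path, fs: BlockFeatureSet) -> None:
    with _h5py().File(path, "w") as f:
        _stamp(f, "features")
        f.attrs["n_fold"] = fs.n_fold
        f.attrs["augmented"] = bool(fs.augmented)
        f.attrs["frame_interval_ns"] = fs.frame_interval
        grp = f.create_group("trajectories")
        for i, traj in enumerate(fs.trajectories):
            g = grp.create_group(f"{i:04d}")
            g.create_dataset("values", data=np.asarray(traj.values, dtype=np.float64))
            g.attrs["trajectory_id"] = traj.trajectory_id
        if fs.spec is not None:
            table = np.column_stack(
                [fs.spec.pairs, fs.spec.block_id, fs.spec.within_block_index]
            )
            d = f.create_dataset("contact_spec", data=table.astype(np.int64))
            d.attrs["atoms_per_subunit"] = fs.spec.atoms_per_subunit


def read_feature_set(path) -> BlockFeatureSet:
    with _h5py().File(path, "r") as f:
        _check_layout(f, "features")
        n_fold = int(f.attrs["n_fold"])
        interval = float(f.attrs["frame_interval_ns"])
        trajs = []
        for key in sorted(f["trajectories"]):
            g = f["trajectories"][key]
            trajs.append(
                TrajectoryFeatures(
                    values=g["values"][...],
                    frame_interval=interval,
                    trajectory_id=str(g.attrs.get("trajectory_id", key)),
                )
            )
        spec = None
        if "contact_spec" in f:
            table = f["contact_spec"][...]
            spec = ContactSpec(
                pairs=table[:, :4], block_id=table[:, 4],
                within_block_index=table[:, 5], n_fold=n_fold,
                atoms_per_subunit=int(f["contact_spec"].attrs["atoms_per_subunit"]),
            )
        return BlockFeatureSet(
            trajectories=trajs, n_fold=n_fold,
            augmented=bool(f.attrs["augmented"]), spec=spec,
        )


def write_symtica_model(path, model: SymTICA) -> None:
    with _h5py().File(path, "w") as f:
        _stamp(f, "symtica")
        f.create_dataset("eigenvalues", data=model.eigenvalues_)
        f.create_dataset("nu_A", data=model.components_)
        f.create_dataset("mean", data=model.mean_)
        f.attrs["lag"] = model.lag_
        f.attrs["n_fold"] = model.n_fold_
        f.attrs["reg"] = model.reg
        f.attrs["rank"] = model.rank_


def read_symtica_model(path) -> SymTICA:
    with _h5py().File(path, "r") as f:
        _check_layout(f, "symtica")
        model = SymTICA(
            lag=int(f.attrs["lag"]),
            n_components=len(f["eigenvalues"]),
            n_fold=int(f.attrs["n_fold"]),
            reg=float(f.attrs["reg"]),
        )
        model.eigenvalues_ = f["eigenvalues"][...]
        model.components_ = f["nu_A"][...]
        model.mean_ = f["mean"][...]
        model.lag_ = int(f.attrs["lag"])
        model.n_fold_ = int(f.attrs["n_fold"])
        model.b_ = model.components_.shape[1]
        model.rank_ = int(f.attrs["rank"])
        return model


def write_projections(path, projections, frame_interval: float = 1.0) -> None:
    """Store per-trajectory subIC arrays (ICs are their exact block sum)."""
    with _h5py().File(path, "w") as f:
        _stamp(f, "projections")
        f.attrs["frame_interval_ns"] = frame_interval
        grp = f.create_group("subics")
        for i, proj in enumerate(projections):
            grp.create_dataset(f"{i:04d}", data=np.asarray(proj.subics, np.float64))


def read_projections(path):
    from .symtica import ProjectionResult

    with _h5py().File(path, "r") as f:
        _check_layout(f, "projections")
        return (
            [ProjectionResult(subics=f["subics"][k][...]) for k in sorted(f["subics"])],
            float(f.attrs["frame_interval_ns"]),
        )


def write_dtrajs(path, dtrajs: DiscreteTrajectorySet) -> None:
    with _h5py().File(path, "w") as f:
        _stamp(f, "dtrajs")
        f.attrs["n_states"] = dtrajs.n_states
        f.attrs["frame_interval_ns"] = dtrajs.frame_interval
        grp = f.create_group("sequences")
        for i, s in enumerate(dtrajs.sequences):
            grp.create_dataset(f"{i:04d}", data=np.asarray(s, dtype=np.int64))
        if dtrajs.centers is not None:
            f.create_dataset("centers", data=np.asarray(dtrajs.centers, np.float64))


def read_dtrajs(path) -> DiscreteTrajectorySet:
    with _h5py().File(path, "r") as f:
        _check_layout(f, "dtrajs")
        return DiscreteTrajectorySet(
            sequences=[f["sequences"][k][...] for k in sorted(f["sequences"])],
            n_states=int(f.attrs["n_states"]),
            centers=f["centers"][...] if "centers" in f else None,
            frame_interval=float(f.attrs["frame_interval_ns"]),
        )
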