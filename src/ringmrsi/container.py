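"""Self-describing HDF5 container for k-space, patterns, weights and maps.

Layout: one group per bundle entry, tagged with a ``class`` attribute
(RingKSpace, RingTrajectory, UndersamplingPattern, DensityWeights, plain
arrays, nested dicts).  The file root carries ``format_version``, the JSON
of the configuration that produced it, the seed, and an optional log.
Arrays round-trip bitwise in their own dtype.  Cartesian image maps can
also be exported as NIfTI.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .kspace import RingKSpace
from .sampling import UndersamplingPattern
from .trajectory import DensityWeights, RingTrajectory, make_ring_trajectory

__all__ = [
    "ContainerError",
    "save_container",
    "load_container",
    "export_nifti",
    "FORMAT_VERSION",
]

FORMAT_VERSION = "1"


class ContainerError(RuntimeError):
    """Raised when a container file cannot be read or has the wrong version."""


def _write_trajectory(grp: h5py.Group, traj: RingTrajectory) -> None:
    grp.attrs["class"] = "RingTrajectory"
    for name in ("n_rings", "points_per_ring", "matrix_size", "fov"):
        grp.attrs[name] = getattr(traj, name)


def _read_trajectory(grp: h5py.Group) -> RingTrajectory:
    return make_ring_trajectory(
        int(grp.attrs["n_rings"]),
        int(grp.attrs["points_per_ring"]),
        int(grp.attrs["matrix_size"]),
        float(grp.attrs["fov"]),
    )


def _write_obj(parent: h5py.Group, key: str, obj) -> None:
    if isinstance(obj, RingKSpace):
        grp = parent.create_group(key)
        grp.attrs["class"] = "RingKSpace"
        grp.attrs["dwell"] = obj.dwell
        grp.attrs["flip_scale"] = obj.flip_scale
        grp.create_dataset("data", data=obj.data)
        grp.create_dataset("measured_rings", data=obj.measured_rings)
        _write_trajectory(grp.create_group("trajectory"), obj.traj)
    elif isinstance(obj, RingTrajectory):
        _write_trajectory(parent.create_group(key), obj)
    elif isinstance(obj, UndersamplingPattern):
        grp = parent.create_group(key)
        grp.attrs["class"] = "UndersamplingPattern"
        grp.attrs["json"] = json.dumps(obj.to_dict())
    elif isinstance(obj, DensityWeights):
        grp = parent.create_group(key)
        grp.attrs["class"] = "DensityWeights"
        grp.attrs["converged"] = obj.converged
        grp.attrs["max_residual"] = obj.max_residual
        grp.attrs["n_iter_run"] = obj.n_iter_run
        grp.create_dataset("w", data=obj.w)
    elif isinstance(obj, dict):
        grp = parent.create_group(key)
        grp.attrs["class"] = "dict"
        for k, v in obj.items():
            _write_obj(grp, str(k), v)
    elif isinstance(obj, np.ndarray):
        parent.create_dataset(key, data=obj)
    elif isinstance(obj, (str, int, float, bool, np.integer, np.floating)):
        grp = parent.create_group(key)
        grp.attrs["class"] = "scalar"
        grp.attrs["value"] = obj
    elif obj is None:
        pass
    else:
        raise TypeError(f"cannot serialize {key!r} of type {type(obj).__name__}")


def _read_obj(node):
    if isinstance(node, h5py.Dataset):
        return node[()]
    cls = node.attrs.get("class", "dict")
    if cls == "RingKSpace":
        return RingKSpace(
            data=node["data"][()],
            traj=_read_trajectory(node["trajectory"]),
            dwell=float(node.attrs["dwell"]),
            measured_rings=node["measured_rings"][()],
            flip_scale=float(node.attrs["flip_scale"]),
        )
    if cls == "RingTrajectory":
        return _read_trajectory(node)
    if cls == "UndersamplingPattern":
        d = json.loads(node.attrs["json"])
        return UndersamplingPattern(
            n_rings=d["n_rings"],
            measured=np.asarray(d["measured"], dtype=bool),
            nominal_R=d["nominal_R"],
            n_full_inner=d["n_full_inner"],
        )
    if cls == "DensityWeights":
        return DensityWeights(
            w=node["w"][()],
            converged=bool(node.attrs["converged"]),
            max_residual=float(node.attrs["max_residual"]),
            n_iter_run=int(node.attrs["n_iter_run"]),
        )
    if cls == "scalar":
        val = node.attrs["value"]
        return val.item() if hasattr(val, "item") else val
    return {k: _read_obj(node[k]) for k in node}


def save_container(
    path,
    bundle: dict,
    config: dict | None = None,
    seed: int | None = None,
    log: list[str] | None = None,
) -> None:
    """Write a bundle of named objects into one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if log:
            f.create_dataset("_log", data=np.array(log, dtype=h5py.string_dtype()))
        for key, obj in bundle.items():
            _write_obj(f, key, obj)


def load_container(path) -> dict:
    """Load a container back into a dict of objects.

    The configuration and seed (if present) are returned under the keys
    ``_config`` and ``_seed``; the log under ``_log``.
    """
    try:
        f = h5py.File(path, "r")
    except (OSError, ValueError) as exc:
        raise ContainerError(f"cannot read container {path}: {exc}") from exc
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ContainerError(
                f"container format version {version!r} does not match "
                f"{FORMAT_VERSION!r}; no migration path is available"
            )
        out = {}
        for key in f:
            if key == "_log":
                out["_log"] = [s.decode() for s in f["_log"][()]]
            else:
                out[key] = _read_obj(f[key])
        if "config_json" in f.attrs:
            out["_config"] = json.loads(f.attrs["config_json"])
        if "seed" in f.attrs:
            out["_seed"] = int(f.attrs["seed"])
    return out


def export_nifti(image: np.ndarray, path, voxel_mm: float = 1.0) -> None:
    """Export a 2D/3D real-valued map as NIfTI."""
    import nibabel as nib

    img = np.asarray(image)
    if np.iscomplexobj(img):
        img = np.abs(img)
    while img.ndim < 3:
        img = img[..., None]
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(img.astype(np.float32), affine), str(path))
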