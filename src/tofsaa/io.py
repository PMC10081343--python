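"""Array containers with grid metadata and operator disk caching.

Images and sinograms are persisted as ``.npz`` archives carrying the grid
size and field of view; system operators (sparse P and T plus their norms)
cache to a file keyed by a hash of the geometry/TOF configuration, so
repeated studies skip the ray tracing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .projectors import ScanGeometry, SystemOperators, TOFModel

__all__ = [
    "save_images",
    "load_images",
    "geometry_key",
    "save_operators",
    "load_operators",
]


def save_images(path, images: dict, grid_n: int, fov_cm: float) -> None:
    """Write named image arrays with grid metadata (n, fov, pixel size)."""
    meta = dict(grid_n=grid_n, fov_cm=fov_cm, pixel_size_cm=fov_cm / grid_n)
    np.savez(path, _meta=json.dumps(meta), **images)


def load_images(path) -> tuple[dict, dict]:
    """Read back images and their grid metadata."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        images = {k: data[k] for k in data.files if k != "_meta"}
    return images, meta


def geometry_key(geom: ScanGeometry, tof: TOFModel) -> str:
    """Stable short hash of a scan/TOF configuration."""
    payload = json.dumps(
        [geom.grid_n, geom.fov_cm, geom.n_views, geom.n_rays,
         tof.fwhm_cm, tof.n_windows],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _csr_arrays(prefix: str, M: sp.csr_matrix) -> dict:
    return {
        f"{prefix}_data": M.data,
        f"{prefix}_indices": M.indices,
        f"{prefix}_indptr": M.indptr,
        f"{prefix}_shape": np.asarray(M.shape),
    }


def _csr_from(prefix: str, data) -> sp.csr_matrix:
    return sp.csr_matrix(
        (data[f"{prefix}_data"], data[f"{prefix}_indices"],
         data[f"{prefix}_indptr"]),
        shape=tuple(data[f"{prefix}_shape"]),
    )


def save_operators(ops: SystemOperators, cache_dir) -> Path:
    """Cache the sparse operators and norms keyed by the geometry hash."""
    if ops.geom is None or ops.tof is None:
        raise ValueError("only operators built from a geometry can be cached")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"ops_{geometry_key(ops.geom, ops.tof)}.npz"
    np.savez(
        path,
        norms=np.asarray([ops.norm_P, ops.norm_T]),
        **_csr_arrays("P", ops.P),
        **_csr_arrays("T", ops.T),
    )
    return path


def load_operators(
    geom: ScanGeometry, tof: TOFModel, cache_dir
) -> SystemOperators | None:
    """Load cached operators for a configuration; None on cache miss."""
    path = Path(cache_dir) / f"ops_{geometry_key(geom, tof)}.npz"
    if not path.exists():
        return None
    with np.load(path) as data:
        norms = data["norms"]
        return SystemOperators(
            P=_csr_from("P", data),
            T=_csr_from("T", data),
            norm_P=float(norms[0]),
            norm_T=float(norms[1]),
            geom=geom,
            tof=tof,
        )
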