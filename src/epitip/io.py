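"""File formats: flat parameter configs, TSV matrices, tabular reports,
HDF5 trajectory containers, fixtures and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    make_all_to_all,
    make_ablated_first_neighbors,
    make_first_neighbors,
    make_heterogeneous,
)
from .params import KineticParameters, ScalingSettings, default_bistable

__all__ = [
    "read_params",
    "write_params",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_npy",
    "read_matrix",
    "write_table",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "generate_fixtures",
    "write_manifest",
]

_SCALING_KEYS = {"omega27", "omega_e"}


def read_params(path: Union[str, Path]) -> tuple[KineticParameters, ScalingSettings]:
    """Read a flat ``key = value`` parameter file (``#`` comments allowed)."""
    kin: dict = {}
    scal: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        value: Optional[float]
        if raw.lower() in ("none", ""):
            value = None
        elif raw.lower() in ("inf", "infinity"):
            value = math.inf
        else:
            value = float(raw)
        if key in _SCALING_KEYS:
            scal[key] = value
        else:
            kin[key] = value
    return KineticParameters(**kin), ScalingSettings(**scal)


def write_params(
    path: Union[str, Path], params: KineticParameters, scaling: ScalingSettings
) -> None:
    lines = ["# epitip kinetic parameter bundle"]
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        lines.append(f"{f.name} = {'none' if v is None else repr(v)}")
    lines.append(f"omega27 = {scaling.omega27!r}")
    lines.append(f"omega_e = {scaling.omega_e!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix_tsv(path: Union[str, Path], conn: ConnectivityMatrix) -> None:
    """Dense header-free TSV plus a ``.meta.yaml`` sidecar with provenance."""
    np.savetxt(path, conn.W, delimiter="\t", fmt="%.12g")
    meta = {"pattern": conn.pattern, "seed": conn.seed, "n_regions": conn.n_regions}
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_matrix_tsv(path: Union[str, Path], pattern: Optional[str] = None) -> ConnectivityMatrix:
    W = np.loadtxt(path, delimiter="\t", ndmin=2)
    if pattern is None:
        meta_path = Path(str(path) + ".meta.yaml")
        pattern = "user"
        if meta_path.exists():
            pattern = yaml.safe_load(meta_path.read_text()).get("pattern", "user")
    return ConnectivityMatrix(W=W, pattern=pattern)


def write_matrix_npy(path: Union[str, Path], conn: ConnectivityMatrix) -> None:
    np.save(path, conn.W)


def read_matrix(path: Union[str, Path]) -> ConnectivityMatrix:
    """Dispatch on extension: ``.npy`` binary array or dense TSV."""
    p = Path(path)
    if p.suffix == ".npy":
        return ConnectivityMatrix(W=np.load(p), pattern="user")
    return read_matrix_tsv(p)


def write_table(
    path: Union[str, Path], df, metadata: Optional[dict] = None
) -> None:
    """Tab-separated table with a '#'-prefixed metadata header."""
    header = [f"# epitip {__version__}"]
    for k, v in (metadata or {}).items():
        header.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_trajectory_h5(path: Union[str, Path], traj, params=None) -> None:
    """Hierarchical container: times, counts/states, seed, parameter snapshot."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=np.asarray(traj.times))
        data = getattr(traj, "states", None)
        fh.create_dataset("states", data=np.asarray(data), compression="gzip")
        fh.attrs["seed"] = traj.seed
        fh.attrs["version"] = __version__
        if params is not None:
            fh.attrs["params"] = json.dumps(
                {k: (v if v is None or np.isfinite(v) else "inf")
                 for k, v in params.as_dict().items()}
            )


def read_trajectory_h5(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray, int]:
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["times"][()], fh["states"][()], int(fh.attrs["seed"])


def generate_fixtures(target_dir: Union[str, Path], n_regions: int = 50,
                      seed: int = 2026) -> dict:
    """Write the four connectivity classes, the default parameter bundle and
    miniature run configs.  Deterministic: identical files on re-run."""
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    w_uniform = 1.0 / (n_regions - 1)
    matrices = {
        "all_to_all": make_all_to_all(n_regions, w_uniform),
        "first_neighbors": make_first_neighbors(
            n_regions, 0.4, 0.6 / max(1, n_regions - 3)
        ),
        "ablated_first_neighbors": make_ablated_first_neighbors(n_regions, 0.5),
        "heterogeneous": make_heterogeneous(
            n_regions,
            _blocks(n_regions),
            weight_intra=0.22,
            weight_inter=0.015,
            seed=seed,
            jitter=0.2,
        ),
    }
    written = {}
    for name, conn in matrices.items():
        path = target / f"{name}.tsv"
        write_matrix_tsv(path, conn)
        written[name] = str(path)
    params, scaling = default_bistable(n_regions)
    ppath = target / "default_bistable.params"
    write_params(ppath, params, scaling)
    written["params"] = str(ppath)
    config = {
        "params": str(ppath),
        "matrix": written["all_to_all"],
        "outdir": str(target / "out"),
        "seed": seed,
        "analyses": {
            "bifurcate": {"parameter": "B", "range": [0.0, 25.0], "n_steps": 26},
            "robustness": {},
            "simulate_cg": {"t_end": 5.0, "dt": 0.01},
        },
    }
    cpath = target / "all_to_all_default.yaml"
    cpath.write_text(yaml.safe_dump(config, sort_keys=True))
    written["config"] = str(cpath)
    return written


def _blocks(n: int) -> list[int]:
    sizes = []
    remaining = n
    for b in (n // 3, n // 3):
        sizes.append(b)
        remaining -= b
    sizes.append(remaining)
    return sizes


def write_manifest(path: Union[str, Path], entries: dict) -> None:
    """Machine-readable run manifest with checksums of produced files."""
    manifest = {"version": __version__, "entries": {}}
    for key, value in entries.items():
        rec = {"value": str(value)}
        p = Path(str(value))
        if p.exists() and p.is_file():
            rec["sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest["entries"][key] = rec
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
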