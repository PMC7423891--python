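"""Text-format readers and writers: composition grids (CSV + JSON sidecar),
XYZ/LAMMPS-dump snapshots, length-trace CSV, and fit summaries as JSON.

All writers embed enough metadata (seed, composition, parameters) for their
readers to reproduce the objects bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .lattice import LatticeConfiguration
from .params import ModelParameters

__all__ = [
    "write_composition_csv", "read_composition_csv",
    "write_trace_csv", "read_trace_csv",
    "write_state_xyz", "write_state_dump",
    "write_fit_json", "read_config_file",
]

_ELEMENTS = {0: "C", 1: "N", 2: "O", 3: "Nd", 4: "Os", 5: "F", 6: "P"}


def write_composition_csv(config: LatticeConfiguration, path) -> None:
    """Composition grid as 0/1 CSV (rows x n_pf) with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, config.composition, fmt="%d", delimiter=",")
    meta = {
        "n_rows": config.n_rows,
        "n_pf": config.n_pf,
        "tether_rows": config.tether_rows,
        "seed": config.seed,
        "frac_uncompressed_nominal": config.frac_uncompressed_nominal,
        "seam_pf_pair": list(config.seam_pf_pair),
        "convention": "1 = uncompressed (GTP/GMPCPP-like), 0 = compressed (GDP-like)",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2) + "\n")


def read_composition_csv(path) -> LatticeConfiguration:
    path = Path(path)
    grid = np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return LatticeConfiguration(
        n_rows=grid.shape[0], n_pf=grid.shape[1], composition=grid,
        tether_rows=int(meta.get("tether_rows", 2)),
        seed=meta.get("seed"),
        frac_uncompressed_nominal=meta.get("frac_uncompressed_nominal"),
        seam_pf_pair=tuple(meta["seam_pf_pair"]) if "seam_pf_pair" in meta else None)


def write_trace_csv(trace, path) -> None:
    """Length trace as CSV columns: time_s, length_um, delta_um."""
    df = pd.DataFrame({
        "time_s": trace.times,
        "length_um": trace.length_um,
        "delta_um": trace.delta_um,
    })
    df.to_csv(path, index=False)


def read_trace_csv(path, source: str = "external"):
    from .kinetics import LengthTrace
    df = pd.read_csv(path)
    if not {"time_s", "length_um"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, length_um")
    return LengthTrace(times=df["time_s"].to_numpy(),
                       length_um=df["length_um"].to_numpy(), source=source)


def write_state_xyz(state, path, comment: str = "") -> None:
    """All beads and sites of the current state in XYZ text format."""
    pos, sub, ptype = state.particle_positions()
    lines = [str(len(pos)), comment or f"t={state.time:.4f} tau"]
    for p, t in zip(pos, ptype):
        lines.append(f"{_ELEMENTS[int(t)]} {p[0]:.5f} {p[1]:.5f} {p[2]:.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_state_dump(state, path) -> None:
    """LAMMPS-dump-style text: id, type, x, y, z per particle."""
    pos, sub, ptype = state.particle_positions()
    lines = [
        "ITEM: TIMESTEP",
        str(int(round(state.time / state.params.timestep))),
        "ITEM: NUMBER OF ATOMS",
        str(len(pos)),
        "ITEM: ATOMS id type x y z",
    ]
    for i, (p, t) in enumerate(zip(pos, ptype), start=1):
        lines.append(f"{i} {int(t)} {p[0]:.5f} {p[1]:.5f} {p[2]:.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory_xyz(traj, path, every: int = 1) -> None:
    """Multi-frame XYZ of subunit centers plus a CSV sidecar of per-frame
    summary metrics (time in tau and seconds, intact rows)."""
    from .kinetics import intact_row_count

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cache: dict = {}
    lines = []
    rows = []
    for i in range(0, traj.n_frames, every):
        state = traj.frame_state(i)
        centers = state.grid_center_positions()
        lines.append(str(len(centers)))
        lines.append(f"t={traj.times[i]:.4f} tau")
        for bt, c in zip(state.body_type, centers):
            lines.append(f"{_ELEMENTS[0] if bt == 2 else 'Si'} "
                         f"{c[0]:.4f} {c[1]:.4f} {c[2]:.4f}")
        rows.append((traj.times[i],
                     traj.times[i] / traj.params.tau_per_second,
                     intact_row_count(traj, i, _cache=cache)))
    path.write_text("\n".join(lines) + "\n")
    side = pd.DataFrame(rows, columns=["time_tau", "time_s", "intact_rows"])
    side.to_csv(path.with_suffix(path.suffix + ".summary.csv"), index=False)


def write_clusters_json(cluster_set, path) -> None:
    """Cluster member lists plus lattice metadata as JSON."""
    data = {
        "seam": cluster_set.seam,
        "n_rows": cluster_set.lattice_ref.n_rows,
        "n_pf": cluster_set.lattice_ref.n_pf,
        "sizes": cluster_set.sizes.tolist(),
        "clusters": [[list(m) for m in c] for c in cluster_set.clusters],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data) + "\n")


def write_fit_json(fit, path, extra: Optional[dict] = None) -> None:
    """Fit summary (any NamedTuple/dataclass-like with _asdict) as JSON."""
    if hasattr(fit, "_asdict"):
        data = dict(fit._asdict())
    elif hasattr(fit, "__dict__"):
        data = dict(vars(fit))
    else:
        data = dict(fit)
    if extra:
        data.update(extra)
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_config_file(path) -> dict:
    """Flat key-value run configuration (TOML)."""
    import tomllib
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def params_from_config(data: dict) -> ModelParameters:
    return ModelParameters.from_dict(data)
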