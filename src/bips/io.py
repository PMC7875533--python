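"""File formats: TSV traces, TIFF images with JSON sidecars, extended XYZ
trajectories, and contact-map TSV.

Images carry their physical calibration (pixel size, frame interval) and
any attached ground truth in a ``<name>.json`` sidecar next to the TIFF, so
a dataset is self-describing; traces are plain two-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .contacts import ContactMap
from .kinetics import IntensityTrace, Kymograph
from .morphology import HeightMap
from .simulator import SimState, Trajectory
from .synthetic import GroundTruth

__all__ = [
    "save_trace",
    "load_trace",
    "save_kymograph",
    "load_kymograph",
    "save_heightmap",
    "load_heightmap",
    "save_trajectory_xyz",
    "save_contact_map",
    "load_contact_map",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_trace(path, trace: IntensityTrace) -> None:
    """Two-column TSV: time_s, intensity."""
    pd.DataFrame(
        {"time_s": trace.time_s, "intensity": trace.intensity}
    ).to_csv(path, sep="\t", index=False)


def load_trace(path) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    return IntensityTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy())


def _write_sidecar(path: Path, meta: dict, truth: GroundTruth | None) -> None:
    side = dict(meta)
    if truth is not None:
        side["ground_truth"] = _jsonable(truth.params)
    path.with_suffix(".json").write_text(json.dumps(_jsonable(side), indent=1))


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}


def save_kymograph(path, kym: Kymograph, truth: GroundTruth | None = None):
    path = Path(path)
    tifffile.imwrite(path, kym.data.astype(np.float32))
    _write_sidecar(
        path,
        {
            "frame_interval_s": kym.frame_interval_s,
            "pixel_size_um": kym.pixel_size_um,
            **kym.meta,
        },
        truth,
    )


def load_kymograph(path) -> Kymograph:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path)
    return Kymograph(
        data,
        float(meta.get("frame_interval_s", 1.0)),
        float(meta.get("pixel_size_um", 0.1)),
        meta,
    )


def save_heightmap(path, hmap: HeightMap, truth: GroundTruth | None = None):
    path = Path(path)
    tifffile.imwrite(path, hmap.data.astype(np.float32))
    _write_sidecar(path, {"pixel_size_nm": hmap.pixel_size_nm, **hmap.meta}, truth)


def load_heightmap(path) -> HeightMap:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path)
    return HeightMap(data, float(meta.get("pixel_size_nm", 1.0)), meta)


def save_trajectory_xyz(path, traj: Trajectory) -> None:
    """Extended XYZ, one block per snapshot; bridge bonds in a .bonds.tsv.

    The comment line carries step, box edge (sigma) and seed; bead lines are
    tagged D (DNA) and bridge lines B.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for st in traj:
            n = st.positions.shape[0]
            fh.write(f"{n}\n")
            fh.write(
                f"step={st.time_steps} box={st.box:.6g} "
                f"seed={traj.params.seed}\n"
            )
            for i in range(st.n_beads):
                x, y, z = st.positions[i]
                fh.write(f"D {x:.5f} {y:.5f} {z:.5f}\n")
            for i in range(st.n_beads, n):
                x, y, z = st.positions[i]
                fh.write(f"B {x:.5f} {y:.5f} {z:.5f}\n")
    rows = []
    for st in traj:
        for b, bead in st.bonds():
            rows.append({"step": st.time_steps, "bridge": b, "bead": bead})
    pd.DataFrame(rows, columns=["step", "bridge", "bead"]).to_csv(
        path.with_suffix(".bonds.tsv"), sep="\t", index=False
    )


def save_contact_map(path, cmap: ContactMap) -> None:
    path = Path(path)
    np.savetxt(path, cmap.matrix, delimiter="\t", fmt="%.6g")
    _write_sidecar(
        path, {"r_c": cmap.r_c, "n_snapshots": cmap.n_snapshots}, None
    )


def load_contact_map(path) -> ContactMap:
    path = Path(path)
    m = np.loadtxt(path, delimiter="\t")
    meta = _read_sidecar(path)
    return ContactMap(
        m, float(meta.get("r_c", 2.5)), int(meta.get("n_snapshots", 1))
    )
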