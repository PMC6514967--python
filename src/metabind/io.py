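"""Plain-text trajectory and manifest I/O.

Trajectories travel as extended multi-frame XYZ: the comment line of each
frame carries ``cv=… time=… walker=…`` so a FrameSet round-trips losslessly
(atom grouping is stored in a sidecar JSON header line of the file).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .frames import FrameSet

__all__ = ["write_xyz", "read_xyz", "write_manifest", "read_manifest"]


def write_xyz(path, frames: FrameSet, element: str = "C") -> None:
    """Write a FrameSet as multi-frame XYZ (coordinates converted nm → Å)."""
    groups = {"backbone": frames.backbone_indices.tolist(),
              "ligand": frames.ligand_indices.tolist()}
    with open(path, "w") as fh:
        fh.write(f"# groups {json.dumps(groups)}\n")
        for i in range(len(frames)):
            fh.write(f"{frames.n_atoms}\n")
            fh.write(f"cv={frames.cv[i]:.9f} time={frames.time[i]:.6f} "
                     f"walker={frames.walker_id[i]}\n")
            for x, y, z in frames.coordinates[i] * 10.0:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> FrameSet:
    """Read a multi-frame XYZ written by :func:`write_xyz` (Å → nm)."""
    coords, cvs, times, walkers = [], [], [], []
    groups = {"backbone": [], "ligand": []}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# groups"):
            groups = json.loads(first.split("groups", 1)[1])
            line = fh.readline()
        else:
            line = first
        while line:
            n = int(line.strip())
            comment = fh.readline().split()
            meta = dict(kv.split("=") for kv in comment if "=" in kv)
            frame = np.empty((n, 3))
            for a in range(n):
                parts = fh.readline().split()
                frame[a] = [float(v) for v in parts[1:4]]
            coords.append(frame / 10.0)
            cvs.append(float(meta.get("cv", "nan")))
            times.append(float(meta.get("time", "0")))
            walkers.append(int(meta.get("walker", "0")))
            line = fh.readline()
    return FrameSet(np.array(coords), np.array(cvs), np.array(times),
                    np.array(walkers),
                    backbone_indices=np.array(groups["backbone"], dtype=int),
                    ligand_indices=np.array(groups["ligand"], dtype=int))


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_default)
                          + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
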