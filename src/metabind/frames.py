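"""Trajectory frame container shared by the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSet"]


@dataclass
class FrameSet:
    """A set of trajectory frames with per-frame collective-variable values.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in nm; all frames share atom count and order.
    cv : ndarray, shape (n_frames,)
        Binding collective variable of each frame (nm).
    time : ndarray, shape (n_frames,)
        Simulation time of each frame (ps).
    walker_id : ndarray, shape (n_frames,)
        Integer id of the walker that produced each frame.
    backbone_indices : ndarray
        Atom indices of the receptor backbone (superposition set).
    ligand_indices : ndarray
        Atom indices of the ligand heavy atoms (clustering set).
    """

    coordinates: np.ndarray
    cv: np.ndarray
    time: np.ndarray
    walker_id: np.ndarray
    backbone_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ligand_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.walker_id = np.asarray(self.walker_id, dtype=int)
        self.backbone_indices = np.asarray(self.backbone_indices, dtype=int)
        self.ligand_indices = np.asarray(self.ligand_indices, dtype=int)
        n = len(self.coordinates)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if not (len(self.cv) == len(self.time) == len(self.walker_id) == n):
            raise ValueError("per-frame arrays must all have the same length")
        if n and not np.all(np.isfinite(self.cv)):
            raise ValueError("CV values must be finite")

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def subset(self, index) -> "FrameSet":
        """Return a new FrameSet containing the selected frames."""
        index = np.asarray(index)
        return FrameSet(
            coordinates=self.coordinates[index],
            cv=self.cv[index],
            time=self.time[index],
            walker_id=self.walker_id[index],
            backbone_indices=self.backbone_indices,
            ligand_indices=self.ligand_indices,
        )

    @staticmethod
    def concatenate(framesets: list["FrameSet"]) -> "FrameSet":
        """Pool several FrameSets (same atom layout) into one."""
        if not framesets:
            raise ValueError("nothing to concatenate")
        first = framesets[0]
        return FrameSet(
            coordinates=np.concatenate([f.coordinates for f in framesets]),
            cv=np.concatenate([f.cv for f in framesets]),
            time=np.concatenate([f.time for f in framesets]),
            walker_id=np.concatenate([f.walker_id for f in framesets]),
            backbone_indices=first.backbone_indices,
            ligand_indices=first.ligand_indices,
        )
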