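"""Binding-mode determination: frame extraction around the free-energy
minimum, backbone superposition, unfitted ligand-RMSD clustering and
population-ranked reporting.

The protocol extracts every multiple-walker frame whose CV lies within
ΔCV ≤ 3 Å of the free-energy minimum, superposes each frame on the receptor
backbone (Kabsch least-squares fit), then clusters on the *unfitted* RMSD of
the ligand heavy atoms — no second fit, so ligand orientation relative to
the receptor is what distinguishes clusters.  Hierarchical agglomerative
(average-linkage) clustering is cut at a target of five clusters, clusters
are ranked by population, and each cluster is represented by the member with
the smallest total RMSD to its cluster mates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .constants import NM_TO_ANGSTROM
from .frames import FrameSet

__all__ = [
    "ExtractionParams",
    "ClusterResult",
    "EmptySelectionError",
    "DegenerateBackboneError",
    "extract_frames",
    "superpose_backbone",
    "ligand_rmsd",
    "cluster_frames",
    "pocket_atom_indices",
    "report_clusters",
]


class EmptySelectionError(ValueError):
    """No frames fall inside the extraction window."""


class DegenerateBackboneError(ValueError):
    """Backbone atoms are collinear; the superposition is underdetermined."""


@dataclass(frozen=True)
class ExtractionParams:
    """Half-width of the CV window around the minimum (nm); default
    0.3 nm = 3 Å."""

    delta_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.delta_cv <= 0:
            raise ValueError("delta_cv must be positive")


def extract_frames(frames: FrameSet, minimum_cv: float,
                   params: ExtractionParams = ExtractionParams()):
    """Select frames with |cv − minimum_cv| ≤ delta_cv (closed interval).

    Returns ``(selected, fraction)`` with the fraction in percent of the
    input frames.
    """
    if len(frames) == 0:
        raise ValueError("no frames to extract from")
    # closed interval; the epsilon keeps boundary frames in despite float
    # representation error (0.8 - 0.5 > 0.3 in doubles)
    mask = np.abs(frames.cv - minimum_cv) <= params.delta_cv + 1e-12
    if not mask.any():
        raise EmptySelectionError(
            f"no frames within {params.delta_cv} nm of CV {minimum_cv}; "
            "consider a larger delta_cv")
    fraction = 100.0 * mask.sum() / len(frames)
    return frames.subset(np.flatnonzero(mask)), float(fraction)


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rotation + translation mapping mobile onto reference."""
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    a = mobile - mob_center
    b = reference - ref_center
    sv = np.linalg.svd(a.T @ b, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1.0):
        raise DegenerateBackboneError(
            "backbone atoms are (nearly) collinear; superposition is "
            "underdetermined")
    rot, _ = Rotation.align_vectors(b, a)
    return rot, mob_center, ref_center


def superpose_backbone(frames: FrameSet, reference_frame: np.ndarray) -> FrameSet:
    """Rigidly fit every frame's backbone onto the reference frame's
    backbone (Kabsch); ligand atoms are co-transformed."""
    ref = np.asarray(reference_frame, dtype=float)
    bb = frames.backbone_indices
    if len(bb) < 3:
        raise DegenerateBackboneError("need at least 3 backbone atoms")
    out = np.empty_like(frames.coordinates)
    ref_bb = ref[bb]
    for i, coords in enumerate(frames.coordinates):
        rot, mob_center, ref_center = _kabsch(coords[bb], ref_bb)
        out[i] = rot.apply(coords - mob_center) + ref_center
    return FrameSet(out, frames.cv.copy(), frames.time.copy(),
                    frames.walker_id.copy(), bb, frames.ligand_indices)


def ligand_rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
                atom_selection) -> float:
    """Unfitted coordinate RMSD over a selection, in Å.

    No superposition is performed here; coordinates are compared as
    positioned by the preceding backbone fit.
    """
    sel = np.asarray(atom_selection, dtype=int)
    a = np.asarray(frame_a, dtype=float)[sel]
    b = np.asarray(frame_b, dtype=float)[sel]
    if a.shape != b.shape:
        raise ValueError("selections are not congruent between frames")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))) * NM_TO_ANGSTROM


@dataclass
class ClusterResult:
    """Population-ranked clustering of extracted frames.

    ``labels`` assigns each input frame to a cluster numbered 1..k in
    descending population; ``populations`` are percentages of the input
    frames; ``representative_indices`` point into the clustered FrameSet.
    ``rmsd_to_reference`` (per-cluster ligand and pocket RMSD, Å) is filled
    by :func:`report_clusters` when a reference is available.
    """

    labels: np.ndarray
    populations: np.ndarray
    representative_indices: np.ndarray
    linkage_log: np.ndarray
    n_clusters: int
    truncated: bool = False
    rmsd_to_reference: pd.DataFrame | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_frames(frames: FrameSet, n_clusters: int = 5) -> ClusterResult:
    """Average-linkage agglomerative clustering on unfitted ligand RMSD.

    The unfitted RMSD between two backbone-superposed frames equals the
    Euclidean distance between their flattened ligand coordinates divided by
    √(n_ligand_atoms), so the condensed distance matrix is computed with a
    single ``pdist``.  Clusters are renumbered 1..k by descending population
    (ties by first occurrence); the representative of a cluster is its
    member with the minimal sum of RMSDs to all other members.

    If the input holds fewer *distinct* conformations than ``n_clusters``
    the achievable number is returned with ``truncated=True``; fewer frames
    than clusters is an error.
    """
    n = len(frames)
    if n_clusters < 1:
        raise ValueError("n_clusters must be at least 1")
    if n < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from {n} frames")
    lig = frames.coordinates[:, frames.ligand_indices, :]
    n_atoms = lig.shape[1]
    x = lig.reshape(n, -1)
    n_distinct = len(np.unique(x, axis=0))
    k = min(n_clusters, n_distinct)
    truncated = k < n_clusters
    condensed = pdist(x) / np.sqrt(n_atoms) * NM_TO_ANGSTROM  # Å
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=k, criterion="maxclust")

    # rank clusters by population, ties by first occurrence
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = np.array([np.flatnonzero(raw == c)[0] for c in ids])
    order = np.lexsort((first_seen, -counts))
    relabel = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    populations = np.array(counts[order], dtype=float) / n * 100.0

    dm = squareform(condensed)
    reps = np.empty(len(ids), dtype=int)
    for c in range(1, len(ids) + 1):
        members = np.flatnonzero(labels == c)
        sums = dm[np.ix_(members, members)].sum(axis=1)
        reps[c - 1] = members[np.argmin(sums)]
    return ClusterResult(labels=labels, populations=populations,
                         representative_indices=reps, linkage_log=z,
                         n_clusters=len(ids), truncated=truncated)


def pocket_atom_indices(reference_frame: np.ndarray, backbone_indices,
                        ligand_indices, cutoff_nm: float = 0.5) -> np.ndarray:
    """Backbone atoms with any atom within ``cutoff_nm`` of the reference
    ligand — the orthosteric-pocket selection (5 Å in the GPCR tables)."""
    ref = np.asarray(reference_frame, dtype=float)
    bb = np.asarray(backbone_indices, dtype=int)
    lig = ref[np.asarray(ligand_indices, dtype=int)]
    d = np.linalg.norm(ref[bb][:, None, :] - lig[None, :, :], axis=2)
    return bb[(d <= cutoff_nm).any(axis=1)]


def report_clusters(result: ClusterResult, frames: FrameSet,
                    reference_frame: np.ndarray | None = None,
                    pocket_cutoff_nm: float = 0.5) -> pd.DataFrame:
    """Tabulate clusters: population %, and — when a reference structure is
    supplied — ligand and pocket RMSD to the reference (Å).

    The reference frame must hold full-system coordinates with the ligand in
    the reference binding mode, already in the backbone frame used for
    superposition.  Also stores the table on ``result.rmsd_to_reference``.
    """
    rows = []
    for c in range(1, result.n_clusters + 1):
        rep = result.representative_indices[c - 1]
        row = {"cluster": c,
               "population_pct": round(float(result.populations[c - 1]), 4),
               "representative_frame": int(rep)}
        if reference_frame is not None:
            ref = np.asarray(reference_frame, dtype=float)
            rep_coords = frames.coordinates[rep]
            row["ligand_rmsd_A"] = round(
                ligand_rmsd(rep_coords, ref, frames.ligand_indices), 2)
            pocket = pocket_atom_indices(ref, frames.backbone_indices,
                                         frames.ligand_indices,
                                         pocket_cutoff_nm)
            row["pocket_rmsd_A"] = round(
                ligand_rmsd(rep_coords, ref, pocket), 2)
        rows.append(row)
    table = pd.DataFrame(rows)
    result.rmsd_to_reference = table
    return table
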