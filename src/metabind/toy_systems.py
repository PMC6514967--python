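"""Synthetic receptor–ligand toy systems with analytically known free energies.

Two system families support validation of the binding-mode protocol at desk
scale:

* a 1D **double well** along the binding CV whose basin free-energy
  difference is calibrated at build time to a requested ΔF, used to validate
  the metadynamics engine and the free-energy reconstruction, and
* a 3D **binding system**: a frozen pseudo-receptor scaffold with a pocket,
  a rigid four-bead ligand, a planted bound pose (the global potential
  minimum), a planted metastable decoy pose in a reversed orientation, and
  an open channel along +z to a solvent region — a miniature analogue of a
  GPCR orthosteric site used to validate extraction, clustering and
  refinement.

A separate generator plants multi-mode conformational ensembles with known
cluster populations for validating the clustering stage in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, KB
from .frames import FrameSet

__all__ = [
    "AnalyticFES",
    "ToySystem",
    "PlantedEnsembleSpec",
    "make_double_well",
    "make_binding_system",
    "sample_planted_ensemble",
    "save_system",
    "load_system",
]


# ---------------------------------------------------------------------------
# analytic free-energy profiles
# ---------------------------------------------------------------------------

class AnalyticFES:
    """Closed-form free energy along the CV, tabulated on a uniform grid."""

    def __init__(self, grid: np.ndarray, free_energy: np.ndarray):
        self.grid = np.asarray(grid, dtype=float)
        self.free_energy = np.asarray(free_energy, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.free_energy.shape:
            raise ValueError("grid and free_energy must be matching 1D arrays")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")

    def __call__(self, s):
        return np.interp(s, self.grid, self.free_energy)

    def partition_function(self, temperature: float) -> float:
        """Boltzmann integral over the full CV range (trapezoid rule)."""
        kT = KB * temperature
        return float(np.trapezoid(np.exp(-(self.free_energy - self.free_energy.min()) / kT),
                                  self.grid))

    def divider(self) -> float:
        """CV of the interior free-energy maximum between the two outermost
        minima (the basin boundary for two-basin profiles)."""
        f = self.free_energy
        lo, hi = np.argmin(f[: len(f) // 2]), len(f) // 2 + np.argmin(f[len(f) // 2:])
        inner = slice(lo, hi + 1)
        return float(self.grid[inner][np.argmax(f[inner])])

    def basin_delta_f(self, temperature: float, divider: float | None = None) -> float:
        """ΔF = F(right basin) − F(left basin) from Boltzmann integration.

        Basins are split at `divider` (default: the interior maximum).
        """
        kT = KB * temperature
        div = self.divider() if divider is None else divider
        w = np.exp(-(self.free_energy - self.free_energy.min()) / kT)
        left = np.trapezoid(np.where(self.grid <= div, w, 0.0), self.grid)
        right = np.trapezoid(np.where(self.grid >= div, w, 0.0), self.grid)
        return float(-kT * np.log(right / left))


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

class DoubleWellPotential:
    """Tilted quartic double well along z for a single mobile particle.

        U(z) = barrier·((z/a)² − 1)² + tilt·z,   a = well_separation / 2

    plus a weak transverse harmonic (k_t) keeping x and y bounded.  The tilt
    is calibrated by the builder so the Boltzmann basin ΔF matches a request.
    """

    kind = "double_well"

    def __init__(self, barrier: float, half_separation: float, tilt: float,
                 mobile_index: int = 1, k_transverse: float = 50.0):
        self.barrier = float(barrier)
        self.a = float(half_separation)
        self.tilt = float(tilt)
        self.mobile_index = int(mobile_index)
        self.k_transverse = float(k_transverse)

    def energy_1d(self, z):
        zr = np.asarray(z, dtype=float) / self.a
        return self.barrier * (zr**2 - 1.0) ** 2 + self.tilt * np.asarray(z, dtype=float)

    def gradient_1d(self, z):
        z = np.asarray(z, dtype=float)
        zr = z / self.a
        return self.barrier * 4.0 * zr * (zr**2 - 1.0) / self.a + self.tilt

    def energy(self, coords: np.ndarray) -> float:
        x, y, z = coords[self.mobile_index]
        return float(self.energy_1d(z) + 0.5 * self.k_transverse * (x * x + y * y))

    def forces(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        x, y, z = coords[self.mobile_index]
        f[self.mobile_index, 0] = -self.k_transverse * x
        f[self.mobile_index, 1] = -self.k_transverse * y
        f[self.mobile_index, 2] = -float(self.gradient_1d(z))
        return f

    def to_dict(self) -> dict:
        return {"kind": self.kind, "barrier": self.barrier,
                "half_separation": self.a, "tilt": self.tilt,
                "mobile_index": self.mobile_index,
                "k_transverse": self.k_transverse}

    @classmethod
    def from_dict(cls, d: dict) -> "DoubleWellPotential":
        d = dict(d)
        d.pop("kind", None)
        return cls(**d)


class BindingPotential:
    """Pose-attraction potential for the rigid-ligand binding system.

    Each planted pose P contributes an (optionally anisotropic) Gaussian
    well in pose space,

        E_pose(X) = −depth · exp(−Σᵢ [ (dxᵢ²+dyᵢ²)/(2·n·σ_xy²)
                                       + dzᵢ²/(2·n·σ_z²) ]),

    whose minimum is exactly the pose, so the bound pose is the global
    minimum by construction.  A tighter width along z (the binding-channel
    axis) than transverse mimics a sterically defined pocket and sharpens
    the free-energy minimum along the CV.  Stiff harmonic springs between
    all ligand bead pairs keep the ligand effectively rigid, and a
    short-range Gaussian repulsion from the scaffold beads closes the
    pocket walls.
    """

    kind = "binding"

    def __init__(self, pose_centers: Sequence[np.ndarray],
                 pose_depths: Sequence[float],
                 pose_sigmas: Sequence[tuple[float, float]],
                 ligand_indices: Sequence[int], scaffold_indices: Sequence[int],
                 bond_pairs: Sequence[tuple[int, int]],
                 bond_lengths: Sequence[float], k_bond: float = 8000.0,
                 repulsion_eps: float = 30.0, repulsion_sigma: float = 0.10):
        self.pose_centers = [np.asarray(p, dtype=float) for p in pose_centers]
        self.pose_depths = [float(d) for d in pose_depths]
        self.pose_sigmas = [(float(sxy), float(sz)) for sxy, sz in pose_sigmas]
        if not (len(self.pose_centers) == len(self.pose_depths)
                == len(self.pose_sigmas)):
            raise ValueError("pose lists must have matching lengths")
        self.ligand_indices = np.asarray(ligand_indices, dtype=int)
        self.scaffold_indices = np.asarray(scaffold_indices, dtype=int)
        self.bond_pairs = [(int(i), int(j)) for i, j in bond_pairs]
        self.bond_lengths = [float(b) for b in bond_lengths]
        self.k_bond = float(k_bond)
        self.repulsion_eps = float(repulsion_eps)
        self.repulsion_sigma = float(repulsion_sigma)
        n = len(self.ligand_indices)
        # per-pose per-axis inverse scales: Q_p = sum(diff^2 * w[p, axis])
        self._pose_w = np.array(
            [[1.0 / (2.0 * n * sxy**2)] * 2 + [1.0 / (2.0 * n * sz**2)]
             for sxy, sz in self.pose_sigmas])               # (P, 3)
        self._pose_w = self._pose_w[:, None, :]              # (P, 1, 3)
        self._pose_stack = np.stack(self.pose_centers)       # (P, n, 3)
        self._depths = np.array(self.pose_depths)
        self._pairs_i = np.array([i for i, _ in self.bond_pairs], dtype=int)
        self._pairs_j = np.array([j for _, j in self.bond_pairs], dtype=int)
        self._b0 = np.array(self.bond_lengths)

    def ligand_field_energy(self, lig: np.ndarray) -> float:
        """Pose-well + scaffold-repulsion energy of a rigid ligand placement
        (no bond terms; they vanish for rigid placements)."""
        return float(self.ligand_field_energy_batch(
            np.asarray(lig, dtype=float)[None])[0])

    def ligand_field_energy_batch(self, ligs: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`ligand_field_energy` for placements of shape
        (n_placements, n_beads, 3)."""
        ligs = np.asarray(ligs, dtype=float)
        e = np.zeros(len(ligs))
        for center, depth, w in zip(self.pose_centers, self.pose_depths,
                                    self._pose_w):
            q = np.sum((ligs - center) ** 2 * w, axis=(1, 2))
            e += -depth * np.exp(-q)
        if self.repulsion_eps and hasattr(self, "_scaffold_coords"):
            diff = ligs[:, :, None, :] - self._scaffold_coords[None, None, :, :]
            d2 = np.sum(diff * diff, axis=3)
            e += np.sum(self.repulsion_eps *
                        np.exp(-d2 / (2.0 * self.repulsion_sigma**2)),
                        axis=(1, 2))
        return e

    def _repulsion(self, lig: np.ndarray):
        if (self.repulsion_eps == 0.0 or len(self.scaffold_indices) == 0
                or not hasattr(self, "_scaffold_coords")):
            return 0.0, np.zeros_like(lig)
        diff = lig[:, None, :] - self._scaffold_coords[None, :, :]
        d2 = np.sum(diff * diff, axis=2)
        w = self.repulsion_eps * np.exp(-d2 / (2.0 * self.repulsion_sigma**2))
        e = float(np.sum(w))
        # d/dlig of eps*exp(-d2/(2s2)) = -(w/s2) * diff
        grad = np.sum((-(w / self.repulsion_sigma**2))[:, :, None] * diff, axis=1)
        return e, grad

    def bind_scaffold(self, scaffold_coords: np.ndarray) -> None:
        """Cache the (frozen) scaffold coordinates used by the repulsion."""
        self._scaffold_coords = np.asarray(scaffold_coords, dtype=float)

    def energy(self, coords: np.ndarray) -> float:
        lig = coords[self.ligand_indices]
        diff = lig[None, :, :] - self._pose_stack
        q = np.einsum("pij,pij->p", diff * self._pose_w, diff)
        e = float(np.sum(-self._depths * np.exp(-q)))
        e += self._repulsion(lig)[0]
        rij = coords[self._pairs_i] - coords[self._pairs_j]
        d = np.sqrt(np.einsum("ij,ij->i", rij, rij))
        e += 0.5 * self.k_bond * float(np.sum((d - self._b0) ** 2))
        return e

    def forces(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        lig = coords[self.ligand_indices]
        diff = lig[None, :, :] - self._pose_stack
        q = np.einsum("pij,pij->p", diff * self._pose_w, diff)
        e_pose = -self._depths * np.exp(-q)                       # (P,)
        # dE/dlig = -E * 2 w ⊙ diff, summed over poses
        grad = np.einsum("p,pij->ij", -2.0 * e_pose, diff * self._pose_w)
        grad += self._repulsion(lig)[1]
        f[self.ligand_indices] -= grad
        rij = coords[self._pairs_i] - coords[self._pairs_j]
        d = np.sqrt(np.einsum("ij,ij->i", rij, rij))
        fij = (-self.k_bond * (d - self._b0) / np.maximum(d, 1e-12))[:, None] * rij
        np.add.at(f, self._pairs_i, fij)
        np.add.at(f, self._pairs_j, -fij)
        return f

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "pose_centers": [p.tolist() for p in self.pose_centers],
            "pose_depths": self.pose_depths,
            "pose_sigmas": [list(s) for s in self.pose_sigmas],
            "ligand_indices": self.ligand_indices.tolist(),
            "scaffold_indices": self.scaffold_indices.tolist(),
            "bond_pairs": [list(p) for p in self.bond_pairs],
            "bond_lengths": self.bond_lengths,
            "k_bond": self.k_bond,
            "repulsion_eps": self.repulsion_eps,
            "repulsion_sigma": self.repulsion_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BindingPotential":
        d = dict(d)
        d.pop("kind", None)
        return cls(**d)


_POTENTIALS = {"double_well": DoubleWellPotential, "binding": BindingPotential}


# ---------------------------------------------------------------------------
# the ToySystem container
# ---------------------------------------------------------------------------

@dataclass
class ToySystem:
    """A synthetic receptor–ligand system.

    ``labels`` holds a tuple of group labels per atom drawn from
    ``receptor_backbone``, ``ligand_heavy``, ``cv_receptor_atom`` and
    ``cv_ligand_atom``; exactly one atom carries each of the two CV labels.
    ``frozen`` marks atoms excluded from integration (the rigid scaffold).
    """

    name: str
    potential: object
    coordinates: np.ndarray          # (n_atoms, 3) initial coordinates, nm
    masses: np.ndarray               # (n_atoms,) amu
    labels: list[tuple[str, ...]]
    frozen: np.ndarray               # (n_atoms,) bool
    reference_pose: np.ndarray       # (n_ligand, 3) known bound mode
    analytic_fes: AnalyticFES | None = None
    temperature: float = DEFAULT_TEMPERATURE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        self.reference_pose = np.asarray(self.reference_pose, dtype=float)
        n = len(self.coordinates)
        if not (len(self.masses) == len(self.labels) == len(self.frozen) == n):
            raise ValueError("per-atom arrays must have matching lengths")
        if len(self._indices_with("cv_receptor_atom")) != 1:
            raise ValueError("exactly one cv_receptor_atom must be designated")
        if len(self._indices_with("cv_ligand_atom")) != 1:
            raise ValueError("exactly one cv_ligand_atom must be designated")
        if self.reference_pose.shape != (len(self.ligand_indices), 3):
            raise ValueError("reference_pose must match the ligand_heavy group")

    def _indices_with(self, label: str) -> np.ndarray:
        return np.array([i for i, labs in enumerate(self.labels) if label in labs],
                        dtype=int)

    @property
    def cv_receptor_index(self) -> int:
        return int(self._indices_with("cv_receptor_atom")[0])

    @property
    def cv_ligand_index(self) -> int:
        return int(self._indices_with("cv_ligand_atom")[0])

    @property
    def ligand_indices(self) -> np.ndarray:
        return self._indices_with("ligand_heavy")

    @property
    def backbone_indices(self) -> np.ndarray:
        return self._indices_with("receptor_backbone")

    def compute_cv(self, coordinates: np.ndarray) -> float:
        from .restraints import binding_cv
        return binding_cv(coordinates, self.cv_receptor_index, self.cv_ligand_index)

    @property
    def reference_cv(self) -> float:
        """CV value of the planted bound pose."""
        coords = self.coordinates.copy()
        coords[self.ligand_indices] = self.reference_pose
        return self.compute_cv(coords)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "potential": self.potential.to_dict(),
            "coordinates": self.coordinates.tolist(),
            "masses": self.masses.tolist(),
            "labels": [list(l) for l in self.labels],
            "frozen": self.frozen.tolist(),
            "reference_pose": self.reference_pose.tolist(),
            "temperature": self.temperature,
            "metadata": _jsonify(self.metadata),
        }
        if self.analytic_fes is not None:
            d["analytic_fes"] = {"grid": self.analytic_fes.grid.tolist(),
                                 "free_energy": self.analytic_fes.free_energy.tolist()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystem":
        pot_dict = d["potential"]
        potential = _POTENTIALS[pot_dict["kind"]].from_dict(pot_dict)
        fes = None
        if "analytic_fes" in d and d["analytic_fes"] is not None:
            fes = AnalyticFES(np.array(d["analytic_fes"]["grid"]),
                              np.array(d["analytic_fes"]["free_energy"]))
        system = cls(
            name=d["name"],
            potential=potential,
            coordinates=np.array(d["coordinates"]),
            masses=np.array(d["masses"]),
            labels=[tuple(l) for l in d["labels"]],
            frozen=np.array(d["frozen"], dtype=bool),
            reference_pose=np.array(d["reference_pose"]),
            analytic_fes=fes,
            temperature=float(d.get("temperature", DEFAULT_TEMPERATURE)),
            metadata=d.get("metadata", {}),
        )
        if isinstance(potential, BindingPotential):
            potential.bind_scaffold(system.coordinates[potential.scaffold_indices])
        return system


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_system(system: ToySystem, path) -> None:
    """Serialize a ToySystem to a YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(system.to_dict(), fh, sort_keys=False)


def load_system(path) -> ToySystem:
    with open(path) as fh:
        return ToySystem.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def make_double_well(delta_f: float, barrier: float, well_separation: float,
                     temperature: float = DEFAULT_TEMPERATURE) -> ToySystem:
    """One mobile particle in a tilted quartic double well along the CV.

    The linear tilt is solved (Brent's method on the trapezoid-rule Boltzmann
    integral) so that the free-energy difference F(upper basin) − F(lower
    basin) equals ``delta_f`` exactly at temperature ``temperature``.  The
    particle's z coordinate relative to a frozen anchor at the origin is the
    binding CV, so ``analytic_fes`` is the 1D potential itself.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if well_separation <= 0:
        raise ValueError("well_separation must be positive")
    a = well_separation / 2.0
    grid = np.linspace(-a - 1.2 * a, a + 1.2 * a, 4001)

    def delta_f_of_tilt(tilt: float) -> float:
        pot = DoubleWellPotential(barrier, a, tilt)
        fes = AnalyticFES(grid, pot.energy_1d(grid))
        return fes.basin_delta_f(temperature)

    if delta_f == 0.0:
        tilt = 0.0
    else:
        # ΔF is monotone increasing in the tilt; bracket and solve
        span = abs(delta_f) / well_separation * 4.0 + 1.0
        tilt = brentq(lambda c: delta_f_of_tilt(c) - delta_f, -span, span,
                      xtol=1e-12)
    potential = DoubleWellPotential(barrier, a, tilt)
    fes = AnalyticFES(grid, potential.energy_1d(grid) -
                      potential.energy_1d(grid).min())
    # reference pose: the deeper basin's minimum
    zmin = grid[np.argmin(fes.free_energy)]
    system = ToySystem(
        name="double_well",
        potential=potential,
        coordinates=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, zmin]]),
        masses=np.array([100.0, 14.0]),
        labels=[("receptor_backbone", "cv_receptor_atom"),
                ("ligand_heavy", "cv_ligand_atom")],
        frozen=np.array([True, False]),
        reference_pose=np.array([[0.0, 0.0, zmin]]),
        analytic_fes=fes,
        temperature=temperature,
        metadata={"delta_f": float(delta_f), "barrier": float(barrier),
                  "well_separation": float(well_separation),
                  "divider_cv": fes.divider()},
    )
    return system


# rigid 4-bead ligand template (local frame, nm); asymmetric so that flipped
# orientations are distinguishable by RMSD
_LIGAND_TEMPLATE = np.array([
    [0.00, 0.00, 0.00],   # bead 0: amine-nitrogen analogue (the CV atom)
    [0.15, 0.00, 0.00],
    [0.30, 0.00, 0.00],
    [0.15, 0.13, 0.00],
])


def _place_ligand(anchor: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rigidly place the ligand template: rotate, then put bead 0 at anchor."""
    return _LIGAND_TEMPLATE @ rotation.T + np.asarray(anchor, dtype=float)


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def make_binding_system(pocket_depth: float = 40.0, decoy_depth: float = 12.0,
                        channel_length: float = 2.0, seed: int = 0,
                        temperature: float = DEFAULT_TEMPERATURE) -> ToySystem:
    """Miniature pocket-and-channel binding system.

    A frozen pseudo-receptor scaffold forms a pocket around the planted bound pose
    (ligand anchor at CV = 0.46 nm, mirroring the histamine reference CV of
    4.6 Å); a reversed-orientation decoy pose is planted higher in the
    channel at CV = 1.2 nm with a shallower well.  The channel opens along
    +z into a flat solvent region ending at CV ≈ 0.46 + channel_length.
    ``analytic_fes`` is obtained by Boltzmann integration of the rigid-ligand
    field over the transverse plane for the two planted orientations.
    """
    if not pocket_depth > decoy_depth > 0:
        raise ValueError("need pocket_depth > decoy_depth > 0")
    if channel_length <= 0:
        raise ValueError("channel_length must be positive")
    rng = np.random.default_rng(seed)

    # frozen scaffold: anchor bead at the origin plus a ring of 8 pocket
    # beads and one base bead; small seed-dependent jitter makes replicate
    # systems distinguishable while staying bitwise reproducible
    angles = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    ring = np.stack([0.70 * np.cos(angles), 0.70 * np.sin(angles),
                     np.full(8, 0.20)], axis=1)
    # a floor ring under the pocket keeps the ligand from slipping out
    # through the receptor interior
    floor_angles = angles[:4] + np.pi / 4
    floor = np.stack([0.35 * np.cos(floor_angles),
                      0.35 * np.sin(floor_angles),
                      np.full(4, -0.05)], axis=1)
    scaffold = np.vstack([[0.0, 0.0, 0.0], ring, floor, [[0.0, 0.0, -0.25]]])
    scaffold[1:] += rng.normal(0.0, 0.01, size=scaffold[1:].shape)

    ref_cv, decoy_cv = 0.46, 1.20
    reference_pose = _place_ligand([0.0, 0.0, ref_cv], np.eye(3))
    decoy_pose = _place_ligand([0.0, 0.0, decoy_cv], _rot_x(np.pi))

    n_scaffold = len(scaffold)
    lig_idx = list(range(n_scaffold, n_scaffold + 4))
    bond_pairs = [(lig_idx[i], lig_idx[j]) for i in range(4) for j in range(i + 1, 4)]
    bond_lengths = [float(np.linalg.norm(_LIGAND_TEMPLATE[i] - _LIGAND_TEMPLATE[j]))
                    for i in range(4) for j in range(i + 1, 4)]
    # the bound pose is a broad capture well plus a narrow core along z:
    # the broad term holds the ligand against thermal kicks, the narrow
    # term defines a sharp free-energy minimum on the CV
    potential = BindingPotential(
        pose_centers=[reference_pose, reference_pose, decoy_pose],
        pose_depths=[0.6 * pocket_depth, 0.4 * pocket_depth, decoy_depth],
        pose_sigmas=[(0.22, 0.22), (0.18, 0.09), (0.18, 0.18)],
        ligand_indices=lig_idx,
        scaffold_indices=list(range(n_scaffold)),
        bond_pairs=bond_pairs,
        bond_lengths=bond_lengths,
    )
    potential.bind_scaffold(scaffold)

    solvent_cv = ref_cv + channel_length
    # initial coordinates: ligand unbound in the solvent region
    start_pose = _place_ligand([0.05, -0.05, solvent_cv - 0.15], np.eye(3))
    coordinates = np.vstack([scaffold, start_pose])
    labels = [("receptor_backbone", "cv_receptor_atom")]
    labels += [("receptor_backbone",)] * (n_scaffold - 1)
    labels += [("ligand_heavy", "cv_ligand_atom")] + [("ligand_heavy",)] * 3
    masses = np.concatenate([np.full(n_scaffold, 100.0), np.full(4, 14.0)])
    frozen = np.array([True] * n_scaffold + [False] * 4)

    system = ToySystem(
        name="binding",
        potential=potential,
        coordinates=coordinates,
        masses=masses,
        labels=labels,
        frozen=frozen,
        reference_pose=reference_pose,
        analytic_fes=None,
        temperature=temperature,
        metadata={
            "pocket_depth": float(pocket_depth),
            "decoy_depth": float(decoy_depth),
            "channel_length": float(channel_length),
            "seed": int(seed),
            "reference_cv": ref_cv,
            "decoy_cv": decoy_cv,
            "decoy_pose": decoy_pose.tolist(),
            "pocket_entry_cv": ref_cv + 0.35,
            "solvent_cv": solvent_cv,
            # toy-scale restraint geometry matched to the channel
            "walls": {"z_low": 0.15, "z_up": solvent_cv, "kappa": 1500.0},
            "funnel": {"d": 0.5, "r1": 0.35, "m": 10.0,
                       "w": ref_cv + 0.5 * channel_length, "h": 100.0,
                       "lam": 500.0},
        },
    )
    system.analytic_fes = _binding_analytic_fes(system)
    return system


def _binding_analytic_fes(system: ToySystem, grid_step: float = 0.01,
                          r_max: float = 0.45) -> AnalyticFES:
    """Free energy along the CV by trapezoid Boltzmann integration of the
    rigid-ligand field over the transverse (x, y) plane.

    Only the two planted orientations are integrated (equal weights); the
    orientational partition sum contributes an additive constant for the
    decoupled orientations of this toy and is dropped.
    """
    pot: BindingPotential = system.potential
    kT = KB * system.temperature
    meta = system.metadata
    zgrid = np.arange(0.2, meta["solvent_cv"] + grid_step / 2, grid_step)
    xy = np.linspace(-r_max, r_max, 31)
    rotations = [np.eye(3), _rot_x(np.pi)]
    gx, gy = np.meshgrid(xy, xy, indexing="ij")
    anchors_xy = np.column_stack([gx.ravel(), gy.ravel()])
    weights = np.zeros_like(zgrid)
    for iz, z in enumerate(zgrid):
        acc = 0.0
        for rot in rotations:
            template = _LIGAND_TEMPLATE @ rot.T
            anchors = np.column_stack(
                [anchors_xy, np.full(len(anchors_xy), z)])
            ligs = anchors[:, None, :] + template[None, :, :]
            acc += float(np.sum(np.exp(-pot.ligand_field_energy_batch(ligs) / kT)))
        weights[iz] = acc
    f = -kT * np.log(weights)
    return AnalyticFES(zgrid, f - f.min())


# ---------------------------------------------------------------------------
# planted conformational ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlantedEnsembleSpec:
    """Specification of a multi-mode ligand ensemble with known populations.

    ``modes`` is a list of (pose coordinates (n_ligand, 3), population
    fraction, positional noise sd in nm) triples.
    """

    modes: list[tuple[np.ndarray, float, float]]
    n_frames: int
    backbone_jitter_sd: float = 0.002
    rigid_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = [m[1] for m in self.modes]
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {sum(fractions)}, not 1")
        if self.n_frames < len(self.modes):
            raise ValueError("n_frames must be at least the number of modes")
        if any(m[2] < 0 for m in self.modes) or self.backbone_jitter_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (normalized random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def sample_planted_ensemble(system: ToySystem,
                            spec: PlantedEnsembleSpec) -> FrameSet:
    """Draw frames mode-by-mode with multinomially assigned counts.

    One multinomial draw fixes the per-mode frame counts; frames are laid
    out mode-by-mode in that order.  Per-atom Gaussian noise is added to the
    ligand (mode-specific sd) and scaffold (backbone_jitter_sd); with
    ``rigid_motion`` a random global rotation about the frame centroid plus
    a random translation is applied to every frame, which backbone
    superposition must undo.
    """
    n_lig = len(system.ligand_indices)
    for pose, _, _ in spec.modes:
        if np.asarray(pose).shape != (n_lig, 3):
            raise ValueError("mode poses must match the system's ligand atoms")
    rng = np.random.default_rng(spec.seed)
    fractions = np.array([m[1] for m in spec.modes], dtype=float)
    counts = rng.multinomial(spec.n_frames, fractions)

    n_atoms = len(system.coordinates)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    labels = np.empty(spec.n_frames, dtype=int)
    pos = 0
    for mode_idx, ((pose, _, noise_sd), count) in enumerate(zip(spec.modes, counts)):
        for _ in range(count):
            frame = system.coordinates.copy()
            frame[system.backbone_indices] += rng.normal(
                0.0, spec.backbone_jitter_sd, size=(len(system.backbone_indices), 3))
            frame[system.ligand_indices] = np.asarray(pose, dtype=float) + rng.normal(
                0.0, noise_sd, size=(n_lig, 3))
            if spec.rigid_motion:
                rot = _random_rotation(rng)
                shift = rng.normal(0.0, 0.1, size=3)
                center = frame.mean(axis=0)
                frame = (frame - center) @ rot.T + center + shift
            coords[pos] = frame
            labels[pos] = mode_idx
            pos += 1
    cv = np.array([system.compute_cv(c) for c in coords])
    frames = FrameSet(
        coordinates=coords,
        cv=cv,
        time=np.arange(spec.n_frames, dtype=float),
        walker_id=np.zeros(spec.n_frames, dtype=int),
        backbone_indices=system.backbone_indices,
        ligand_indices=system.ligand_indices,
    )
    frames.true_mode = labels  # planted ground truth, for validation
    frames.mode_counts = counts
    return frames
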