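"""Langevin dynamics for toy systems under system + restraint + metadynamics
forces.

The integrator is BAOAB-discretized Langevin dynamics (kick / drift /
Ornstein–Uhlenbeck / drift / kick), which samples the canonical ensemble at
the target temperature and reduces to velocity Verlet in the zero-friction,
zero-temperature limit.  Scaffold atoms marked frozen are excluded from
integration.  Forces are

    F = −∇(U_system + V_wall(z) + V_funnel(x, y, z) + V_meta(s)),

where the wall and metadynamics terms act along the CV (the z displacement
from the receptor anchor to the ligand anchor) and the funnel acts on the
full anchor displacement.  Because the anchor atoms are frozen, restraint
reaction forces on the receptor are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .frames import FrameSet
from .metadynamics import MetaDParams, SharedHills, deposit
from .restraints import (FunnelParams, WallParams, funnel_gradient,
                         wall_gradient)
from .toy_systems import ToySystem

__all__ = ["SystemState", "RunSpec", "IntegrationError", "run_segment",
           "run_multiwalker", "initial_state"]


class IntegrationError(RuntimeError):
    """Raised when forces or coordinates become non-finite."""


@dataclass
class SystemState:
    """Instantaneous mechanical state of a toy system."""

    coordinates: np.ndarray   # (n_atoms, 3) nm
    velocities: np.ndarray    # (n_atoms, 3) nm/ps
    time: float = 0.0         # ps

    def __post_init__(self) -> None:
        self.coordinates = np.array(self.coordinates, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        if self.coordinates.shape != self.velocities.shape:
            raise ValueError("coordinates and velocities must have equal shapes")
        if not (np.all(np.isfinite(self.coordinates))
                and np.all(np.isfinite(self.velocities))):
            raise ValueError("state must be finite")

    def copy(self) -> "SystemState":
        return SystemState(self.coordinates.copy(), self.velocities.copy(),
                           self.time)


@dataclass(frozen=True)
class RunSpec:
    """Parameters of one dynamics segment.

    Defaults: 2 fs time step, 1 ps⁻¹ friction, 310 K.  ``biased`` runs
    deposit well-tempered hills and require ``metad``.
    """

    n_steps: int
    dt: float = 0.002
    friction: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    output_stride: int = 100
    biased: bool = False
    walls: Optional[WallParams] = None
    funnel: Optional[FunnelParams] = None
    metad: Optional[MetaDParams] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.biased and self.metad is None:
            raise ValueError("biased runs require metadynamics parameters")


def initial_state(system: ToySystem, spec: RunSpec,
                  coordinates: np.ndarray | None = None,
                  rng: np.random.Generator | None = None) -> SystemState:
    """Build a start state: given (or system default) coordinates with
    Maxwell–Boltzmann velocities on the mobile atoms."""
    rng = rng or np.random.default_rng(spec.seed)
    coords = np.array(system.coordinates if coordinates is None else coordinates,
                      dtype=float)
    vel = np.zeros_like(coords)
    mobile = ~system.frozen
    if spec.temperature > 0:
        sd = np.sqrt(KB * spec.temperature / system.masses[mobile])
        vel[mobile] = rng.normal(size=(mobile.sum(), 3)) * sd[:, None]
    return SystemState(coords, vel, 0.0)


class _WalkerIntegrator:
    """BAOAB integrator for one walker, sharing a hill list with others."""

    def __init__(self, system: ToySystem, state: SystemState, spec: RunSpec,
                 rng: np.random.Generator, shared_hills: SharedHills | None,
                 walker_id: int = 0):
        self.system = system
        self.state = state.copy()
        self.spec = spec
        self.rng = rng
        self.hills = shared_hills
        self.walker_id = walker_id
        idx = np.flatnonzero(~system.frozen)
        self.n_mobile = len(idx)
        # contiguous mobile blocks index as slices (views, no copies)
        if len(idx) and np.all(np.diff(idx) == 1):
            self.mobile = slice(int(idx[0]), int(idx[-1]) + 1)
        else:
            self.mobile = idx
        self.masses = system.masses[idx][:, None]
        self.i_rec = system.cv_receptor_index
        self.i_lig = system.cv_ligand_index
        kT = KB * spec.temperature
        self.c1 = np.exp(-spec.friction * spec.dt)
        self.c2 = np.sqrt(kT * (1.0 - self.c1**2)) / np.sqrt(self.masses)
        self.step_count = 0
        self.forces = self._compute_forces(self.state.coordinates)
        self.rec_coords: list[np.ndarray] = []
        self.rec_cv: list[float] = []
        self.rec_time: list[float] = []

    # -- forces -------------------------------------------------------------
    def _compute_forces(self, coords: np.ndarray) -> np.ndarray:
        f = self.system.potential.forces(coords)
        disp = coords[self.i_lig] - coords[self.i_rec]
        z = disp[2]
        if self.spec.walls is not None:
            f[self.i_lig, 2] -= wall_gradient(z, self.spec.walls)
        if self.spec.funnel is not None:
            f[self.i_lig] -= funnel_gradient(disp[0], disp[1], z,
                                             self.spec.funnel)
        if self.spec.biased and self.hills is not None and len(self.hills):
            f[self.i_lig, 2] -= self.hills.bias_derivative(z)
        # nan/inf propagate through the sum, so one scalar check suffices
        if not np.isfinite(f[self.mobile].sum()):
            raise IntegrationError(
                f"non-finite force at step {self.step_count} "
                f"(walker {self.walker_id})")
        return f

    @property
    def cv(self) -> float:
        c = self.state.coordinates
        return float(c[self.i_lig, 2] - c[self.i_rec, 2])

    def _record(self) -> None:
        self.rec_coords.append(self.state.coordinates.copy())
        self.rec_cv.append(self.cv)
        self.rec_time.append(self.state.time)

    # -- integration --------------------------------------------------------
    def advance(self, n_steps: int) -> None:
        """Advance BAOAB steps; records every output_stride global steps."""
        x = self.state.coordinates
        v = self.state.velocities
        m = self.mobile
        dt = self.spec.dt
        for _ in range(n_steps):
            v[m] += 0.5 * dt * self.forces[m] / self.masses
            x[m] += 0.5 * dt * v[m]
            v[m] = self.c1 * v[m] + self.c2 * self.rng.standard_normal(
                (self.n_mobile, 3))
            x[m] += 0.5 * dt * v[m]
            self.forces = self._compute_forces(x)
            v[m] += 0.5 * dt * self.forces[m] / self.masses
            self.step_count += 1
            self.state.time += dt
            if self.step_count % self.spec.output_stride == 0:
                self._record()

    def deposit_hill(self) -> None:
        deposit(self.cv, self.state.time, self.walker_id, self.hills,
                self.spec.metad)
        # new hill changes the bias force immediately
        self.forces = self._compute_forces(self.state.coordinates)

    def frameset(self) -> FrameSet:
        coords = (np.array(self.rec_coords) if self.rec_coords
                  else np.empty((0, len(self.system.coordinates), 3)))
        return FrameSet(
            coordinates=coords,
            cv=np.array(self.rec_cv),
            time=np.array(self.rec_time),
            walker_id=np.full(len(self.rec_cv), self.walker_id, dtype=int),
            backbone_indices=self.system.backbone_indices,
            ligand_indices=self.system.ligand_indices,
        )


def run_segment(system: ToySystem, state: SystemState, spec: RunSpec,
                shared_hills: SharedHills | None = None,
                rng: np.random.Generator | None = None, walker_id: int = 0):
    """Run one dynamics segment.

    Returns ``(trajectory, colvar, hills)``: the recorded FrameSet, a list of
    ``(time, cv)`` records at the output stride, and the (possibly shared)
    hill list.  Unbiased runs neither read nor write hills and return an
    empty list in that slot.
    """
    if state.coordinates.shape != system.coordinates.shape:
        raise ValueError("state does not match the system's atom list")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    hills = shared_hills
    if spec.biased and hills is None:
        hills = SharedHills()
    walker = _WalkerIntegrator(system, state, spec, rng,
                               hills if spec.biased else None,
                               walker_id=walker_id)
    stride = spec.metad.stride if spec.biased else spec.n_steps
    done = 0
    while done < spec.n_steps:
        chunk = min(stride, spec.n_steps - done)
        walker.advance(chunk)
        done += chunk
        if spec.biased and chunk == stride:
            walker.deposit_hill()
    traj = walker.frameset()
    colvar = list(zip(walker.rec_time, walker.rec_cv))
    state.coordinates[:] = walker.state.coordinates
    state.velocities[:] = walker.state.velocities
    state.time = walker.state.time
    return traj, colvar, (hills if spec.biased else SharedHills())


def run_multiwalker(system: ToySystem, seeds: FrameSet, spec: RunSpec,
                    n_walkers: int):
    """Interleaved multiple-walker metadynamics with one shared hill list.

    ``seeds`` supplies one start conformation per walker.  Walkers advance in
    round-robin chunks of one deposition stride; each deposit is visible to
    every walker from the next force evaluation onward.  Returns
    ``(trajectories, colvars, hills)`` with per-walker FrameSets and COLVAR
    records plus the merged hill list tagged by walker id.
    """
    if len(seeds) != n_walkers:
        raise ValueError(f"need {n_walkers} seed frames, got {len(seeds)}")
    if not spec.biased or spec.metad is None:
        raise ValueError("multiwalker runs are metadynamics runs; "
                         "set biased=True with metad parameters")
    hills = SharedHills()
    streams = np.random.SeedSequence(spec.seed).spawn(n_walkers)
    walkers = []
    for w in range(n_walkers):
        rng = np.random.default_rng(streams[w])
        state = initial_state(system, spec, seeds.coordinates[w], rng=rng)
        walkers.append(_WalkerIntegrator(system, state, spec, rng, hills,
                                         walker_id=w))
    stride = spec.metad.stride
    done = 0
    while done < spec.n_steps:
        chunk = min(stride, spec.n_steps - done)
        for walker in walkers:
            try:
                walker.advance(chunk)
                if chunk == stride:
                    walker.deposit_hill()
            except IntegrationError as err:
                raise IntegrationError(
                    f"walker {walker.walker_id} failed: {err}") from err
        done += chunk
    trajectories = [w.frameset() for w in walkers]
    colvars = [list(zip(w.rec_time, w.rec_cv)) for w in walkers]
    return trajectories, colvars, hills
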