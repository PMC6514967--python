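"""Free-energy profile reconstruction from deposited hills.

For well-tempered metadynamics the bias converges to −ΔT/(T+ΔT)·F, so the
free energy along the CV is recovered as

    F(s) = −(γ / (γ − 1)) · V(s),

the standard rescaling applied by the PLUMED post-processing tools.  The
profile is shifted so its global minimum sits at zero, and the minimum is
refined by a parabolic fit through the minimum grid point and its two
neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .metadynamics import SharedHills, total_bias

__all__ = ["FESProfile", "FlatProfileError", "reconstruct_fes",
           "locate_minimum", "basin_delta_f", "write_fes", "read_fes"]


class FlatProfileError(ValueError):
    """Raised when a minimum is requested from a featureless profile."""


@dataclass
class FESProfile:
    """Gridded free energy along the binding CV, minimum shifted to zero."""

    grid: np.ndarray
    free_energy: np.ndarray
    minimum_cv: float | None
    gamma_used: float
    flat: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.shape != self.free_energy.shape or self.grid.ndim != 1:
            raise ValueError("grid and free_energy must be matching 1D arrays")
        steps = np.diff(self.grid)
        if len(steps) and not (np.all(steps > 0)
                               and np.allclose(steps, steps[0], rtol=1e-8)):
            raise ValueError("grid must be uniform and strictly increasing")


def reconstruct_fes(hills, gamma: float, grid_min: float | None = None,
                    grid_max: float | None = None,
                    grid_step: float = 0.01) -> FESProfile:
    """Reconstruct F(s) = −(γ/(γ−1))·V(s) on a uniform grid.

    The grid range defaults to [min hill center − 3σ, max hill center + 3σ].
    An empty hill list yields a flat all-zero profile flagged with
    ``flat=True`` (and a warning) rather than an exception.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not isinstance(hills, SharedHills):
        hills = SharedHills(hills)
    if len(hills) == 0:
        warnings.warn("empty hill list: returning a flat free-energy profile",
                      stacklevel=2)
        lo = 0.0 if grid_min is None else grid_min
        hi = 1.0 if grid_max is None else grid_max
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        return FESProfile(grid, np.zeros_like(grid), None, gamma, flat=True)
    centers = np.array([h.center for h in hills])
    sigmas = np.array([h.sigma for h in hills])
    lo = centers.min() - 3 * sigmas.max() if grid_min is None else grid_min
    hi = centers.max() + 3 * sigmas.max() if grid_max is None else grid_max
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    f = -(gamma / (gamma - 1.0)) * np.asarray(total_bias(grid, hills))
    f -= f.min()
    profile = FESProfile(grid, f, None, gamma)
    profile.minimum_cv = locate_minimum(profile)
    return profile


def locate_minimum(profile: FESProfile) -> float:
    """CV of the global minimum, parabolic-refined; ties (within 1e-9)
    broken toward the smaller CV."""
    f = profile.free_energy
    if profile.flat or np.ptp(f) < 1e-12:
        raise FlatProfileError("profile is flat; no minimum to locate")
    idx = int(np.flatnonzero(f <= f.min() + 1e-9)[0])
    if idx == 0 or idx == len(f) - 1:
        return float(profile.grid[idx])
    y0, y1, y2 = f[idx - 1], f[idx], f[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(profile.grid[idx])
    h = profile.grid[1] - profile.grid[0]
    shift = 0.5 * (y0 - y2) / denom
    return float(profile.grid[idx] + np.clip(shift, -0.5, 0.5) * h)


def basin_delta_f(profile: FESProfile, divider: float,
                  temperature: float) -> float:
    """ΔF = F(basin above divider) − F(basin below divider) by trapezoid
    Boltzmann integration of the reconstructed profile."""
    kT = KB * temperature
    w = np.exp(-(profile.free_energy - profile.free_energy.min()) / kT)
    left = np.trapezoid(np.where(profile.grid <= divider, w, 0.0), profile.grid)
    right = np.trapezoid(np.where(profile.grid >= divider, w, 0.0), profile.grid)
    if left <= 0 or right <= 0:
        raise ValueError("divider leaves an empty basin")
    return float(-kT * np.log(right / left))


def write_fes(path, profile: FESProfile) -> None:
    """Two-column text file: ``cv free_energy``."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS cv free_energy\n")
        if profile.minimum_cv is not None:
            fh.write(f"#! SET minimum_cv {profile.minimum_cv:.9f}\n")
        fh.write(f"#! SET gamma {profile.gamma_used}\n")
        for s, f in zip(profile.grid, profile.free_energy):
            fh.write(f"{s:.9f} {f:.9f}\n")


def read_fes(path) -> FESProfile:
    minimum_cv, gamma = None, float("nan")
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#! SET minimum_cv"):
                minimum_cv = float(line.split()[-1])
            elif line.startswith("#! SET gamma"):
                gamma = float(line.split()[-1])
            elif not line.startswith("#"):
                rows.append([float(v) for v in line.split()])
    data = np.array(rows)
    flat = bool(np.ptp(data[:, 1]) < 1e-12)
    return FESProfile(data[:, 0], data[:, 1], minimum_cv, gamma, flat=flat)
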