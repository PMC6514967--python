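"""Well-tempered hill deposition, shared multiple-walker bias, and
PLUMED-dialect HILLS / COLVAR files.

In well-tempered metadynamics a Gaussian of width σ is deposited at the
current CV value every ``stride`` integration steps, with height

    W = W₀ · exp(−V(s, t) / (kB·ΔT)),        ΔT = (γ − 1)·T,

where V(s, t) is the bias already accumulated at the deposition point and γ
is the bias factor.  With several walkers all hills live in one shared list:
every walker feels, and scales its deposits by, the bias of all walkers.
The behavioural contract is that of file-synchronized PLUMED walkers — all
walkers feel all hills from the deposition event onward — realised here as
an in-process shared list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KB
from .frames import FrameSet

__all__ = [
    "MetaDParams",
    "Hill",
    "SharedHills",
    "hill_height",
    "total_bias",
    "total_bias_derivative",
    "deposit",
    "select_walker_seeds",
    "write_hills",
    "read_hills",
    "write_colvar",
    "read_colvar",
]


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics settings.

    Defaults are the published multiple-walker settings (γ = 20,
    W₀ = 5 kJ/mol, σ = 0.1 nm); the initial pathway-sampling runs used
    γ = 50 and W₀ = 7 kJ/mol.  The deposition stride is 500 integration
    steps (1 ps at a 2 fs time step).
    """

    gamma: float = 20.0
    w0: float = 5.0
    sigma: float = 0.1
    stride: int = 500
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("bias factor gamma must exceed 1")
        if self.w0 <= 0 or self.sigma <= 0:
            raise ValueError("w0 and sigma must be positive")
        if self.stride < 1:
            raise ValueError("stride must be at least 1")

    @property
    def delta_t(self) -> float:
        """ΔT = (γ−1)·T, the well-tempered fictitious temperature boost."""
        return (self.gamma - 1.0) * self.temperature


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: V_k(s) = height·exp(−(s−center)²/(2σ²))."""

    time: float
    center: float
    sigma: float
    height: float
    walker_id: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.sigma <= 0:
            raise ValueError("hill height and sigma must be positive")


class SharedHills:
    """Append-only hill list shared by all walkers, stored as growable
    arrays so the bias sum stays vectorized."""

    def __init__(self, hills: Iterable[Hill] = ()):  # noqa: D107
        self._hills: list[Hill] = []
        self._centers = np.empty(0)
        self._sigmas = np.empty(0)
        self._heights = np.empty(0)
        for h in hills:
            self.append(h)

    def append(self, hill: Hill) -> None:
        self._hills.append(hill)
        self._centers = np.append(self._centers, hill.center)
        self._sigmas = np.append(self._sigmas, hill.sigma)
        self._heights = np.append(self._heights, hill.height)

    def __len__(self) -> int:
        return len(self._hills)

    def __iter__(self):
        return iter(self._hills)

    def __getitem__(self, i):
        return self._hills[i]

    @property
    def hills(self) -> list[Hill]:
        return list(self._hills)

    def bias(self, s):
        """Total bias V(s) = Σ_k W_k exp(−(s−c_k)²/(2σ_k²)) over all walkers."""
        if len(self) == 0:
            out = np.zeros_like(np.asarray(s, dtype=float))
            return float(out) if out.ndim == 0 else out
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty(len(s_arr))
        # chunk over probe points; hills axis stays vectorized
        for i, si in enumerate(s_arr):
            d = (si - self._centers) / self._sigmas
            out[i] = np.dot(self._heights, np.exp(-0.5 * d * d))
        return float(out[0]) if np.ndim(s) == 0 else out

    def bias_derivative(self, s: float) -> float:
        """dV/ds at a scalar CV value."""
        if len(self) == 0:
            return 0.0
        d = (s - self._centers) / self._sigmas
        return float(np.sum(self._heights * np.exp(-0.5 * d * d) *
                            (-(s - self._centers) / self._sigmas**2)))


def hill_height(v_bias_here: float, params: MetaDParams) -> float:
    """Well-tempered hill height W = W₀·exp(−V/(kB·ΔT))."""
    if v_bias_here < 0:
        raise ValueError("accumulated bias cannot be negative "
                         "(it is a sum of positive Gaussians)")
    return params.w0 * float(np.exp(-v_bias_here / (KB * params.delta_t)))


def total_bias(s, hills) -> float | np.ndarray:
    """Total bias at CV value(s) ``s`` from a hill list (all walkers)."""
    if not isinstance(hills, SharedHills):
        hills = SharedHills(hills)
    return hills.bias(s)


def total_bias_derivative(s: float, hills) -> float:
    if not isinstance(hills, SharedHills):
        hills = SharedHills(hills)
    return hills.bias_derivative(s)


def deposit(state_cv: float, time: float, walker_id: int,
            hills: SharedHills, params: MetaDParams) -> Hill:
    """Deposit one well-tempered hill at the walker's current CV value.

    The height is scaled by the bias already present at ``state_cv`` from
    ALL walkers; the new hill is immediately visible to every walker.
    """
    height = hill_height(hills.bias(state_cv), params)
    hill = Hill(time=time, center=float(state_cv), sigma=params.sigma,
                height=height, walker_id=int(walker_id))
    hills.append(hill)
    return hill


def select_walker_seeds(frames: FrameSet, n: int) -> FrameSet:
    """Pick ``n`` frames with CV values equidistantly spanning the observed
    CV range (nearest frame per target; ties broken by earliest time)."""
    if n < 2:
        raise ValueError("need at least 2 walker seeds")
    if len(frames) < n:
        raise ValueError(
            f"cannot seed {n} walkers from {len(frames)} frames "
            f"({n - len(frames)} more needed)")
    targets = np.linspace(frames.cv.min(), frames.cv.max(), n)
    chosen = []
    for t in targets:
        dist = np.abs(frames.cv - t)
        best = np.min(dist)
        cand = np.flatnonzero(dist <= best + 1e-15)
        # earliest time wins; then smallest index
        cand = cand[np.lexsort((cand, frames.time[cand]))]
        chosen.append(int(cand[0]))
    return frames.subset(np.array(chosen))


# ---------------------------------------------------------------------------
# PLUMED-dialect files
# ---------------------------------------------------------------------------

def write_hills(path, hills, cv_name: str = "cvz",
                gamma: float | None = None) -> None:
    """Write a HILLS file in the PLUMED v2 dialect.

    Header: ``#! FIELDS time <cv> sigma_<cv> height biasf``; a trailing
    ``walker`` column tags the depositing walker in merged files.
    """
    hills = list(hills)
    biasf = gamma if gamma is not None else float("nan")
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {cv_name} sigma_{cv_name} height biasf walker\n")
        for h in hills:
            fh.write(f"{h.time:.6f} {h.center:.9f} {h.sigma:.9f} "
                     f"{h.height:.9f} {biasf:.3f} {h.walker_id}\n")


def read_hills(paths) -> list[Hill]:
    """Read one or several HILLS files (merged or per-walker).

    Columns are taken from the ``#! FIELDS`` header; a ``walker`` column is
    honoured when present, otherwise walker ids are numbered per file.
    Hills from all files are pooled and sorted by deposition time.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    hills: list[Hill] = []
    for file_idx, path in enumerate(paths):
        with open(path) as fh:
            header = fh.readline().split()
        if len(header) < 3 or header[:2] != ["#!", "FIELDS"]:
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        fields = header[2:]
        data = np.atleast_2d(np.loadtxt(path, comments="#"))
        if data.size == 0:
            continue
        col = {name: i for i, name in enumerate(fields)}
        cv_field = fields[1]
        for row in data:
            walker = int(row[col["walker"]]) if "walker" in col else file_idx
            hills.append(Hill(time=float(row[col["time"]]),
                              center=float(row[col[cv_field]]),
                              sigma=float(row[col[f"sigma_{cv_field}"]]),
                              height=float(row[col["height"]]),
                              walker_id=walker))
    hills.sort(key=lambda h: (h.time, h.walker_id))
    return hills


def write_colvar(path, time: Sequence[float], cv: Sequence[float],
                 cv_name: str = "cvz", extra: dict | None = None) -> None:
    """Write a COLVAR time series (``#! FIELDS time <cv> ...``)."""
    extra = extra or {}
    names = ["time", cv_name] + list(extra)
    cols = [np.asarray(time, dtype=float), np.asarray(cv, dtype=float)]
    cols += [np.asarray(v, dtype=float) for v in extra.values()]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def read_colvar(path) -> pd.DataFrame:
    """Read a COLVAR file into a DataFrame keyed by the header fields."""
    with open(path) as fh:
        header = fh.readline().split()
    if len(header) < 3 or header[:2] != ["#!", "FIELDS"]:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    return pd.DataFrame(data, columns=header[2:])
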