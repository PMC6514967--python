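"""Langevin integrator: equilibrium, equipartition, determinism, walkers."""

import numpy as np
import pytest

from metabind import (FrameSet, MetaDParams, RunSpec, SystemState,
                      WallParams, FunnelParams, initial_state, run_multiwalker,
                      run_segment)
from metabind.constants import KB
from metabind.toy_systems import DoubleWellPotential, ToySystem


def harmonic_system(k=100.0, mass=14.0):
    """Single mobile particle in an isotropic harmonic well (via a stiff
    double-well degenerate limit is avoided; built directly)."""

    class Harmonic:
        kind = "harmonic"

        def __init__(self, k):
            self.k = k

        def energy(self, coords):
            return 0.5 * self.k * float(np.sum(coords[1] ** 2))

        def forces(self, coords):
            f = np.zeros_like(coords)
            f[1] = -self.k * coords[1]
            return f

        def to_dict(self):
            return {"kind": self.kind, "k": self.k}

    return ToySystem(
        name="harmonic",
        potential=Harmonic(k),
        coordinates=np.zeros((2, 3)),
        masses=np.array([100.0, mass]),
        labels=[("receptor_backbone", "cv_receptor_atom"),
                ("ligand_heavy", "cv_ligand_atom")],
        frozen=np.array([True, False]),
        reference_pose=np.zeros((1, 3)),
        temperature=310.0,
    )


class TestRunSegment:
    def test_static_at_minimum_zero_temperature(self):
        system = harmonic_system()
        spec = RunSpec(n_steps=10_000, dt=0.002, temperature=0.0, seed=0,
                       output_stride=1000)
        state = SystemState(np.zeros((2, 3)), np.zeros((2, 3)))
        traj, _, _ = run_segment(system, state, spec)
        assert np.max(np.abs(traj.coordinates)) <= 1e-8

    def test_equipartition_variance(self):
        k = 100.0
        system = harmonic_system(k=k)
        spec = RunSpec(n_steps=200_000, dt=0.002, temperature=310.0,
                       friction=5.0, seed=1, output_stride=20)
        state = initial_state(system, spec)
        traj, _, _ = run_segment(system, state, spec)
        # the three axes are iid harmonic dofs; pool them so the variance
        # estimate has enough effective samples for a 5% check
        var = np.var(traj.coordinates[1000:, 1, :])
        expected = KB * 310.0 / k
        assert abs(var - expected) / expected < 0.05

    def test_bitwise_determinism(self):
        system = harmonic_system()
        spec = RunSpec(n_steps=5000, seed=7, output_stride=100)
        t1, _, _ = run_segment(system, initial_state(system, spec), spec)
        t2, _, _ = run_segment(system, initial_state(system, spec), spec)
        assert np.array_equal(t1.coordinates, t2.coordinates)

    def test_energy_conservation_deterministic_limit(self):
        k = 100.0
        system = harmonic_system(k=k)
        spec = RunSpec(n_steps=10_000, dt=0.002, temperature=0.0,
                       friction=0.0, seed=0, output_stride=100)
        x0 = np.zeros((2, 3))
        x0[1, 2] = 0.1
        state = SystemState(x0, np.zeros((2, 3)))
        pot0 = system.potential.energy(x0)
        traj, _, _ = run_segment(system, state, spec)
        # total energy drift per step in the velocity-Verlet limit
        xf = state.coordinates
        vf = state.velocities
        e_final = (system.potential.energy(xf)
                   + 0.5 * system.masses[1] * float(np.sum(vf[1] ** 2)))
        assert abs(e_final - pot0) / spec.n_steps <= 1e-6

    def test_unbiased_boltzmann_basin_occupancy(self, ):
        """Long unbiased run on a shallow double well reproduces analytic
        basin weights (chi-squared not rejected at alpha=0.01)."""
        from scipy.stats import chi2
        from metabind import make_double_well

        system = make_double_well(delta_f=3.0, barrier=4.0,
                                  well_separation=1.2)
        spec = RunSpec(n_steps=400_000, dt=0.01, temperature=310.0,
                       friction=1.0, seed=3, output_stride=4)
        state = initial_state(system, spec)
        traj, _, _ = run_segment(system, state, spec)
        div = system.metadata["divider_cv"]
        n = len(traj)
        indicator = (traj.cv > div).astype(float)
        observed = np.array([n - indicator.sum(), indicator.sum()])
        delta_f = system.analytic_fes.basin_delta_f(310.0, divider=div)
        p_right = 1.0 / (1.0 + np.exp(delta_f / (KB * 310.0)))
        expected = n * np.array([1.0 - p_right, p_right])
        # frames are correlated on the basin-hopping timescale: correct the
        # statistic by the measured integrated autocorrelation time
        x = indicator - indicator.mean()
        acf = np.correlate(x, x, mode="full")[n - 1:] / np.dot(x, x)
        first_neg = np.argmax(acf < 0)
        tau_int = 0.5 + acf[1:first_neg].sum()
        stat = float(np.sum((observed - expected) ** 2 / expected))
        assert stat / (2.0 * tau_int) < chi2.ppf(0.99, df=1)

    def test_nonfinite_forces_raise(self):
        system = harmonic_system()
        spec = RunSpec(n_steps=100, dt=1e6, temperature=0.0, friction=0.0,
                       seed=0)
        x0 = np.zeros((2, 3))
        x0[1] = 1.0
        from metabind import IntegrationError
        with pytest.raises((IntegrationError, ValueError)):
            run_segment(system, SystemState(x0, np.zeros((2, 3))), spec)


@pytest.fixture(scope="module")
def dw():
    from metabind import make_double_well
    return make_double_well(delta_f=5.0, barrier=8.0, well_separation=1.6)


class TestMultiwalker:

    def _seeds(self, system, n):
        zs = np.linspace(-0.8, 0.8, n)
        coords = np.array([[[0, 0, 0], [0, 0, z]] for z in zs])
        return FrameSet(coords, zs, np.zeros(n), np.arange(n),
                        system.backbone_indices, system.ligand_indices)

    def test_single_walker_reduces_to_run_segment(self, dw):
        md = MetaDParams(gamma=20.0, w0=5.0, sigma=0.1, stride=100)
        spec = RunSpec(n_steps=2000, dt=0.01, seed=5, biased=True, metad=md,
                       output_stride=100)
        seeds = self._seeds(dw, 2).subset([0])
        trajs, _, hills_mw = run_multiwalker(dw, seeds, spec, 1)

        stream = np.random.SeedSequence(spec.seed).spawn(1)[0]
        rng = np.random.default_rng(stream)
        state = initial_state(dw, spec, seeds.coordinates[0], rng=rng)
        traj, _, hills = run_segment(dw, state, spec, rng=rng)
        assert np.array_equal(trajs[0].coordinates, traj.coordinates)
        assert len(hills) == len(hills_mw)
        assert np.allclose([h.height for h in hills],
                           [h.height for h in hills_mw])

    def test_merged_hill_count(self, dw):
        md = MetaDParams(gamma=20.0, w0=5.0, sigma=0.1, stride=100)
        spec = RunSpec(n_steps=1000, dt=0.01, seed=6, biased=True, metad=md)
        trajs, _, hills = run_multiwalker(dw, self._seeds(dw, 2), spec, 2)
        assert len(hills) == 2 * (1000 // 100)
        assert {h.walker_id for h in hills} == {0, 1}

    def test_all_walkers_feel_all_hills_replay(self, dw):
        """Shared-bias bookkeeping equals a single-process replay."""
        from metabind.metadynamics import SharedHills, total_bias
        md = MetaDParams(gamma=20.0, w0=5.0, sigma=0.1, stride=200)
        spec = RunSpec(n_steps=1000, dt=0.01, seed=8, biased=True, metad=md)
        _, _, hills = run_multiwalker(dw, self._seeds(dw, 3), spec, 3)
        replay = SharedHills()
        for h in hills:
            expected = md.w0 * np.exp(-replay.bias(h.center)
                                      / (KB * md.delta_t))
            assert h.height == pytest.approx(expected, rel=1e-12)
            replay.append(h)

    def test_seed_count_mismatch(self, dw):
        md = MetaDParams()
        spec = RunSpec(n_steps=100, biased=True, metad=md)
        with pytest.raises(ValueError, match="seed frames"):
            run_multiwalker(dw, self._seeds(dw, 3), spec, 4)


def test_funnel_confinement(binding_system):
    """Biased dynamics under the funnel keeps the ligand anchor inside
    R(z) + 0.1 nm for >99% of frames."""
    from metabind import funnel_radius
    meta = binding_system.metadata
    walls = WallParams(**meta["walls"])
    funnel = FunnelParams(**meta["funnel"])
    md = MetaDParams(gamma=20.0, w0=5.0, sigma=0.1, stride=500)
    spec = RunSpec(n_steps=60_000, dt=0.005, seed=9, biased=True,
                   walls=walls, funnel=funnel, metad=md, output_stride=20)
    state = initial_state(binding_system, spec)
    traj, _, _ = run_segment(binding_system, state, spec)
    anchor = traj.coordinates[:, binding_system.cv_ligand_index, :]
    center = traj.coordinates[:, binding_system.cv_receptor_index, :]
    disp = anchor - center
    r = np.hypot(disp[:, 0], disp[:, 1])
    outside = r > funnel_radius(disp[:, 2], funnel) + 0.1
    assert outside.mean() < 0.01
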