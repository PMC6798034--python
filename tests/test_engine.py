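import numpy as np
import pytest
from scipy import integrate, stats

from enmremd.bias import BiasSpec, bias_energy_forces, centroid_distances
from enmremd.constants import AKMA_ENERGY, KB
from enmremd.engine import (
    BAOAB,
    NetworkPotential,
    SimState,
    maxwell_velocities,
    physical_energy_forces,
    run_segment,
)
from enmremd.errors import IntegrationError
from enmremd.fixtures import DoubleWell


class Harmonic:
    """Isotropic spring u = ½k|x|² for closed-form thermostat checks."""

    def __init__(self, k):
        self.k = k

    def energy_forces(self, coords):
        x = np.asarray(coords, dtype=float)
        return 0.5 * self.k * (x**2).sum(axis=(-2, -1)), -self.k * x


def one_bead_state(seed=0, x0=0.0, ndim=1):
    return SimState(
        coords=np.full((1, ndim), float(x0)),
        velocities=np.zeros((1, ndim)),
        rng=np.random.default_rng(seed),
    )


class TestPhysicalModel:
    def test_enm_reference_is_minimum(self, toy_model, toy):
        structure, _ = toy
        e, f = physical_energy_forces(structure.coords, toy_model)
        assert e == pytest.approx(0.0, abs=1e-10)
        assert np.abs(f).max() < 1e-8

    def test_double_well_minima_and_barrier(self):
        dw = DoubleWell(1.5, 2.0)
        assert dw.energy(2.0) == pytest.approx(0.0)
        assert dw.energy(-2.0) == pytest.approx(0.0)
        assert dw.energy(0.0) == pytest.approx(1.5)

    def test_forces_match_finite_differences(self, toy_model, toy):
        structure, _ = toy
        pot = NetworkPotential(toy_model)
        x = structure.coords + np.random.default_rng(3).normal(
            scale=0.5, size=structure.coords.shape
        )
        e0, f = pot.energy_forces(x)
        rng = np.random.default_rng(1)
        h = 1e-5
        for _ in range(5):
            u = rng.standard_normal(x.shape)
            u /= np.linalg.norm(u)
            ep, _ = pot.energy_forces(x + h * u)
            em, _ = pot.energy_forces(x - h * u)
            fd = -(ep - em) / (2 * h)
            assert float((f * u).sum()) == pytest.approx(fd, rel=1e-6)

    def test_double_well_force_matches_finite_difference(self):
        dw = DoubleWell(1.0, 1.0)
        x = np.array([[[0.37]]])
        _, f = dw.energy_forces(x)
        h = 1e-6
        fd = -(dw.energy_forces(x + h)[0] - dw.energy_forces(x - h)[0]) / (2 * h)
        assert f[0, 0, 0] == pytest.approx(float(fd[0]), rel=1e-6)

    def test_repulsion_clips_overlapping_beads_with_warning(self, toy_model):
        pot = NetworkPotential(toy_model, repulsion_epsilon=1.0, repulsion_sigma=3.0)
        x = toy_model.ref_coords.copy()
        x[1] = x[0] + 1e-3  # overlap
        with pytest.warns(UserWarning, match="clipped"):
            e, f = pot.energy_forces(x)
        assert np.all(np.isfinite(f))


class TestLangevin:
    def test_harmonic_equipartition(self):
        """Long Langevin sampling of u=½kx²: var(x) = k_B T / k."""
        pot = Harmonic(3.0)
        state = one_bead_state(seed=11)
        state, frames = run_segment(
            state, 120_000, pot, masses=np.array([50.0]),
            dt=0.01, friction=2.0, temperature=300.0, stride=25,
        )
        x = frames.coords[400:, 0, 0]
        expected = KB * 300.0 / 3.0
        # std error of a variance estimate from n eff. samples ≈ var·√(2/n)
        n_eff = len(x) / 4
        assert abs(x.var() - expected) < 3 * expected * np.sqrt(2 / n_eff)

    def test_zero_friction_zero_temperature_is_velocity_verlet(self):
        pot = Harmonic(2.0)
        m = np.array([10.0])
        state = one_bead_state(x0=1.0)
        state, frames = run_segment(
            state, 500, pot, masses=m, dt=0.002, friction=0.0,
            temperature=0.0, stride=500,
        )
        # manual velocity Verlet
        x, v = np.array([[1.0]]), np.array([[0.0]])
        for _ in range(500):
            f = -2.0 * x
            v = v + 0.5 * 0.002 * f * AKMA_ENERGY / 10.0
            x = x + 0.002 * v
            f = -2.0 * x
            v = v + 0.5 * 0.002 * f * AKMA_ENERGY / 10.0
        assert state.coords[0, 0] == pytest.approx(x[0, 0], rel=1e-10)

    def test_overdamped_cold_relaxation_to_minimum(self):
        dw = DoubleWell(1.0, 1.0)
        state = one_bead_state(x0=1.6)
        state, _ = run_segment(
            state, 20_000, dw, masses=np.array([10.0]), dt=0.005,
            friction=50.0, temperature=0.0, stride=1000,
        )
        assert state.coords[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_identical_seeds_give_bit_identical_trajectories(self):
        dw = DoubleWell(1.0, 1.0)
        out = []
        for _ in range(2):
            state = one_bead_state(seed=5, x0=1.0)
            state, frames = run_segment(
                state, 2000, dw, masses=np.array([10.0]), dt=0.01,
                friction=1.0, temperature=300.0, stride=50,
            )
            out.append(frames.coords)
        assert np.array_equal(out[0], out[1])

    def test_zero_steps_is_identity(self):
        dw = DoubleWell(1.0, 1.0)
        state = one_bead_state(x0=0.5)
        new, frames = run_segment(
            state, 0, dw, masses=np.array([10.0]), dt=0.01,
            friction=1.0, temperature=300.0,
        )
        assert np.array_equal(new.coords, state.coords)
        assert len(frames.times) == 0

    def test_zero_bias_scale_matches_unbiased_run(self, toy, toy_model):
        structure, partition = toy
        d0 = centroid_distances(structure.coords, partition)
        spec = BiasSpec.from_level(1.0, d0=d0, halfwidth=np.full(6, 3.0))

        def bias_fn(c):
            return bias_energy_forces(c, spec, partition)

        runs = []
        for bias in (None, bias_fn):
            state = SimState(
                coords=structure.coords.copy(),
                velocities=np.zeros_like(structure.coords),
                rng=np.random.default_rng(9),
            )
            state, frames = run_segment(
                state, 300, toy_model, masses=structure.masses,
                bias_fn=bias, bias_scale=0.0, dt=0.01, friction=1.0,
                temperature=300.0, stride=50,
            )
            runs.append(frames.coords)
        assert np.array_equal(runs[0], runs[1])

    def test_blowup_names_the_step(self):
        pot = Harmonic(-50.0)  # unstable on purpose
        state = one_bead_state(x0=1.0)
        with pytest.raises(IntegrationError, match="step"):
            run_segment(
                state, 5000, pot, masses=np.array([1.0]), dt=0.5,
                friction=0.0, temperature=0.0, stride=10,
            )

    def test_invalid_step_parameters_rejected(self):
        with pytest.raises(IntegrationError):
            BAOAB(np.array([1.0]), dt=-0.01, friction=1.0, temperature=300.0)
        with pytest.raises(IntegrationError):
            BAOAB(np.array([1.0]), dt=0.01, friction=-1.0, temperature=300.0)


class TestConservation:
    def test_energy_conservation_with_frozen_bias(self, toy, toy_model):
        """Symplectic (no-thermostat) integration of ENM + frozen bias:
        total-energy drift below 1 % of the mean kinetic energy over
        10,000 steps."""
        structure, partition = toy
        d0 = centroid_distances(structure.coords, partition)
        spec = BiasSpec.from_level(2.25, d0=d0 * 0.99, halfwidth=np.full(6, 3.0))

        def bias_fn(c):
            return bias_energy_forces(c, spec, partition)

        rng = np.random.default_rng(4)
        vel = maxwell_velocities(
            structure.masses, 300.0, rng, structure.coords.shape
        )
        state = SimState(
            coords=structure.coords.copy(), velocities=vel, rng=rng
        )
        masses = structure.masses

        def kinetic(s):
            return 0.5 * (masses[:, None] * s.velocities**2).sum() / AKMA_ENERGY

        ke0 = kinetic(state)
        e_start = ke0 + bias_energy_forces(state.coords, spec, partition)[0]
        state, frames = run_segment(
            state, 10_000, toy_model, masses=masses, bias_fn=bias_fn,
            bias_scale=1.0, dt=0.005, friction=0.0, temperature=0.0,
            stride=100,
        )
        ke_end = kinetic(state)
        e_end = ke_end + frames.physical_energy[-1] + frames.bias_energy[-1]
        mean_ke = 0.5 * (ke0 + ke_end)
        assert abs(e_end - e_start) < 0.01 * mean_ke

    def test_com_preserved_without_friction_or_bias(self, toy, toy_model):
        structure, _ = toy
        rng = np.random.default_rng(8)
        vel = maxwell_velocities(structure.masses, 300.0, rng, structure.coords.shape)
        vel -= vel.mean(axis=0)  # remove COM velocity
        state = SimState(coords=structure.coords.copy(), velocities=vel, rng=rng)
        state, _ = run_segment(
            state, 2000, toy_model, masses=structure.masses, dt=0.005,
            friction=0.0, temperature=0.0, stride=500,
        )
        com0 = structure.coords.mean(axis=0)
        com1 = state.coords.mean(axis=0)
        assert np.allclose(com0, com1, atol=1e-8)


class TestBoltzmannSampling:
    def test_double_well_matches_boltzmann(self):
        """Pooled unbiased Langevin sampling of the double well is not
        distinguishable from the Boltzmann distribution (χ², α=0.01)."""
        h, w, m, T = 1.0, 1.0, 20.0, 300.0
        dw = DoubleWell(h, w)
        pot_curv = 8 * h / w**2
        rng_master = np.random.SeedSequence(77)
        xs = []
        for i, seq in enumerate(rng_master.spawn(12)):
            state = SimState(
                coords=np.array([[1.0 if i % 2 else -1.0]]),
                velocities=np.zeros((1, 1)),
                rng=np.random.default_rng(seq),
            )
            state, frames = run_segment(
                state, 60_000, dw, masses=np.array([m]), dt=0.01,
                friction=1.0, temperature=T, stride=100,
            )
            xs.append(frames.coords[60:, 0, 0])
        xs = np.concatenate(xs)
        beta = 1.0 / (KB * T)

        def u(x):
            return h * ((x / w) ** 2 - 1) ** 2

        edges = np.linspace(-2.2, 2.2, 23)
        z, _ = integrate.quad(lambda x: np.exp(-beta * u(x)), -6, 6)
        probs = np.array(
            [
                integrate.quad(lambda x: np.exp(-beta * u(x)) / z, a, b)[0]
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        obs, _ = np.histogram(xs, bins=edges)
        probs /= probs.sum()
        _, p = stats.chisquare(obs, obs.sum() * probs)
        assert p > 0.01
        del pot_curv
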