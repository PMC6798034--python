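"""Coarse-grained Langevin dynamics engine.

Replaces an explicit-solvent atomistic MD layer with a desk-scale
physical model: the elastic network itself serves as the (harmonic)
potential for protein runs, and a 1D double well serves as the
closed-form reference for thermostat and exchange statistics.

Integration uses the BAOAB splitting of Langevin dynamics (half kick /
half drift / Ornstein-Uhlenbeck / half drift / half kick), which reduces
to velocity Verlet at zero friction and temperature and has excellent
configurational sampling accuracy at moderate step sizes.

Internally all stepping operates on stacked coordinate arrays of shape
``(n_replicas, n_atoms, n_dim)`` so a whole replica ladder advances in a
few vectorized numpy operations per step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .constants import AKMA_ENERGY, KB, DEFAULT_TEMPERATURE
from .enm import ENMModel
from .errors import IntegrationError

__all__ = [
    "SimState",
    "NetworkPotential",
    "physical_energy_forces",
    "langevin_step",
    "run_segment",
    "maxwell_velocities",
]


@dataclass
class SimState:
    """State of one replica's dynamics.

    ``rng`` is this replica's own random stream; exchanges swap
    coordinates between replica slots, never streams, so a run is
    bit-reproducible from the master seed.
    """

    coords: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    replica_index: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if not (
            np.all(np.isfinite(self.coords))
            and np.all(np.isfinite(self.velocities))
        ):
            raise IntegrationError("non-finite coordinates or velocities")


class NetworkPotential:
    """Harmonic pair-spring potential E = Σ ½ k_ij (r_ij − r0_ij)².

    Built from an :class:`~enmremd.enm.ENMModel`'s spring table; at the
    reference coordinates the energy and forces are exactly zero (the
    reference is the minimum).  An optional soft-core repulsion
    u(r) = ε((σ/r)² − 1)² for r < σ over *all* bead pairs guards against
    bead overlap; its force is clipped below ``r_min`` with a warning.
    """

    ndim = 3

    def __init__(
        self,
        model: ENMModel,
        repulsion_epsilon: float = 0.0,
        repulsion_sigma: float = 3.0,
        repulsion_rmin: float = 0.5,
    ):
        self.pairs = np.asarray(model.pairs)
        self.k = np.asarray(model.spring_constants)
        self.r0 = np.asarray(model.rest_lengths)
        self.n_atoms = model.n_atoms
        self.repulsion_epsilon = float(repulsion_epsilon)
        self.repulsion_sigma = float(repulsion_sigma)
        self.repulsion_rmin = float(repulsion_rmin)
        # sparse incidence matrix: atom forces = S @ pair forces
        p = len(self.pairs)
        rows = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
        cols = np.concatenate([np.arange(p), np.arange(p)])
        vals = np.concatenate([np.ones(p), -np.ones(p)])
        self._incidence = sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_atoms, p)
        )
        if self.repulsion_epsilon > 0.0:
            iu, ju = np.triu_indices(self.n_atoms, k=1)
            self._rep_pairs = np.stack([iu, ju], axis=1)

    def energy_forces(self, coords: np.ndarray):
        """Energy (per replica) and forces for (..., n_atoms, 3) coords."""
        x = np.asarray(coords, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        dvec = x[:, i, :]
        dvec -= x[:, j, :]  # (R, P, 3)
        r = np.sqrt(np.einsum("rpk,rpk->rp", dvec, dvec))
        stretch = r - self.r0
        energy = 0.5 * np.einsum("p,rp,rp->r", self.k, stretch, stretch)
        coef = self.k * stretch
        coef /= -r
        dvec *= coef[..., None]  # now the pair force along i
        n_rep = x.shape[0]
        flat = np.transpose(dvec, (1, 0, 2)).reshape(len(self.pairs), -1)
        forces = (
            self._incidence.dot(flat)
            .reshape(self.n_atoms, n_rep, 3)
            .transpose(1, 0, 2)
            .copy()
        )
        if self.repulsion_epsilon > 0.0:
            e_rep, f_rep = self._repulsion(x)
            energy = energy + e_rep
            forces = forces + f_rep
        if squeeze:
            return float(energy[0]), forces[0]
        return energy, forces

    def _repulsion(self, x: np.ndarray):
        eps, sig = self.repulsion_epsilon, self.repulsion_sigma
        i, j = self._rep_pairs[:, 0], self._rep_pairs[:, 1]
        dvec = x[:, i, :] - x[:, j, :]
        r = np.linalg.norm(dvec, axis=-1)
        if np.any(r < self.repulsion_rmin):
            warnings.warn(
                "overlapping beads under repulsion; force clipped", stacklevel=3
            )
            r = np.maximum(r, self.repulsion_rmin)
        q = (sig / r) ** 2 - 1.0
        active = r < sig
        energy = np.where(active, eps * q**2, 0.0).sum(axis=-1)
        mag = np.where(active, 4.0 * eps * q * sig**2 / r**4, 0.0)
        fpair = mag[..., None] * dvec
        forces = np.zeros_like(x)
        np.add.at(forces, (slice(None), i), fpair)
        np.add.at(forces, (slice(None), j), -fpair)
        return energy, forces


def physical_energy_forces(coords: np.ndarray, model) -> tuple:
    """Energy and forces of the physical (CG) model at ``coords``.

    ``model`` is anything exposing ``energy_forces`` (a
    :class:`NetworkPotential`, a :class:`~enmremd.fixtures.DoubleWell`, or
    an :class:`~enmremd.enm.ENMModel`, which is wrapped on the fly).
    """
    if isinstance(model, ENMModel):
        model = NetworkPotential(model)
    return model.energy_forces(coords)


def maxwell_velocities(
    masses: np.ndarray,
    temperature: float,
    rng: np.random.Generator,
    shape: tuple,
) -> np.ndarray:
    """Maxwell-Boltzmann velocities, Å/ps, for (..., n_atoms, ndim) shape."""
    sigma = np.sqrt(KB * max(temperature, 0.0) * AKMA_ENERGY / masses)
    return rng.standard_normal(shape) * sigma[..., :, None]


class BAOAB:
    """Stacked BAOAB integrator with precomputed per-atom coefficients."""

    def __init__(
        self,
        masses: np.ndarray,
        dt: float,
        friction: float,
        temperature: float,
    ):
        if dt <= 0:
            raise IntegrationError("dt must be positive")
        if friction < 0 or temperature < 0:
            raise IntegrationError("friction and temperature must be ≥ 0")
        self.dt = float(dt)
        m = np.asarray(masses, dtype=float)[:, None]  # broadcast over dims
        self.accel_per_force = AKMA_ENERGY / m  # Å/ps² per kcal/mol/Å
        self.c1 = np.exp(-friction * dt)
        sigma_v = np.sqrt(KB * temperature * AKMA_ENERGY / m)
        self.noise = np.sqrt(max(1.0 - self.c1**2, 0.0)) * sigma_v
        self.stochastic = friction > 0 and temperature > 0

    def step(self, coords, velocities, forces, force_fn, rngs):
        """One BAOAB step; ``rngs`` is one Generator per leading index."""
        dt = self.dt
        velocities = velocities + 0.5 * dt * forces * self.accel_per_force
        coords = coords + 0.5 * dt * velocities
        if self.stochastic:
            xi = np.stack(
                [rng.standard_normal(coords.shape[1:]) for rng in rngs]
            )
            velocities = self.c1 * velocities + self.noise * xi
        else:
            velocities = self.c1 * velocities
        coords = coords + 0.5 * dt * velocities
        energy, forces = force_fn(coords)
        velocities = velocities + 0.5 * dt * forces * self.accel_per_force
        return coords, velocities, energy, forces


def langevin_step(
    state: SimState,
    dt: float,
    friction: float,
    temperature: float,
    potential,
    bias_fn: Callable | None = None,
    bias_scale: float = 0.0,
) -> SimState:
    """Advance one replica by a single BAOAB step.

    With ``friction=0`` and ``temperature=0`` this is velocity Verlet.
    ``bias_fn(coords) -> (energy, forces)`` is added at ``bias_scale``.
    """
    integ = BAOAB(_masses_of(potential, state.coords), dt, friction, temperature)

    def total(c):
        e, f = physical_energy_forces(c[0], potential)
        if bias_fn is not None and bias_scale != 0.0:
            eb, fb = bias_fn(c[0])
            e, f = e + bias_scale * eb, f + bias_scale * fb
        return np.atleast_1d(e), f[None]

    _, f0 = total(state.coords[None])
    c, v, _, _ = integ.step(
        state.coords[None], state.velocities[None], f0, total, [state.rng]
    )
    return replace(
        state, coords=c[0], velocities=v[0], time=state.time + dt
    )


def _masses_of(potential, coords) -> np.ndarray:
    m = getattr(potential, "masses", None)
    if m is not None:
        return np.asarray(m, dtype=float)
    return np.full(np.asarray(coords).shape[-2], 1.0)


@dataclass
class Frames:
    """Recorded trajectory segment with energy decomposition."""

    times: np.ndarray
    coords: np.ndarray          # (n_frames, n_atoms, ndim)
    physical_energy: np.ndarray
    bias_energy: np.ndarray

    def energies_tsv(self) -> str:
        lines = ["time_ps\tphysical_kcal\tbias_kcal"]
        for t, ep, eb in zip(self.times, self.physical_energy, self.bias_energy):
            lines.append(f"{t:.4f}\t{ep:.6f}\t{eb:.6f}")
        return "\n".join(lines) + "\n"


def run_segment(
    state: SimState,
    n_steps: int,
    potential,
    masses: np.ndarray | None = None,
    bias_fn: Callable | None = None,
    bias_scale: float = 0.0,
    dt: float = 0.01,
    friction: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    stride: int = 10,
) -> tuple[SimState, Frames]:
    """Run one replica for ``n_steps``, recording every ``stride`` steps.

    The total potential is physical + ``bias_scale``·bias.  Raises
    :class:`IntegrationError` naming the step if the energy goes
    non-finite.
    """
    if masses is None:
        masses = _masses_of(potential, state.coords)
    integ = BAOAB(masses, dt, friction, temperature)
    if isinstance(potential, ENMModel):
        potential = NetworkPotential(potential)

    def total(c):
        e, f = potential.energy_forces(c)
        eb = np.zeros_like(np.atleast_1d(e))
        if bias_fn is not None and bias_scale != 0.0:
            for r in range(c.shape[0]):
                ebr, fbr = bias_fn(c[r])
                eb[r] = bias_scale * ebr
                f[r] = f[r] + bias_scale * fbr
        return np.atleast_1d(e) + eb, f, eb

    coords = state.coords[None].copy()
    vel = state.velocities[None].copy()
    e_tot, forces, e_bias = total(coords)
    times, cframes, eph, ebi = [], [], [], []
    t = state.time
    half_dt = 0.5 * dt
    accel = integ.accel_per_force
    rng = state.rng
    shape = coords.shape[1:]
    for step in range(n_steps):
        vel += half_dt * forces * accel
        coords += half_dt * vel
        vel *= integ.c1
        if integ.stochastic:
            vel += integ.noise * rng.standard_normal(shape)
        coords += half_dt * vel
        e_tot, forces, e_bias = total(coords)
        vel += half_dt * forces * accel
        t += dt
        if (step + 1) % stride == 0 or step == n_steps - 1:
            if not np.isfinite(e_tot[0]):
                raise IntegrationError(
                    f"non-finite energy at step {step + 1} (t={t:.4f} ps)"
                )
            times.append(t)
            cframes.append(coords[0].copy())
            eph.append(e_tot[0] - e_bias[0])
            ebi.append(e_bias[0])
    new_state = replace(state, coords=coords[0], velocities=vel[0], time=t)
    frames = Frames(
        times=np.array(times),
        coords=np.array(cframes) if cframes else np.zeros((0,) + coords.shape[1:]),
        physical_energy=np.array(eph),
        bias_energy=np.array(ebi),
    )
    return new_state, frames
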