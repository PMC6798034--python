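"""Hamiltonian replica exchange with adaptive bias-amplitude control.

A ladder of replicas shares one physical Hamiltonian; replica m adds the
centroid-distance bias at multiplier ``scales[m]`` (replica 0 is the
unbiased reference).  Neighbour exchanges are attempted periodically with
the Metropolis criterion; because the physical energy cancels between
replicas, only the four bias energies enter:

    p = min(1, exp(−β·[(V_m(x_n) + V_n(x_m)) − (V_m(x_m) + V_n(x_n))]))

Two adaptive elements mirror the published protocol:

* an acceptance controller: whenever any neighbour pair's acceptance over
  the control window drops below 20 % (or exceeds 60 %), every biased
  replica's amplitude is lowered (raised) by 10 %;
* reference-distance tracking: each replica's d0_ij follows the running
  average of its own sampled centroid distances over a trailing window of
  twice the control period, so the bias keeps destabilizing the *current*
  domain arrangement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .bias import (
    BiasSpec,
    ReplicaLadder,
    bias_energy,
    bias_energy_deriv,
)
from .constants import KB, DEFAULT_TEMPERATURE
from .engine import BAOAB, Frames, NetworkPotential, SimState, maxwell_velocities
from .enm import CENTROID_PAIRS, ENMModel
from .errors import ConfigurationError, GeometryError, IntegrationError
from .structure import DomainPartition

__all__ = [
    "ControllerState",
    "ExchangeRecord",
    "CentroidBias",
    "GaussianBias",
    "exchange_probability",
    "attempt_exchanges",
    "adapt_amplitudes",
    "adapt_ladder_gaps",
    "update_reference_distances",
    "run_hremd",
    "HREMDResult",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# bias wrappers

class CentroidBias:
    """Per-replica quartic centroid-distance bias with mutable d0."""

    def __init__(self, spec: BiasSpec, partition: DomainPartition):
        self.spec = spec
        self.partition = partition
        self._w = partition.membership_matrix()  # (4, N)
        self._pairs = np.array(CENTROID_PAIRS)

    def distances(self, coords: np.ndarray) -> np.ndarray:
        c = self._w @ coords
        i, j = self._pairs.T
        return np.linalg.norm(c[i] - c[j], axis=1)

    def energy(self, coords: np.ndarray) -> float:
        d = self.distances(coords)
        s = self.spec
        return float(bias_energy(d, s.d0, s.halfwidth, s.amplitude).sum())

    def energy_forces(self, coords: np.ndarray):
        c = self._w @ coords
        i, j = self._pairs.T
        diff = c[i] - c[j]
        d = np.linalg.norm(diff, axis=1)
        if np.any(d < 1e-9):
            raise GeometryError("coincident centroids")
        s = self.spec
        e = float(bias_energy(d, s.d0, s.halfwidth, s.amplitude).sum())
        dvdd = bias_energy_deriv(d, s.d0, s.halfwidth, s.amplitude)
        unit = diff / d[:, None]
        f_cent = np.zeros((4, 3))
        np.add.at(f_cent, i, -dvdd[:, None] * unit)
        np.add.at(f_cent, j, +dvdd[:, None] * unit)
        return e, self._w.T @ f_cent

    def set_d0(self, d0: np.ndarray) -> None:
        self.spec = self.spec.with_d0(d0)


class GaussianBias:
    """Barrier-lowering Gaussian bias −h·exp(−x²/2σ²) for the 1D double well.

    Used by exchange-statistics tests: higher replicas see a flattened
    barrier, so the ladder shuttles well-hopping configurations down to
    the unbiased reference.
    """

    def __init__(self, height: float, width: float, center: float = 0.0):
        self.height = float(height)
        self.width = float(width)
        self.center = float(center)

    def energy(self, coords: np.ndarray) -> float:
        x = np.asarray(coords, dtype=float)
        g = np.exp(-((x - self.center) ** 2) / (2.0 * self.width**2))
        return float(-self.height * g.sum())

    def energy_forces(self, coords: np.ndarray):
        x = np.asarray(coords, dtype=float)
        dev = x - self.center
        g = np.exp(-(dev**2) / (2.0 * self.width**2))
        e = float(-self.height * g.sum())
        forces = -self.height * g * dev / self.width**2
        return e, forces

    def distances(self, coords):  # no reference distances to track
        return None

    def set_d0(self, d0):  # pragma: no cover - interface symmetry
        pass


# --------------------------------------------------------------------------
# exchange machinery

def exchange_probability(
    v_m_xm: float,
    v_m_xn: float,
    v_n_xm: float,
    v_n_xn: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Metropolis acceptance probability for swapping two configurations.

    ``v_a_xb`` is the bias energy of configuration x_b under replica a's
    Hamiltonian (kcal/mol); the shared physical energy cancels.
    """
    beta = 1.0 / (KB * temperature)
    delta = (v_m_xn + v_n_xm) - (v_m_xm + v_n_xn)
    if delta <= 0:
        return 1.0
    with np.errstate(over="ignore", under="ignore"):
        return float(np.exp(-beta * delta))


@dataclass
class ExchangeRecord:
    """One attempted neighbour swap, reproducible from its energies."""

    time: float
    pair: tuple
    v_m_xm: float
    v_m_xn: float
    v_n_xm: float
    v_n_xn: float
    probability: float
    accepted: bool


def attempt_exchanges(
    states: list[SimState],
    ladder: ReplicaLadder,
    biases: list,
    parity: int,
    rng: np.random.Generator,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[list[SimState], list[ExchangeRecord]]:
    """Attempt swaps for all neighbour pairs of the given parity (0 or 1).

    Accepted swaps exchange coordinates and velocities between replica
    slots; bias scales (and rng streams) stay with the slot.
    """
    if len(states) != ladder.n_replicas:
        raise ConfigurationError(
            f"{len(states)} states for {ladder.n_replicas} replicas"
        )
    coords = np.stack([s.coords for s in states])
    vels = np.stack([s.velocities for s in states])
    swapped, records = _attempt_exchanges_stacked(
        coords, vels, ladder, biases, parity, rng, temperature,
        time=states[0].time,
    )
    new_states = [
        replace(s, coords=coords[i], velocities=vels[i])
        for i, s in enumerate(states)
    ]
    return new_states, records


def _attempt_exchanges_stacked(
    coords: np.ndarray,
    vels: np.ndarray,
    ladder: ReplicaLadder,
    biases: list,
    parity: int,
    rng: np.random.Generator,
    temperature: float,
    time: float = 0.0,
) -> tuple[np.ndarray, list[ExchangeRecord]]:
    """In-place stacked exchange pass; returns accepted mask and records.

    The per-replica bias multipliers are the ladder *levels* (kcal/mol
    per unit-peak bias object).
    """
    n = ladder.n_replicas
    mult = ladder.levels()
    records: list[ExchangeRecord] = []
    accepted_pairs = np.zeros(n - 1, dtype=bool)
    for m in range(parity % 2, n - 1, 2):
        nn = m + 1
        b_m_xm = biases[m].energy(coords[m]) if mult[m] != 0 else 0.0
        b_m_xn = biases[m].energy(coords[nn]) if mult[m] != 0 else 0.0
        b_n_xm = biases[nn].energy(coords[m]) if mult[nn] != 0 else 0.0
        b_n_xn = biases[nn].energy(coords[nn]) if mult[nn] != 0 else 0.0
        v = (
            mult[m] * b_m_xm,
            mult[m] * b_m_xn,
            mult[nn] * b_n_xm,
            mult[nn] * b_n_xn,
        )
        p = exchange_probability(*v, temperature=temperature)
        accept = bool(rng.random() < p)
        if accept:
            coords[[m, nn]] = coords[[nn, m]]
            vels[[m, nn]] = vels[[nn, m]]
            accepted_pairs[m] = True
        records.append(
            ExchangeRecord(
                time=time, pair=(m, nn),
                v_m_xm=v[0], v_m_xn=v[1], v_n_xm=v[2], v_n_xn=v[3],
                probability=p, accepted=accept,
            )
        )
    return accepted_pairs, records


# --------------------------------------------------------------------------
# adaptive controller

@dataclass
class ControllerState:
    """Acceptance-window controller for the bias amplitudes.

    Counters accumulate per neighbour pair over the current control
    window; :func:`adapt_amplitudes` consumes the resulting rates.
    """

    n_pairs: int
    window_low: float = 0.20
    window_high: float = 0.60
    adjust_fraction: float = 0.10
    control_period: float = 200.0   # ps of simulated time (0.2 ns)
    d0_window: float = 400.0        # ps (0.4 ns)
    attempts: np.ndarray = field(default=None)  # type: ignore[assignment]
    accepts: np.ndarray = field(default=None)   # type: ignore[assignment]
    level_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.window_low < self.window_high < 1.0):
            raise ConfigurationError("need 0 < window_low < window_high < 1")
        if not (0.0 < self.adjust_fraction < 1.0):
            raise ConfigurationError("adjust_fraction must be in (0, 1)")
        if self.attempts is None:
            self.attempts = np.zeros(self.n_pairs, dtype=int)
        if self.accepts is None:
            self.accepts = np.zeros(self.n_pairs, dtype=int)

    def record(self, records: list[ExchangeRecord]) -> None:
        for r in records:
            self.attempts[r.pair[0]] += 1
            self.accepts[r.pair[0]] += int(r.accepted)

    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.attempts > 0, self.accepts / np.maximum(self.attempts, 1), np.nan
            )

    def reset_window(self) -> None:
        self.attempts[:] = 0
        self.accepts[:] = 0


def adapt_amplitudes(
    controller: ControllerState,
    ladder: ReplicaLadder,
    acceptance: np.ndarray,
) -> ReplicaLadder:
    """Apply the ±10 % amplitude rule from per-pair acceptance estimates.

    If any pair's acceptance is below the window, all biased scales are
    multiplied by (1 − adjust_fraction); else if any is above, by
    (1 + adjust_fraction).  Lowering has priority when both occur.  Pairs
    without attempts (NaN) are ignored.
    """
    acc = np.asarray(acceptance, dtype=float)
    valid = np.isfinite(acc)
    if not np.any(valid):
        return ladder
    low = valid & (acc < controller.window_low)
    high = valid & (acc > controller.window_high)
    if np.any(low):
        pair = int(np.flatnonzero(low)[0])
        factor = 1.0 - controller.adjust_fraction
        logger.info(
            "controller: pair %d-%d acceptance %.3f < %.2f; level x%.2f",
            pair, pair + 1, acc[pair], controller.window_low, factor,
        )
        return ladder.rescaled(factor)
    if np.any(high):
        pair = int(np.flatnonzero(high)[0])
        factor = 1.0 + controller.adjust_fraction
        logger.info(
            "controller: pair %d-%d acceptance %.3f > %.2f; level x%.2f",
            pair, pair + 1, acc[pair], controller.window_high, factor,
        )
        return ladder.rescaled(factor)
    return ladder


def adapt_ladder_gaps(
    controller: ControllerState,
    ladder: ReplicaLadder,
    acceptance: np.ndarray,
) -> ReplicaLadder:
    """Per-pair variant of the ±10 % rule: tune each neighbour gap.

    The biasing-level increment between replicas m and m+1 is lowered by
    10 % when that pair's acceptance falls below the window and raised by
    10 % when it exceeds it; scales are rebuilt as the cumulative sum of
    the gaps, so the ladder stays non-decreasing with an unbiased
    reference.  Pairs without attempts (NaN) are left alone.
    """
    acc = np.asarray(acceptance, dtype=float)
    gaps = np.diff(ladder.scales)
    changed = False
    for m, a in enumerate(acc):
        if not np.isfinite(a):
            continue
        if a < controller.window_low:
            gaps[m] *= 1.0 - controller.adjust_fraction
            changed = True
            logger.info(
                "controller: pair %d-%d acceptance %.3f < %.2f; gap x%.2f",
                m, m + 1, a, controller.window_low,
                1.0 - controller.adjust_fraction,
            )
        elif a > controller.window_high:
            gaps[m] *= 1.0 + controller.adjust_fraction
            changed = True
            logger.info(
                "controller: pair %d-%d acceptance %.3f > %.2f; gap x%.2f",
                m, m + 1, a, controller.window_high,
                1.0 + controller.adjust_fraction,
            )
    if not changed:
        return ladder
    scales = np.concatenate([[0.0], np.cumsum(gaps)])
    return ReplicaLadder(scales, ladder.unit_level, ladder.reference_index)


def update_reference_distances(
    times: np.ndarray,
    distances: np.ndarray,
    spec: BiasSpec,
    window: float,
) -> BiasSpec:
    """New spec with d0 set to the trailing-window time average of d_ij.

    ``times`` (n,) and ``distances`` (n, 6) are this replica's sampled
    centroid distances.  If the history does not yet span ``window`` the
    update is skipped with a log entry and the spec returned unchanged.
    """
    times = np.asarray(times, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if len(times) == 0 or times[-1] - times[0] < window - 1e-9:
        logger.info("d0 update skipped: history shorter than %.3f ps", window)
        return spec
    mask = times >= times[-1] - window - 1e-9
    return spec.with_d0(distances[mask].mean(axis=0))


# --------------------------------------------------------------------------
# orchestrator

@dataclass
class HREMDResult:
    """Trajectories and diagnostics of one H-REMD run."""

    frames: dict                      # replica slot -> Frames
    exchange_records: list
    acceptance_history: list          # (time, per-pair rates) tuples
    level_history: list               # (time, per-replica levels) tuples
    ladder: ReplicaLadder
    n_steps: int
    dt: float

    def acceptance_by_pair(self, t_min: float = 0.0) -> np.ndarray:
        """Per-pair acceptance rate over attempts at time > ``t_min``."""
        n_pairs = self.ladder.n_replicas - 1
        att = np.zeros(n_pairs)
        acc = np.zeros(n_pairs)
        for r in self.exchange_records:
            if r.time > t_min:
                att[r.pair[0]] += 1
                acc[r.pair[0]] += int(r.accepted)
        with np.errstate(invalid="ignore"):
            return acc / np.maximum(att, 1) * np.where(att > 0, 1.0, np.nan)

    def acceptance_tsv(self) -> str:
        lines = ["time_ps\t" + "\t".join(
            f"pair_{m}_{m + 1}" for m in range(self.ladder.n_replicas - 1)
        )]
        for t, rates in self.acceptance_history:
            lines.append(
                f"{t:.4f}\t" + "\t".join(f"{r:.4f}" for r in rates)
            )
        return "\n".join(lines) + "\n"

    def levels_tsv(self) -> str:
        lines = ["time_ps\t" + "\t".join(
            f"replica_{m}" for m in range(self.ladder.n_replicas)
        )]
        for t, levels in self.level_history:
            lines.append(f"{t:.4f}\t" + "\t".join(f"{v:.5f}" for v in levels))
        return "\n".join(lines) + "\n"

    def exchanges_tsv(self) -> str:
        lines = ["time_ps\tpair\tprobability\taccepted"]
        for r in self.exchange_records:
            lines.append(
                f"{r.time:.4f}\t{r.pair[0]}-{r.pair[1]}\t"
                f"{r.probability:.6f}\t{int(r.accepted)}"
            )
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# stacked bias adapters (vectorized hot path over the whole ladder)

class _StackedCentroidBias:
    """All replicas' centroid biases evaluated in a few array operations.

    Holds the shared half-widths/amplitudes (unit peak) and a (R, 6) array
    of per-replica reference distances d0.
    """

    def __init__(self, biases: list):
        spec0 = biases[0].spec
        self.partition = biases[0].partition
        self._w = biases[0]._w                      # (4, N)
        self.halfwidth = spec0.halfwidth
        self.amplitude = spec0.amplitude
        self.d0 = np.stack([b.spec.d0 for b in biases])  # (R, 6)
        self._pairs = np.array(CENTROID_PAIRS)
        # centroid incidence: force on centroid c = sum_p inc[c,p] * f_pair[p]
        inc = np.zeros((4, 6))
        for p, (a, b) in enumerate(CENTROID_PAIRS):
            inc[a, p] = 1.0
            inc[b, p] = -1.0
        self._inc = inc
        self._biases = biases
        self._last_d = None

    def distances(self, coords: np.ndarray) -> np.ndarray:
        cent = np.einsum("dn,rnk->rdk", self._w, coords)
        i, j = self._pairs.T
        diff = cent[:, i, :] - cent[:, j, :]
        return np.linalg.norm(diff, axis=-1), diff

    def unit_energy_forces(self, coords: np.ndarray):
        cent = np.einsum("dn,rnk->rdk", self._w, coords)
        i, j = self._pairs.T
        diff = cent[:, i, :] - cent[:, j, :]              # (R, 6, 3)
        d = np.linalg.norm(diff, axis=-1)                 # (R, 6)
        if np.any(d < 1e-9):
            raise GeometryError("coincident centroids")
        self._last_d = d
        dev = d - self.d0
        q = dev**2 - self.halfwidth**2
        inside = np.abs(dev) <= self.halfwidth
        e = np.where(inside, self.amplitude * q**2, 0.0).sum(axis=1)
        dvdd = np.where(inside, 4.0 * self.amplitude * dev * q, 0.0)
        fpair = (-dvdd / d)[..., None] * diff             # (R, 6, 3)
        f_cent = np.einsum("cp,rpk->rck", self._inc, fpair)
        forces = np.einsum("dn,rdk->rnk", self._w, f_cent)  # w.T @ f_cent
        return e, forces

    def unit_cross_energy(self, d_all: np.ndarray, ham: int, cfg: int) -> float:
        """Unit bias energy of configuration ``cfg`` under replica ``ham``'s d0."""
        dev = d_all[cfg] - self.d0[ham]
        q = dev**2 - self.halfwidth**2
        inside = np.abs(dev) <= self.halfwidth
        return float(np.where(inside, self.amplitude * q**2, 0.0).sum())

    def set_d0(self, m: int, d0: np.ndarray) -> None:
        self.d0[m] = d0
        self._biases[m].set_d0(d0)


class _StackedGaussianBias:
    """All replicas' (identical, unit) Gaussian biases in one vector op."""

    def __init__(self, biases: list):
        b0 = biases[0]
        self.height = b0.height
        self.width = b0.width
        self.center = b0.center
        self._biases = biases

    def distances(self, coords):
        return None, None

    def unit_energy_forces(self, coords: np.ndarray):
        dev = coords - self.center
        g = np.exp(-(dev**2) / (2.0 * self.width**2))
        e = -self.height * g.sum(axis=(-2, -1))
        f = -self.height * g * dev / self.width**2
        return e, f

    def unit_cross_energy(self, coords_all, ham: int, cfg: int) -> float:
        dev = coords_all[cfg] - self.center
        g = np.exp(-(dev**2) / (2.0 * self.width**2))
        return float(-self.height * g.sum())

    def set_d0(self, m, d0):  # nothing to track
        pass


class _StackedGenericBias:
    """Fallback adapter looping over arbitrary per-replica bias objects."""

    def __init__(self, biases: list):
        self._biases = biases

    def distances(self, coords: np.ndarray):
        d = [b.distances(coords[m]) for m, b in enumerate(self._biases)]
        if any(x is None for x in d):
            return None, None
        return np.stack(d), None

    def unit_energy_forces(self, coords: np.ndarray):
        e = np.empty(len(self._biases))
        f = np.empty_like(coords)
        for m, b in enumerate(self._biases):
            e[m], f[m] = b.energy_forces(coords[m])
        return e, f

    def unit_cross_energy(self, coords_all, ham: int, cfg: int) -> float:
        return self._biases[ham].energy(coords_all[cfg])

    def set_d0(self, m: int, d0) -> None:
        self._biases[m].set_d0(d0)


def _make_adapter(biases: list):
    if all(isinstance(b, CentroidBias) for b in biases):
        return _StackedCentroidBias(biases)
    if (
        all(isinstance(b, GaussianBias) for b in biases)
        and len({(b.height, b.width, b.center) for b in biases}) == 1
    ):
        return _StackedGaussianBias(biases)
    return _StackedGenericBias(biases)


def run_hremd(
    potential,
    biases: list,
    ladder: ReplicaLadder,
    init_coords: np.ndarray,
    masses: np.ndarray,
    *,
    n_steps: int,
    exchange_period_steps: int,
    control_period_steps: int,
    d0_window_steps: int,
    temperature: float = DEFAULT_TEMPERATURE,
    dt: float = 0.01,
    friction: float = 1.0,
    output_stride: int = 20,
    seed: int = 0,
    adapt: bool = True,
    controller_mode: str = "per_pair",
    update_d0: bool = True,
    d0_mode: str = "shared",
    record_replicas: tuple = (0,),
    controller: ControllerState | None = None,
) -> HREMDResult:
    """Run the full adaptive H-REMD simulation.

    ``d0_mode`` selects how the bias reference distances track the
    simulation: ``"shared"`` (default) keeps a single bias shape for the
    whole ladder, with d0 the trailing running average pooled over every
    replica — only the amplitude differs between replicas, as in a ladder
    of "increasing amplitudes" of one potential; ``"per_replica"`` lets
    each replica's d0 follow its own trajectory.

    The bias objects must have *unit* peak amplitude; the per-replica
    multipliers are the ladder levels (kcal/mol), so replica 0 — the
    unbiased reference — always runs on the unmodified physical
    Hamiltonian.  Exchanges are attempted every ``exchange_period_steps``
    with alternating even/odd neighbour parity; controller and d0 updates
    happen every ``control_period_steps`` with the d0 running average over
    the trailing ``d0_window_steps``.

    Fully reproducible from ``seed``: one spawned rng stream per replica,
    plus one for exchange decisions and one for initial velocities.
    """
    n_rep = ladder.n_replicas
    if len(biases) != n_rep:
        raise ConfigurationError("one bias object per replica required")
    if d0_mode not in ("shared", "per_replica"):
        raise ConfigurationError(f"unknown d0_mode {d0_mode!r}")
    if controller_mode not in ("per_pair", "global"):
        raise ConfigurationError(f"unknown controller_mode {controller_mode!r}")
    if isinstance(potential, ENMModel):
        potential = NetworkPotential(potential)
    init_coords = np.asarray(init_coords, dtype=float)
    if init_coords.ndim == 2:
        coords = np.repeat(init_coords[None], n_rep, axis=0).copy()
    else:
        coords = init_coords.copy()
    seqs = np.random.SeedSequence(seed).spawn(n_rep + 2)
    rngs = [np.random.default_rng(s) for s in seqs[:n_rep]]
    rng_ex = np.random.default_rng(seqs[n_rep])
    rng_init = np.random.default_rng(seqs[n_rep + 1])
    vels = maxwell_velocities(masses, temperature, rng_init, coords.shape)

    integ = BAOAB(masses, dt, friction, temperature)
    adapter = _make_adapter(biases)
    mult = ladder.levels()
    beta = 1.0 / (KB * temperature) if temperature > 0 else np.inf

    if controller is None:
        controller = ControllerState(
            n_pairs=n_rep - 1,
            control_period=control_period_steps * dt,
            d0_window=d0_window_steps * dt,
        )
    hist_len = max(d0_window_steps // exchange_period_steps + 1, 2)
    d_hist_t: list = [[] for _ in range(n_rep)]
    d_hist: list = [[] for _ in range(n_rep)]

    n_segments = n_steps // exchange_period_steps
    records: list[ExchangeRecord] = []
    acceptance_history: list = []
    level_history: list = [(0.0, ladder.levels().copy())]
    frame_times: dict = {m: [] for m in record_replicas}
    frame_coords: dict = {m: [] for m in record_replicas}
    frame_eph: dict = {m: [] for m in record_replicas}
    frame_ebi: dict = {m: [] for m in record_replicas}

    # cached energy/force components; the bias part is cheap to refresh on
    # its own after swaps, d0 updates or amplitude changes, the physical
    # part swaps exactly with the coordinates
    e_phys, f_phys = potential.energy_forces(coords)
    e_bias, f_bias = adapter.unit_energy_forces(coords)
    forces = f_phys + mult[:, None, None] * f_bias
    accel = integ.accel_per_force  # (N, 1) broadcastable
    half_dt = 0.5 * dt
    t = 0.0
    step = 0
    kick_shape = (exchange_period_steps,) + coords.shape[1:]
    for seg in range(n_segments):
        if integ.stochastic:
            # one block draw per replica per segment: same per-stream value
            # sequence as per-step draws, far less call overhead
            kicks = np.stack(
                [rng.standard_normal(kick_shape) for rng in rngs], axis=1
            )
            kicks *= integ.noise
        for k in range(exchange_period_steps):
            vels += half_dt * forces * accel
            coords += half_dt * vels
            vels *= integ.c1
            if integ.stochastic:
                vels += kicks[k]
            coords += half_dt * vels
            e_phys, f_phys = potential.energy_forces(coords)
            e_bias, f_bias = adapter.unit_energy_forces(coords)
            forces = f_phys + mult[:, None, None] * f_bias
            vels += half_dt * forces * accel
            step += 1
            t = step * dt
            if step % output_stride == 0:
                if not np.all(np.isfinite(e_phys)):
                    bad = int(np.flatnonzero(~np.isfinite(e_phys))[0])
                    raise IntegrationError(
                        f"replica {bad} blew up at step {step} (t={t:.4f} ps)"
                    )
                for m in record_replicas:
                    frame_times[m].append(t)
                    frame_coords[m].append(coords[m].copy())
                    frame_eph[m].append(float(e_phys[m]))
                    frame_ebi[m].append(float(mult[m] * e_bias[m]))
        # sample centroid distances for the d0 running averages
        d_all, _ = adapter.distances(coords)
        if d_all is not None:
            for m in range(n_rep):
                d_hist_t[m].append(t)
                d_hist[m].append(d_all[m].copy())
                if len(d_hist[m]) > hist_len:
                    d_hist_t[m].pop(0)
                    d_hist[m].pop(0)
            cross_src = d_all
        else:
            cross_src = coords
        # neighbour exchanges, alternating parity
        any_accept = False
        for m in range(seg % 2, n_rep - 1, 2):
            nn = m + 1
            b_m_xm = adapter.unit_cross_energy(cross_src, m, m) if mult[m] else 0.0
            b_m_xn = adapter.unit_cross_energy(cross_src, m, nn) if mult[m] else 0.0
            b_n_xm = adapter.unit_cross_energy(cross_src, nn, m) if mult[nn] else 0.0
            b_n_xn = adapter.unit_cross_energy(cross_src, nn, nn) if mult[nn] else 0.0
            v = (
                mult[m] * b_m_xm,
                mult[m] * b_m_xn,
                mult[nn] * b_n_xm,
                mult[nn] * b_n_xn,
            )
            delta = (v[1] + v[2]) - (v[0] + v[3])
            p = 1.0 if delta <= 0 else float(np.exp(-beta * delta))
            accept = bool(rng_ex.random() < p)
            if accept:
                coords[[m, nn]] = coords[[nn, m]]
                vels[[m, nn]] = vels[[nn, m]]
                f_phys[[m, nn]] = f_phys[[nn, m]]
                e_phys[[m, nn]] = e_phys[[nn, m]]
                any_accept = True
            records.append(
                ExchangeRecord(
                    time=t, pair=(m, nn),
                    v_m_xm=v[0], v_m_xn=v[1], v_n_xm=v[2], v_n_xn=v[3],
                    probability=p, accepted=accept,
                )
            )
            controller.attempts[m] += 1
            controller.accepts[m] += int(accept)
        if any_accept:
            # physical components were swapped with the coordinates; only
            # the (cheap) bias part needs re-evaluation under each slot's d0
            e_bias, f_bias = adapter.unit_energy_forces(coords)
            forces = f_phys + mult[:, None, None] * f_bias
        # controller + d0 updates on the control grid
        if step % control_period_steps == 0:
            rates = controller.rates()
            acceptance_history.append((t, rates))
            if adapt:
                if controller_mode == "per_pair":
                    new_ladder = adapt_ladder_gaps(controller, ladder, rates)
                else:
                    new_ladder = adapt_amplitudes(controller, ladder, rates)
                if new_ladder is not ladder:
                    ladder = new_ladder
                    mult = ladder.levels()
                    forces = f_phys + mult[:, None, None] * f_bias
            level_history.append((t, ladder.levels().copy()))
            controller.level_history.append((t, ladder.levels().copy()))
            controller.reset_window()
            if update_d0 and d_hist[0]:
                window = controller.d0_window
                if d0_mode == "shared":
                    # one bias shape for the whole ladder: pool the trailing
                    # window over every replica's sampled distances
                    times_0 = np.array(d_hist_t[0])
                    if times_0[-1] - times_0[0] >= window - 1e-9:
                        mask = times_0 >= times_0[-1] - window - 1e-9
                        pooled = np.mean(
                            [np.array(d_hist[m])[mask] for m in range(n_rep)],
                            axis=(0, 1),
                        )
                        for m in range(n_rep):
                            adapter.set_d0(m, pooled)
                    else:
                        logger.info("d0 update skipped: short history")
                else:
                    for m in range(n_rep):
                        if mult[m] == 0.0:
                            continue
                        times_m = np.array(d_hist_t[m])
                        if times_m[-1] - times_m[0] < window - 1e-9:
                            logger.info(
                                "d0 update skipped for replica %d: short history",
                                m,
                            )
                            continue
                        mask = times_m >= times_m[-1] - window - 1e-9
                        adapter.set_d0(m, np.array(d_hist[m])[mask].mean(axis=0))
                e_bias, f_bias = adapter.unit_energy_forces(coords)
                forces = f_phys + mult[:, None, None] * f_bias

    frames = {
        m: Frames(
            times=np.array(frame_times[m]),
            coords=np.array(frame_coords[m])
            if frame_coords[m]
            else np.zeros((0,) + coords.shape[1:]),
            physical_energy=np.array(frame_eph[m]),
            bias_energy=np.array(frame_ebi[m]),
        )
        for m in record_replicas
    }
    return HREMDResult(
        frames=frames,
        exchange_records=records,
        acceptance_history=acceptance_history,
        level_history=level_history,
        ladder=ladder,
        n_steps=n_steps,
        dt=dt,
    )
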