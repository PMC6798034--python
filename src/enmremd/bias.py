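"""Centroid-distance biasing potential and replica bias ladder.

The bias on each of the six inter-centroid distances d_ij is the quartic
bump

    V(d_ij) = k·((d_ij − d0_ij)² − Δd_ij²)²   if |d_ij − d0_ij| ≤ Δd_ij
    V(d_ij) = 0                               otherwise

which is maximal (k·Δd⁴) at the current reference arrangement d0 and
vanishes C¹-continuously at the window edges ±Δd: it *destabilizes* the
present domain arrangement without preferring any direction of escape.
The printed "biasing level" (kcal/mol) is the peak height k·Δd⁴ per pair;
``k`` itself (kcal mol⁻¹ Å⁻⁴) is derived from the requested level and the
ENM-derived half-width Δd of each pair.

A :class:`ReplicaLadder` holds per-replica dimensionless multipliers of
the unit-level bias; replica 0 is always the unbiased reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .enm import CENTROID_PAIRS
from .errors import ConfigurationError, GeometryError, PartitionError
from .structure import DomainPartition

__all__ = [
    "BiasSpec",
    "ReplicaLadder",
    "compute_centroids",
    "centroid_distances",
    "bias_energy",
    "bias_energy_deriv",
    "bias_forces",
    "total_bias_energy",
    "bias_energy_forces",
    "build_ladder",
]


def compute_centroids(coords: np.ndarray, p: DomainPartition) -> np.ndarray:
    """Unweighted mean Cα position of each of the four domains, (4, 3) Å."""
    if np.any(p.sizes() == 0):
        raise PartitionError("empty domain in partition")
    return p.membership_matrix() @ np.asarray(coords, dtype=float)


def centroid_distances(coords: np.ndarray, p: DomainPartition) -> np.ndarray:
    """The six pairwise centroid distances, Å, in canonical pair order."""
    c = compute_centroids(coords, p)
    i, j = np.array(CENTROID_PAIRS).T
    d = np.linalg.norm(c[i] - c[j], axis=1)
    if np.any(d < 1e-9):
        raise GeometryError("coincident centroids")
    return d


@dataclass
class BiasSpec:
    """Per-pair bias parameters for the four-centroid system.

    ``d0`` and ``halfwidth`` are (6,) arrays in Å over the canonical pair
    order [(1,2),(1,3),(1,4),(2,3),(2,4),(3,4)]; ``amplitude`` is the (6,)
    quartic coefficient k in kcal mol⁻¹ Å⁻⁴.
    """

    d0: np.ndarray
    halfwidth: np.ndarray
    amplitude: np.ndarray
    pairs: tuple = field(default=CENTROID_PAIRS)

    def __post_init__(self) -> None:
        self.d0 = np.atleast_1d(np.asarray(self.d0, dtype=float))
        self.halfwidth = np.atleast_1d(np.asarray(self.halfwidth, dtype=float))
        self.amplitude = np.broadcast_to(
            np.asarray(self.amplitude, dtype=float), self.d0.shape
        ).copy()
        if len(self.pairs) != 6 or len(self.d0) != 6:
            raise ConfigurationError("four centroids require exactly 6 pairs")
        if np.any(self.halfwidth <= 0):
            raise ConfigurationError("halfwidths Δd must be positive")
        if np.any(self.d0 <= 0):
            raise ConfigurationError("reference distances d0 must be positive")
        if np.any(self.amplitude < 0):
            raise ConfigurationError("amplitude k must be ≥ 0")

    @classmethod
    def from_level(
        cls, level: float, d0: np.ndarray, halfwidth: np.ndarray
    ) -> "BiasSpec":
        """Build a spec whose per-pair peak height k·Δd⁴ equals ``level``."""
        halfwidth = np.asarray(halfwidth, dtype=float)
        return cls(d0=d0, halfwidth=halfwidth, amplitude=level / halfwidth**4)

    def peak_heights(self) -> np.ndarray:
        """Per-pair maximum bias k·Δd⁴, kcal/mol (at d = d0)."""
        return self.amplitude * self.halfwidth**4

    def with_d0(self, d0: np.ndarray) -> "BiasSpec":
        return replace(self, d0=np.asarray(d0, dtype=float))

    def to_tsv(self) -> str:
        lines = ["pair\td0\thalfwidth\tpeak_height"]
        for (a, b), d0, hw, pk in zip(
            self.pairs, self.d0, self.halfwidth, self.peak_heights()
        ):
            lines.append(f"c{a + 1}-c{b + 1}\t{d0:.4f}\t{hw:.4f}\t{pk:.4f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "BiasSpec":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        if len(rows) != 6:
            raise ConfigurationError(f"expected 6 pair rows, got {len(rows)}")
        d0 = np.array([float(r[1]) for r in rows])
        hw = np.array([float(r[2]) for r in rows])
        peak = np.array([float(r[3]) for r in rows])
        return cls(d0=d0, halfwidth=hw, amplitude=peak / hw**4)


def bias_energy(d, d0, halfwidth, k):
    """Quartic bump energy, kcal/mol (vectorized over pairs)."""
    d = np.asarray(d, dtype=float)
    dev = d - d0
    inside = np.abs(dev) <= halfwidth
    return np.where(inside, k * (dev**2 - np.asarray(halfwidth) ** 2) ** 2, 0.0)


def bias_energy_deriv(d, d0, halfwidth, k):
    """dV/dd, kcal mol⁻¹ Å⁻¹; zero outside the window and at d = d0."""
    d = np.asarray(d, dtype=float)
    dev = d - d0
    inside = np.abs(dev) <= halfwidth
    return np.where(inside, 4.0 * k * dev * (dev**2 - np.asarray(halfwidth) ** 2), 0.0)


def total_bias_energy(
    coords: np.ndarray, spec: BiasSpec, p: DomainPartition, scale: float = 1.0
) -> float:
    """Sum of the six pair bias terms, kcal/mol, at bias multiplier ``scale``."""
    d = centroid_distances(coords, p)
    return float(scale * bias_energy(d, spec.d0, spec.halfwidth, spec.amplitude).sum())


def bias_forces(
    coords: np.ndarray, spec: BiasSpec, p: DomainPartition, scale: float = 1.0
) -> np.ndarray:
    """Per-atom bias forces, kcal mol⁻¹ Å⁻¹, shape (n_atoms, 3).

    The force −dV/dd_ij acts along the centroid-centroid unit vector and
    is distributed equally over each domain's member atoms (∂centroid/∂x
    = 1/N_domain); net force and net torque of the total bias vanish.
    """
    return bias_energy_forces(coords, spec, p, scale)[1]


def bias_energy_forces(
    coords: np.ndarray, spec: BiasSpec, p: DomainPartition, scale: float = 1.0
) -> tuple[float, np.ndarray]:
    coords = np.asarray(coords, dtype=float)
    w = p.membership_matrix()
    centroids = w @ coords
    i, j = np.array(CENTROID_PAIRS).T
    diff = centroids[i] - centroids[j]  # (6, 3)
    d = np.linalg.norm(diff, axis=1)
    if np.any(d < 1e-9):
        raise GeometryError("coincident centroids: bias direction undefined")
    unit = diff / d[:, None]
    energy = scale * bias_energy(d, spec.d0, spec.halfwidth, spec.amplitude).sum()
    dvdd = scale * bias_energy_deriv(d, spec.d0, spec.halfwidth, spec.amplitude)
    # force on centroid a of pair p: -dV/dd * unit; on centroid b: +...
    f_cent = np.zeros((4, 3))
    np.add.at(f_cent, i, -dvdd[:, None] * unit)
    np.add.at(f_cent, j, +dvdd[:, None] * unit)
    forces = w.T @ f_cent  # chain rule through the unweighted mean
    return float(energy), forces


@dataclass
class ReplicaLadder:
    """Per-replica bias multipliers; replica 0 is the unbiased reference.

    ``unit_level`` is the per-pair peak height (kcal/mol) corresponding to
    multiplier 1, so replica m's per-pair peak bias is
    ``scales[m] * unit_level``.
    """

    scales: np.ndarray
    unit_level: float
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if len(self.scales) < 2:
            raise ConfigurationError("ladder needs at least 2 replicas")
        if self.scales[0] != 0.0:
            raise ConfigurationError("reference replica scale must be 0")
        if np.any(np.diff(self.scales) < 0):
            raise ConfigurationError("scales must be non-decreasing")
        if np.any(self.scales < 0):
            raise ConfigurationError("scales must be ≥ 0")

    @property
    def n_replicas(self) -> int:
        return len(self.scales)

    def levels(self) -> np.ndarray:
        """Per-replica per-pair peak bias heights, kcal/mol."""
        return self.scales * self.unit_level

    def rescaled(self, factor: float) -> "ReplicaLadder":
        scales = self.scales.copy()
        scales[1:] = np.maximum(scales[1:] * factor, 0.0)
        return ReplicaLadder(scales, self.unit_level, self.reference_index)


def build_ladder(
    n_replicas: int = 12,
    start_increment: float = 2.25,
    spacing: str = "linear",
    geometric_ratio: float = 1.3,
) -> ReplicaLadder:
    """Replica ladder with the peak bias growing per replica step.

    With linear spacing (default) replica m has per-pair peak bias
    m·``start_increment`` kcal/mol, so consecutive replicas start
    ``start_increment`` apart; replica 0 is unbiased.
    """
    if n_replicas < 2:
        raise ConfigurationError("n_replicas must be ≥ 2")
    if spacing == "linear":
        scales = np.arange(n_replicas, dtype=float)
    elif spacing == "geometric":
        scales = np.concatenate(
            [[0.0], geometric_ratio ** np.arange(n_replicas - 1, dtype=float)]
        )
    else:
        raise ConfigurationError(f"unknown ladder spacing {spacing!r}")
    return ReplicaLadder(scales=scales, unit_level=float(start_increment))
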