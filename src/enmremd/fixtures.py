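"""Deterministic synthetic systems for end-to-end testing without downloads.

Two fixtures:

* a hinged four-domain *toy dimer* standing in for a truncated two-monomer
  chaperone: two helical-arc "arms", each made of a central (C-like) and a
  terminal (M-like) bead domain, joined at a C–C interface.  Its softest
  internal elastic-network mode is a hinge/opening motion that mainly
  changes the c1–c4 (terminal-terminal) centroid distance.
* a 1D *double well* particle, the closed-form reference system for
  Langevin-thermostat and replica-exchange statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .structure import CoarseStructure, DomainPartition, assign_domains

__all__ = ["ToyDimerParams", "make_toy_dimer", "DoubleWell", "make_double_well"]


@dataclass
class ToyDimerParams:
    """Geometry of the synthetic four-domain dimer.

    beads_per_domain : beads in each of the 4 domains (default 20 → 80 beads)
    hinge_angle : angle in degrees between the two arm axes (180° = collinear)
    bead_spacing : target adjacent-bead distance, Å (Cα-like 3.8 Å)
    helix_radius : radius of the helical arc each arm follows, Å
    interface_gap : distance between the two innermost beads, Å
    jitter : σ of seeded Gaussian positional noise, Å
    """

    beads_per_domain: int = 20
    hinge_angle: float = 100.0
    bead_spacing: float = 3.8
    helix_radius: float = 2.0
    axial_rise: float = 3.0
    interface_gap: float = 5.0
    jitter: float = 0.1
    seed: int = 0


def _arm_coords(p: ToyDimerParams, sign: float) -> np.ndarray:
    """Bead positions of one arm, from the interface outward."""
    n = 2 * p.beads_per_domain
    half = np.deg2rad(p.hinge_angle / 2.0)
    u = np.array([sign * np.sin(half), 0.0, np.cos(half)])
    n1 = np.array([0.0, 1.0, 0.0])
    n2 = np.cross(u, n1)
    n2 /= np.linalg.norm(n2)
    # twist per bead chosen so the helical chord matches bead_spacing
    chord = np.sqrt(max(p.bead_spacing**2 - p.axial_rise**2, 0.0))
    twist = 2.0 * np.arcsin(min(chord / (2.0 * p.helix_radius), 1.0))
    t = np.arange(n)
    start = np.array([sign * p.interface_gap / 2.0, 0.0, 0.0])
    return (
        start
        + t[:, None] * p.axial_rise * u
        + p.helix_radius
        * (np.cos(twist * t)[:, None] * n1 + np.sin(twist * t)[:, None] * n2)
    )


def make_toy_dimer(
    params: ToyDimerParams | None = None,
) -> tuple[CoarseStructure, DomainPartition]:
    """Build the deterministic toy dimer.

    Returns the Cα-like structure and its four-domain partition in the
    canonical centroid order: domain 1 = terminal (M-like) domain of arm 1,
    domains 2 and 3 = the two interface (C-like) domains, domain 4 =
    terminal domain of arm 2.
    """
    p = params or ToyDimerParams()
    if p.beads_per_domain < 3:
        raise ConfigurationError("beads_per_domain must be ≥ 3")
    rng = np.random.default_rng(p.seed)
    n = p.beads_per_domain
    arms = [_arm_coords(p, -1.0), _arm_coords(p, +1.0)]
    coords = np.concatenate(arms, axis=0)
    coords = coords + rng.normal(scale=p.jitter, size=coords.shape)
    n_total = 4 * n
    s = CoarseStructure(
        coords=coords,
        residue_ids=np.concatenate([np.arange(1, 2 * n + 1)] * 2),
        chain_ids=np.repeat(["A", "B"], 2 * n),
        masses=np.full(n_total, 110.0),
    )
    partition = assign_domains(s, default_domain_ranges(p.beads_per_domain))
    return s, partition


def default_domain_ranges(beads_per_domain: int = 20):
    """The toy dimer's shipped domain ranges (interface-first numbering)."""
    n = beads_per_domain
    return {
        # chain A: residues 1..n at the interface (C-like, centroid c2),
        # residues n+1..2n terminal (M-like, centroid c1)
        "A": [(1, n, 2), (n + 1, 2 * n, 1)],
        "B": [(1, n, 3), (n + 1, 2 * n, 4)],
    }


class DoubleWell:
    """1D symmetric quartic double well u(x) = h((x/w)² − 1)².

    Minima at x = ±w with u = 0, barrier of height ``h`` at x = 0.
    Acts on the x component of a single bead; used as the closed-form
    reference system for thermostat and replica-exchange statistics.
    """

    ndim = 1

    def __init__(self, height: float, half_separation: float):
        if height <= 0 or half_separation <= 0:
            raise ConfigurationError("double well needs h > 0 and w > 0")
        self.height = float(height)
        self.half_separation = float(half_separation)

    def energy(self, x):
        q = (np.asarray(x) / self.half_separation) ** 2 - 1.0
        return self.height * q**2

    def energy_forces(self, coords: np.ndarray):
        """Energy and forces for coords of shape (..., 1, 1)."""
        x = np.asarray(coords, dtype=float)
        h, w = self.height, self.half_separation
        q = (x / w) ** 2 - 1.0
        energy = (h * q**2).sum(axis=(-2, -1))
        forces = -4.0 * h * q * x / w**2
        return energy, forces


def make_double_well(height: float, half_separation: float) -> DoubleWell:
    """Factory kept for symmetry with :func:`make_toy_dimer`."""
    return DoubleWell(height, half_separation)
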