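"""Elastic network model: Hessian assembly, normal modes, thermal excitation,
and inter-centroid distance-fluctuation amplitudes.

The network connects Cα beads by harmonic pair springs.  Two named spring
rules are provided:

``hinsen``
    Distance-dependent force constants in the style of Hinsen's Cα force
    field: a linear law k(r) = 205.5·r − 571.2 kcal mol⁻¹ Å⁻² for pair
    distances below 4 Å (i.e. sequence-neighbour contacts) and an r⁻⁶
    decay k(r) = 305920·r⁻⁶ at and above 4 Å, applied to all pairs.
``cutoff``
    Uniform force constant (default 1 kcal mol⁻¹ Å⁻²) for all pairs
    within a cutoff (default 10 Å); the classic anisotropic network model.

Normal modes are eigenpairs of the mass-weighted Hessian; the first
``n_modes`` non-rigid modes are excited each with a thermal energy of RT,
giving per-mode amplitudes a_k = sqrt(2RT/λ_k) in mass-weighted
coordinates.  The amplitudes of the six inter-centroid distance
fluctuations, Δd_ij, follow by first-order propagation of the mode
displacements onto the centroid distances; they set the half-widths of
the biasing potential.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .constants import KB, DEFAULT_TEMPERATURE
from .errors import ConfigurationError, GeometryError, NumericalError
from .structure import CoarseStructure, DomainPartition

__all__ = [
    "ENMModel",
    "ModeExcitation",
    "build_network",
    "compute_modes",
    "excite_modes",
    "distance_fluctuations",
    "hinsen_spring_constant",
]

logger = logging.getLogger(__name__)

#: relative eigenvalue threshold below which a mode counts as rigid-body;
#: true rigid modes sit at machine zero while the softest internal modes of
#: a weakly-coupled multi-domain network can be ~1e-8 of the stiffest, so
#: the threshold must sit well below that scale
RIGID_THRESHOLD = 1e-10

#: force constants below this (kcal/mol/Å²) are pruned from the pair list
SPRING_PRUNE = 1e-6


def hinsen_spring_constant(r):
    """Distance-dependent force constant, kcal mol⁻¹ Å⁻², for distance r in Å."""
    r = np.asarray(r, dtype=float)
    return np.where(r < 4.0, 205.545 * r - 571.22, 305920.0 * r ** -6.0)


@dataclass
class ENMModel:
    """Elastic network with (optionally) computed normal modes.

    ``eigenvalues`` are ascending, in kcal mol⁻¹ Å⁻² amu⁻¹ (mass-weighted);
    ``eigenvectors[:, k]`` is the orthonormal mode k in mass-weighted
    displacement coordinates of length 3N.
    """

    ref_coords: np.ndarray          # (N, 3) Å
    pairs: np.ndarray               # (P, 2) int
    spring_constants: np.ndarray    # (P,) kcal/mol/Å²
    rest_lengths: np.ndarray        # (P,) Å
    masses: np.ndarray              # (N,) amu
    hessian: np.ndarray             # (3N, 3N) mass-weighted
    connected: bool = True
    eigenvalues: np.ndarray | None = field(default=None)
    eigenvectors: np.ndarray | None = field(default=None)
    n_rigid: int | None = field(default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.ref_coords)

    def nonrigid_indices(self) -> np.ndarray:
        if self.eigenvalues is None:
            raise NumericalError("modes not computed yet")
        return np.arange(self.n_rigid, len(self.eigenvalues))


@dataclass
class ModeExcitation:
    """Thermal excitation of the first soft internal modes.

    Each selected mode k carries an energy of RT at full amplitude:
    a_k = sqrt(2RT/λ_k), in mass-weighted coordinates (Å·amu^½).
    """

    mode_indices: np.ndarray
    temperature: float
    amplitudes: np.ndarray


def _spring_table(coords: np.ndarray, rule: str, **params):
    n = len(coords)
    dists = squareform(pdist(coords))
    iu, ju = np.triu_indices(n, k=1)
    r = dists[iu, ju]
    if rule == "hinsen":
        k = hinsen_spring_constant(r)
        keep = k > SPRING_PRUNE
    elif rule == "cutoff":
        cutoff = float(params.get("cutoff", 10.0))
        k_uniform = float(params.get("k", 1.0))
        keep = r <= cutoff
        k = np.full(r.shape, k_uniform)
    else:
        raise ConfigurationError(f"unknown spring rule {rule!r}")
    pairs = np.stack([iu[keep], ju[keep]], axis=1)
    return pairs, k[keep], r[keep]


def build_network(
    s: CoarseStructure,
    spring_rule: str = "hinsen",
    masses: np.ndarray | None = None,
    **rule_params,
) -> ENMModel:
    """Assemble the elastic network and its mass-weighted Hessian.

    The Hessian is the sum of pairwise super-elements
    −(k_ij/r_ij²)·(r_ij ⊗ r_ij) (off-diagonal blocks), with diagonal blocks
    closing each row sum to zero, then mass-weighted M^{-1/2} H M^{-1/2}.
    A disconnected network is tolerated but flagged (``connected=False``)
    with a warning, since its zero-mode count exceeds 6.
    """
    coords = np.asarray(s.coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise GeometryError("need at least 2 atoms for a network")
    m = s.masses if masses is None else np.asarray(masses, dtype=float)
    pairs, k, r0 = _spring_table(coords, spring_rule, **rule_params)

    hessian = np.zeros((3 * n, 3 * n))
    dvec = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    unit = dvec / r0[:, None]
    blocks = k[:, None, None] * unit[:, :, None] * unit[:, None, :]  # (P,3,3)
    for (i, j), b in zip(pairs, blocks):
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hessian[sl_i, sl_j] -= b
        hessian[sl_j, sl_i] -= b
        hessian[sl_i, sl_i] += b
        hessian[sl_j, sl_j] += b
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(m), 3)
    hessian *= inv_sqrt_m[:, None]
    hessian *= inv_sqrt_m[None, :]

    adj = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    connected = n_comp == 1
    if not connected:
        warnings.warn(
            f"elastic network has {n_comp} disconnected components; "
            "zero-mode count will exceed 6",
            stacklevel=2,
        )
    return ENMModel(
        ref_coords=coords,
        pairs=pairs,
        spring_constants=k,
        rest_lengths=r0,
        masses=m,
        hessian=hessian,
        connected=connected,
    )


def compute_modes(model: ENMModel) -> ENMModel:
    """Diagonalize the mass-weighted Hessian in place; returns the model.

    Eigenvalues are sorted ascending; modes with λ < 1e-6 × λ_max are
    classified as rigid-body (or spurious zero) modes.
    """
    try:
        evals, evecs = scipy.linalg.eigh(model.hessian)
    except scipy.linalg.LinAlgError as exc:
        cond = np.linalg.cond(model.hessian)
        raise NumericalError(
            f"eigensolver failed (condition number {cond:.3e}): {exc}"
        ) from exc
    model.eigenvalues = evals
    model.eigenvectors = evecs
    threshold = RIGID_THRESHOLD * max(evals[-1], 1e-300)
    model.n_rigid = int(np.count_nonzero(evals < threshold))
    return model


def excite_modes(
    model: ENMModel,
    n_modes: int = 50,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ModeExcitation:
    """Excite the first ``n_modes`` non-rigid modes, each with energy RT.

    Amplitudes are a_k = sqrt(2RT/λ_k) in mass-weighted coordinates; at
    full amplitude the harmonic energy ½λ_k a_k² of each mode equals RT.
    Requests beyond the available non-rigid modes are clamped with a
    warning.
    """
    if model.eigenvalues is None:
        compute_modes(model)
    available = model.nonrigid_indices()
    if n_modes > len(available):
        warnings.warn(
            f"requested {n_modes} modes but only {len(available)} non-rigid "
            "modes exist; clamping",
            stacklevel=2,
        )
        n_modes = len(available)
    idx = available[:n_modes]
    lam = model.eigenvalues[idx]
    if np.any(lam <= 0):
        raise NumericalError("non-positive eigenvalue among selected modes")
    rt = KB * temperature
    amplitudes = np.sqrt(2.0 * rt / lam)
    return ModeExcitation(
        mode_indices=idx, temperature=float(temperature), amplitudes=amplitudes
    )


CENTROID_PAIRS = tuple(itertools.combinations(range(4), 2))


def centroid_distance_gradients(
    coords: np.ndarray, masses: np.ndarray, partition: DomainPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Distances d_ij and their gradients w.r.t. mass-weighted coordinates.

    Returns ``(d, G)`` with ``d`` of shape (6,) and ``G`` of shape (6, 3N):
    row p is ∂d_p/∂q with q = sqrt(m)·x.
    """
    n = len(coords)
    w = partition.membership_matrix()
    centroids = w @ coords
    d = np.empty(len(CENTROID_PAIRS))
    grads = np.zeros((len(CENTROID_PAIRS), 3 * n))
    inv_sqrt_m = 1.0 / np.sqrt(masses)
    for p, (a, b) in enumerate(CENTROID_PAIRS):
        diff = centroids[a] - centroids[b]
        dist = np.linalg.norm(diff)
        if dist < 1e-9:
            raise GeometryError(f"coincident centroids c{a + 1} and c{b + 1}")
        d[p] = dist
        unit = diff / dist
        dd_dx = (w[a] - w[b])[:, None] * unit[None, :]  # (N, 3)
        grads[p] = (dd_dx * inv_sqrt_m[:, None]).ravel()
    return d, grads


def distance_fluctuations(
    model: ENMModel,
    excitation: ModeExcitation,
    partition: DomainPartition,
) -> np.ndarray:
    """Δd_ij for the six centroid pairs, Å, by linear mode propagation.

    Δd_ij = sqrt( Σ_k (g_ij · a_k v_k)² ) over the excited modes, where
    g_ij is the gradient of the centroid distance with respect to
    mass-weighted coordinates.  Rigid-body modes contribute nothing
    (internal distances are invariant); zero excited modes give zeros.
    """
    _, grads = centroid_distance_gradients(
        model.ref_coords, model.masses, partition
    )
    if len(excitation.mode_indices) == 0:
        return np.zeros(len(CENTROID_PAIRS))
    v = model.eigenvectors[:, excitation.mode_indices]  # (3N, K)
    proj = grads @ v  # (6, K)
    contrib = (proj * excitation.amplitudes[None, :]) ** 2
    return np.sqrt(contrib.sum(axis=1))


def mode_pair_contributions(
    model: ENMModel, excitation: ModeExcitation, partition: DomainPartition
) -> np.ndarray:
    """Per-mode, per-pair squared Δd contributions, shape (K, 6).

    Used to identify which centroid distance a given mode drives (the toy
    dimer's softest mode should be dominated by the c1–c4 pair).
    """
    _, grads = centroid_distance_gradients(
        model.ref_coords, model.masses, partition
    )
    v = model.eigenvectors[:, excitation.mode_indices]
    proj = (grads @ v).T  # (K, 6)
    return (proj * excitation.amplitudes[:, None]) ** 2


def export_modes(model: ENMModel, n_modes: int | None = None) -> str:
    """Plain whitespace-separated eigenvalue/eigenvector table."""
    if model.eigenvalues is None:
        raise NumericalError("modes not computed yet")
    k = len(model.eigenvalues) if n_modes is None else n_modes
    lines = ["# eigenvalue  eigenvector(3N components)"]
    for i in range(k):
        vec = " ".join(f"{x:.8e}" for x in model.eigenvectors[:, i])
        lines.append(f"{model.eigenvalues[i]:.8e} {vec}")
    return "\n".join(lines) + "\n"
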