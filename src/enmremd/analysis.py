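"""Trajectory analyses: optimal superposition RMSD, per-residue RMSF, and
the four-centroid global coordinates (six distances, opening angle,
dihedral torsion).

The opening angle is measured at the vertex v = (c2 + c3)/2 — the
midpoint of the two central (C-like) domain centroids — between the rays
v→c1 and v→c4; the torsion is the signed dihedral of the c1-c2-c3-c4
chain in the IUPAC convention (cis = 0°, range (−180°, 180°]).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .bias import compute_centroids
from .enm import CENTROID_PAIRS
from .errors import ConfigurationError, GeometryError
from .structure import DomainPartition

__all__ = [
    "GlobalCoordinates",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "global_coordinates",
    "opening_angle",
    "dihedral_torsion",
]


def _check_selection(x: np.ndarray) -> None:
    if len(x) < 3:
        raise GeometryError("need at least 3 atoms for superposition")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear or coincident) selection")


def kabsch_superpose(
    mobile: np.ndarray,
    ref: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` optimally fits ``ref`` over the
    selected atoms; the rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    sel = slice(None) if selection is None else np.asarray(selection)
    mob_s, ref_s = mobile[sel], ref[sel]
    if len(mob_s) != len(ref_s):
        raise GeometryError("selection size mismatch between mobile and ref")
    _check_selection(ref_s)
    _check_selection(mob_s)
    mob_c = mob_s.mean(axis=0)
    ref_c = ref_s.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_s - ref_c, mob_s - mob_c)
    rmsd = rssd / np.sqrt(len(mob_s))
    rmat = rot.as_matrix()
    trans = ref_c - rmat @ mob_c
    return rmat, trans, float(rmsd)


def rmsd_series(
    traj: np.ndarray,
    refs: list | np.ndarray,
    selection: np.ndarray | None = None,
    names: list | None = None,
) -> np.ndarray:
    """Per-frame RMSD of the trajectory against each reference structure.

    ``traj`` is (n_frames, n_atoms, 3); each frame is optimally aligned to
    each reference before the deviation is taken.  Returns an
    (n_frames, n_refs) array.
    """
    traj = np.asarray(traj, dtype=float)
    if isinstance(refs, np.ndarray) and refs.ndim == 2:
        refs = [refs]
    out = np.empty((len(traj), len(refs)))
    for r, ref in enumerate(refs):
        ref = np.asarray(ref, dtype=float)
        if ref.shape != traj.shape[1:]:
            label = names[r] if names else f"#{r}"
            raise GeometryError(
                f"selection mismatch for reference {label}: "
                f"{ref.shape} vs {traj.shape[1:]}"
            )
        for f in range(len(traj)):
            out[f, r] = kabsch_superpose(traj[f], ref, selection)[2]
    return out


def rmsf(traj: np.ndarray, n_iterations: int = 2) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the mean structure.

    Frames are iteratively superposed onto the running mean structure
    (``n_iterations`` passes, starting from the first frame), then the
    per-atom RMSF is sqrt of the time-averaged squared deviation from the
    converged mean.
    """
    traj = np.asarray(traj, dtype=float)
    if len(traj) < 2:
        raise ConfigurationError("RMSF undefined for fewer than 2 frames")
    aligned = traj.copy()
    ref = aligned[0]
    for _ in range(n_iterations):
        for f in range(len(aligned)):
            rmat, trans, _ = kabsch_superpose(aligned[f], ref)
            aligned[f] = aligned[f] @ rmat.T + trans
        ref = aligned.mean(axis=0)
    dev = aligned - ref
    return np.sqrt((dev**2).sum(axis=-1).mean(axis=0))


def opening_angle(centroids: np.ndarray) -> float:
    """Angle (degrees) at the (c2+c3)/2 vertex between c1 and c4."""
    c1, c2, c3, c4 = centroids
    v = 0.5 * (c2 + c3)
    a, b = c1 - v, c4 - v
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise GeometryError("angle vertex coincides with c1 or c4")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_torsion(centroids: np.ndarray) -> float:
    """Signed torsion (degrees) of the c1-c2-c3-c4 chain, IUPAC convention.

    Planar cis gives 0°, planar trans 180°; result in (−180°, 180°].
    Returns NaN if three consecutive centroids are collinear (torsion
    undefined); raises on coincident points.
    """
    c1, c2, c3, c4 = centroids
    b1, b2, b3 = c2 - c1, c3 - c2, c4 - c3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("coincident centroids in torsion definition")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return float("nan")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


@dataclass
class GlobalCoordinates:
    """Per-frame global coordinates of the four-centroid arrangement."""

    times: np.ndarray
    distances: np.ndarray   # (n_frames, 6) Å, canonical pair order
    angle: np.ndarray       # degrees, [0, 180]
    dihedral: np.ndarray    # degrees, (−180, 180]

    def to_tsv(self) -> str:
        header = ["time_ps"] + [
            f"d_c{a + 1}_c{b + 1}" for a, b in CENTROID_PAIRS
        ] + ["angle_deg", "dihedral_deg"]
        lines = ["\t".join(header)]
        for f in range(len(self.angle)):
            row = [f"{self.times[f]:.4f}"]
            row += [f"{d:.4f}" for d in self.distances[f]]
            row += [f"{self.angle[f]:.4f}", f"{self.dihedral[f]:.4f}"]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def global_coordinates(
    traj: np.ndarray,
    partition: DomainPartition,
    times: np.ndarray | None = None,
) -> GlobalCoordinates:
    """Six centroid distances, opening angle and torsion per frame."""
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 2:
        traj = traj[None]
    n = len(traj)
    times = np.arange(n, dtype=float) if times is None else np.asarray(times)
    dist = np.empty((n, 6))
    ang = np.empty(n)
    dih = np.empty(n)
    i, j = np.array(CENTROID_PAIRS).T
    for f in range(n):
        c = compute_centroids(traj[f], partition)
        d = np.linalg.norm(c[i] - c[j], axis=1)
        if np.any(d < 1e-9):
            raise GeometryError(f"coincident centroids at frame {f}")
        dist[f] = d
        ang[f] = opening_angle(c)
        dih[f] = dihedral_torsion(c)
    return GlobalCoordinates(times=times, distances=dist, angle=ang, dihedral=dih)
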