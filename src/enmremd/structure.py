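"""Cα-level structure handling: PDB reading, truncation, domain assignment.

A protein is reduced to one bead per residue (the Cα atom).  Domain
membership is what the rest of the package consumes: four domains whose
unweighted Cα centroids define the six biased inter-centroid distances.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import DEFAULT_RESIDUE_MASS, RESIDUE_MASSES
from .errors import (
    ConfigurationError,
    DegenerateStructureError,
    PartitionError,
    StructureFormatError,
    StructureParseError,
)

__all__ = [
    "CoarseStructure",
    "DomainPartition",
    "read_structure",
    "write_pdb",
    "truncate_n_terminal",
    "assign_domains",
]


@dataclass
class CoarseStructure:
    """One-bead-per-residue (Cα) protein model.

    Attributes
    ----------
    coords : (n_atoms, 3) float array, Å
    residue_ids : (n_atoms,) int array, author numbering from the PDB file
    chain_ids : (n_atoms,) str array
    masses : (n_atoms,) float array, amu, strictly positive
    res_names : (n_atoms,) str array, three-letter residue names
    ins_codes : (n_atoms,) str array, PDB insertion codes ('' if none)
    """

    coords: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray
    res_names: np.ndarray = field(default=None)  # type: ignore[assignment]
    ins_codes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.coords)
        if self.res_names is None:
            self.res_names = np.full(n, "ALA", dtype="U3")
        if self.ins_codes is None:
            self.ins_codes = np.full(n, "", dtype="U1")
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise DegenerateStructureError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureFormatError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise StructureFormatError("masses must be strictly positive")
        keys = list(zip(self.chain_ids, self.residue_ids, self.ins_codes))
        if len(set(keys)) != len(keys):
            raise StructureFormatError(
                "duplicate (chain, residue, insertion-code) identifiers"
            )

    def subset(self, mask: np.ndarray) -> "CoarseStructure":
        return CoarseStructure(
            coords=self.coords[mask],
            residue_ids=self.residue_ids[mask],
            chain_ids=self.chain_ids[mask],
            masses=self.masses[mask],
            res_names=self.res_names[mask],
            ins_codes=self.ins_codes[mask],
        )


@dataclass
class DomainPartition:
    """Assignment of atoms to the four domains.

    ``domain_of`` holds, per atom, a domain index in ``{0, 1, 2, 3}`` or
    ``-1`` for unassigned residues (excluded from centroids).  By
    convention domain 0 (c1) and domain 3 (c4) are the terminal (M-like)
    domains of the two monomers while domains 1 and 2 (c2, c3) are the
    central, dimer-forming (C-like) domains: the global opening angle has
    its vertex at the midpoint of the c2 and c3 centroids.
    """

    domain_of: np.ndarray
    n_domains: int = 4

    def __post_init__(self) -> None:
        self.domain_of = np.asarray(self.domain_of, dtype=int)
        sizes = self.sizes()
        if np.any(sizes == 0):
            empty = [d + 1 for d in range(self.n_domains) if sizes[d] == 0]
            raise PartitionError(f"empty domain(s): {empty}")

    def members(self, domain: int) -> np.ndarray:
        """Atom indices of domain ``domain`` (0-based)."""
        return np.flatnonzero(self.domain_of == domain)

    def sizes(self) -> np.ndarray:
        return np.array(
            [np.count_nonzero(self.domain_of == d) for d in range(self.n_domains)]
        )

    def membership_matrix(self) -> np.ndarray:
        """(4, n_atoms) row-stochastic matrix mapping coordinates to centroids."""
        n = len(self.domain_of)
        w = np.zeros((self.n_domains, n))
        for d in range(self.n_domains):
            idx = self.members(d)
            w[d, idx] = 1.0 / len(idx)
        return w


def _resolve_masses(res_names: np.ndarray, mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.full(len(res_names), DEFAULT_RESIDUE_MASS)
    if mode == "residue":
        return np.array(
            [RESIDUE_MASSES.get(r, DEFAULT_RESIDUE_MASS) for r in res_names]
        )
    raise ConfigurationError(f"unknown mass mode {mode!r}")


def read_structure(
    pdb_text: str,
    chain_filter: Sequence[str] | None = None,
    masses: str = "uniform",
) -> CoarseStructure:
    """Parse PDB text into a Cα model.

    One atom per residue is kept (atom name CA); alternate locations are
    resolved to the highest-occupancy, first-listed conformer.  Residues
    with insertion codes are kept in file order.

    Parameters
    ----------
    pdb_text : PDB-format text with ATOM records.
    chain_filter : keep only these chain identifiers, if given.
    masses : ``"uniform"`` (110 amu per residue) or ``"residue"``.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various parse errors
        raise StructureParseError(f"could not parse PDB text: {exc}") from exc
    mask = atoms.atom_name == "CA"
    if chain_filter is not None:
        mask &= np.isin(atoms.chain_id, np.asarray(chain_filter))
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise StructureParseError("no CA atoms found in ATOM records")
    ins = getattr(ca, "ins_code", np.full(ca.array_length(), ""))
    try:
        return CoarseStructure(
            coords=ca.coord,
            residue_ids=ca.res_id,
            chain_ids=ca.chain_id,
            masses=_resolve_masses(ca.res_name, masses),
            res_names=ca.res_name,
            ins_codes=ins,
        )
    except StructureFormatError as exc:
        raise StructureFormatError(f"unresolvable CA duplication: {exc}") from exc


def write_pdb(s: CoarseStructure, coords: np.ndarray | None = None) -> str:
    """Render a structure (or a trajectory over its topology) as PDB text.

    ``coords`` may be ``(n_atoms, 3)`` or ``(n_frames, n_atoms, 3)``; the
    latter produces a multi-model file.
    """
    if coords is None:
        coords = s.coords
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    stack_coords = coords[None] if single else coords
    n = s.n_atoms
    template = struc.AtomArray(n)
    template.coord = stack_coords[0]
    template.chain_id = s.chain_ids
    template.res_id = s.residue_ids
    template.ins_code = s.ins_codes
    template.res_name = s.res_names
    template.atom_name = np.full(n, "CA")
    template.element = np.full(n, "C")
    template.hetero = np.zeros(n, dtype=bool)
    if single:
        out = template
    else:
        out = struc.from_template(template, stack_coords)
    pdb = PDBFile()
    pdb.set_structure(out)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def truncate_n_terminal(s: CoarseStructure, boundary: int) -> CoarseStructure:
    """Remove every residue with author number ≤ ``boundary`` from all chains.

    Mirrors the construction of an N-terminally truncated multi-domain
    protein (e.g. removing a nucleotide-binding domain up to the start of
    the middle domain).  ``boundary=0`` is the identity.
    """
    if boundary < 0:
        raise ConfigurationError("truncation boundary must be ≥ 0")
    mask = s.residue_ids > boundary
    if not np.any(mask):
        raise DegenerateStructureError(
            f"truncation at residue {boundary} removes every atom"
        )
    return s.subset(mask)


DomainRanges = Mapping[str, Sequence[tuple[int, int, int]]]


def assign_domains(s: CoarseStructure, ranges: DomainRanges) -> DomainPartition:
    """Assign residues to the four domains from per-chain residue intervals.

    Parameters
    ----------
    ranges : mapping ``chain_id -> [(first_res, last_res, domain), ...]``
        with inclusive residue bounds and domain indices in 1..4.
        Intervals must not overlap within a chain.  Residues covered by no
        interval stay unassigned (and do not contribute to centroids).
    """
    domain_of = np.full(s.n_atoms, -1, dtype=int)
    for chain, intervals in ranges.items():
        seen: list[tuple[int, int]] = []
        for first, last, dom in intervals:
            if not (1 <= dom <= 4):
                raise ConfigurationError(f"domain index {dom} outside 1..4")
            if last < first:
                raise ConfigurationError(
                    f"empty interval ({first}, {last}) for chain {chain}"
                )
            for f0, l0 in seen:
                if first <= l0 and last >= f0:
                    raise ConfigurationError(
                        f"overlapping intervals in chain {chain}: "
                        f"({f0},{l0}) and ({first},{last})"
                    )
            seen.append((first, last))
            mask = (
                (s.chain_ids == chain)
                & (s.residue_ids >= first)
                & (s.residue_ids <= last)
            )
            domain_of[mask] = dom - 1
    try:
        return DomainPartition(domain_of)
    except PartitionError as exc:
        raise ConfigurationError(f"fewer than 4 nonempty domains: {exc}") from exc
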