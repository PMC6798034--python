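"""Plain-text trajectory and table I/O: XYZ, multi-model PDB, TSV."""
from __future__ import annotations

import numpy as np

from .errors import StructureParseError
from .structure import CoarseStructure, write_pdb

__all__ = ["write_xyz", "read_xyz", "write_trajectory_pdb"]


def write_xyz(
    coords: np.ndarray, comment: str = "", symbols=None
) -> str:
    """Render (n_frames, n_atoms, 3) or (n_atoms, 3) coordinates as XYZ text."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    if symbols is None:
        symbols = ["C"] * n
    lines = []
    for f, frame in enumerate(coords):
        lines.append(str(n))
        lines.append(comment or f"frame {f}")
        for sym, (x, y, z) in zip(symbols, frame):
            lines.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"


def read_xyz(text: str) -> np.ndarray:
    """Parse XYZ text into a (n_frames, n_atoms, 3) array."""
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise StructureParseError(f"bad XYZ atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise StructureParseError("truncated XYZ frame")
        frames.append(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        i += 2 + n
    if not frames:
        raise StructureParseError("no frames in XYZ text")
    return np.array(frames)


def write_trajectory_pdb(s: CoarseStructure, coords: np.ndarray) -> str:
    """Multi-model PDB text over the structure's topology."""
    return write_pdb(s, coords)
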