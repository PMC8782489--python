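"""Light in-memory trajectory container shared by the analysis modules.

Coordinates are in Å, frames are 0-based.  The container is deliberately
minimal: ``io.read_trajectory`` builds it from PDB/XTC/DCD files through
MDAnalysis, and the synthetic generators build it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Coordinate series plus a flat atom table.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, Å.
    names : atom names, length n_atoms.
    resids : per-atom residue index (0-based, global over both strands).
    resnames : per-atom residue name (e.g. "DA", "DT", "ION").
    segids : per-atom segment/chain label ("W" Watson, "C" Crick, ...).
    box : optional (3,) orthorhombic box lengths in Å.
    """

    coords: np.ndarray
    names: list[str]
    resids: np.ndarray
    resnames: list[str]
    segids: list[str]
    box: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        self.resids = np.asarray(self.resids, dtype=int)
        if self.coords.shape[1] != len(self.names):
            raise ValueError("coords and atom table disagree on atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.resids.max()) + 1 if self.n_atoms else 0

    def atom_index(self, resid: int, name: str) -> int:
        """Index of the atom ``name`` in residue ``resid``; raises KeyError."""
        for i in range(self.n_atoms):
            if self.resids[i] == resid and self.names[i] == name:
                return i
        raise KeyError(f"residue {resid} has no atom named {name!r}")

    def atom_positions(self, resid: int, name: str) -> np.ndarray:
        """(n_frames, 3) positions of one named atom of one residue."""
        return self.coords[:, self.atom_index(resid, name), :]

    def select(self, name: str | None = None, segid: str | None = None,
               resname: str | None = None) -> np.ndarray:
        """Boolean mask over atoms matching all given exact-name filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            mask &= np.array([n == name for n in self.names])
        if segid is not None:
            mask &= np.array([s == segid for s in self.segids])
        if resname is not None:
            mask &= np.array([r == resname for r in self.resnames])
        return mask

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Trajectory":
        """Rigidly transformed copy (same rotation applied to every frame)."""
        coords = self.coords.copy()
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return Trajectory(coords, list(self.names), self.resids.copy(),
                          list(self.resnames), list(self.segids),
                          None if self.box is None else self.box.copy(),
                          dict(self.meta))
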