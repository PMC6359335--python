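"""In-memory trajectory container.

A :class:`TrajectorySet` holds Cartesian coordinates for a fixed set of
atoms over many frames, together with per-atom residue metadata and a
per-frame segment (replica) label.  Conversion to/from biotite
``AtomArrayStack`` gives multi-model PDB round trips without a hand-rolled
parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import biotite.structure as struc


@dataclass
class TrajectorySet:
    """Frames x atoms Cartesian coordinates with residue/atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    atom_names
        Per-atom PDB atom names (e.g. ``"N"``, ``"CA"``, ``"C"``, ``"O"``,
        ``"H"``).
    res_ids
        Per-atom 1-based residue numbers.
    res_names
        Per-atom residue names (three-letter or peptaibol-style labels).
    segments
        Per-frame replica/segment label (0-based).  Defaults to a single
        segment.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    segments: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U6")
        n_atoms = self.coords.shape[1]
        for name, arr in (
            ("atom_names", self.atom_names),
            ("res_ids", self.res_ids),
            ("res_names", self.res_names),
        ):
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length {n_atoms}")
        if self.segments is None:
            self.segments = np.zeros(self.coords.shape[0], dtype=int)
        self.segments = np.asarray(self.segments, dtype=int)
        if self.segments.shape != (self.coords.shape[0],):
            raise ValueError("segments must have one label per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue numbers."""
        return np.unique(self.res_ids)

    def atom_index(self, res_id: int, atom_name: str) -> int:
        """Index of a named atom in a residue; -1 if absent."""
        hits = np.flatnonzero((self.res_ids == res_id) & (self.atom_names == atom_name))
        return int(hits[0]) if hits.size else -1

    def atom_coords(self, res_id: int, atom_name: str) -> np.ndarray:
        """Coordinates (n_frames, 3) of one named atom; raises if absent."""
        idx = self.atom_index(res_id, atom_name)
        if idx < 0:
            raise ValueError(f"atom {atom_name!r} missing in residue {res_id}")
        return self.coords[:, idx, :]

    def residue_name(self, res_id: int) -> str:
        hits = np.flatnonzero(self.res_ids == res_id)
        return str(self.res_names[hits[0]]) if hits.size else ""

    def select_frames(self, indices) -> "TrajectorySet":
        return TrajectorySet(
            self.coords[indices],
            self.atom_names,
            self.res_ids,
            self.res_names,
            self.segments[indices],
        )

    def to_atom_array_stack(self) -> struc.AtomArrayStack:
        stack = struc.AtomArrayStack(self.n_frames, self.n_atoms)
        stack.coord[:] = self.coords
        stack.atom_name = self.atom_names
        stack.res_id = self.res_ids
        stack.res_name = self.res_names
        stack.chain_id = np.full(self.n_atoms, "A", dtype="U4")
        stack.element = np.array([n[0] for n in self.atom_names], dtype="U2")
        stack.hetero = np.zeros(self.n_atoms, dtype=bool)
        return stack

    @classmethod
    def from_atom_array_stack(cls, stack: struc.AtomArrayStack) -> "TrajectorySet":
        return cls(
            np.asarray(stack.coord, dtype=float),
            np.asarray(stack.atom_name),
            np.asarray(stack.res_id, dtype=int),
            np.asarray(stack.res_name),
        )
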