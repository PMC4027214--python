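"""Cartesian structure container for the DNA-drug complex.

A :class:`Structure` holds named atoms (molecule id, residue number, atom
name, element) with coordinates in Angstrom, an optional covalent bond
list (atom index pairs), and a model id.  Atom identity is the triple
``(mol, resnum, name)``; multi-model ensembles share one identity list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AtomKey = tuple[str, int, str]


@dataclass
class Structure:
    """Named atoms + coordinates for one model of a DNA(-ligand) complex."""

    mols: list[str]
    resnums: list[int]
    names: list[str]
    elements: list[str]
    coords: np.ndarray  # (N, 3) float64, Angstrom
    bonds: list[tuple[int, int]] = field(default_factory=list)
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.mols)
        if not (len(self.resnums) == len(self.names) == len(self.elements) == n
                == self.coords.shape[0]):
            raise ValueError("inconsistent atom field lengths")
        self._index: dict[AtomKey, int] | None = None

    # -- identity ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.mols)

    def keys(self) -> list[AtomKey]:
        return list(zip(self.mols, self.resnums, self.names))

    def index_of(self, mol: str, resnum: int, name: str) -> int:
        if self._index is None:
            self._index = {k: i for i, k in enumerate(self.keys())}
            if len(self._index) != self.n_atoms:
                raise ValueError("duplicate atom identity keys")
        try:
            return self._index[(mol, resnum, name)]
        except KeyError:
            raise KeyError(f"no atom {mol}/{resnum}/{name}") from None

    def xyz(self, mol: str, resnum: int, name: str) -> np.ndarray:
        return self.coords[self.index_of(mol, resnum, name)]

    # -- selections -------------------------------------------------------
    def select(self, mol: str | None = None, resnum: int | None = None,
               element: str | None = None) -> np.ndarray:
        """Boolean mask over atoms matching the given fields."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if mol is not None:
            mask &= np.array([m == mol for m in self.mols])
        if resnum is not None:
            mask &= np.array([r == resnum for r in self.resnums])
        if element is not None:
            mask &= np.array([e == element for e in self.elements])
        return mask

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def proton_mask(self) -> np.ndarray:
        """Protons, including pseudo-atom centroids (element 'H')."""
        return np.array([e == "H" for e in self.elements])

    # -- transforms -------------------------------------------------------
    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        """Copy sharing identity lists but with new coordinates."""
        return replace(
            self,
            coords=np.asarray(coords, dtype=float).reshape(-1, 3).copy(),
            model_id=self.model_id if model_id is None else model_id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply a rigid motion x -> R x + t."""
        return self.with_coords(self.coords @ np.asarray(rotation).T + translation)

    def same_identity(self, other: "Structure") -> bool:
        return self.keys() == other.keys()


def concatenate(parts: list[Structure], model_id: int = 1) -> Structure:
    """Concatenate structures (e.g. DNA + ligands) into one model.

    Bond indices are offset so they keep referring to the same atoms.
    """
    mols: list[str] = []
    resnums: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    coords = []
    bonds: list[tuple[int, int]] = []
    offset = 0
    for p in parts:
        mols += p.mols
        resnums += p.resnums
        names += p.names
        elements += p.elements
        coords.append(p.coords)
        bonds += [(i + offset, j + offset) for i, j in p.bonds]
        offset += p.n_atoms
    return Structure(mols, resnums, names, elements, np.vstack(coords), bonds, model_id)
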