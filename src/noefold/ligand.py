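"""Bis-intercalator ligand topology and placement.

The drug is modelled as two planar tricyclic phenazine chromophores, each
carrying a C1 carboxamide and a C9 methyl, joined by a carboxamide
aminoalkyl linker whose two gamma-amino nitrogens are protonated (+1) at
pH 7.  Each phenazine+half-linker is one "moiety" (residue 1 or 2 of the
ligand molecule), mirroring the XR1-1/XR1-2/XR2-1/XR2-2 naming used for
the two drug copies XR1 and XR2.

Placement puts a phenazine ring-system centroid at the midpoint between
the flanking base-pair planes of an opened intercalation gap, ring plane
perpendicular to the local helix axis and the linker emerging on the
major-groove side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import compute_frames
from .geometry import place_atom
from .structure import Structure, concatenate
from .topology import DuplexTopology

_L = 1.40          # aromatic C-C
_HEX = 1.2124356   # L * sqrt(3)/2


class PlacementError(ValueError):
    """Raised when an intercalation site has no opened gap."""


#: phenazine heavy atoms of one moiety, planar (z = 0), long axis along x
_RING = {
    "N5": (0.0, -1.4), "N10": (0.0, 1.4),
    "C4A": (-_HEX, -0.7), "C10A": (-_HEX, 0.7),
    "C5A": (_HEX, -0.7), "C9A": (_HEX, 0.7),
    "C1": (-2 * _HEX, 1.4), "C2": (-3 * _HEX, 0.7),
    "C3": (-3 * _HEX, -0.7), "C4": (-2 * _HEX, -1.4),
    "C6": (2 * _HEX, -1.4), "C7": (3 * _HEX, -0.7),
    "C8": (3 * _HEX, 0.7), "C9": (2 * _HEX, 1.4),
}

_RING_BONDS = [
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C4A"),
    ("C4A", "N5"), ("N5", "C5A"), ("C5A", "C6"), ("C6", "C7"),
    ("C7", "C8"), ("C8", "C9"), ("C9", "C9A"), ("C9A", "N10"),
    ("N10", "C10A"), ("C10A", "C1"), ("C4A", "C10A"), ("C5A", "C9A"),
]

_AROMATIC_H = {"H2": "C2", "H3": "C3", "H4": "C4",
               "H6": "C6", "H7": "C7", "H8": "C8"}


@dataclass(frozen=True)
class LigandTopology:
    """Atom naming, bonding and charges for one bis-phenazine ligand."""

    moiety_names: tuple[str, ...]          # per-moiety atom names
    moiety_elements: tuple[str, ...]
    moiety_bonds: tuple[tuple[str, str], ...]
    charges: dict[str, float]              # name -> formal charge
    ring_atoms: tuple[str, ...]            # planar ring-system atoms

    @property
    def protons(self) -> tuple[str, ...]:
        return tuple(n for n, e in zip(self.moiety_names, self.moiety_elements)
                     if e == "H")


def build_moiety() -> tuple[list[str], list[str], np.ndarray, list[tuple[str, str]]]:
    """One phenazine + carboxamide + aminoethyl half-linker, local frame.

    Atom names: ring atoms as in _RING; C9M/Q9M the 9-methyl carbon and its
    methyl pseudo-proton; CC/OC/NAM the carboxamide; CB1/CB2 the ethylene;
    NG the protonated gamma-amino nitrogen; CGM/QGM its N-methyl.
    Aromatic protons H2,H3,H4 (ring A) and H6,H7,H8 (ring C).
    """
    pos: dict[str, np.ndarray] = {n: np.array([x, y, 0.0]) for n, (x, y) in _RING.items()}
    names = list(_RING)
    elements = ["N" if n.startswith("N") else "C" for n in names]

    def add(name: str, el: str, xyz: np.ndarray) -> None:
        pos[name] = xyz
        names.append(name)
        elements.append(el)

    # aromatic protons, radially outward from the owning ring's center
    centers = {"C2": (-2 * _HEX, 0.0), "C3": (-2 * _HEX, 0.0), "C4": (-2 * _HEX, 0.0),
               "C6": (2 * _HEX, 0.0), "C7": (2 * _HEX, 0.0), "C8": (2 * _HEX, 0.0)}
    for h, c in _AROMATIC_H.items():
        ctr = np.array([*centers[c], 0.0])
        u = pos[c] - ctr
        add(h, "H", pos[c] + 1.08 * u / np.linalg.norm(u))

    # C9 methyl + pseudo-proton
    u9 = pos["C9"] - np.array([2 * _HEX, 0.0, 0.0])
    u9 /= np.linalg.norm(u9)
    add("C9M", "C", pos["C9"] + 1.50 * u9)
    add("Q9M", "H", pos["C9M"] + 0.36 * u9)

    # carboxamide + aminoethyl chain, grown as an extended zig-zag
    add("CC", "C", place_atom(pos["C10A"], pos["C1"], pos["C2"], 1.50, 120.0, 180.0))
    add("OC", "O", place_atom(pos["C1"], pos["C2"], pos["CC"], 1.23, 121.0, 0.0))
    add("NAM", "N", place_atom(pos["C1"], pos["C2"], pos["CC"], 1.34, 116.0, 180.0))
    add("CB1", "C", place_atom(pos["C2"], pos["CC"], pos["NAM"], 1.46, 121.0, 180.0))
    add("CB2", "C", place_atom(pos["CC"], pos["NAM"], pos["CB1"], 1.53, 112.0, 180.0))
    add("NG", "N", place_atom(pos["NAM"], pos["CB1"], pos["CB2"], 1.49, 112.0, 180.0))
    add("CGM", "C", place_atom(pos["CB1"], pos["CB2"], pos["NG"], 1.49, 110.0, 60.0))
    u = pos["CGM"] - pos["NG"]
    add("QGM", "H", pos["CGM"] + 0.36 * u / np.linalg.norm(u))
    for hn, hp in (("HB11", 1), ("HB12", -1)):
        n_ = pos["CB1"]
        z = np.array([0.0, 0.0, float(hp)])
        add(hn, "H", n_ + 1.09 * z)
    for hn, hp in (("HB21", 1), ("HB22", -1)):
        add(hn, "H", pos["CB2"] + 1.09 * np.array([0.0, 0.0, float(hp)]))

    bonds = list(_RING_BONDS)
    bonds += [(h, c) for h, c in _AROMATIC_H.items()]
    bonds += [("C9", "C9M"), ("C9M", "Q9M"), ("C1", "CC"), ("CC", "OC"),
              ("CC", "NAM"), ("NAM", "CB1"), ("CB1", "CB2"), ("CB2", "NG"),
              ("NG", "CGM"), ("CGM", "QGM"),
              ("CB1", "HB11"), ("CB1", "HB12"), ("CB2", "HB21"), ("CB2", "HB22")]
    coords = np.array([pos[n] for n in names])
    return names, elements, coords, bonds


def ligand_topology() -> LigandTopology:
    names, elements, _c, bonds = build_moiety()
    charges = {"NG": 1.0}  # protonated gamma-amino nitrogen at pH 7
    return LigandTopology(tuple(names), tuple(elements), tuple(bonds), charges,
                          tuple(_RING))


#: the refined TFF1 complex: XR1 spans gaps at steps C5pA6 (weak, moiety 1) and
#: C7pG8 (strong, moiety 2); XR2 spans G9pT10 (strong, moiety 1) and
#: G11pG12 (weak, moiety 2).  Steps are 0-based pair-step indices.
TFF1_SITES: dict[str, tuple[tuple[int, int], ...]] = {
    "XR1": ((1, 4), (2, 6)),
    "XR2": ((1, 8), (2, 10)),
}


def place_ligands(structure: Structure, topology: DuplexTopology,
                  sites: dict[str, tuple[tuple[int, int], ...]] | None = None,
                  min_gap_rise: float = 5.0) -> Structure:
    """Insert ligand copies into opened intercalation gaps.

    ``sites`` maps a ligand molecule id to ``(moiety, step_index)`` pairs.
    Each phenazine centroid lands at the midpoint of the flanking pair
    origins with its long axis along the mean pair long axis and the
    linker on the major-groove side.  A step whose measured rise is below
    ``min_gap_rise`` has no room for a chromophore -> PlacementError.
    """
    if sites is None:
        sites = TFF1_SITES
    if not sites:
        return structure

    frames = compute_frames(structure, topology)
    parts = [structure]
    for mol, placements in sites.items():
        moiety_parts = []
        ng_pos: dict[int, np.ndarray] = {}
        for moiety, step in placements:
            f1, f2 = frames[step], frames[step + 1]
            zm = f1.z + f2.z
            zm /= np.linalg.norm(zm)
            rise = float(np.dot(f2.origin - f1.origin, zm))
            if rise < min_gap_rise:
                raise PlacementError(
                    f"step {step} rise {rise:.2f} A < {min_gap_rise} A: no opened gap")
            mid = (f1.origin + f2.origin) / 2.0
            xm = (f1.axes[:, 0] + f2.axes[:, 0]) / 2.0
            xm -= np.dot(xm, zm) * zm
            xm /= np.linalg.norm(xm)
            ym = np.cross(zm, xm)
            # ligand local x (long axis) -> ym, local y (linker side) -> xm
            R = np.column_stack([ym, xm, zm])
            if np.linalg.det(R) < 0:
                R = np.column_stack([-ym, xm, zm])
            names, elements, coords, bonds_by_name = build_moiety()
            ring_centroid = coords[:len(_RING)].mean(axis=0)
            coords = (coords - ring_centroid) @ R.T + mid
            idx = {n: i for i, n in enumerate(names)}
            moiety_parts.append(Structure(
                [mol] * len(names), [moiety] * len(names), names, elements,
                coords, [(idx[a], idx[b]) for a, b in bonds_by_name]))
            ng_pos[moiety] = coords[idx["NG"]]
        lig = concatenate(moiety_parts)
        # central ethylene bridging the two gamma-amino nitrogens; the
        # bridge is interpolated in cylindrical coordinates about the
        # helix axis so it follows the groove instead of cutting a chord
        # through the backbone
        if len(ng_pos) == 2:
            a, b = ng_pos[1], ng_pos[2]

            def cyl_lerp(t: float, r_floor: float = 7.0) -> np.ndarray:
                ra, rb = np.hypot(*a[:2]), np.hypot(*b[:2])
                ta, tb = np.arctan2(a[1], a[0]), np.arctan2(b[1], b[0])
                dt = np.arctan2(np.sin(tb - ta), np.cos(tb - ta))
                r = ra + t * (rb - ra)
                # dip toward the groove floor mid-bridge, clear of the
                # phosphate backbone helix
                if r > r_floor:
                    r -= 4.0 * t * (1.0 - t) * (r - r_floor)
                th = ta + t * dt
                return np.array([r * np.cos(th), r * np.sin(th),
                                 a[2] + t * (b[2] - a[2])])

            cl = np.array([cyl_lerp(1.0 / 3.0), cyl_lerp(2.0 / 3.0)])
            bridge = Structure([mol, mol], [1, 1], ["CL1", "CL2"], ["C", "C"],
                               cl, [(0, 1)])
            lig = concatenate([lig, bridge])
            lig.bonds.append((lig.index_of(mol, 1, "NG"), lig.index_of(mol, 1, "CL1")))
            lig.bonds.append((lig.index_of(mol, 1, "CL2"), lig.index_of(mol, 2, "NG")))
        parts.append(lig)
    return concatenate(parts, model_id=structure.model_id)
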