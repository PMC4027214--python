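"""Idealized B-DNA coordinate construction.

Bases are encoded as heavy-atom templates in the standard base reference
frame (origin on the pair axis, x toward the major groove, base plane at
z = 0).  A Watson-Crick partner is generated by the 180 deg rotation about
x (y -> -y, z -> -z).  The deoxyribose/phosphate backbone is grown from
C1' by internal-coordinate (NeRF) construction with a C2'-endo pucker and
B-form torsion angles; a handful of branch torsions were calibrated once
so that the uniform 36 deg / 3.4 A helix closes the sugar ring and gives
contiguous O3'-P backbone links, and are frozen below.

A duplex model is assembled pair by pair: pair s is the paired-nucleotide
template rotated by the cumulative twist about z and translated by the
cumulative rise along z.  Per-step rise/twist lists therefore *are* the
helical parameters the analysis module measures back.
"""

from __future__ import annotations

import numpy as np

from .structure import Structure, concatenate
from .topology import DuplexTopology

# -- standard-reference-frame base templates (heavy atoms, Angstrom) -------

BASE_TEMPLATES: dict[str, list[tuple[str, str, float, float, float]]] = {
    "A": [
        ("N9", "N", -1.291, 4.498, 0.000),
        ("C8", "C", 0.024, 4.897, 0.000),
        ("N7", "N", 0.877, 3.902, 0.000),
        ("C5", "C", 0.071, 2.771, 0.000),
        ("C6", "C", 0.369, 1.398, 0.000),
        ("N6", "N", 1.611, 0.909, 0.000),
        ("N1", "N", -0.668, 0.532, 0.000),
        ("C2", "C", -1.912, 1.023, 0.000),
        ("N3", "N", -2.320, 2.290, 0.000),
        ("C4", "C", -1.267, 3.124, 0.000),
        ("C1'", "C", -2.479, 5.346, 0.000),
    ],
    "G": [
        ("N9", "N", -1.289, 4.551, 0.000),
        ("C8", "C", 0.023, 4.962, 0.000),
        ("N7", "N", 0.870, 3.969, 0.000),
        ("C5", "C", 0.071, 2.833, 0.000),
        ("C6", "C", 0.424, 1.460, 0.000),
        ("O6", "O", 1.554, 0.955, 0.000),
        ("N1", "N", -0.700, 0.641, 0.000),
        ("C2", "C", -1.999, 1.087, 0.000),
        ("N2", "N", -2.949, 0.139, -0.001),
        ("N3", "N", -2.342, 2.364, 0.001),
        ("C4", "C", -1.265, 3.177, 0.000),
        ("C1'", "C", -2.477, 5.399, 0.000),
    ],
    "C": [
        ("N1", "N", -1.285, 4.542, 0.000),
        ("C2", "C", -1.472, 3.158, 0.000),
        ("O2", "O", -2.628, 2.709, 0.001),
        ("N3", "N", -0.391, 2.344, 0.000),
        ("C4", "C", 0.837, 2.868, 0.000),
        ("N4", "N", 1.875, 2.027, 0.001),
        ("C5", "C", 1.056, 4.275, 0.000),
        ("C6", "C", -0.023, 5.068, 0.000),
        ("C1'", "C", -2.477, 5.402, 0.000),
    ],
    "T": [
        ("N1", "N", -1.284, 4.500, 0.000),
        ("C2", "C", -1.462, 3.135, 0.000),
        ("O2", "O", -2.562, 2.608, 0.000),
        ("N3", "N", -0.298, 2.407, 0.000),
        ("C4", "C", 0.994, 2.897, 0.000),
        ("O4", "O", 1.944, 2.119, 0.000),
        ("C5", "C", 1.106, 4.338, 0.000),
        ("C7", "C", 2.466, 4.961, 0.001),
        ("C6", "C", -0.024, 5.057, 0.000),
        ("C1'", "C", -2.481, 5.354, 0.000),
    ],
}

#: Ring atoms used when fitting an observed base to its template.
BASE_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

BASE_BONDS: dict[str, list[tuple[str, str]]] = {
    "A": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "N6"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
          ("C4", "N9"), ("N9", "C1'")],
    "G": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "O6"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "N2"), ("C2", "N3"), ("N3", "C4"),
          ("C4", "C5"), ("C4", "N9"), ("N9", "C1'")],
    "C": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N4"),
          ("C4", "C5"), ("C5", "C6"), ("C6", "N1"), ("N1", "C1'")],
    "T": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "O4"),
          ("C4", "C5"), ("C5", "C7"), ("C5", "C6"), ("C6", "N1"), ("N1", "C1'")],
}

SUGAR_BONDS = [
    ("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"),
    ("O4'", "C1'"), ("C3'", "O3'"), ("C4'", "C5'"), ("C5'", "O5'"),
]
PHOSPHATE_BONDS = [("O5'", "P"), ("P", "OP1"), ("P", "OP2")]

# Backbone internal coordinates.  Ring pucker is C2'-endo (P = 162 deg,
# tau_m = 38 deg); branch torsions marked 'calibrated' were fitted once so
# the uniform helix closes the sugar ring (C4'-O4' ~1.45 A) and links
# O3'(i)-P(i+1) at ~1.60 A, then frozen.
BACKBONE = {
    "chi": -115.32,      # O4'-C1'-N-C(4/2) glycosidic, B-form, calibrated
    "b_c2": -114.85,     # C2' branch offset from chi about the C1'-N bond, calibrated
    "nu1": 36.1,         # O4'-C1'-C2'-C3'
    "nu2": -36.1,        # C1'-C2'-C3'-C4'
    "b_o3": 123.90,      # O3' branch offset from nu2 about C2'-C3', calibrated
    "b_c5": -125.88,     # C5' branch offset from nu3 about C3'-C4', calibrated
    "nu3": 22.3,         # C2'-C3'-C4'-O4'
    "gamma": 42.18,      # O5'-C5'-C4'-C3', calibrated
    "beta": 150.60,      # P-O5'-C5'-C4', calibrated
    "b_op": 115.0,       # OP1/OP2 branch offsets about the O5'-P bond
    # bond lengths / angles
    "r_C1pN": 1.47, "r_CC": 1.525, "r_CO_ring": 1.446, "r_C3O3": 1.423,
    "r_C5O5": 1.423, "r_OP": 1.593, "r_POP": 1.485,
    "a_NC1O4": 108.2, "a_NC1C2": 113.7, "a_C1C2C3": 102.7, "a_C2C3C4": 102.7,
    "a_C2C3O3": 109.4, "a_C3C4C5": 114.7, "a_C4C5O5": 110.9, "a_C5O5P": 119.7,
    "a_O5POP": 108.1,
}

_RH = 1.09  # C-H bond length
_RNH = 1.03  # N-H bond length


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    torsion(a,b,c,d) as requested (degrees)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _tetrahedral_h(center: np.ndarray, neighbors: list[np.ndarray],
                   n_h: int, r: float = _RH) -> list[np.ndarray]:
    """Place 1 or 2 hydrogens completing a tetrahedral (or trigonal) center."""
    units = [(v - center) / np.linalg.norm(v - center) for v in neighbors]
    s = -sum(units)
    norm = np.linalg.norm(s)
    if n_h == 1 or norm < 1e-9:
        return [center + r * s / norm]
    # two hydrogens: open them symmetrically about the bisector, in the
    # plane perpendicular to the neighbor-neighbor axis
    bis = s / norm
    perp = np.cross(units[0] - units[1], bis)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(109.5 / 2.0)
    h1 = center + r * (np.cos(half) * bis + np.sin(half) * perp)
    h2 = center + r * (np.cos(half) * bis - np.sin(half) * perp)
    return [h1, h2]


def _base_protons(base: str, pos: dict[str, np.ndarray]) -> list[tuple[str, np.ndarray]]:
    """Aromatic CH protons, the imino proton, and the thymine methyl
    pseudo-proton (name Q5M, centroid of the three methyl hydrogens)."""
    out: list[tuple[str, np.ndarray]] = []

    def aromatic(name: str, center: str, n1: str, n2: str, r: float = _RH) -> None:
        out.append((name, _tetrahedral_h(pos[center], [pos[n1], pos[n2]], 1, r)[0]))

    if base == "A":
        aromatic("H8", "C8", "N7", "N9")
        aromatic("H2", "C2", "N1", "N3")
    elif base == "G":
        aromatic("H8", "C8", "N7", "N9")
        aromatic("H1", "N1", "C2", "C6", _RNH)  # imino (bookkeeping)
    elif base == "C":
        aromatic("H5", "C5", "C4", "C6")
        aromatic("H6", "C6", "C5", "N1")
    elif base == "T":
        aromatic("H6", "C6", "C5", "N1")
        aromatic("H3", "N3", "C2", "C4", _RNH)  # imino (bookkeeping)
        u = pos["C7"] - pos["C5"]
        out.append(("Q5M", pos["C7"] + 0.36 * u / np.linalg.norm(u)))
    return out


def build_nucleotide(base: str, terminal5: bool = False) -> tuple[
        list[str], list[str], np.ndarray, list[tuple[str, str]]]:
    """One nucleotide (heavy atoms + non-exchangeable/imino protons) in the
    standard base reference frame.

    Returns (names, elements, coords, bonds-by-name).  5'-terminal residues
    carry no phosphate group (free 5'-OH; the hydroxyl proton is omitted).
    """
    bb = BACKBONE
    pos: dict[str, np.ndarray] = {}
    names: list[str] = []
    elements: list[str] = []
    for name, el, x, y, z in BASE_TEMPLATES[base]:
        pos[name] = np.array([x, y, z])
        names.append(name)
        elements.append(el)

    ngly = "N9" if base in "AG" else "N1"
    cref = "C4" if base in "AG" else "C2"

    def put(name: str, el: str, a: str, b: str, c: str,
            bond: float, angle: float, torsion: float) -> None:
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, angle, torsion)
        names.append(name)
        elements.append(el)

    put("O4'", "O", cref, ngly, "C1'", bb["r_CO_ring"], bb["a_NC1O4"], bb["chi"])
    put("C2'", "C", cref, ngly, "C1'", bb["r_CC"], bb["a_NC1C2"], bb["chi"] + bb["b_c2"])
    put("C3'", "C", "O4'", "C1'", "C2'", bb["r_CC"], bb["a_C1C2C3"], bb["nu1"])
    put("C4'", "C", "C1'", "C2'", "C3'", bb["r_CC"], bb["a_C2C3C4"], bb["nu2"])
    put("O3'", "O", "C1'", "C2'", "C3'", bb["r_C3O3"], bb["a_C2C3O3"],
        bb["nu2"] + bb["b_o3"])
    put("C5'", "C", "C2'", "C3'", "C4'", bb["r_CC"], bb["a_C3C4C5"],
        bb["nu3"] + bb["b_c5"])
    put("O5'", "O", "C3'", "C4'", "C5'", bb["r_C5O5"], bb["a_C4C5O5"], bb["gamma"])
    if not terminal5:
        put("P", "P", "C4'", "C5'", "O5'", bb["r_OP"], bb["a_C5O5P"], bb["beta"])
        put("OP1", "O", "C5'", "O5'", "P", bb["r_POP"], bb["a_O5POP"], bb["b_op"])
        put("OP2", "O", "C5'", "O5'", "P", bb["r_POP"], bb["a_O5POP"], -bb["b_op"])

    # sugar hydrogens
    h_defs = [
        ("H1'", "C1'", [ngly, "O4'", "C2'"], 1),
        ("H3'", "C3'", ["C2'", "C4'", "O3'"], 1),
        ("H4'", "C4'", ["C3'", "O4'", "C5'"], 1),
    ]
    for hname, center, nb, nh in h_defs:
        for p in _tetrahedral_h(pos[center], [pos[x] for x in nb], nh):
            pos[hname] = p
            names.append(hname)
            elements.append("H")
    for hname, p in zip(("H2'", "H2''"),
                        _tetrahedral_h(pos["C2'"], [pos["C1'"], pos["C3'"]], 2)):
        pos[hname] = p
        names.append(hname)
        elements.append("H")
    for hname, p in zip(("H5'", "H5''"),
                        _tetrahedral_h(pos["C5'"], [pos["C4'"], pos["O5'"]], 2)):
        pos[hname] = p
        names.append(hname)
        elements.append("H")
    for hname, p in _base_protons(base, pos):
        pos[hname] = p
        names.append(hname)
        elements.append("H")

    bonds = list(BASE_BONDS[base]) + list(SUGAR_BONDS)
    if not terminal5:
        bonds += PHOSPHATE_BONDS
    # covalent bonds for every proton/pseudo-proton
    h_parent = {"H1'": "C1'", "H2'": "C2'", "H2''": "C2'", "H3'": "C3'",
                "H4'": "C4'", "H5'": "C5'", "H5''": "C5'",
                "H8": "C8", "H2": "C2", "H6": "C6", "H5": "C5",
                "H1": "N1", "H3": "N3", "Q5M": "C7"}
    bonds += [(h, h_parent[h]) for h in names if h in h_parent]
    coords = np.array([pos[n] for n in names])
    return names, elements, coords, bonds


_FLIP = np.diag([1.0, -1.0, -1.0])  # Watson-Crick partner in the pair frame


def _rotz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_helix(topology: DuplexTopology, rises: np.ndarray,
                twists: np.ndarray) -> Structure:
    """Assemble a duplex with explicit per-step rise (A) and twist (deg).

    Pair s (0-based) sits at cumulative rise sum(rises[:s]) along z,
    rotated by the cumulative twist about z.  The complement nucleotide of
    each pair is the 180-deg x-flip of its template, which makes the two
    strands antiparallel.
    """
    n = topology.n_pairs
    rises = np.asarray(rises, dtype=float)
    twists = np.asarray(twists, dtype=float)
    if rises.shape != (n - 1,) or twists.shape != (n - 1,):
        raise ValueError(f"need {n - 1} per-step rises and twists")
    z = np.concatenate([[0.0], np.cumsum(rises)])
    theta = np.concatenate([[0.0], np.cumsum(twists)])

    parts: list[Structure] = []
    for s in range(n):
        rot = _rotz(theta[s])
        shift = np.array([0.0, 0.0, z[s]])
        sense_res = s + 1
        comp_res = 2 * n - s  # partner of sense_res
        # sense nucleotide
        for resnum, base, flip in (
            (sense_res, topology.base(sense_res), False),
            (comp_res, topology.base(comp_res), True),
        ):
            # 5'-terminal check: sense strand starts at residue 1;
            # complement strand starts at residue n+1 (pair index n-1).
            term5 = (resnum == 1) or (resnum == n + 1)
            names, elements, coords, bonds_by_name = build_nucleotide(base, term5)
            if flip:
                coords = coords @ _FLIP.T
            coords = coords @ rot.T + shift
            name_idx = {nm: i for i, nm in enumerate(names)}
            bonds = [(name_idx[a], name_idx[b]) for a, b in bonds_by_name]
            parts.append(Structure(
                ["DNA"] * len(names), [resnum] * len(names), names, elements,
                coords, bonds))
    struct = concatenate(parts)
    # inter-residue O3'(i) -> P(i+1) links within each strand
    for i in range(1, 2 * n):
        if i == n:  # strand boundary: residue n is sense 3'-end
            continue
        struct.bonds.append((struct.index_of("DNA", i, "O3'"),
                             struct.index_of("DNA", i + 1, "P")))
    return struct


def build_bdna(topology: DuplexTopology, rise_per_step: float = 3.4,
               twist_per_step: float = 36.0) -> Structure:
    """Uniform idealized B-DNA duplex (fiber-like geometry)."""
    n = topology.n_pairs
    return build_helix(topology,
                       np.full(n - 1, float(rise_per_step)),
                       np.full(n - 1, float(twist_per_step)))
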