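"""NOE distance restraints: calibration, classification, energies.

Peak volumes are converted to distances with the isolated-spin-pair
r^-6 law, referenced to the fixed cytosine H5-H6 distance of 2.45 A:
r = r_ref * (V_ref / V)^(1/6).  Flat bounds are placed at +/-20% of the
target; pseudo-atom corrections (methyl groups represented by a centroid)
inflate the upper bound.  Outside the bounds a (possibly skewed)
bi-harmonic penalty applies, with force constants chosen per category
(30 kcal/mol/A^2 for NOE restraints, 60 for hydrogen bonds at the final
schedule stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import BASE_TEMPLATES
from .structure import AtomKey, Structure
from .topology import DuplexTopology

CATEGORIES = ("intraresidue", "sequential", "hydrogen_bond", "drug", "drug_dna")

#: Upper-bound inflation (A) for pseudo-atoms representing unresolved
#: equivalent protons (Wuthrich-style corrections).
PSEUDOATOM_CORRECTIONS = {
    "methyl": 1.0,
    "methylene": 0.9,
    "aromatic_pair": 2.0,
}


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceRestraint:
    """A bounded inter-proton (or heavy-atom) distance restraint."""

    atom_i: AtomKey
    atom_j: AtomKey
    target: float
    lower: float
    upper: float
    category: str
    pseudoatom_correction: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.target <= self.upper):
            raise RestraintError(
                f"bounds must satisfy 0 < lower <= target <= upper, got "
                f"({self.lower}, {self.target}, {self.upper})")

    def distance(self, structure: Structure) -> float:
        a = structure.xyz(*self.atom_i)
        b = structure.xyz(*self.atom_j)
        return float(np.linalg.norm(a - b))


@dataclass
class RestraintSet:
    """A list of restraints plus calibration bookkeeping."""

    restraints: list[DistanceRestraint] = field(default_factory=list)
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.restraints)

    def __len__(self) -> int:
        return len(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    def extend(self, other: "RestraintSet") -> "RestraintSet":
        return RestraintSet(self.restraints + list(other), self.n_rejected)


@dataclass(frozen=True)
class CalibrationModel:
    """ISPA volume calibration against the cytosine H5-H6 reference."""

    r_ref: float = 2.45          # A, cytosine H5-H6
    bound_fraction: float = 0.20  # flat bounds at +/-20% of the target

    def __post_init__(self) -> None:
        if self.r_ref <= 0 or not 0 < self.bound_fraction < 1:
            raise RestraintError("invalid calibration model")


def pseudo_correction(name: str) -> float:
    """Upper-bound correction for an atom name (pseudo-atoms start with Q)."""
    if name.startswith("Q") and name.endswith("M"):
        return PSEUDOATOM_CORRECTIONS["methyl"]
    if name.startswith("Q"):
        return PSEUDOATOM_CORRECTIONS["methylene"]
    return 0.0


def _category_of(atom_i: AtomKey, atom_j: AtomKey,
                 topology: DuplexTopology) -> str:
    mol_i, res_i, _ = atom_i
    mol_j, res_j, _ = atom_j
    dna_i, dna_j = mol_i == "DNA", mol_j == "DNA"
    if dna_i != dna_j:
        return "drug_dna"
    if not dna_i:
        return "drug"
    if res_i == res_j:
        return "intraresidue"
    n = topology.n_pairs
    same_strand = (res_i <= n) == (res_j <= n)
    if same_strand and abs(res_i - res_j) == 1:
        return "sequential"
    # cross-strand: same pair or adjacent pair step
    pi = res_i - 1 if res_i <= n else 2 * n - res_i
    pj = res_j - 1 if res_j <= n else 2 * n - res_j
    if not same_strand and abs(pi - pj) <= 1:
        return "sequential"
    return "long_range"


def calibrate(peaks, topology: DuplexTopology,
              model: CalibrationModel | None = None) -> RestraintSet:
    """Convert a NOESY peak list into bounded distance restraints.

    The reference peak's volume defines V_ref; every other peak maps to
    r = r_ref (V_ref/V)^(1/6) with bounds at -/+ ``bound_fraction`` of r
    and pseudo-atom corrections added to the upper bound.  Non-positive
    volumes are rejected (counted, with a warning).
    """
    model = model or CalibrationModel()
    ref = peaks.reference_peak()
    if ref is None or ref.volume <= 0:
        raise RestraintError("reference cytosine H5-H6 peak missing or non-positive")
    v_ref = ref.volume
    out = RestraintSet()
    for pk in peaks.peaks:
        if pk is ref:
            continue
        if pk.volume <= 0:
            out.n_rejected += 1
            continue
        r = model.r_ref * (v_ref / pk.volume) ** (1.0 / 6.0)
        corr = pseudo_correction(pk.proton_i[2]) + pseudo_correction(pk.proton_j[2])
        out.restraints.append(DistanceRestraint(
            pk.proton_i, pk.proton_j, r,
            (1.0 - model.bound_fraction) * r,
            (1.0 + model.bound_fraction) * r + corr,
            _category_of(pk.proton_i, pk.proton_j, topology),
            pseudoatom_correction=corr,
        ))
    if out.n_rejected:
        warnings.warn(f"rejected {out.n_rejected} non-positive peak volume(s)",
                      stacklevel=2)
    return out


def classify(restraint_set: RestraintSet,
             topology: DuplexTopology) -> dict[str, int]:
    """Category counts (re-derived from atom identities; hydrogen-bond
    restraints keep their creation flag).  Counts sum to len(set)."""
    counts = {c: 0 for c in CATEGORIES}
    counts["long_range"] = 0
    for r in restraint_set:
        if r.category == "hydrogen_bond":
            cat = "hydrogen_bond"
        else:
            cat = _category_of(r.atom_i, r.atom_j, topology)
        counts[cat] += 1
    return counts


# -- hydrogen-bond restraints ---------------------------------------------

def _wc_distances() -> dict[str, list[tuple[str, str, float]]]:
    """Donor/acceptor distances of ideal Watson-Crick pairs, measured on
    the standard-reference-frame templates (partner flipped about x)."""
    flip = np.diag([1.0, -1.0, -1.0])

    def tpl(base):
        return {n: np.array([x, y, z]) for n, _e, x, y, z in BASE_TEMPLATES[base]}

    out: dict[str, list[tuple[str, str, float]]] = {}
    a, t, g, c = tpl("A"), tpl("T"), tpl("G"), tpl("C")
    t_f = {n: flip @ v for n, v in t.items()}
    c_f = {n: flip @ v for n, v in c.items()}
    out["AT"] = [
        ("N1", "N3", float(np.linalg.norm(a["N1"] - t_f["N3"]))),
        ("N6", "O4", float(np.linalg.norm(a["N6"] - t_f["O4"]))),
    ]
    out["GC"] = [
        ("N1", "N3", float(np.linalg.norm(g["N1"] - c_f["N3"]))),
        ("O6", "N4", float(np.linalg.norm(g["O6"] - c_f["N4"]))),
    ]
    return out


_WC = _wc_distances()


def make_hbond_restraints(topology: DuplexTopology,
                          pairs_subset: list[int] | None = None,
                          half_width: float = 0.2) -> RestraintSet:
    """Two flat restraints per selected Watson-Crick pair (N1...N3 and the
    carbonyl...amino donor pair), +-``half_width`` A around ideal geometry.

    ``pairs_subset`` lists 0-based pair indices; default: all non-terminal
    pairs.
    """
    n = topology.n_pairs
    if pairs_subset is None:
        pairs_subset = list(range(1, n - 1))
    out = RestraintSet()
    for idx in pairs_subset:
        i, j = topology.pairs[idx]
        # purine member carries N1/N6 or N1/O6
        if topology.base(i) in "AG":
            pur, pyr = i, j
        else:
            pur, pyr = j, i
        kind = topology.pair_kind(idx)
        for pur_atom, pyr_atom, dist in _WC[kind]:
            out.restraints.append(DistanceRestraint(
                ("DNA", pur, pur_atom), ("DNA", pyr, pyr_atom),
                dist, dist - half_width, dist + half_width, "hydrogen_bond"))
    return out


# -- restraint energy ------------------------------------------------------

@dataclass(frozen=True)
class RestraintEnergyParams:
    """Force constants (kcal/mol/A^2) and upper/lower skew factors."""

    k_noe: float = 30.0
    k_hbond: float = 60.0
    skew_upper: float = 1.0
    skew_lower: float = 1.0

    def __post_init__(self) -> None:
        if self.k_noe < 0 or self.k_hbond < 0:
            raise RestraintError("force constants must be >= 0")


def restraint_energy(distance: float, restraint: DistanceRestraint,
                     params: RestraintEnergyParams | None = None
                     ) -> tuple[float, float]:
    """Skewed bi-harmonic flat-well energy and d(energy)/d(distance).

    Zero inside [lower, upper]; k*skew*(d - bound)^2 outside, with k per
    category.  Energy and gradient are continuous at the bounds.
    """
    params = params or RestraintEnergyParams()
    k = params.k_hbond if restraint.category == "hydrogen_bond" else params.k_noe
    if distance > restraint.upper:
        ks = k * params.skew_upper
        dx = distance - restraint.upper
        return ks * dx * dx, 2.0 * ks * dx
    if distance < restraint.lower:
        ks = k * params.skew_lower
        dx = distance - restraint.lower
        return ks * dx * dx, 2.0 * ks * dx
    return 0.0, 0.0
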