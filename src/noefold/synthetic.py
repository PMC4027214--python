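"""Synthetic ground-truth complexes, NOESY peak lists and FID titrations.

These generators define the study conditions every downstream stage is
tested under:

* a B-DNA duplex with four intercalation gaps at the drug binding sites,
  enlarged rise and local unwinding as measured for the refined complex
  (rises 6.01/6.34/5.95/5.86 A, site unwinding 32/28 deg, ~7 deg at the
  central step, 4-5 deg spill-over into the +-1 steps);
* r^-6 NOESY volumes with multiplicative log-normal noise, referenced to
  the cytosine H5-H6 calibration peak (2.45 A);
* hyperbolic 2:1 equal-site binding titrations with replicate noise
  (duplex 16.7 uM, drug 0-100 uM, 3 replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import fid as _fid
from .geometry import build_helix
from .ligand import TFF1_SITES, place_ligands
from .restraints import DistanceRestraint, RestraintSet, make_hbond_restraints
from .structure import AtomKey, Structure
from .topology import TFF1_ERE_SENSE, DuplexTopology, build_duplex

REFERENCE_DISTANCE = 2.45  # A, cytosine H5-H6 calibration standard


class SpecError(ValueError):
    pass


# -- ground-truth complex --------------------------------------------------

@dataclass(frozen=True)
class IntercalationSite:
    """One opened dinucleotide step: 0-based step index, target rise (A),
    local unwinding (deg) applied at the step itself."""

    step: int
    rise: float
    unwinding: float


@dataclass(frozen=True)
class GroundTruthSpec:
    """Recipe for a ground-truth DNA-drug complex."""

    topology: DuplexTopology
    sites: tuple[IntercalationSite, ...]
    ligand_sites: dict[str, tuple[tuple[int, int], ...]] | None = None
    neighbor_unwinding: float = 4.5   # deg added to each +-1 step; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        steps = [s.step for s in self.sites]
        if len(set(steps)) != len(steps):
            raise SpecError("overlapping intercalation sites")
        n = self.topology.n_pairs
        for s in self.sites:
            if not 0 <= s.step < n - 1:
                raise SpecError(f"step {s.step} outside 0..{n - 2}")
            # a site either opens a gap (rise 5-8 A) or only unwinds a
            # spanned step at the stacked 3.4 A rise
            if not (5.0 <= s.rise <= 8.0 or abs(s.rise - 3.4) < 1e-9):
                raise SpecError(f"target rise {s.rise} outside [5, 8] A")


def tff1_complex_spec(seed: int = 0) -> GroundTruthSpec:
    """The refined-complex geometry: gaps at C5pA6, C7pG8, G9pT10 and
    G11pG12 with the printed rises; 32/28 deg site unwinding split over
    the 3-step sites; ~7 deg at the central G8pG9 step."""
    topo = build_duplex(TFF1_ERE_SENSE)
    sites = (
        IntercalationSite(4, 5.95, 13.0),   # C5pA6, weak XR1-1
        IntercalationSite(5, 3.40, 6.0),    # spanned step A6pC7
        IntercalationSite(6, 6.01, 13.0),   # C7pG8, strong XR1-2 -> site total 32
        IntercalationSite(7, 3.40, 7.0),    # central G8pG9 between the drugs
        IntercalationSite(8, 6.34, 12.0),   # G9pT10, strong XR2-1
        IntercalationSite(9, 3.40, 4.0),    # spanned step T10pG11
        IntercalationSite(10, 5.86, 12.0),  # G11pG12, weak XR2-2 -> site total 28
    )
    return GroundTruthSpec(topo, sites, TFF1_SITES, neighbor_unwinding=4.5,
                           seed=seed)


def make_ground_truth(spec: GroundTruthSpec) -> Structure:
    """Build the ground-truth complex a spec describes.

    Unlisted steps keep 3.4 A / 36 deg except the +-1 neighbours of opened
    gaps, which lose ``neighbor_unwinding`` degrees of twist each.
    """
    topo = spec.topology
    n = topo.n_pairs
    rises = np.full(n - 1, 3.4)
    twists = np.full(n - 1, 36.0)
    listed = {s.step for s in spec.sites}
    for s in spec.sites:
        rises[s.step] = s.rise
        twists[s.step] = 36.0 - s.unwinding
    if spec.neighbor_unwinding:
        for s in spec.sites:
            if s.rise < 5.0:
                continue  # only opened gaps spill unwinding outward
            for nb in (s.step - 1, s.step + 1):
                if 0 <= nb < n - 1 and nb not in listed:
                    twists[nb] -= spec.neighbor_unwinding
    struct = build_helix(topo, rises, twists)
    if spec.ligand_sites:
        struct = place_ligands(struct, topo, spec.ligand_sites)
    return struct


# -- NOESY simulation ------------------------------------------------------

@dataclass(frozen=True)
class NoePeak:
    proton_i: AtomKey
    proton_j: AtomKey
    volume: float
    mixing_time_ms: float = 150.0


@dataclass
class NoePeakList:
    peaks: list[NoePeak]
    reference_index: int
    cutoff_used: float
    seed: int = 0

    def reference_peak(self) -> NoePeak | None:
        if 0 <= self.reference_index < len(self.peaks):
            return self.peaks[self.reference_index]
        return None


def simulate_noesy(structure: Structure, topology: DuplexTopology,
                   cutoff: float = 5.5, noise_sd: float = 0.10,
                   seed: int = 0, mixing_time_ms: float = 150.0,
                   volume_scale: float = 1.0e6) -> NoePeakList:
    """One r^-6 peak per proton pair closer than ``cutoff``.

    Volumes follow V = C r^-6 exp(eps) with eps ~ Normal(0, noise_sd) per
    peak (multiplicative log-normal error).  The cytosine H5-H6 reference
    peak is always emitted, with its volume computed from the nominal
    2.45 A calibration distance so that noise-free calibration round-trips
    distances exactly.
    """
    rng = np.random.default_rng(seed)
    pmask = structure.proton_mask()
    pidx = np.flatnonzero(pmask)
    keys = structure.keys()

    # reference: first cytosine H5/H6 pair (cytosine is the only base
    # carrying both H5 and H6)
    ref_pair = None
    n = topology.n_pairs
    for res in topology.residue_numbers:
        if topology.base(res) == "C":
            try:
                i = structure.index_of("DNA", res, "H5")
                j = structure.index_of("DNA", res, "H6")
            except KeyError:
                continue
            ref_pair = (i, j)
            break
    if ref_pair is None:
        raise SpecError("no cytosine H5/H6 in structure: cannot set reference")

    tree = cKDTree(structure.coords[pidx])
    pairs = sorted(tree.query_pairs(cutoff))
    peaks: list[NoePeak] = []
    ref_index = -1
    for a, b in pairs:
        i, j = int(pidx[a]), int(pidx[b])
        if (i, j) == ref_pair or (j, i) == ref_pair:
            continue  # reference emitted separately at nominal distance
        r = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        peaks.append(NoePeak(keys[i], keys[j],
                             volume_scale * r ** -6 * np.exp(eps),
                             mixing_time_ms))
    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    peaks.append(NoePeak(keys[ref_pair[0]], keys[ref_pair[1]],
                         volume_scale * REFERENCE_DISTANCE ** -6 * np.exp(eps),
                         mixing_time_ms))
    ref_index = len(peaks) - 1
    return NoePeakList(peaks, ref_index, cutoff, seed)


# -- FID titration simulation ----------------------------------------------

@dataclass(frozen=True)
class TitrationSpec:
    """Study conditions of the displacement titration."""

    true_kd: float = 9.65e-7          # M, equal-site dissociation constant
    amplitude_b: float = 1.0
    duplex_total: float = 16.7e-6     # M
    drug_totals: tuple[float, ...] = tuple(np.linspace(0.0, 100e-6, 13))
    noise_sd: float = 0.02            # relative to the amplitude
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.drug_totals, default=0.0) < 0 or self.duplex_total < 0:
            raise SpecError("concentrations must be >= 0")
        if self.noise_sd < 0 or self.replicates < 1:
            raise SpecError("invalid noise/replicate settings")


def simulate_fid(spec: TitrationSpec) -> "_fid.TitrationTable":
    """Noisy bound-fraction titration under the equal-site 2:1 model.

    Free drug is obtained from totals by the same mass balance the fitter
    uses; per-replicate noise is i.i.d. Normal(0, noise_sd * B).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for x_total in spec.drug_totals:
        x_free = _fid.free_ligand(x_total, spec.duplex_total,
                                  spec.true_kd, spec.amplitude_b)
        f0 = spec.amplitude_b * x_free / (spec.true_kd + x_free)
        for rep in range(1, spec.replicates + 1):
            noise = (rng.normal(0.0, spec.noise_sd * spec.amplitude_b)
                     if spec.noise_sd > 0 else 0.0)
            rows.append((x_total, rep, f0 + noise))
    return _fid.TitrationTable(rows, duplex_total=spec.duplex_total)


# -- Table-style restraint inventory ---------------------------------------

#: Restraint-inventory category totals of the refined complex.
INVENTORY_COUNTS = {"intraresidue": 357, "sequential": 153,
                    "hydrogen_bond": 24, "drug": 79, "drug_dna": 56}

_DNA_PROTONS = ("H1'", "H2'", "H2''", "H3'", "H4'", "H5'", "H5''")
_DRUG_PROTONS = ("H2", "H3", "H4", "H6", "H7", "H8", "Q9M", "QGM",
                 "HB11", "HB12", "HB21", "HB22")


def restraint_inventory(topology: DuplexTopology | None = None,
                     counts: dict[str, int] | None = None) -> RestraintSet:
    """A deterministic restraint set reproducing the published category
    inventory (357 intraresidue / 153 sequential / 24 hydrogen bonds /
    79 drug / 56 drug-DNA = 669) with synthetic 3 A +/-20% targets.

    Used as the bookkeeping fixture for the classifier; targets are
    nominal, not measured.
    """
    topo = topology or build_duplex(TFF1_ERE_SENSE)
    counts = dict(INVENTORY_COUNTS if counts is None else counts)
    n = topo.n_pairs

    def mk(ai: AtomKey, aj: AtomKey, cat: str) -> DistanceRestraint:
        return DistanceRestraint(ai, aj, 3.0, 2.4, 3.6, cat)

    out: list[DistanceRestraint] = []
    # intraresidue: proton pairs within one residue, cycling residues
    need = counts["intraresidue"]
    k = 0
    while len(out) < need:
        res = 1 + k % (2 * n)
        combos = [(a, b) for ii, a in enumerate(_DNA_PROTONS)
                  for b in _DNA_PROTONS[ii + 1:]]
        a, b = combos[(k // (2 * n)) % len(combos)]
        out.append(mk(("DNA", res, a), ("DNA", res, b), "intraresidue"))
        k += 1
    # sequential: adjacent residues on one strand
    base = len(out)
    k = 0
    while len(out) - base < counts["sequential"]:
        res = 1 + k % (2 * n - 2)
        if res == n:  # strand boundary is not sequential
            k += 1
            continue
        a = _DNA_PROTONS[k % len(_DNA_PROTONS)]
        b = _DNA_PROTONS[(k // (2 * n)) % len(_DNA_PROTONS)]
        out.append(mk(("DNA", res, a), ("DNA", res + 1, b), "sequential"))
        k += 1
    # hydrogen bonds: 12 pairs x 2; the non-terminal pairs with clearly
    # observed imino protons, excluding the weak-site pair G11:C20
    hb_pairs = [i for i in range(1, n - 1) if i != 10][:12]
    hb = make_hbond_restraints(topo, hb_pairs)
    assert len(hb) == counts["hydrogen_bond"]
    out += list(hb)
    # drug: proton pairs within one ligand
    base = len(out)
    k = 0
    while len(out) - base < counts["drug"]:
        mol = "XR1" if k % 2 == 0 else "XR2"
        combos = [(a, b) for ii, a in enumerate(_DRUG_PROTONS)
                  for b in _DRUG_PROTONS[ii + 1:]]
        a, b = combos[(k // 2) % len(combos)]
        moi = 1 + (k // (2 * len(combos))) % 2
        out.append(mk((mol, moi, a), (mol, moi, b), "drug"))
        k += 1
    # drug-DNA: intermolecular
    base = len(out)
    k = 0
    while len(out) - base < counts["drug_dna"]:
        mol = "XR1" if k % 2 == 0 else "XR2"
        res = 1 + k % (2 * n)
        out.append(mk((mol, 1 + k % 2, _DRUG_PROTONS[k % 6]),
                      ("DNA", res, _DNA_PROTONS[k % len(_DNA_PROTONS)]),
                      "drug_dna"))
        k += 1
    return RestraintSet(out)
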