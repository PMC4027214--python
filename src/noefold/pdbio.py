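"""File formats: multi-model PDB, peak-list TSV, restraint tables, FID CSV.

PDB input/output goes through gemmi; the package's molecule naming maps
onto chains A (sense strand), B (complement) and C/D (the two ligand
copies).  Peak lists and restraint tables are plain TSV with headers;
titrations are CSV.  An X-PLOR-style ``assign`` writer is provided for
interoperability with classical structure-calculation software.
"""

from __future__ import annotations

import csv
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .annealing import Ensemble
from .restraints import DistanceRestraint, RestraintSet
from .structure import Structure
from .synthetic import NoePeak, NoePeakList


class PdbError(ValueError):
    pass


_CHAIN_OF = {"DNA": None, "XR1": "C", "XR2": "D"}  # DNA split into A/B
_DNA_RESNAMES = {"A": "DA", "G": "DG", "C": "DC", "T": "DT"}
_RESNAME_TO_BASE = {v: k for k, v in _DNA_RESNAMES.items()}
_LIG_RESNAME = "XRB"


def _chain_for(mol: str, resnum: int, n_pairs: int) -> str:
    if mol == "DNA":
        return "A" if resnum <= n_pairs else "B"
    return _CHAIN_OF.get(mol, "E")


def write_pdb_ensemble(path: str | Path, models: list[Structure],
                       topology=None, remarks: list[str] | None = None) -> None:
    """Write models as a standard multi-model PDB (MODEL/ENDMDL records)."""
    if not models:
        raise PdbError("no models to write")
    n_pairs = topology.n_pairs if topology is not None else max(
        (r for m, r in zip(models[0].mols, models[0].resnums) if m == "DNA"),
        default=0) // 2
    st = gemmi.Structure()
    st.name = "noefold"
    for rem in remarks or []:
        st.raw_remarks.append(f"REMARK 250 {rem}")
    for model in models:
        # gemmi containers copy on add: build residues fully, then chains,
        # then the model
        order: list[tuple[str, str, int]] = []
        groups: dict[tuple[str, str, int], list[int]] = {}
        for i in range(model.n_atoms):
            cid = _chain_for(model.mols[i], model.resnums[i], n_pairs)
            key = (cid, model.mols[i], model.resnums[i])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        gm = gemmi.Model(str(model.model_id))
        for cid in sorted({k[0] for k in order}):
            chain = gemmi.Chain(cid)
            for key in sorted((k for k in order if k[0] == cid),
                              key=lambda k: k[2]):
                _c, mol, resnum = key
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(resnum, " ")
                if mol == "DNA":
                    res.name = (_DNA_RESNAMES[topology.base(resnum)]
                                if topology is not None else "DN")
                else:
                    res.name = _LIG_RESNAME
                res.het_flag = "A" if mol == "DNA" else "H"
                for i in groups[key]:
                    atom = gemmi.Atom()
                    atom.name = model.names[i]
                    atom.element = gemmi.Element(model.elements[i])
                    x, y, z = model.coords[i]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    res.add_atom(atom)
                chain.add_residue(res)
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def read_pdb_ensemble(path: str | Path,
                      chain_map: dict[str, str] | None = None) -> list[Structure]:
    """Read a (multi-)model PDB file into a list of structures.

    Chains named A/B (or mapped via ``chain_map``) become molecule "DNA";
    other chains become ligand molecules named after the chain (C -> XR1,
    D -> XR2 by default).  Atom names are normalised to the package's
    prime convention (H2'' etc.).  Single-model files give a one-element
    list.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PdbError(f"{path}: empty file")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PdbError(f"{path}: {exc}") from None
    if len(st) == 0:
        raise PdbError(f"{path}: no models found")
    default_map = {"A": "DNA", "B": "DNA", "C": "XR1", "D": "XR2"}
    cmap = chain_map or default_map
    out: list[Structure] = []
    for mi, gm in enumerate(st, start=1):
        mols, resnums, names, elements, coords = [], [], [], [], []
        for ch in gm:
            mol = cmap.get(ch.name, ch.name)
            for res in ch:
                for atom in res:
                    nm = atom.name
                    mols.append(mol)
                    resnums.append(res.seqid.num)
                    names.append(nm)
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not mols:
            raise PdbError(f"{path}: model {mi} contains no atoms")
        out.append(Structure(mols, resnums, names, elements,
                             np.array(coords), [], model_id=mi))
    return out


def read_ensemble(path: str | Path, **kw) -> Ensemble:
    """Read a PDB ensemble into the annealing Ensemble container
    (energies/violations unknown -> zeros)."""
    models = read_pdb_ensemble(path, **kw)
    n = len(models)
    return Ensemble(models, [0.0] * n, [0.0] * n, [0] * n,
                    [0] * n, [""] * n)


# -- peak lists ------------------------------------------------------------

def write_peaks_tsv(path: str | Path, peaks: NoePeakList) -> None:
    rows = []
    for k, pk in enumerate(peaks.peaks):
        rows.append({
            "proton_i": "/".join(map(str, pk.proton_i)),
            "proton_j": "/".join(map(str, pk.proton_j)),
            "volume": pk.volume,
            "mixing_time_ms": pk.mixing_time_ms,
            "is_reference": int(k == peaks.reference_index),
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path: str | Path) -> NoePeakList:
    df = pd.read_csv(path, sep="\t")
    peaks = []
    ref = -1
    for k, row in df.iterrows():
        mi, ri, ni = str(row["proton_i"]).split("/")
        mj, rj, nj = str(row["proton_j"]).split("/")
        peaks.append(NoePeak((mi, int(ri), ni), (mj, int(rj), nj),
                             float(row["volume"]), float(row["mixing_time_ms"])))
        if int(row.get("is_reference", 0)):
            ref = int(k)
    return NoePeakList(peaks, ref, cutoff_used=float("nan"))


# -- restraint tables ------------------------------------------------------

def write_restraints_tsv(path: str | Path, restraints: RestraintSet) -> None:
    rows = [{
        "atom_i": "/".join(map(str, r.atom_i)),
        "atom_j": "/".join(map(str, r.atom_j)),
        "target_A": r.target, "lower_A": r.lower, "upper_A": r.upper,
        "category": r.category, "pseudo_corr_A": r.pseudoatom_correction,
    } for r in restraints]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path: str | Path) -> RestraintSet:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _k, row in df.iterrows():
        mi, ri, ni = str(row["atom_i"]).split("/")
        mj, rj, nj = str(row["atom_j"]).split("/")
        out.append(DistanceRestraint(
            (mi, int(ri), ni), (mj, int(rj), nj), float(row["target_A"]),
            float(row["lower_A"]), float(row["upper_A"]), str(row["category"]),
            float(row.get("pseudo_corr_A", 0.0))))
    return RestraintSet(out)


def write_xplor_assign(path: str | Path, restraints: RestraintSet) -> None:
    """Classical ``assign`` restraint syntax for interoperability."""
    lines = []
    for r in restraints:
        mi, ri, ni = r.atom_i
        mj, rj, nj = r.atom_j
        d = r.target
        dminus = r.target - r.lower
        dplus = r.upper - r.target
        lines.append(
            f"assign (segid {mi:<4s} and resid {ri:>3d} and name {ni:<4s}) "
            f"(segid {mj:<4s} and resid {rj:>3d} and name {nj:<4s}) "
            f"{d:6.2f} {dminus:5.2f} {dplus:5.2f} ! {r.category}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- titration CSV ---------------------------------------------------------

def write_titration_csv(path: str | Path, table) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_total_uM", "replicate", "fluorescence_fraction"])
        for x, rep, f in table.rows:
            w.writerow([f"{x * 1e6:.12g}", rep, f"{f:.12g}"])


def read_titration_csv(path: str | Path, duplex_total: float = 16.7e-6):
    from .fid import TitrationTable
    rows = []
    with open(path) as fh:
        for rec in csv.DictReader(fh):
            rows.append((float(rec["x_total_uM"]) * 1e-6, int(rec["replicate"]),
                         float(rec["fluorescence_fraction"])))
    return TitrationTable(rows, duplex_total=duplex_total)
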