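"""Helical-parameter and ensemble statistics.

Base-pair frames are obtained by least-squares fitting the observed base
ring atoms to the standard-reference-frame templates; the pair frame is
the average of the two base frames after flipping the complement base
frame by 180 deg about x.  Step parameters use the mid-step convention:
rise is the projection of the inter-origin vector on the mean z-axis and
twist the rotation of the paired x/y axes about it.  Unwinding is quoted
against the 36 deg/step B-DNA reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import BASE_RING_ATOMS, BASE_TEMPLATES
from .structure import Structure
from .topology import DuplexTopology

B_DNA_TWIST = 36.0  # deg/step reference for unwinding


class AnalysisError(ValueError):
    pass


# -- rigid superposition ---------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimising |R P + t - Q|.

    Returns (R, t, rmsd).  Reflections are excluded.  SVD-based; this is
    the package's own implementation and is cross-checked in the tests
    against an independent quaternion-based solver.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise AnalysisError("need two equal sets of >= 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def superpose_rmsd(a: Structure, b: Structure,
                   mask: np.ndarray | None = None) -> float:
    """Heavy-atom (or custom selection) RMSD after optimal superposition."""
    if not a.same_identity(b):
        raise AnalysisError("structures have different atom identity lists")
    if mask is None:
        mask = a.heavy_mask()
    if int(mask.sum()) < 3:
        raise AnalysisError("selection has fewer than 3 atoms")
    return kabsch(a.coords[mask], b.coords[mask])[2]


# -- base-pair frames ------------------------------------------------------

@dataclass(frozen=True)
class BasePairFrame:
    """Origin (A) and right-handed orthonormal axes of one base pair;
    columns of ``axes`` are x (major groove), y (long pair axis), z."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns x,y,z

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


_FLIP = np.diag([1.0, -1.0, -1.0])


def _base_frame(model: Structure, resnum: int, base: str) -> tuple[np.ndarray, np.ndarray]:
    names = BASE_RING_ATOMS[base]
    tpl = {n: np.array([x, y, z]) for n, _e, x, y, z in BASE_TEMPLATES[base]}
    try:
        obs = np.array([model.xyz("DNA", resnum, n) for n in names])
    except KeyError as exc:
        raise AnalysisError(f"residue {resnum}: {exc}") from None
    ref = np.array([tpl[n] for n in names])
    R, t, _ = kabsch(ref, obs)  # maps template frame into the model
    return R, R @ np.zeros(3) + t  # axes, origin (template origin is 0)


def compute_frames(model: Structure, topology: DuplexTopology) -> list[BasePairFrame]:
    """One frame per Watson-Crick pair (sense order, 5'->3')."""
    frames = []
    for i, j in topology.pairs:
        Ri, oi = _base_frame(model, i, topology.base(i))
        Rj, oj = _base_frame(model, j, topology.base(j))
        Rj = Rj @ _FLIP  # complement base: flip y,z into the pair frame
        # average the two rotations along the geodesic, and the origins
        Rm = (Rotation.from_matrix(Ri) * (
            Rotation.from_matrix(Ri).inv() * Rotation.from_matrix(Rj)
        ) ** 0.5).as_matrix()
        frames.append(BasePairFrame((oi + oj) / 2.0, Rm))
    return frames


@dataclass(frozen=True)
class StepParameters:
    """Mid-step helical parameters of one base-pair step."""

    step: int          # 0-based index: step between pairs step and step+1
    rise: float        # A
    twist: float       # deg, in (-180, 180]

    @property
    def unwinding(self) -> float:
        return B_DNA_TWIST - self.twist


def step_parameters(frames: list[BasePairFrame]) -> list[StepParameters]:
    """Per-step rise/twist from consecutive pair frames (mid-step scheme)."""
    if len(frames) < 2:
        raise AnalysisError("need at least two frames")
    out = []
    for s, (f1, f2) in enumerate(zip(frames, frames[1:])):
        r1 = Rotation.from_matrix(f1.axes)
        r2 = Rotation.from_matrix(f2.axes)
        rm = (r1 * (r1.inv() * r2) ** 0.5).as_matrix()
        zm = rm[:, 2]
        rise = float(np.dot(f2.origin - f1.origin, zm))
        # twist: rotation of the x-axes about zm
        x1 = f1.axes[:, 0] - np.dot(f1.axes[:, 0], zm) * zm
        x2 = f2.axes[:, 0] - np.dot(f2.axes[:, 0], zm) * zm
        x1 /= np.linalg.norm(x1)
        x2 /= np.linalg.norm(x2)
        twist = float(np.degrees(np.arctan2(np.dot(np.cross(x1, x2), zm),
                                            np.dot(x1, x2))))
        out.append(StepParameters(s, rise, twist))
    return out


def site_unwinding(steps: list[StepParameters], first_step: int,
                   last_step: int) -> float:
    """Total unwinding (deg) summed over steps first_step..last_step
    (0-based, inclusive), relative to the 36 deg/step reference."""
    sel = [p for p in steps if first_step <= p.step <= last_step]
    if not sel:
        raise AnalysisError("empty step range")
    return float(sum(p.unwinding for p in sel))


# -- ensemble statistics ---------------------------------------------------

@dataclass
class StatsReport:
    """Restraint-violation and precision statistics for an ensemble."""

    n_models: int
    violations_per_model: list[int]       # count of excesses > threshold
    violation_rmsd: float                 # RMS of out-of-bound excess (A)
    mean_pairwise_rmsd: float             # heavy atoms, optimal superposition
    pairwise_rmsd_sd: float
    bond_dev: float | None = None         # mean |dev| from ideal bonds (A)
    angle_dev: float | None = None        # deg
    improper_dev: float | None = None     # deg

    def as_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "noe_violations_gt_threshold": {
                "mean": float(np.mean(self.violations_per_model)),
                "sd": float(np.std(self.violations_per_model)),
                "per_model": self.violations_per_model,
            },
            "rmsd_of_violations_A": self.violation_rmsd,
            "pairwise_heavy_atom_rmsd_A": {
                "mean": self.mean_pairwise_rmsd, "sd": self.pairwise_rmsd_sd},
            "bond_deviation_A": self.bond_dev,
            "angle_deviation_deg": self.angle_dev,
            "improper_deviation_deg": self.improper_dev,
        }


def restraint_violations(model: Structure, restraints, threshold: float = 0.2
                         ) -> tuple[int, np.ndarray]:
    """Count restraint-bound violations > threshold and return all excesses.

    Excess is measured against the violated bound (not the target): the
    amount above the upper bound or below the lower bound.
    """
    excesses = []
    for r in restraints:
        d = r.distance(model)
        if d > r.upper:
            excesses.append(d - r.upper)
        elif d < r.lower:
            excesses.append(r.lower - d)
    excesses = np.array(excesses) if excesses else np.zeros(0)
    return int(np.sum(excesses > threshold)), excesses


def ensemble_stats(models: list[Structure], restraints=None,
                   threshold: float = 0.2,
                   forcefield=None,
                   heavy_mask: np.ndarray | None = None) -> StatsReport:
    """Table-style statistics over a multi-model ensemble.

    Pairwise RMSD is the mean over all model pairs of the heavy-atom RMSD
    after optimal rigid superposition.  If ``forcefield`` is given,
    covalent deviations from its ideal values are reported too.
    """
    if not models:
        raise AnalysisError("empty ensemble")
    for m in models[1:]:
        if not m.same_identity(models[0]):
            raise AnalysisError("models do not share an atom identity list")
    viol_counts = []
    all_exc = []
    if restraints is not None:
        for m in models:
            c, exc = restraint_violations(m, restraints, threshold)
            viol_counts.append(c)
            all_exc.append(exc)
        exc = np.concatenate(all_exc) if all_exc else np.zeros(0)
        viol_rmsd = float(np.sqrt(np.mean(exc ** 2))) if exc.size else 0.0
    else:
        viol_counts = [0] * len(models)
        viol_rmsd = 0.0

    if heavy_mask is None:
        heavy_mask = models[0].heavy_mask()
    prmsd = [superpose_rmsd(a, b, heavy_mask)
             for i, a in enumerate(models) for b in models[i + 1:]]
    mean_rmsd = float(np.mean(prmsd)) if prmsd else 0.0
    sd_rmsd = float(np.std(prmsd)) if prmsd else 0.0

    bond_dev = angle_dev = improper_dev = None
    if forcefield is not None:
        bd, ad, idv = [], [], []
        for m in models:
            b, a, im = forcefield.geometry_deviations(m.coords)
            bd.append(b)
            ad.append(a)
            idv.append(im)
        bond_dev = float(np.mean(bd))
        angle_dev = float(np.mean(ad))
        improper_dev = float(np.mean(idv))
    return StatsReport(len(models), viol_counts, viol_rmsd, mean_rmsd, sd_rmsd,
                       bond_dev, angle_dev, improper_dev)
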