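"""Restrained molecular-dynamics simulated annealing.

The staged protocol is encoded as data: equilibration at 300 K for 20 ps
with all restraint force constants at 1 kcal/mol/A^2, heating to 1000 K
for 3 ps, a 24 ps ramp of the force constants to their final values of
30 (NOE) and 60 (hydrogen bond) kcal/mol/A^2, cooling in 25 K decrements
of 1000 x 3 fs steps down to 300 K, 3 ps of final equilibration, a 3 ps
coordinate-averaging window, and 250 steps of energy minimization.
Heating stages integrate at 1 fs, cooling at the protocol's 3 fs.

Each ensemble member starts from an independent Maxwell-Boltzmann
velocity draw (seed + model index); the integrator is velocity Verlet
with a per-step velocity-rescaling thermostat.  A desk-scale factor
shrinks all stage durations (not temperatures or force constants) for
routine runs; 1.0 reproduces the full protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .forcefield import KB, KCAL_ACC, ForceField
from .restraints import RestraintSet
from .structure import Structure

ENERGY_ABORT = 1.0e9  # kcal/mol: beyond this a trajectory is flagged divergent


class AnnealingError(RuntimeError):
    pass


@dataclass(frozen=True)
class Stage:
    """One constant-temperature segment of the protocol."""

    name: str
    temperature: float            # K
    n_steps: int
    timestep_fs: float
    k_noe: float                  # kcal/mol/A^2 at stage end
    k_hbond: float
    ramp_from: tuple[float, float] | None = None  # linear ramp start (noe, hb)
    average: bool = False         # accumulate coordinates for averaging


@dataclass(frozen=True)
class AnnealingSchedule:
    stages: tuple[Stage, ...]
    minimize_steps: int = 250

    @property
    def n_cooling_cycles(self) -> int:
        return sum(1 for s in self.stages if s.name.startswith("cool"))

    @property
    def final_temperature(self) -> float:
        md = [s for s in self.stages if s.n_steps > 0]
        return md[-1].temperature if md else 0.0


def default_schedule(scale: float = 1.0) -> AnnealingSchedule:
    """The refinement protocol; ``scale`` < 1 gives a desk-scale run with
    proportionally shortened stage durations."""

    def steps(t_ps: float, dt_fs: float) -> int:
        return max(1, round(scale * t_ps * 1000.0 / dt_fs))

    stages: list[Stage] = [
        Stage("equilibrate_300K", 300.0, steps(20.0, 1.0), 1.0, 1.0, 1.0),
        Stage("heat_1000K", 1000.0, steps(3.0, 1.0), 1.0, 1.0, 1.0),
        Stage("ramp_k", 1000.0, steps(24.0, 1.0), 1.0, 30.0, 60.0,
              ramp_from=(1.0, 1.0)),
    ]
    t = 1000.0
    while t > 300.0:
        t -= 25.0
        stages.append(Stage(f"cool_{int(t)}K", t, max(1, round(scale * 1000)),
                            3.0, 30.0, 60.0))
    stages.append(Stage("equilibrate_final", 300.0, steps(3.0, 3.0), 3.0,
                        30.0, 60.0))
    stages.append(Stage("average", 300.0, steps(3.0, 3.0), 3.0, 30.0, 60.0,
                        average=True))
    return AnnealingSchedule(tuple(stages), minimize_steps=250)


def zero_schedule() -> AnnealingSchedule:
    """No dynamics, no minimization: output equals input."""
    return AnnealingSchedule((), minimize_steps=0)


def schedule_to_yaml(schedule: AnnealingSchedule, path) -> None:
    """Serialize a schedule as a YAML config."""
    import yaml

    payload = {
        "minimize_steps": schedule.minimize_steps,
        "stages": [{
            "name": s.name, "temperature_K": s.temperature,
            "n_steps": s.n_steps, "timestep_fs": s.timestep_fs,
            "k_noe": s.k_noe, "k_hbond": s.k_hbond,
            "ramp_from": list(s.ramp_from) if s.ramp_from else None,
            "average": s.average,
        } for s in schedule.stages],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def schedule_from_yaml(path) -> AnnealingSchedule:
    """Load a schedule from a YAML config."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    stages = tuple(Stage(
        d["name"], float(d["temperature_K"]), int(d["n_steps"]),
        float(d["timestep_fs"]), float(d["k_noe"]), float(d["k_hbond"]),
        tuple(d["ramp_from"]) if d.get("ramp_from") else None,
        bool(d.get("average", False)),
    ) for d in payload.get("stages", []))
    return AnnealingSchedule(stages, int(payload.get("minimize_steps", 250)))


@dataclass
class Ensemble:
    """Refined models with per-model selection metadata."""

    models: list[Structure]
    total_energies: list[float]
    restraint_energies: list[float]
    violation_counts: list[int]
    seeds: list[int]
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def subset(self, order: list[int]) -> "Ensemble":
        pick = lambda xs: [xs[i] for i in order]
        return Ensemble(pick(self.models), pick(self.total_energies),
                        pick(self.restraint_energies), pick(self.violation_counts),
                        pick(self.seeds), pick(self.flags) if self.flags else [])


def _kinetic_temperature(vel: np.ndarray, masses: np.ndarray) -> float:
    ke = 0.5 * np.sum(masses[:, None] * vel * vel) / KCAL_ACC
    return 2.0 * ke / (3.0 * len(masses) * KB)


def _draw_velocities(rng, masses: np.ndarray, temperature: float) -> np.ndarray:
    sigma = np.sqrt(KCAL_ACC * KB * temperature / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v -= np.average(v, axis=0, weights=masses)  # remove COM drift
    return v


def run_annealing(start: Structure, restraints: RestraintSet,
                  schedule: AnnealingSchedule, forcefield: ForceField | None = None,
                  n_models: int = 1, seed: int = 0,
                  reference: Structure | None = None,
                  violation_threshold: float = 0.2,
                  nb_rebuild: int = 15, log=None) -> Ensemble:
    """Run the annealing protocol for ``n_models`` independent trajectories.

    Deterministic given (inputs, seed): model i draws its velocities from
    seed + i.  Divergent trajectories (non-finite or runaway energy) are
    flagged and their last coordinates kept, never silently dropped.
    """
    from .analysis import restraint_violations  # local: avoid cycle

    if n_models < 1:
        raise AnnealingError("n_models must be >= 1")
    ff = forcefield or ForceField(start, restraints, reference=reference)
    if ff.r_idx.shape[0] != len(restraints):
        ff.set_restraints(restraints, start)

    models: list[Structure] = []
    etot_l: list[float] = []
    erest_l: list[float] = []
    viol_l: list[int] = []
    flags: list[str] = []

    for m in range(n_models):
        rng = np.random.default_rng(seed + m)
        x = start.coords.copy()
        vel = np.zeros_like(x)
        flag = ""
        avg_sum = np.zeros_like(x)
        avg_n = 0
        k_noe = k_hb = 1.0
        for stage in schedule.stages:
            if stage.n_steps <= 0:
                continue
            dt = stage.timestep_fs
            if not np.any(vel):
                vel = _draw_velocities(rng, ff.masses, stage.temperature)
            ff.build_neighbor_list(x)
            k_noe, k_hb = stage.k_noe, stage.k_hbond
            e, er, g = ff.energy(x, k_noe, k_hb)
            for step in range(stage.n_steps):
                if stage.ramp_from is not None:
                    frac = (step + 1) / stage.n_steps
                    k_noe = stage.ramp_from[0] + frac * (stage.k_noe - stage.ramp_from[0])
                    k_hb = stage.ramp_from[1] + frac * (stage.k_hbond - stage.ramp_from[1])
                acc = -g * (KCAL_ACC / ff.masses[:, None])
                vel += 0.5 * dt * acc
                x = x + dt * vel
                if step % nb_rebuild == nb_rebuild - 1:
                    ff.build_neighbor_list(x)
                e, er, g = ff.energy(x, k_noe, k_hb)
                acc = -g * (KCAL_ACC / ff.masses[:, None])
                vel += 0.5 * dt * acc
                tk = _kinetic_temperature(vel, ff.masses)
                if tk > 0:
                    vel *= np.sqrt(stage.temperature / tk)
                if not np.isfinite(e) or abs(e) > ENERGY_ABORT:
                    flag = f"divergent at {stage.name} step {step}"
                    break
                if stage.average:
                    avg_sum += x
                    avg_n += 1
            if log is not None:
                log(f"model {m} {stage.name}: T={stage.temperature:.0f}K "
                    f"E={e:.1f} E_restr={er:.1f}")
            if flag:
                break

        if not flag and avg_n > 0:
            x = avg_sum / avg_n
        if not flag and schedule.minimize_steps > 0:
            ff.build_neighbor_list(x)

            def fun(flat):
                e, _er, g = ff.energy(flat.reshape(-1, 3), k_noe, k_hb)
                return e, g.ravel()

            res = minimize(fun, x.ravel(), jac=True, method="L-BFGS-B",
                           options={"maxiter": schedule.minimize_steps})
            x = res.x.reshape(-1, 3)

        ff.build_neighbor_list(x)
        e, er, _g = ff.energy(x, k_noe, k_hb)
        model = start.with_coords(x, model_id=m + 1)
        nv, _exc = restraint_violations(model, restraints, violation_threshold)
        models.append(model)
        etot_l.append(float(e))
        erest_l.append(float(er))
        viol_l.append(nv)
        flags.append(flag)
    return Ensemble(models, etot_l, erest_l, viol_l,
                    [seed + m for m in range(n_models)], flags)


def select_models(candidates: Ensemble, n: int = 10) -> Ensemble:
    """Pick the n best models: fewest restraint violations first, then
    lowest total energy, with a stable index tie-break."""
    if len(candidates) < n:
        raise AnnealingError(f"only {len(candidates)} candidates for n={n}")
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates.violation_counts[i],
                                  candidates.total_energies[i], i))
    return candidates.subset(order[:n])
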