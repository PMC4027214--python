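"""Annealing protocol data, integrator behaviour and model selection."""

import numpy as np
import pytest

from noefold.annealing import (AnnealingError, Ensemble, default_schedule,
                               run_annealing, select_models, zero_schedule,
                               _draw_velocities, _kinetic_temperature)
from noefold.forcefield import ForceField


class TestSchedule:
    def test_protocol_encoded_exactly(self):
        sched = default_schedule()
        names = [s.name for s in sched.stages]
        assert names[0] == "equilibrate_300K"
        # 300 K / 20 ps at 1 fs with all restraint k = 1
        s0 = sched.stages[0]
        assert (s0.temperature, s0.n_steps, s0.timestep_fs) == (300.0, 20000, 1.0)
        assert (s0.k_noe, s0.k_hbond) == (1.0, 1.0)
        # 1000 K / 3 ps, then 24 ps ramp to (30, 60)
        s1, s2 = sched.stages[1], sched.stages[2]
        assert (s1.temperature, s1.n_steps) == (1000.0, 3000)
        assert (s2.n_steps, s2.k_noe, s2.k_hbond) == (24000, 30.0, 60.0)
        assert s2.ramp_from == (1.0, 1.0)
        # cooling 1000 -> 300 K in 25 K decrements of 1000 x 3 fs steps
        assert sched.n_cooling_cycles == (1000 - 300) // 25 == 28
        cool = [s for s in sched.stages if s.name.startswith("cool")]
        assert cool[0].temperature == 975.0
        assert cool[-1].temperature == 300.0
        assert all((c.n_steps, c.timestep_fs) == (1000, 3.0) for c in cool)
        assert sched.final_temperature == 300.0
        assert sched.minimize_steps == 250

    def test_yaml_round_trip(self, tmp_path):
        from noefold.annealing import schedule_from_yaml, schedule_to_yaml
        sched = default_schedule(scale=0.1)
        path = tmp_path / "schedule.yaml"
        schedule_to_yaml(sched, path)
        assert schedule_from_yaml(path) == sched

    def test_desk_scale_shrinks_durations_only(self):
        full = default_schedule()
        desk = default_schedule(scale=0.1)
        assert desk.stages[0].n_steps == full.stages[0].n_steps // 10
        assert [s.temperature for s in desk.stages] == \
            [s.temperature for s in full.stages]
        assert desk.minimize_steps == 250


class TestRunAnnealing:
    def test_zero_schedule_is_identity(self, ground_truth, full_restraints):
        ens = run_annealing(ground_truth, full_restraints, zero_schedule(),
                            n_models=1, seed=0)
        assert np.array_equal(ens.models[0].coords, ground_truth.coords)

    def test_deterministic_given_seed(self, ground_truth, full_restraints):
        sched = default_schedule(scale=0.002)
        ff = ForceField(ground_truth, full_restraints, reference=ground_truth)
        runs = [run_annealing(ground_truth, full_restraints, sched,
                              forcefield=ff, n_models=1, seed=42)
                for _ in range(2)]
        assert np.array_equal(runs[0].models[0].coords,
                              runs[1].models[0].coords)
        assert runs[0].total_energies == runs[1].total_energies

    def test_restraint_energy_descends_from_perturbed_start(
            self, ground_truth, full_restraints):
        # descent property of the full protocol, asserted over 5 seeds
        ff = ForceField(ground_truth, full_restraints, reference=ground_truth)
        rng = np.random.default_rng(7)
        start = ground_truth.with_coords(
            ground_truth.coords + rng.normal(0, 0.3, ground_truth.coords.shape))
        ff.build_neighbor_list(start.coords)
        _, e_start, _ = ff.energy(start.coords, 30.0, 60.0)
        sched = default_schedule(scale=0.005)
        ens = run_annealing(start, full_restraints, sched, forcefield=ff,
                            n_models=5, seed=0)
        assert ens.flags == [""] * 5
        n_down = sum(e <= e_start for e in ens.restraint_energies)
        assert n_down >= 4
        assert np.mean(ens.restraint_energies) < e_start

    def test_thermostat_hits_target_temperature(self, ground_truth):
        rng = np.random.default_rng(0)
        masses = np.full(ground_truth.n_atoms, 12.0)
        v = _draw_velocities(rng, masses, 300.0)
        # Maxwell-Boltzmann draw lands within 5% for ~1000 atoms
        assert _kinetic_temperature(v, masses) == pytest.approx(300.0, rel=0.05)
        # a rescale is exact by construction
        v *= np.sqrt(1000.0 / _kinetic_temperature(v, masses))
        assert _kinetic_temperature(v, masses) == pytest.approx(1000.0, rel=1e-12)


class TestSelectModels:
    @staticmethod
    def _ensemble(viol, energy):
        n = len(viol)
        models = [None] * n  # selection only touches metadata
        return Ensemble(list(models), list(energy), [0.0] * n, list(viol),
                        list(range(n)), [""] * n)

    def test_selects_requested_number(self):
        ens = self._ensemble(list(range(20)), [0.0] * 20)
        assert len(select_models(ens, 10)) == 10

    def test_identical_candidates_tie_break_by_index(self):
        ens = self._ensemble([1] * 12, [5.0] * 12)
        sel = select_models(ens, 10)
        assert sel.seeds == list(range(10))

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        viol = rng.integers(0, 5, 30).tolist()
        energy = rng.normal(0, 100, 30).tolist()
        ens = self._ensemble(viol, energy)
        sel = select_models(ens, 10)
        brute = sorted(range(30), key=lambda i: (viol[i], energy[i], i))[:10]
        assert sel.seeds == brute

    def test_too_few_candidates_raises(self):
        with pytest.raises(AnnealingError):
            select_models(self._ensemble([0] * 3, [0.0] * 3), 10)
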