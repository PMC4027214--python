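"""Restraint calibration, classification, hydrogen bonds and energies."""

import numpy as np
import pytest

from noefold.restraints import (CalibrationModel, DistanceRestraint,
                                RestraintEnergyParams, RestraintError,
                                calibrate, classify, make_hbond_restraints,
                                restraint_energy)
from noefold.synthetic import NoePeak, NoePeakList, simulate_noesy
from noefold.topology import build_duplex


def _peaklist(volumes, topo_pair=("DNA", 5)):
    """Peak list with the cytosine H5-H6 reference plus synthetic peaks."""
    mol, res = topo_pair
    peaks = [NoePeak((mol, res, "H5"), (mol, res, "H6"), 1000.0)]
    for k, v in enumerate(volumes):
        peaks.append(NoePeak(("DNA", 2, "H8"), ("DNA", 3 + k, "H1'"), v))
    return NoePeakList(peaks, 0, cutoff_used=5.5)


class TestCalibration:
    def test_reference_volume_maps_to_reference_distance(self, tff1_topology):
        rs = calibrate(_peaklist([1000.0]), tff1_topology)
        r = rs[0]
        assert r.target == pytest.approx(2.45, abs=1e-12)
        assert r.lower == pytest.approx(1.96, abs=1e-9)
        assert r.upper == pytest.approx(2.94, abs=1e-9)

    def test_sixty_fourfold_weaker_peak_doubles_distance(self, tff1_topology):
        rs = calibrate(_peaklist([1000.0 / 64.0]), tff1_topology)
        assert rs[0].target == pytest.approx(4.90, abs=1e-9)

    def test_distance_monotone_decreasing_in_volume(self, tff1_topology):
        vols = [10.0, 100.0, 1000.0, 1e6]
        rs = calibrate(_peaklist(vols), tff1_topology)
        targets = [r.target for r in rs]
        assert targets == sorted(targets, reverse=True)

    def test_nonpositive_volume_rejected_with_warning(self, tff1_topology):
        with pytest.warns(UserWarning, match="rejected 1"):
            rs = calibrate(_peaklist([100.0, -5.0]), tff1_topology)
        assert len(rs) == 1
        assert rs.n_rejected == 1

    def test_missing_reference_raises(self, tff1_topology):
        peaks = NoePeakList([NoePeak(("DNA", 2, "H8"), ("DNA", 3, "H1'"), 1.0)],
                            -1, 5.5)
        with pytest.raises(RestraintError):
            calibrate(peaks, tff1_topology)

    def test_pseudoatom_correction_inflates_upper_bound(self, tff1_topology):
        peaks = NoePeakList([
            NoePeak(("DNA", 5, "H5"), ("DNA", 5, "H6"), 1000.0),
            NoePeak(("DNA", 4, "Q5M"), ("DNA", 4, "H6"), 1000.0),
        ], 0, 5.5)
        rs = calibrate(peaks, tff1_topology)
        r = rs[0]
        assert r.pseudoatom_correction == 1.0
        assert r.upper == pytest.approx(1.2 * r.target + 1.0, abs=1e-9)

    def test_noise_free_calibration_recovers_true_distances(
            self, noiseless_peaks, complex_spec, ground_truth):
        rs = calibrate(noiseless_peaks, complex_spec.topology)
        errs = [abs(r.target - r.distance(ground_truth)) / r.target
                for r in rs if r.pseudoatom_correction == 0.0]
        assert max(errs) < 1e-10

    def test_noisy_bounds_cover_truth(self, ground_truth, complex_spec):
        # with 10% volume noise >= 95% of true distances fall inside the
        # +-20% flat bounds, checked over 20 seeds
        hits = total = 0
        for seed in range(20):
            pk = simulate_noesy(ground_truth, complex_spec.topology,
                                cutoff=4.0, noise_sd=0.10, seed=seed)
            rs = calibrate(pk, complex_spec.topology)
            for r in rs:
                if r.pseudoatom_correction:
                    continue
                d = r.distance(ground_truth)
                hits += r.lower <= d <= r.upper
                total += 1
        assert hits / total >= 0.95


class TestClassification:
    def test_empty_set_all_zero(self, tff1_topology):
        from noefold.restraints import RestraintSet
        counts = classify(RestraintSet(), tff1_topology)
        assert all(v == 0 for v in counts.values())

    def test_counts_match_independent_classifier(self, full_restraints,
                                                 complex_spec):
        topo = complex_spec.topology
        n = topo.n_pairs
        expected = {"intraresidue": 0, "sequential": 0, "hydrogen_bond": 0,
                    "drug": 0, "drug_dna": 0, "long_range": 0}

        def pair_index(res):
            return res - 1 if res <= n else 2 * n - res

        for r in full_restraints:
            (mi, ri, _), (mj, rj, _) = r.atom_i, r.atom_j
            if r.category == "hydrogen_bond":
                expected["hydrogen_bond"] += 1
            elif mi != "DNA" and mj != "DNA":
                expected["drug"] += 1
            elif (mi == "DNA") != (mj == "DNA"):
                expected["drug_dna"] += 1
            elif ri == rj:
                expected["intraresidue"] += 1
            elif ((ri <= n) == (rj <= n) and abs(ri - rj) == 1) or \
                    ((ri <= n) != (rj <= n) and abs(pair_index(ri) - pair_index(rj)) <= 1):
                expected["sequential"] += 1
            else:
                expected["long_range"] += 1
        assert classify(full_restraints, topo) == expected
        assert sum(expected.values()) == len(full_restraints)


class TestHydrogenBonds:
    def test_two_restraints_per_selected_pair(self, tff1_topology):
        assert len(make_hbond_restraints(tff1_topology, list(range(12)))) == 24
        assert len(make_hbond_restraints(tff1_topology, [])) == 0

    @pytest.mark.parametrize("k", [1, 5, 13])
    def test_count_scales_with_subset(self, tff1_topology, k):
        assert len(make_hbond_restraints(tff1_topology, list(range(k)))) == 2 * k

    def test_targets_match_built_duplex(self, tff1_topology):
        from noefold.geometry import build_bdna
        s = build_bdna(tff1_topology)
        for r in make_hbond_restraints(tff1_topology):
            assert r.distance(s) == pytest.approx(r.target, abs=1e-6)


class TestRestraintEnergy:
    R = DistanceRestraint(("DNA", 1, "H8"), ("DNA", 2, "H8"),
                          3.0, 2.4, 3.6, "sequential")

    def test_zero_inside_bounds(self):
        for d in (2.4, 2.9, 3.0, 3.6):
            assert restraint_energy(d, self.R) == (0.0, 0.0)

    def test_quadratic_above_upper(self):
        e, g = restraint_energy(3.7, self.R,
                                RestraintEnergyParams(k_noe=30.0))
        assert e == pytest.approx(0.30, abs=1e-12)
        assert g == pytest.approx(2 * 30.0 * 0.1, abs=1e-9)

    def test_hydrogen_bond_uses_final_force_constant(self):
        hb = DistanceRestraint(("DNA", 1, "N1"), ("DNA", 30, "N3"),
                               2.9, 2.7, 3.1, "hydrogen_bond")
        e, _ = restraint_energy(3.2, hb, RestraintEnergyParams())
        assert e == pytest.approx(60.0 * 0.1 ** 2, abs=1e-9)

    def test_skew_applies_below_lower_bound(self):
        p = RestraintEnergyParams(k_noe=30.0, skew_lower=2.0)
        e, g = restraint_energy(2.3, self.R, p)
        assert e == pytest.approx(2.0 * 30.0 * 0.1 ** 2, abs=1e-9)
        assert g < 0

    def test_gradient_matches_finite_differences(self):
        h = 1e-7
        for d in (2.2, 2.399, 3.601, 4.5):
            e0, g = restraint_energy(d, self.R)
            e1, _ = restraint_energy(d + h, self.R)
            assert g == pytest.approx((e1 - e0) / h, abs=1e-5)

    def test_continuous_at_bounds(self):
        for b in (2.4, 3.6):
            e_in, g_in = restraint_energy(b, self.R)
            e_out, g_out = restraint_energy(b + 1e-9, self.R)
            assert abs(e_out - e_in) < 1e-12
            assert abs(g_out - g_in) < 1e-6

    def test_invalid_bounds_rejected(self):
        with pytest.raises(RestraintError):
            DistanceRestraint(("DNA", 1, "H8"), ("DNA", 2, "H8"),
                              3.0, 3.5, 2.5, "sequential")

    def test_invalid_calibration_model_rejected(self):
        with pytest.raises(RestraintError):
            CalibrationModel(r_ref=-1.0)
        with pytest.raises(RestraintError):
            CalibrationModel(bound_fraction=1.5)
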