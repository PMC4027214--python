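"""Synthetic-data generators: ground-truth geometry, NOESY volumes and
binding titrations."""

import numpy as np
import pytest

from noefold.analysis import compute_frames, step_parameters, site_unwinding
from noefold.fid import fit_kd, free_ligand
from noefold.synthetic import (GroundTruthSpec, IntercalationSite, SpecError,
                               TitrationSpec, make_ground_truth,
                               tff1_complex_spec, simulate_fid,
                               simulate_noesy, restraint_inventory)
from noefold.restraints import classify
from noefold.topology import build_duplex


class TestGroundTruth:
    def test_refined_geometry_reproduced(self, complex_spec, ground_truth):
        sp = step_parameters(compute_frames(ground_truth, complex_spec.topology))
        targets = {4: 5.95, 6: 6.01, 8: 6.34, 10: 5.86}
        for step, rise in targets.items():
            assert sp[step].rise == pytest.approx(rise, abs=0.05)
        # 3-step site unwinding and the central inter-complex step
        assert site_unwinding(sp, 4, 6) == pytest.approx(32.0, abs=0.5)
        assert site_unwinding(sp, 8, 10) == pytest.approx(28.0, abs=0.5)
        assert sp[7].unwinding == pytest.approx(7.0, abs=0.5)

    def test_empty_site_list_gives_plain_bdna(self, tff1_topology):
        spec = GroundTruthSpec(tff1_topology, ())
        sp = step_parameters(compute_frames(make_ground_truth(spec),
                                            tff1_topology))
        assert np.allclose([p.rise for p in sp], 3.4, atol=1e-6)
        assert np.allclose([p.twist for p in sp], 36.0, atol=1e-6)

    def test_single_site_unwinding_budget(self, tff1_topology):
        spec = GroundTruthSpec(tff1_topology,
                               (IntercalationSite(6, 6.0, 10.0),),
                               neighbor_unwinding=0.0)
        sp = step_parameters(compute_frames(make_ground_truth(spec),
                                            tff1_topology))
        total = sum(p.twist for p in sp)
        assert total == pytest.approx(14 * 36.0 - 10.0, abs=1e-6)

    def test_overlapping_sites_rejected(self, tff1_topology):
        with pytest.raises(SpecError):
            GroundTruthSpec(tff1_topology, (IntercalationSite(6, 6.0, 10.0),
                                            IntercalationSite(6, 5.5, 5.0)))

    def test_gap_rise_outside_band_rejected(self, tff1_topology):
        with pytest.raises(SpecError):
            GroundTruthSpec(tff1_topology, (IntercalationSite(6, 9.0, 0.0),))


class TestNoesy:
    def test_deterministic_given_seed(self, ground_truth, complex_spec):
        a = simulate_noesy(ground_truth, complex_spec.topology, seed=5)
        b = simulate_noesy(ground_truth, complex_spec.topology, seed=5)
        assert [p.volume for p in a.peaks] == [p.volume for p in b.peaks]

    def test_volume_ratio_follows_r6_law(self, noiseless_peaks, ground_truth):
        ref = noiseless_peaks.reference_peak()
        pk = noiseless_peaks.peaks[0]
        r = np.linalg.norm(ground_truth.xyz(*pk.proton_i)
                           - ground_truth.xyz(*pk.proton_j))
        assert pk.volume / ref.volume == pytest.approx((2.45 / r) ** 6, rel=1e-9)

    def test_peak_count_matches_brute_force(self, ground_truth, complex_spec):
        peaks = simulate_noesy(ground_truth, complex_spec.topology,
                               cutoff=4.0, noise_sd=0.0)
        mask = ground_truth.proton_mask()
        idx = np.flatnonzero(mask)
        xyz = ground_truth.coords[idx]
        n_brute = 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if np.linalg.norm(xyz[a] - xyz[b]) <= 4.0:
                    n_brute += 1
        # reference peak is emitted even when H5-H6 exceeds the cutoff;
        # here 2.45 < 4.0 so counts agree exactly
        assert len(peaks.peaks) == n_brute

    def test_no_cytosine_raises(self):
        topo = build_duplex("ATAT")
        from noefold.geometry import build_bdna
        with pytest.raises(SpecError):
            simulate_noesy(build_bdna(topo), topo)


class TestFidSimulation:
    def test_zero_drug_gives_zero_fraction(self):
        t = simulate_fid(TitrationSpec(noise_sd=0.0))
        first = [f for x, _r, f in t.rows if x == 0.0]
        assert all(f == 0.0 for f in first)

    def test_half_saturation_at_kd(self):
        spec = TitrationSpec(noise_sd=0.0)
        x_free = spec.true_kd
        # choose a total that makes free drug equal K_D, then fraction = B/2
        x_total = x_free + 2 * spec.duplex_total * spec.amplitude_b * \
            x_free / (spec.true_kd + x_free)
        assert free_ligand(x_total, spec.duplex_total, spec.true_kd,
                           spec.amplitude_b) == pytest.approx(x_free, rel=1e-9)

    def test_noise_free_round_trip_recovers_kd(self):
        t = simulate_fid(TitrationSpec(noise_sd=0.0))
        fit = fit_kd(t)
        assert fit.kd == pytest.approx(9.65e-7, rel=1e-6)
        assert fit.b == pytest.approx(1.0, rel=1e-6)


class TestInventory:
    def test_reproduces_published_category_counts(self, tff1_topology):
        inv = restraint_inventory(tff1_topology)
        counts = classify(inv, tff1_topology)
        assert counts["intraresidue"] == 357
        assert counts["sequential"] == 153
        assert counts["hydrogen_bond"] == 24
        assert counts["drug"] == 79
        assert counts["drug_dna"] == 56
        assert len(inv) == 669
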