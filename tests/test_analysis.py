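"""Helical-frame analysis, superposition and ensemble statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from noefold.analysis import (AnalysisError, compute_frames, ensemble_stats,
                              kabsch, site_unwinding, step_parameters,
                              superpose_rmsd, StepParameters)
from noefold.geometry import build_bdna
from noefold.structure import Structure
from noefold.topology import build_duplex


def _random_structure(rng, n=20):
    return Structure(["DNA"] * n, list(range(1, n + 1)),
                     [f"C{i}" for i in range(n)], ["C"] * n,
                     rng.normal(0, 5, (n, 3)))


class TestFrames:
    def test_one_frame_per_pair(self, tff1_topology):
        s = build_bdna(tff1_topology)
        assert len(compute_frames(s, tff1_topology)) == 15

    def test_first_frame_axes_canonical(self, tff1_topology):
        # the builder works in the standard frame: pair 1 sits at the
        # origin with z along the helix axis
        f = compute_frames(build_bdna(tff1_topology), tff1_topology)[0]
        assert np.allclose(f.z, [0, 0, 1], atol=1e-9)
        assert np.allclose(f.origin, 0.0, atol=1e-9)

    def test_parameters_invariant_under_rigid_motion(self, tff1_topology):
        s = build_bdna(tff1_topology)
        R = Rotation.from_rotvec([0.4, -0.9, 1.3]).as_matrix()
        s2 = s.transformed(R, np.array([10.0, -4.0, 2.5]))
        sp1 = step_parameters(compute_frames(s, tff1_topology))
        sp2 = step_parameters(compute_frames(s2, tff1_topology))
        for a, b in zip(sp1, sp2):
            assert a.twist == pytest.approx(b.twist, abs=1e-8)
            assert a.rise == pytest.approx(b.rise, abs=1e-8)

    def test_missing_base_atoms_reported(self, tff1_topology):
        s = build_bdna(tff1_topology)
        keep = [i for i, (m, r, n) in enumerate(zip(s.mols, s.resnums, s.names))
                if not (r == 3 and n == "N1")]
        s2 = Structure([s.mols[i] for i in keep], [s.resnums[i] for i in keep],
                       [s.names[i] for i in keep], [s.elements[i] for i in keep],
                       s.coords[keep])
        with pytest.raises(AnalysisError):
            compute_frames(s2, tff1_topology)


class TestStepParameters:
    def test_needs_two_frames(self, tff1_topology):
        s = build_bdna(tff1_topology)
        with pytest.raises(AnalysisError):
            step_parameters(compute_frames(s, tff1_topology)[:1])

    def test_unwinding_arithmetic(self):
        steps = [StepParameters(i, 3.4, t) for i, t in enumerate([30, 30, 36])]
        assert site_unwinding(steps, 0, 2) == pytest.approx(12.0)

    def test_uniform_duplex_has_zero_unwinding(self, tff1_topology):
        sp = step_parameters(compute_frames(build_bdna(tff1_topology),
                                            tff1_topology))
        assert site_unwinding(sp, 0, 13) == pytest.approx(0.0, abs=1e-9)

    def test_empty_site_range_rejected(self):
        steps = [StepParameters(0, 3.4, 36.0)]
        with pytest.raises(AnalysisError):
            site_unwinding(steps, 5, 7)


class TestSuperposition:
    def test_self_rmsd_zero(self, rng):
        s = _random_structure(rng)
        assert superpose_rmsd(s, s, np.ones(s.n_atoms, bool)) == pytest.approx(0.0)

    def test_rigid_copy_rmsd_zero(self, rng):
        s = _random_structure(rng)
        R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        s2 = s.transformed(R, np.array([3.0, 1.0, -7.0]))
        assert superpose_rmsd(s, s2, np.ones(s.n_atoms, bool)) < 1e-8

    def test_single_displaced_atom_bound(self, rng):
        s = _random_structure(rng, n=25)
        c2 = s.coords.copy()
        c2[0] += np.array([1.0, 0.0, 0.0])
        s2 = s.with_coords(c2)
        r = superpose_rmsd(s, s2, np.ones(s.n_atoms, bool))
        assert 0.0 < r <= 1.0 / np.sqrt(25) + 1e-9

    def test_too_few_atoms_rejected(self, rng):
        s = _random_structure(rng, n=5)
        mask = np.zeros(5, bool)
        mask[:2] = True
        with pytest.raises(AnalysisError):
            superpose_rmsd(s, s, mask)

    def test_kabsch_matches_scipy_oracle(self, rng):
        # dual route: own SVD Kabsch vs scipy's quaternion align_vectors
        for _ in range(20):
            P = rng.normal(0, 3, (12, 3))
            R_true = Rotation.random(random_state=rng).as_matrix()
            Q = P @ R_true.T + rng.normal(0, 0.1, (12, 3)) + [4.0, -2.0, 9.0]
            R, t, rmsd = kabsch(P, Q)
            rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
            assert rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-8)
            assert np.allclose(R, rot.as_matrix(), atol=1e-6)


class TestEnsembleStats:
    def test_identical_models_zero_spread(self, ground_truth, full_restraints):
        models = [ground_truth, ground_truth.with_coords(ground_truth.coords, 2)]
        st = ensemble_stats(models, full_restraints)
        assert st.mean_pairwise_rmsd == pytest.approx(0.0)

    def test_satisfied_restraints_zero_violations(self, ground_truth,
                                                  full_restraints):
        st = ensemble_stats([ground_truth], full_restraints)
        assert st.violations_per_model == [0]
        assert st.violation_rmsd == 0.0

    def test_pairwise_rmsd_matches_brute_force(self, rng):
        models = [_random_structure(rng) for _ in range(3)]
        base = models[0]
        models = [base] + [base.with_coords(
            base.coords + rng.normal(0, 0.5, base.coords.shape), i + 2)
            for i in range(2)]
        st = ensemble_stats(models, None, heavy_mask=np.ones(base.n_atoms, bool))
        brute = []
        for i in range(3):
            for j in range(i + 1, 3):
                brute.append(kabsch(models[i].coords, models[j].coords)[2])
        assert st.mean_pairwise_rmsd == pytest.approx(np.mean(brute), abs=1e-10)

    def test_mismatched_models_rejected(self, rng, ground_truth):
        with pytest.raises(AnalysisError):
            ensemble_stats([ground_truth, _random_structure(rng)])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(AnalysisError):
            ensemble_stats([])
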