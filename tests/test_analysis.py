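"""Free-energy profiles, TSE extraction, phi-values and contact maps."""

import numpy as np
import pytest

from frustfold import (
    ContactMapMatrix,
    TransitionStateEnsemble,
    contact_difference_map,
    extract_tse,
    free_energy_profile,
    generic_contact_map,
    phi_values,
    delta_phi,
    tse_contact_map,
)
from frustfold.fixtures import make_labeled_trajectory
from frustfold.vtf import FoldingHistogram, build_histogram, contact_count_bins


def native_tse(topo, n=3):
    frames = np.repeat(topo.ca0[None], n, axis=0)
    return TransitionStateEnsemble(0.3, 0.7, np.arange(n), frames)


class TestFreeEnergyProfile:
    def test_uniform_two_bins_no_difference(self):
        q = np.concatenate([np.full(100, 0.25), np.full(100, 0.75)])
        _, F = free_energy_profile(q, 0.4, bins=2)
        assert F[0] == pytest.approx(F[1], abs=1e-12)

    def test_two_to_one_ratio_gives_t_ln2(self):
        q = np.concatenate([np.full(200, 0.25), np.full(100, 0.75)])
        _, F = free_energy_profile(q, 0.4, bins=2)
        assert F[1] - F[0] == pytest.approx(0.4 * np.log(2), rel=1e-9)

    def test_empty_bins_are_nan_not_zero(self):
        _, F = free_energy_profile(np.full(50, 0.05), 0.4, bins=10)
        assert np.isfinite(F[0])
        assert np.isnan(F[5:]).all()

    def test_differences_invariant_to_sample_size(self):
        q = np.concatenate([np.full(20, 0.25), np.full(10, 0.75)])
        _, f1 = free_energy_profile(q, 0.4, bins=2)
        _, f3 = free_energy_profile(np.tile(q, 5), 0.4, bins=2)
        assert f1[1] - f1[0] == pytest.approx(f3[1] - f3[0], abs=1e-12)

    def test_barrier_between_generator_modes(self, rng):
        q = np.concatenate([
            np.clip(rng.normal(0.2, 0.05, 5000), 0, 1),
            np.clip(rng.normal(0.85, 0.05, 5000), 0, 1)])
        centers, F = free_energy_profile(q, 0.4, bins=20)
        inner = (centers > 0.3) & (centers < 0.75) & np.isfinite(F)
        barrier = centers[inner][np.nanargmax(F[inner])]
        assert 0.3 < barrier < 0.75

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            free_energy_profile([], 0.4)
        with pytest.raises(ValueError):
            free_energy_profile([0.5], 0.0)


class TestExtractTse:
    def test_window_midpoint_arithmetic(self, hairpin_topology):
        hist = FoldingHistogram(
            np.linspace(0, 1, 11), np.zeros(10), True,
            unfolded_peak_Q=0.2, folded_peak_Q=0.9, valley_Q=0.5,
            unfolded_height=1.0, folded_height=1.0)
        traj, _ = make_labeled_trajectory(hairpin_topology, 0.5, 50, seed=0)
        tse = extract_tse(hist, traj)
        assert tse.Q1 == pytest.approx(0.35)
        assert tse.Q2 == pytest.approx(0.7)

    def test_members_equal_direct_filter(self, hairpin_topology):
        traj, _ = make_labeled_trajectory(hairpin_topology, 0.5, 400, seed=3)
        hist = build_histogram(traj.q,
                               contact_count_bins(hairpin_topology.n_contacts))
        tse = extract_tse(hist, traj)
        expected = np.where((traj.q > tse.Q1) & (traj.q < tse.Q2))[0]
        np.testing.assert_array_equal(tse.frame_indices, expected)

    def test_unimodal_histogram_rejected(self, hairpin_topology):
        hist = FoldingHistogram(np.linspace(0, 1, 11), np.zeros(10),
                                False, mode_Q=0.8)
        traj, _ = make_labeled_trajectory(hairpin_topology, 1.0, 10, seed=0)
        with pytest.raises(ValueError, match="unimodal"):
            extract_tse(hist, traj)

    def test_empty_window_warns(self, hairpin_topology):
        # the labeled trajectory has Q ~ 0 or ~1 only; a narrow mid window
        # catches nothing
        hist = FoldingHistogram(
            np.linspace(0, 1, 11), np.zeros(10), True,
            unfolded_peak_Q=0.45, folded_peak_Q=0.55, valley_Q=0.5,
            unfolded_height=1.0, folded_height=1.0)
        traj, _ = make_labeled_trajectory(hairpin_topology, 0.5, 50, seed=0)
        with pytest.warns(UserWarning, match="empty"):
            tse = extract_tse(hist, traj)
        assert tse.n_members == 0


class TestPhiValues:
    def test_native_only_tse_gives_phi_one(self, hairpin_topology):
        prof = phi_values(native_tse(hairpin_topology), hairpin_topology)
        defined = prof.native_counts > 0
        np.testing.assert_allclose(prof.phi[defined], 1.0)
        assert np.isnan(prof.phi[~defined]).all()

    def test_fully_extended_tse_gives_phi_zero(self, hairpin_topology):
        t = hairpin_topology
        frames = np.repeat((3.0 * t.ca0)[None], 2, axis=0)
        tse = TransitionStateEnsemble(0.3, 0.7, np.arange(2), frames)
        prof = phi_values(tse, t)
        defined = prof.native_counts > 0
        np.testing.assert_allclose(prof.phi[defined], 0.0)

    def test_half_native_two_frame_hand_count(self, hairpin_topology):
        # one native frame (all contacts held) + one expanded frame
        # (none held): every defined phi must be exactly 1/2
        t = hairpin_topology
        frames = np.stack([t.ca0, 3.0 * t.ca0])
        tse = TransitionStateEnsemble(0.3, 0.7, np.arange(2), frames)
        prof = phi_values(tse, t)
        defined = prof.native_counts > 0
        np.testing.assert_allclose(prof.phi[defined], 0.5)

    def test_phi_monotone_under_contact_loss(self, hairpin_topology, rng):
        # removing held contacts from TSE frames can only lower phi
        t = hairpin_topology
        mixed = np.stack([t.ca0, t.ca0, 3.0 * t.ca0])
        fewer = np.stack([t.ca0, 3.0 * t.ca0, 3.0 * t.ca0])
        tse_hi = TransitionStateEnsemble(0.3, 0.7, np.arange(3), mixed)
        tse_lo = TransitionStateEnsemble(0.3, 0.7, np.arange(3), fewer)
        hi = phi_values(tse_hi, t).phi
        lo = phi_values(tse_lo, t).phi
        defined = ~np.isnan(hi)
        assert np.all(lo[defined] <= hi[defined] + 1e-12)

    def test_empty_tse_rejected(self, hairpin_topology):
        t = hairpin_topology
        tse = TransitionStateEnsemble(0.3, 0.7, np.zeros(0, int),
                                      np.zeros((0, t.n_residues, 3)))
        with pytest.raises(ValueError, match="empty"):
            phi_values(tse, t)


class TestDeltaPhi:
    def test_identical_profiles_are_zero(self, hairpin_topology):
        a = phi_values(native_tse(hairpin_topology), hairpin_topology)
        d, means = delta_phi(a, a, {"B1": [(1, 6)]})
        defined = ~np.isnan(d)
        np.testing.assert_allclose(d[defined], 0.0)
        assert means["B1"] == pytest.approx(0.0)

    def test_element_average_hand_computed(self, hairpin_topology):
        from frustfold.analysis import PhiProfile
        t = hairpin_topology
        counts = phi_values(native_tse(t), t).native_counts
        phi_a = np.where(counts > 0, 0.8, np.nan)
        phi_b = np.where(counts > 0, 0.5, np.nan)
        a = PhiProfile(phi_a, counts, phi_a * counts)
        b = PhiProfile(phi_b, counts, phi_b * counts)
        d, means = delta_phi(a, b, {"B1": [(1, 5)], "turnB": [(6, 7), (8, 12)]})
        defined = ~np.isnan(d)
        np.testing.assert_allclose(d[defined], 0.3)
        assert means["B1"] == pytest.approx(0.3)

    def test_mismatched_topologies_rejected(self, hairpin_topology, toy_topology):
        a = phi_values(native_tse(hairpin_topology), hairpin_topology)
        b = phi_values(native_tse(toy_topology), toy_topology)
        with pytest.raises(ValueError):
            delta_phi(a, b)


class TestContactMaps:
    def test_distant_pair_excluded(self):
        frame = np.array([[0.0, 0, 0], [20.0, 0, 0], [3, 4, 0], [9, 9, 3]])
        m = generic_contact_map(frame, 10.0)
        assert m.matrix[0, 1] == 0.0
        assert m.matrix[0, 2] == 1.0

    def test_symmetric_zero_diagonal(self, toy_topology):
        m = generic_contact_map(toy_topology.ca0, 10.0)
        assert np.array_equal(m.matrix, m.matrix.T)
        assert np.all(np.diag(m.matrix) == 0)

    def test_helix_like_geometry_near_diagonal_band(self):
        # ideal helix: ~5.4 A pitch, 3.6 residues/turn -> i, i+3/i+4 close
        k = np.arange(20)
        frame = np.column_stack([
            2.3 * np.cos(2 * np.pi * k / 3.6),
            2.3 * np.sin(2 * np.pi * k / 3.6),
            1.5 * k])
        m = generic_contact_map(frame, 7.0).matrix
        band = [m[i, i + 3] for i in range(16)]
        far = [m[i, i + 9] for i in range(10)]
        assert np.mean(band) > 0.9
        assert np.mean(far) < 0.1

    def test_cutoff_outside_customary_range_warns(self, toy_topology):
        with pytest.warns(UserWarning, match="7-15"):
            generic_contact_map(toy_topology.ca0, 5.0)

    def test_native_tse_map_is_indicator_of_native_pairs(self, hairpin_topology):
        t = hairpin_topology
        m = tse_contact_map(native_tse(t), t).matrix
        assert np.all(m[t.contact_i, t.contact_j] == 1.0)
        assert m.sum() == 2 * t.n_contacts      # symmetric, nothing else set

    def test_two_frame_fractions_exact(self, hairpin_topology):
        t = hairpin_topology
        frames = np.stack([t.ca0, 3.0 * t.ca0])
        tse = TransitionStateEnsemble(0.3, 0.7, np.arange(2), frames)
        m = tse_contact_map(tse, t).matrix
        np.testing.assert_allclose(m[t.contact_i, t.contact_j], 0.5)

    def test_row_marginals_reproduce_phi_numerator(self, hairpin_topology, rng):
        t = hairpin_topology
        frames = t.ca0 + 0.6 * rng.standard_normal((20,) + t.ca0.shape)
        tse = TransitionStateEnsemble(0.3, 0.7, np.arange(20), frames)
        m = tse_contact_map(tse, t).matrix
        prof = phi_values(tse, t)
        np.testing.assert_allclose(m.sum(axis=1), prof.tse_mean_counts,
                                   atol=1e-12)

    def test_difference_map_identity_and_planted_patch(self, hairpin_topology):
        t = hairpin_topology
        base = tse_contact_map(native_tse(t), t)
        assert np.all(contact_difference_map(base, base).matrix == 0)
        planted = ContactMapMatrix(np.clip(base.matrix - 0.4, 0, 1),
                                   "native-contact-ensemble")
        diff = contact_difference_map(base, planted).matrix
        on = base.matrix > 0.5
        assert np.allclose(diff[on], 0.4)
        assert np.allclose(diff[~on], 0.0)
        assert diff.min() >= -1 and diff.max() <= 1

    def test_split_triangle_layout(self, hairpin_topology):
        t = hairpin_topology
        a = tse_contact_map(native_tse(t), t)
        b = ContactMapMatrix(0.5 * a.matrix, a.kind)
        s = a.split_triangle(b)
        iu = np.triu_indices(t.n_residues, 1)
        il = np.tril_indices(t.n_residues, -1)
        np.testing.assert_allclose(s[iu], a.matrix[iu])
        np.testing.assert_allclose(s[il], b.matrix[il])

    def test_shape_mismatch_rejected(self, hairpin_topology):
        a = tse_contact_map(native_tse(hairpin_topology), hairpin_topology)
        b = ContactMapMatrix(np.zeros((5, 5)), "difference")
        with pytest.raises(ValueError):
            contact_difference_map(a, b)
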