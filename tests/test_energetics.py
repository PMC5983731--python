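"""Potential-energy terms and analytic forces.

The reference oracle here is a deliberately naive pure-python evaluation
of the potential, written independently of the compiled kernels (its
dihedral uses the two-plane-normal construction rather than the atan2
form used by the production code).
"""

import math

import numpy as np
import pytest

from frustfold import (
    ModelParams,
    System,
    bonded_energy,
    native_contact_energy,
    nonnative_energy,
    total_energy_and_forces,
)
from frustfold.energetics import nonnative_pairs
from frustfold.topology import (
    NativeTopology,
    bond_angles,
    bond_lengths,
    dihedral_angles,
)


# ---------------------------------------------------------------------------
# independent scalar oracle
# ---------------------------------------------------------------------------

def scalar_energy(pos, topo, p: ModelParams):
    """Term-by-term evaluation with plain python floats."""
    n = len(pos)
    u = 0.0
    for k in range(n - 1):
        r = math.dist(pos[k], pos[k + 1])
        u += 0.5 * p.K_b * (r - topo.bond_r0[k]) ** 2
    for k in range(n - 2):
        a, b, c = pos[k], pos[k + 1], pos[k + 2]
        v1 = a - b
        v2 = c - b
        th = math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        u += 0.5 * p.K_theta * (th - topo.theta0[k]) ** 2
    for k in range(n - 3):
        b1 = pos[k + 1] - pos[k]
        b2 = pos[k + 2] - pos[k + 1]
        b3 = pos[k + 3] - pos[k + 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        cosphi = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        phi = math.acos(max(-1.0, min(1.0, cosphi)))
        if np.dot(np.cross(n1, n2), b2) < 0:
            phi = -phi
        if p.dihedral_form == "native_centered":
            d = phi - topo.phi0[k]
            u += p.K_phi * ((1 - math.cos(d)) + 0.5 * (1 - math.cos(3 * d)))
        else:
            u += 0.5 * p.K_phi * (1 - math.cos(2 * phi - math.pi / 2)) ** 2
    for i, j, r0, eps in zip(topo.contact_i, topo.contact_j,
                             topo.contact_r0, topo.contact_eps):
        q = r0 / math.dist(pos[i], pos[j])
        u += eps * (5 * q ** 12 - 6 * q ** 10)
    nn_i, nn_j, hh = nonnative_pairs(topo)
    for i, j, is_hh in zip(nn_i, nn_j, hh):
        r = math.dist(pos[i], pos[j])
        if p.model_flavor == "frustrated" and is_hh:
            q = p.C_f / r
            u += p.sigma * p.eps_bar * (5 * q ** 12 - 6 * q ** 10)
            if p.frustration_additive:
                u += p.eps_bar * (p.C / r) ** 12
        else:
            u += p.eps_bar * (p.C / r) ** 12
    return u


def five_bead_pair_topology(r: float, sequence: str = "AGGGA"):
    """Five beads whose only sequence-separated pair (0, 4) sits at
    distance ``r`` with no native contact (Calpha-only heavy atoms put
    the pair exactly at the cutoff boundary only when r >= cutoff)."""
    ca = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 3.0, 0.5],
        [r / 2, 4.2, -0.5],
        [r - 1.0, 3.0, 0.5],
        [r, 0.0, 0.0],
    ])
    return NativeTopology(
        sequence, ca, bond_lengths(ca), bond_angles(ca), dihedral_angles(ca),
        np.zeros(0, int), np.zeros(0, int), np.zeros(0), np.zeros(0),
        np.array([aa in set("AVLIMFWYC") for aa in sequence]))


class TestBondedEnergy:
    def test_zero_at_native_frame(self, hairpin_topology):
        assert bonded_energy(hairpin_topology.ca0, hairpin_topology) == \
            pytest.approx(0.0, abs=1e-12)

    def test_single_bond_stretch_costs_kb_over_two(self, hairpin_topology):
        t = hairpin_topology
        pos = t.ca0.copy()
        # move the last bead 0.1 A outward along the final bond: only the
        # final bond length changes among the bonded terms
        u = pos[-1] - pos[-2]
        pos[-1] += 0.1 * u / np.linalg.norm(u)
        assert bonded_energy(pos, t) == pytest.approx(200.0 / 2 * 0.01, rel=1e-9)

    def test_matches_scalar_oracle_on_perturbed_frames(self, toy_topology, rng):
        t = toy_topology
        p = ModelParams()
        for _ in range(5):
            pos = t.ca0 + 0.2 * rng.standard_normal(t.ca0.shape)
            terms = System(t, p).energy_terms(pos)
            bonded = terms["bond"] + terms["angle"] + terms["dihedral"]
            # oracle minus its own pair terms
            pair_only = ModelParams(K_b=1e-300, K_theta=1e-300, K_phi=1e-300)
            expected = scalar_energy(pos, t, p) - scalar_energy(pos, t, pair_only)
            assert bonded == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_as_printed_dihedral_is_not_native_centered(self, hairpin_topology):
        p = ModelParams(dihedral_form="as_printed")
        u = bonded_energy(hairpin_topology.ca0, hairpin_topology, p)
        assert u > 0.01     # the printed form does not vanish at the native state


class TestNativeContactEnergy:
    def test_native_frame_is_minus_sum_of_couplings(self, hairpin_topology):
        t = hairpin_topology
        assert native_contact_energy(t.ca0, t) == \
            pytest.approx(-t.contact_eps.sum(), abs=1e-12)

    def test_large_expansion_tends_to_zero(self, hairpin_topology):
        t = hairpin_topology
        assert abs(native_contact_energy(t.ca0 * 100.0, t)) < 1e-8

    def test_held_pair_at_1p2_r0(self, hairpin_topology):
        t = hairpin_topology
        # uniform scaling puts every pair at exactly 1.2 r0
        expected = t.contact_eps.sum() * (5 * 1.2 ** -12 - 6 * 1.2 ** -10)
        assert native_contact_energy(t.ca0 * 1.2, t) == \
            pytest.approx(expected, rel=1e-12)


class TestNonnativeEnergy:
    def test_frustrated_well_minimum_at_cf(self):
        topo = five_bead_pair_topology(5.5, "AGGGA")
        p = ModelParams(model_flavor="frustrated")
        assert nonnative_energy(topo.ca0, topo, p) == \
            pytest.approx(-p.sigma * p.eps_bar, rel=1e-12)

    def test_non_hydrophobic_partner_keeps_pure_repulsion(self):
        topo = five_bead_pair_topology(5.5, "TGGGA")     # Thr kills sigma_ij
        p = ModelParams(model_flavor="frustrated")
        minimal = ModelParams(model_flavor="minimal")
        assert nonnative_energy(topo.ca0, topo, p) == \
            pytest.approx(nonnative_energy(topo.ca0, topo, minimal), rel=1e-14)

    def test_minimal_repulsion_is_eps_bar_at_c(self):
        topo = five_bead_pair_topology(4.0, "AGGGA")
        p = ModelParams(model_flavor="minimal")
        assert nonnative_energy(topo.ca0, topo, p) == \
            pytest.approx(p.eps_bar, rel=1e-12)

    @pytest.mark.parametrize("r", [5.1, 5.5, 6.5, 8.0])
    def test_frustration_lowers_energy_in_attractive_region(self, r):
        # for r > C_f * sqrt(5/6) ~ 5.02 A the 12-10 well is attractive,
        # so the frustrated model must lie below the minimal repulsion
        topo = five_bead_pair_topology(r, "AGGGA")
        u_f = nonnative_energy(topo.ca0, topo, ModelParams(model_flavor="frustrated"))
        u_m = nonnative_energy(topo.ca0, topo, ModelParams(model_flavor="minimal"))
        assert u_f < u_m

    def test_additive_mode_adds_repulsion(self):
        topo = five_bead_pair_topology(5.5, "AGGGA")
        p_add = ModelParams(model_flavor="frustrated", frustration_additive=True)
        p_rep = ModelParams(model_flavor="minimal")
        expected = -p_add.sigma * p_add.eps_bar \
            + nonnative_energy(topo.ca0, topo, p_rep)
        assert nonnative_energy(topo.ca0, topo, p_add) == \
            pytest.approx(expected, rel=1e-12)


class TestTotalEnergyAndForces:
    def test_total_matches_scalar_oracle(self, toy_topology, rng):
        t = toy_topology
        for flavor in ("minimal", "frustrated"):
            p = ModelParams(model_flavor=flavor)
            pos = t.ca0 + 0.25 * rng.standard_normal(t.ca0.shape)
            u, _ = total_energy_and_forces(pos, t, p)
            assert u == pytest.approx(scalar_energy(pos, t, p), rel=1e-10)

    def test_rigid_motion_invariance(self, toy_topology, rng):
        from scipy.spatial.transform import Rotation
        t = toy_topology
        p = ModelParams(model_flavor="frustrated")
        pos = t.ca0 + 0.2 * rng.standard_normal(t.ca0.shape)
        u0, f0 = total_energy_and_forces(pos, t, p)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-20, 20, 3)
        u1, f1 = total_energy_and_forces(pos @ rot.T + shift, t, p)
        assert abs(u1 - u0) < 1e-9
        np.testing.assert_allclose(f1, f0 @ rot.T, atol=1e-9)
        # net force vanishes (translation invariance)
        np.testing.assert_allclose(f1.sum(axis=0), 0.0, atol=1e-9)

    def test_sigma_zero_reproduces_minimal_bitwise(self, toy_topology, rng):
        t = toy_topology
        p_min = ModelParams(model_flavor="minimal")
        p_f0 = ModelParams(model_flavor="frustrated", sigma=0.0)
        for _ in range(10):
            pos = t.ca0 + 0.5 * rng.standard_normal(t.ca0.shape)
            um, fm = total_energy_and_forces(pos, t, p_min)
            uf, ff = total_energy_and_forces(pos, t, p_f0)
            assert um == uf
            assert np.array_equal(fm, ff)

    def test_coincident_beads_rejected(self, toy_topology):
        pos = toy_topology.ca0.copy()
        pos[7] = pos[2]
        with pytest.raises(ValueError, match="coincident|zero"):
            total_energy_and_forces(pos, toy_topology)

    def test_collinear_triplet_rejected(self, toy_topology):
        pos = toy_topology.ca0.copy()
        pos[1] = 0.5 * (pos[0] + pos[2])    # exact midpoint: angle undefined
        with pytest.raises(ValueError, match="collinear"):
            total_energy_and_forces(pos, toy_topology)
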