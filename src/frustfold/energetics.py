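"""Potential energy and analytic forces of the coarse-grained model.

The minimal (structure-based) potential is

    U = sum Kb/2 (r - r0)^2                       bonds
      + sum Kth/2 (th - th0)^2                    angles
      + dihedral term (see below)
      + sum_NC  eps_ij [5 (r0/r)^12 - 6 (r0/r)^10]    native 12-10 wells
      + sum_NNC eps_bar (C/r)^12                      nonnative repulsion

with native contacts (NC) the pairs j - i >= 4 in contact in the native
structure and nonnative pairs (NNC) all remaining j - i >= 4 pairs.  The
frustrated variant replaces the repulsion of hydrophobic-hydrophobic NNC
pairs by an attractive 12-10 well of depth sigma * eps_bar centred at C_f
(optionally it is added on top of the repulsion instead).

Two dihedral forms are available.  ``native_centered`` (default) is the
standard structure-based form K_phi[(1 - cos(phi - phi0)) +
1/2 (1 - cos 3(phi - phi0))], which vanishes at the native state as the
model construction requires.  ``as_printed`` is the native-independent
form K_phi/2 (1 - cos(2 phi - pi/2))^2 kept for fidelity experiments.

All energies are in eps0 units, lengths in angstrom, forces in eps0/A.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParams
from .topology import NativeTopology

__all__ = [
    "System",
    "nonnative_pairs",
    "bonded_energy",
    "native_contact_energy",
    "nonnative_energy",
    "total_energy_and_forces",
]

_DIH_NATIVE = 0
_DIH_PRINTED = 1


def _positions(frame) -> np.ndarray:
    """Accept a bare (N, 3) array or any object with a ``positions`` field."""
    pos = getattr(frame, "positions", frame)
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("frame positions must be an (N, 3) array")
    if not np.all(np.isfinite(pos)):
        raise ValueError("frame contains non-finite coordinates")
    return pos


def nonnative_pairs(topology: NativeTopology):
    """All pairs with j - i >= 4 that are not native contacts.

    Returns ``(i, j, hh)`` with ``hh`` True when both residues are
    hydrophobic (the pairs eligible for the frustration well).
    """
    n = topology.n_residues
    iu, ju = np.triu_indices(n, k=4)
    native = set(zip(topology.contact_i.tolist(), topology.contact_j.tolist()))
    keep = np.array([(a, b) not in native for a, b in zip(iu, ju)], dtype=bool) \
        if len(iu) else np.zeros(0, dtype=bool)
    i, j = iu[keep], ju[keep]
    hh = topology.hydrophobic[i] & topology.hydrophobic[j]
    return i.astype(np.int64), j.astype(np.int64), hh


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _energy_forces(pos, bond_r0, K_b, theta0, K_theta, phi0, K_phi, dih_form,
                   nc_i, nc_j, nc_r0, nc_eps,
                   nn_i, nn_j, nn_well, eps_bar, C, C_f,
                   frustrated, additive):
    """Returns (U_bond, U_angle, U_dih, U_nc, U_nn, F, status).

    status: 0 ok, 1 collinear angle triplet, 2 coincident pair.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    u_bond = 0.0
    u_angle = 0.0
    u_dih = 0.0
    u_nc = 0.0
    u_nn = 0.0
    status = 0

    # bonds
    for k in range(n - 1):
        dx = pos[k + 1, 0] - pos[k, 0]
        dy = pos[k + 1, 1] - pos[k, 1]
        dz = pos[k + 1, 2] - pos[k, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= 0.0:
            return u_bond, u_angle, u_dih, u_nc, u_nn, F, 2
        dr = r - bond_r0[k]
        u_bond += 0.5 * K_b * dr * dr
        g = K_b * dr / r
        F[k, 0] += g * dx
        F[k, 1] += g * dy
        F[k, 2] += g * dz
        F[k + 1, 0] -= g * dx
        F[k + 1, 1] -= g * dy
        F[k + 1, 2] -= g * dz

    # angles (centre bead k + 1)
    for k in range(n - 2):
        ux = pos[k, 0] - pos[k + 1, 0]
        uy = pos[k, 1] - pos[k + 1, 1]
        uz = pos[k, 2] - pos[k + 1, 2]
        vx = pos[k + 2, 0] - pos[k + 1, 0]
        vy = pos[k + 2, 1] - pos[k + 1, 1]
        vz = pos[k + 2, 2] - pos[k + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu <= 0.0 or nv <= 0.0:
            return u_bond, u_angle, u_dih, u_nc, u_nn, F, 2
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s = np.sqrt(1.0 - c * c)
        if s < 1.0e-10:
            return u_bond, u_angle, u_dih, u_nc, u_nn, F, 1
        theta = np.arccos(c)
        dth = theta - theta0[k]
        u_angle += 0.5 * K_theta * dth * dth
        dudth = K_theta * dth
        # d(theta)/d(r_end) = (c * e_hat - other_hat) / (|e| * s)
        cfu = dudth / (nu * s)
        cfv = dudth / (nv * s)
        fax = -cfu * (c * ux / nu - vx / nv)
        fay = -cfu * (c * uy / nu - vy / nv)
        faz = -cfu * (c * uz / nu - vz / nv)
        fcx = -cfv * (c * vx / nv - ux / nu)
        fcy = -cfv * (c * vy / nv - uy / nu)
        fcz = -cfv * (c * vz / nv - uz / nu)
        F[k, 0] += fax
        F[k, 1] += fay
        F[k, 2] += faz
        F[k + 2, 0] += fcx
        F[k + 2, 1] += fcy
        F[k + 2, 2] += fcz
        F[k + 1, 0] -= fax + fcx
        F[k + 1, 1] -= fay + fcy
        F[k + 1, 2] -= faz + fcz

    # dihedrals over beads k..k+3
    for k in range(n - 3):
        b1x = pos[k + 1, 0] - pos[k, 0]
        b1y = pos[k + 1, 1] - pos[k, 1]
        b1z = pos[k + 1, 2] - pos[k, 2]
        b2x = pos[k + 2, 0] - pos[k + 1, 0]
        b2y = pos[k + 2, 1] - pos[k + 1, 1]
        b2z = pos[k + 2, 2] - pos[k + 1, 2]
        b3x = pos[k + 3, 0] - pos[k + 2, 0]
        b3y = pos[k + 3, 1] - pos[k + 2, 1]
        b3z = pos[k + 3, 2] - pos[k + 2, 2]
        # n1 = b1 x b2, n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1.0e-18 or n2sq < 1.0e-18 or b2n <= 0.0:
            return u_bond, u_angle, u_dih, u_nc, u_nn, F, 1
        # signed dihedral, IUPAC convention, (-pi, pi]
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (n1y * n2z - n1z * n2y) * b2x / b2n \
            + (n1z * n2x - n1x * n2z) * b2y / b2n \
            + (n1x * n2y - n1y * n2x) * b2z / b2n
        phi = np.arctan2(y, x)
        if dih_form == 0:
            d = phi - phi0[k]
            u_dih += K_phi * ((1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d)))
            dudphi = K_phi * (np.sin(d) + 1.5 * np.sin(3.0 * d))
        else:
            g = 2.0 * phi - 0.5 * np.pi
            omc = 1.0 - np.cos(g)
            u_dih += 0.5 * K_phi * omc * omc
            dudphi = 2.0 * K_phi * omc * np.sin(g)
        # gradients of phi (standard four-body formulas)
        ga = b2n / n1sq
        gd = b2n / n2sq
        dpa_x = -ga * n1x
        dpa_y = -ga * n1y
        dpa_z = -ga * n1z
        dpd_x = gd * n2x
        dpd_y = gd * n2y
        dpd_z = gd * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        dpb_x = -(1.0 + s12) * dpa_x + s32 * dpd_x
        dpb_y = -(1.0 + s12) * dpa_y + s32 * dpd_y
        dpb_z = -(1.0 + s12) * dpa_z + s32 * dpd_z
        dpc_x = s12 * dpa_x - (1.0 + s32) * dpd_x
        dpc_y = s12 * dpa_y - (1.0 + s32) * dpd_y
        dpc_z = s12 * dpa_z - (1.0 + s32) * dpd_z
        F[k, 0] -= dudphi * dpa_x
        F[k, 1] -= dudphi * dpa_y
        F[k, 2] -= dudphi * dpa_z
        F[k + 1, 0] -= dudphi * dpb_x
        F[k + 1, 1] -= dudphi * dpb_y
        F[k + 1, 2] -= dudphi * dpb_z
        F[k + 2, 0] -= dudphi * dpc_x
        F[k + 2, 1] -= dudphi * dpc_y
        F[k + 2, 2] -= dudphi * dpc_z
        F[k + 3, 0] -= dudphi * dpd_x
        F[k + 3, 1] -= dudphi * dpd_y
        F[k + 3, 2] -= dudphi * dpd_z

    # native 12-10 wells
    for k in range(nc_i.shape[0]):
        i = nc_i[k]
        j = nc_j[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            return u_bond, u_angle, u_dih, u_nc, u_nn, F, 2
        q2 = nc_r0[k] * nc_r0[k] / r2
        q10 = q2 * q2 * q2 * q2 * q2
        q12 = q10 * q2
        u_nc += nc_eps[k] * (5.0 * q12 - 6.0 * q10)
        # dU/dr * (1/r) = -60 eps (q^12 - q^10) / r^2
        g = -60.0 * nc_eps[k] * (q12 - q10) / r2
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz

    # nonnative pairs
    for k in range(nn_i.shape[0]):
        i = nn_i[k]
        j = nn_j[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            return u_bond, u_angle, u_dih, u_nc, u_nn, F, 2
        g = 0.0
        well = frustrated and nn_well[k] > 0.0
        if (not well) or additive:
            c2 = C * C / r2
            c12 = c2 * c2 * c2 * c2 * c2 * c2
            u_nn += eps_bar * c12
            g += -12.0 * eps_bar * c12 / r2
        if well:
            q2 = C_f * C_f / r2
            q10 = q2 * q2 * q2 * q2 * q2
            q12 = q10 * q2
            u_nn += nn_well[k] * eps_bar * (5.0 * q12 - 6.0 * q10)
            g += -60.0 * nn_well[k] * eps_bar * (q12 - q10) / r2
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz

    return u_bond, u_angle, u_dih, u_nc, u_nn, F, status


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

class System:
    """A topology + parameter set compiled to flat arrays for the kernels.

    This is the force-field object the integrator propagates; it exposes
    ``energy_and_forces`` and ``energy_terms``.
    """

    def __init__(self, topology: NativeTopology, params: ModelParams | None = None):
        self.topology = topology
        self.params = params if params is not None else ModelParams()
        nn_i, nn_j, hh = nonnative_pairs(topology)
        self.nn_i, self.nn_j = nn_i, nn_j
        self.nn_hh = hh
        # per-pair frustration strength (sigma for h-h pairs, 0 otherwise)
        self.nn_well = np.where(hh, self.params.sigma, 0.0)

    @property
    def n_beads(self) -> int:
        return self.topology.n_residues

    def _kernel(self, pos: np.ndarray):
        p = self.params
        t = self.topology
        out = _energy_forces(
            pos, t.bond_r0, p.K_b, t.theta0, p.K_theta, t.phi0, p.K_phi,
            _DIH_NATIVE if p.dihedral_form == "native_centered" else _DIH_PRINTED,
            t.contact_i, t.contact_j, t.contact_r0, t.contact_eps,
            self.nn_i, self.nn_j, self.nn_well, p.eps_bar, p.C, p.C_f,
            p.model_flavor == "frustrated", p.frustration_additive)
        status = out[6]
        if status == 1:
            raise ValueError("collinear bead triplet: angle/dihedral undefined")
        if status == 2:
            raise ValueError("coincident beads: pair distance is zero")
        return out

    def energy_terms(self, frame) -> dict:
        pos = _positions(frame)
        ub, ua, ud, unc, unn, _, _ = self._kernel(pos)
        return {"bond": ub, "angle": ua, "dihedral": ud,
                "native_contact": unc, "nonnative": unn}

    def energy_and_forces(self, frame):
        pos = _positions(frame)
        ub, ua, ud, unc, unn, F, _ = self._kernel(pos)
        return ub + ua + ud + unc + unn, F

    def total_energy(self, frame) -> float:
        return self.energy_and_forces(frame)[0]


def bonded_energy(frame, topology: NativeTopology,
                  params: ModelParams | None = None) -> float:
    """Harmonic bond + angle + dihedral energy (eps0 units).

    Zero at the native frame when ``dihedral_form`` is ``native_centered``.
    """
    terms = System(topology, params).energy_terms(frame)
    return terms["bond"] + terms["angle"] + terms["dihedral"]


def native_contact_energy(frame, topology: NativeTopology) -> float:
    """Sum of the 12-10 native-contact wells; equals -sum(eps_ij) at the
    native frame (every term is eps_ij (5 - 6) there)."""
    return System(topology, ModelParams()).energy_terms(frame)["native_contact"]


def nonnative_energy(frame, topology: NativeTopology,
                     params: ModelParams | None = None) -> float:
    """Nonnative-pair energy: pure (C/r)^12 repulsion in the minimal model;
    in the frustrated model hydrophobic-hydrophobic pairs get the
    sigma-scaled 12-10 well at C_f instead."""
    return System(topology, params).energy_terms(frame)["nonnative"]


def total_energy_and_forces(frame, topology: NativeTopology,
                            params: ModelParams | None = None):
    """Total potential energy (eps0) and analytic forces (eps0/A, N x 3)."""
    return System(topology, params).energy_and_forces(frame)
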