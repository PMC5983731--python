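"""Transition-state-ensemble analysis: free-energy profiles, phi-values
and contact maps.

The transition-state ensemble (TSE) collects the conformations whose Q
lies in the window (Q1, Q2) straddling the barrier of the -ln P(Q)
profile: Q1 is the midpoint of the valley and the unfolded peak, Q2 the
midpoint of the valley and the folded peak.  Per-residue phi-values are
the TSE-averaged number of held native contacts of a residue divided by
its native-state contact count; phi = 1 means the residue is native-like
in the transition state, phi = 0 unfolded.  Residues without native
contacts have an undefined phi (NaN), not zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .topology import NativeTopology
from .vtf import FoldingHistogram
from .dynamics import Trajectory

__all__ = [
    "TransitionStateEnsemble",
    "PhiProfile",
    "ContactMapMatrix",
    "free_energy_profile",
    "extract_tse",
    "phi_values",
    "delta_phi",
    "generic_contact_map",
    "tse_contact_map",
    "contact_difference_map",
]


@dataclass
class TransitionStateEnsemble:
    """Frames whose Q falls strictly inside the barrier window (Q1, Q2)."""

    Q1: float
    Q2: float
    frame_indices: np.ndarray      # indices into the source trajectory
    positions: np.ndarray          # (n_members, N, 3)
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.Q1 < self.Q2 < 1.0:
            raise ValueError("require 0 < Q1 < Q2 < 1")

    @property
    def n_members(self) -> int:
        return self.positions.shape[0]


@dataclass
class PhiProfile:
    """Per-residue phi-values with the counts they are built from."""

    phi: np.ndarray                # (N,), NaN where undefined
    native_counts: np.ndarray      # (N,) native-state contact count per residue
    tse_mean_counts: np.ndarray    # (N,) TSE-averaged held-contact count


@dataclass
class ContactMapMatrix:
    """N x N contact matrix.

    ``kind`` is one of ``generic-distance`` (binary, one conformation),
    ``native-contact-ensemble`` (TSE-averaged hold probabilities on native
    pairs) or ``difference`` (frustrated minus minimal, in [-1, 1])."""

    matrix: np.ndarray
    kind: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def split_triangle(self, other: "ContactMapMatrix") -> np.ndarray:
        """Two-model display layout: this map in the upper-left triangle,
        ``other`` in the lower-right."""
        if self.matrix.shape != other.matrix.shape:
            raise ValueError("maps must have the same shape")
        return np.triu(self.matrix, 1) + np.tril(other.matrix, -1)


def free_energy_profile(q_series, T_theta: float, bins=50):
    """Apparent free energy F(Q) = -T_theta * ln P(Q) in eps0 units
    (k_B = 1), on the given binning.

    Returns ``(bin_centers, F)``; bins with no samples get NaN, not zero.
    Only free-energy *differences* are meaningful — the profile is
    invariant (up to an additive constant) to the sample size.
    """
    if T_theta <= 0:
        raise ValueError("T_theta must be positive")
    q = np.asarray(q_series, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q series")
    edges = np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) \
        else np.asarray(bins, dtype=float)
    p, edges = np.histogram(q, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = np.full_like(p, np.nan)
    occupied = p > 0
    F[occupied] = -T_theta * np.log(p[occupied])
    return centers, F


def extract_tse(hist: FoldingHistogram, trajectory: Trajectory,
                source: str = "") -> TransitionStateEnsemble:
    """Collect the TSE from a bimodal histogram and a trajectory.

    Q1 = (valley + unfolded peak)/2, Q2 = (valley + folded peak)/2;
    members are the trajectory frames with Q1 < Q < Q2.
    """
    if not hist.bimodal:
        raise ValueError("histogram is unimodal; sample longer (or closer to "
                         "the collapse temperature) before extracting a TSE")
    q1 = 0.5 * (hist.valley_Q + hist.unfolded_peak_Q)
    q2 = 0.5 * (hist.valley_Q + hist.folded_peak_Q)
    inside = (trajectory.q > q1) & (trajectory.q < q2)
    idx = np.where(inside)[0]
    if idx.size == 0:
        warnings.warn("no trajectory frame falls in the TSE window "
                      f"({q1:.3f}, {q2:.3f}); the ensemble is empty",
                      stacklevel=2)
    return TransitionStateEnsemble(q1, q2, idx, trajectory.positions[idx],
                                   source=source)


def _held_matrix(positions: np.ndarray, topology: NativeTopology,
                 hold_ratio: float) -> np.ndarray:
    """(n_frames, n_contacts) boolean: contact held in frame."""
    d = np.linalg.norm(positions[:, topology.contact_j, :]
                       - positions[:, topology.contact_i, :], axis=2)
    return d <= hold_ratio * topology.contact_r0


def phi_values(tse: TransitionStateEnsemble, topology: NativeTopology,
               hold_ratio: float = 1.2) -> PhiProfile:
    """Per-residue phi = <N_i>_TSE / N_i^nat.

    N_i counts the residue's native contacts held under the Calpha
    criterion r <= hold_ratio * r0.  Residues with no native contact get
    phi = NaN (undefined), never zero.
    """
    if tse.n_members == 0:
        raise ValueError("empty transition-state ensemble")
    n = topology.n_residues
    native_counts = np.zeros(n)
    np.add.at(native_counts, topology.contact_i, 1)
    np.add.at(native_counts, topology.contact_j, 1)

    held = _held_matrix(tse.positions, topology, hold_ratio)
    mean_held = held.mean(axis=0)          # per-contact hold probability
    tse_counts = np.zeros(n)
    np.add.at(tse_counts, topology.contact_i, mean_held)
    np.add.at(tse_counts, topology.contact_j, mean_held)

    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(native_counts > 0, tse_counts / native_counts, np.nan)
    return PhiProfile(phi, native_counts, tse_counts)


def delta_phi(profile_a: PhiProfile, profile_b: PhiProfile,
              ss_elements: dict | None = None):
    """Per-residue phi difference (a minus b, e.g. frustrated minus
    minimal) and, if ``ss_elements`` is given, unweighted means over each
    named secondary-structure element (defined residues only).

    ``ss_elements`` maps names to lists of 1-based inclusive ranges.
    """
    if profile_a.phi.shape != profile_b.phi.shape:
        raise ValueError("profiles come from different topologies")
    if not np.array_equal(profile_a.native_counts, profile_b.native_counts):
        raise ValueError("profiles come from different topologies "
                         "(native contact counts differ)")
    dphi = profile_a.phi - profile_b.phi
    if ss_elements is None:
        return dphi, {}
    element_means = {}
    for name, ranges in ss_elements.items():
        idx = np.concatenate([np.arange(a - 1, b) for a, b in ranges])
        vals = dphi[idx]
        defined = ~np.isnan(vals)
        element_means[name] = float(vals[defined].mean()) if defined.any() \
            else float("nan")
    return dphi, element_means


def generic_contact_map(frame, r_c: float = 10.0) -> ContactMapMatrix:
    """Binary distance contact map of one conformation: a_ij = 1 iff the
    Calpha distance d_ij < r_c (diagonal zero).  The customary cutoff lies
    between 7 and 15 A; values outside that range trigger a warning."""
    from .energetics import _positions
    pos = _positions(frame)
    if not 7.0 <= r_c <= 15.0:
        warnings.warn(f"contact-map cutoff r_c = {r_c} A is outside the "
                      "customary 7-15 A range", stacklevel=2)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    a = (d < r_c).astype(float)
    np.fill_diagonal(a, 0.0)
    return ContactMapMatrix(a, "generic-distance")


def tse_contact_map(tse: TransitionStateEnsemble, topology: NativeTopology,
                    hold_ratio: float = 1.2) -> ContactMapMatrix:
    """Ensemble contact map c_ij = fraction of TSE frames in which the
    native pair (i, j) is held; entries of non-native pairs are zero."""
    if tse.n_members == 0:
        raise ValueError("empty transition-state ensemble")
    held = _held_matrix(tse.positions, topology, hold_ratio).mean(axis=0)
    n = topology.n_residues
    c = np.zeros((n, n))
    c[topology.contact_i, topology.contact_j] = held
    c[topology.contact_j, topology.contact_i] = held
    return ContactMapMatrix(c, "native-contact-ensemble")


def contact_difference_map(c_frustrated: ContactMapMatrix,
                           c_minimal: ContactMapMatrix) -> ContactMapMatrix:
    """Between-model difference map, frustrated minus minimal; positive
    entries mark enhanced contacts, negative entries weakened ones."""
    if c_frustrated.matrix.shape != c_minimal.matrix.shape:
        raise ValueError("contact maps have different shapes")
    return ContactMapMatrix(c_frustrated.matrix - c_minimal.matrix,
                            "difference")
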