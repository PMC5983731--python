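"""Self-contained synthetic native structures and labeled trajectories.

Everything here is generated programmatically so the full pipeline —
structure parsing, contact extraction, dynamics, sampling and analysis —
is exercisable without downloading any real structure.  The geometries
are idealized (flat pleated strands, circular-arc linkers); they exist to
exercise code paths and carry no biological claims.
"""

from __future__ import annotations

import numpy as np

from .topology import NativeStructure

__all__ = [
    "make_hairpin",
    "make_mock_sandwich",
    "make_toy_chain",
    "make_labeled_trajectory",
    "write_pdb",
    "MOCK_SANDWICH_SS",
]

#: Secondary-structure ranges of the mock 110-residue Ig-like sandwich
#: (1-based inclusive).  Eight strands B1-B8; the latter six form three
#: hairpins BH1-BH3.
MOCK_SANDWICH_SS = {
    "B1": [(1, 12)],
    "L1": [(13, 15)],
    "B2": [(16, 24)],
    "L2": [(25, 35)],
    "BH1": [(36, 43), (44, 51)],
    "L3": [(52, 63)],
    "BH2": [(64, 70), (71, 80)],
    "L4": [(81, 85)],
    "BH3": [(86, 96), (97, 110)],
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _pdb_model(sequence: str, ca: np.ndarray, cb: np.ndarray | None = None):
    """ATOM record lines for one model (CA trace, optional CB atoms)."""
    lines = []
    serial = 1
    for k, aa in enumerate(sequence):
        res = _ONE_TO_THREE[aa]
        x, y, z = ca[k]
        lines.append(
            f"ATOM  {serial:5d}  CA  {res} A{k + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        serial += 1
        if cb is not None and np.all(np.isfinite(cb[k])):
            x, y, z = cb[k]
            lines.append(
                f"ATOM  {serial:5d}  CB  {res} A{k + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
    return lines


def write_pdb(structure: NativeStructure) -> str:
    """Serialize a structure to single-model PDB text (all heavy atoms;
    the first atom of each residue is written as CA, any second as CB)."""
    lines = []
    serial = 1
    names = ["CA", "CB", "CG", "CD"]
    for k, aa in enumerate(structure.sequence):
        res = _ONE_TO_THREE[aa]
        for a, xyz in enumerate(structure.heavy_atoms[k]):
            x, y, z = xyz
            name = names[a] if a < len(names) else f"C{a}"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res} A{k + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_hairpin(n_residues: int = 12, sequence: str | None = None,
                 seed: int = 0, strand_sep: float = 4.6,
                 rise: float = 3.5) -> NativeStructure:
    """An ideal antiparallel beta-hairpin: two pleated strands joined by a
    two-residue turn, with cross-strand Calpha distances ~= ``strand_sep``
    so native contacts form under the 5.5 A rule.

    ``n_residues`` must be even and >= 8.  The default sequence
    alternates Ala/Val on the strands (all hydrophobic, so the frustrated
    model has nonnative wells to work with) with an Asn-Gly turn.
    Deterministic for a given seed.
    """
    n = n_residues
    if n < 8 or n % 2:
        raise ValueError("hairpin needs an even number of residues >= 8")
    ns = (n - 2) // 2           # beads per strand
    rng = np.random.default_rng(seed)
    pleat = 0.45
    ca = np.zeros((n, 3))
    # strand A: levels 0..ns-1 going up
    for k in range(ns):
        ca[k] = (pleat * (-1) ** k, 0.0, k * rise)
    # strand B: bead n-1-k sits opposite bead k (same z level, same pleat
    # phase, offset by strand_sep in x) so each cross pair is strand_sep apart
    for k in range(ns):
        ca[n - 1 - k] = (strand_sep + pleat * (-1) ** k, 0.0, k * rise)
    # two turn beads bridging the strand tops
    top = (ns - 1) * rise
    ca[ns] = (0.6, 1.9, top + 2.6)
    ca[ns + 1] = (strand_sep - 0.6, 1.9, top + 2.6)
    # tiny deterministic jitter: breaks exact collinearity/symmetry without
    # moving any pair across the contact cutoff
    ca += 0.02 * rng.standard_normal(ca.shape)

    if sequence is None:
        strand = "".join("AV"[k % 2] for k in range(ns))
        sequence = strand + "NG" + strand[::-1]
    if len(sequence) != n:
        raise ValueError("sequence length must equal n_residues")
    return NativeStructure(sequence, ca, [ca[k] for k in range(n)])


def _arc_points(a: np.ndarray, b: np.ndarray, m: int, spacing: float,
                hint: np.ndarray) -> np.ndarray:
    """``m`` interior points on a circular arc from ``a`` to ``b`` whose
    arc length is ~``spacing * (m + 1)``, bowing along ``hint``."""
    chord_v = b - a
    chord = np.linalg.norm(chord_v)
    arc_len = max(spacing * (m + 1), chord * 1.02)
    perp = hint - np.dot(hint, chord_v) * chord_v / chord ** 2
    perp = perp / np.linalg.norm(perp)
    # solve chord/arc = sin(t/2)/(t/2) for the subtended angle t
    lo, hi = 1e-6, 2 * np.pi - 1e-6
    for _ in range(80):
        t = 0.5 * (lo + hi)
        if np.sin(t / 2) / (t / 2) > chord / arc_len:
            lo = t
        else:
            hi = t
    radius = arc_len / t
    # center sits opposite the bulge, so the arc apex lies along +perp
    center = 0.5 * (a + b) - perp * radius * np.cos(t / 2)
    # rotate (a - center) toward (b - center): the in-plane unit tangent
    # at angle 0 that lands exactly on b at angle t
    u = (a - center) / radius
    v = (b - center) / radius
    tang = (v - np.cos(t) * u) / np.sin(t)
    tang = tang / np.linalg.norm(tang)
    pts = np.empty((m, 3))
    for k in range(m):
        ang = t * (k + 1) / (m + 1)
        pts[k] = center + radius * (np.cos(ang) * u + np.sin(ang) * tang)
    return pts


def make_mock_sandwich(seed: int = 0):
    """A mock 110-residue two-sheet beta-sandwich.

    Eight idealized strands are arranged in two flat pleated sheets packed
    10 A apart, with side-chain (CB) pseudo-atoms pointing alternately
    into and out of the core so that both intra-sheet (CA-CA ~ 4.8 A) and
    inter-sheet (CB-CB ~ 5.2 A) native contacts arise under the 5.5 A
    minimum-heavy-atom rule.  Secondary-structure element ranges follow
    :data:`MOCK_SANDWICH_SS`; linker residues are laid on circular arcs
    that bow away from the sandwich body.

    Returns ``(structure, ss_elements)``.  The sequence places hydrophobic
    residues at core-facing positions and fixed identities at the
    mutation sites studied for this fold (R23, N36, D43, T53, V60, D71,
    A80, Y94).
    """
    rng = np.random.default_rng(seed)
    n = 110
    rise = 3.5
    sheet_y = {1: 0.0, 2: 10.0}
    slot_dx = 4.8

    # (range, sheet, slot, direction, z_first): spatial strand order in
    # sheet 2 is B1 BH3b BH3a BH1a BH1b, in sheet 1 B2 BH2a BH2b, so that
    # hairpin partners are adjacent, B1 packs against the C-strand of BH3
    # and sits right across the core from B2, and every hairpin turn spans
    # neighbouring slots at matching height.
    strands = [
        ((1, 12), 2, 0, +1, -19.25),    # B1
        ((16, 24), 1, 0, -1, 14.0),     # B2
        ((36, 43), 2, 3, +1, -12.25),   # BH1 N-strand
        ((44, 51), 2, 4, -1, 12.25),    # BH1 C-strand
        ((64, 70), 1, 1, +1, -10.5),    # BH2 N-strand
        ((71, 80), 1, 2, -1, 10.5),     # BH2 C-strand
        ((86, 96), 2, 2, +1, -10.5),    # BH3 N-strand
        ((97, 110), 2, 1, -1, 24.5),    # BH3 C-strand
    ]

    ca = np.full((n, 3), np.nan)
    cb = np.full((n, 3), np.nan)
    core_facing = np.zeros(n, dtype=bool)
    for (a, b), sheet, slot, direction, z_first in strands:
        for m in range(b - a + 1):
            res = a - 1 + m
            z = z_first + direction * rise * m
            y0 = sheet_y[sheet]
            inward = 1.0 if sheet == 1 else -1.0   # toward the other sheet
            # pleat phase from the global height level, so the core-facing
            # side chains of facing strands meet at matching z
            phase = int(np.floor(z / rise + 0.5)) % 2 == 0
            ca_y = y0 + (0.25 if phase else -0.25) * inward
            ca[res] = (slot * slot_dx, ca_y, z)
            cb[res] = (slot * slot_dx,
                       ca_y + (2.4 if phase else -1.5) * inward, z)
            core_facing[res] = phase

    # linkers: circular arcs between the flanking strand ends, arc length
    # matched to ~3.8 A per virtual bond, each bowing away from the body
    # of the sandwich along a per-linker direction hint
    strand_set = {r for (a, b), *_ in strands for r in range(a - 1, b)}
    bow_hints = {
        12: np.array([0.0, 0.4, 1.0]),       # L1, over the top
        24: np.array([0.0, -1.0, -0.5]),     # L2, under the bottom, -y side
        51: np.array([0.0, 0.0, -1.0]),      # L3, straight under the bottom
        80: np.array([0.0, 0.6, -1.0]),      # L4, under the bottom, +y side
    }
    runs = []
    for r in range(n):
        if r in strand_set:
            continue
        if runs and runs[-1][-1] == r - 1:
            runs[-1].append(r)
        else:
            runs.append([r])
    for run in runs:
        a = ca[run[0] - 1]
        b = ca[run[-1] + 1]
        m = len(run)
        ca[run[0]:run[-1] + 1] = _arc_points(
            a, b, m, 3.8, bow_hints.get(run[0], np.array([0.0, 0.0, 1.0])))
    ca += 0.05 * rng.standard_normal(ca.shape)

    # sequence: hydrophobic at core-facing strand positions, polar otherwise
    hydro = "VLIF"
    polar = "TSNQ"
    seq = []
    for r in range(n):
        if r in strand_set:
            seq.append(hydro[r % 4] if core_facing[r] else polar[r % 4])
        else:
            seq.append("GSEK"[r % 4])
    # fixed identities at the studied mutation sites (1-based)
    for site, aa in [(23, "R"), (36, "N"), (43, "D"), (53, "T"),
                     (60, "V"), (71, "D"), (80, "A"), (94, "Y")]:
        seq[site - 1] = aa
    sequence = "".join(seq)

    heavy = []
    for r in range(n):
        if np.all(np.isfinite(cb[r])):
            heavy.append(np.vstack([ca[r], cb[r]]))
        else:
            heavy.append(ca[r][None, :])
    structure = NativeStructure(sequence, ca, heavy)
    return structure, dict(MOCK_SANDWICH_SS)


def _compact_walk(n: int, rng: np.random.Generator, bond: float,
                  min_sep: float):
    """One attempt at a compact self-avoiding walk; None on dead end."""
    pos = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    while len(pos) < n:
        centroid = np.mean(pos, axis=0)
        for _ in range(200):
            perturb = rng.standard_normal(3)
            # bias back toward the centroid so the chain stays compact
            # enough to form native contacts
            pull = centroid - pos[-1]
            pull_n = np.linalg.norm(pull)
            cand_dir = (0.5 * direction + 0.9 * perturb / np.linalg.norm(perturb)
                        + (0.8 * pull / pull_n if pull_n > 1e-9 else 0.0))
            cand_dir /= np.linalg.norm(cand_dir)
            cand = pos[-1] + bond * cand_dir
            d = np.linalg.norm(np.array(pos[:-1]) - cand, axis=1) \
                if len(pos) > 1 else np.array([np.inf])
            if d.min() > min_sep:
                pos.append(cand)
                direction = cand_dir
                break
        else:
            return None
    return pos


def make_toy_chain(n_residues: int = 10, seed: int = 0,
                   bond: float = 3.8, min_sep: float = 4.0) -> NativeStructure:
    """A random compact self-avoiding chain (Calpha only) for numerical
    tests: bonds at ``bond`` A, random turn angles, no two beads closer
    than ``min_sep``.  Deterministic for a given seed."""
    pos = None
    for attempt in range(32):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, attempt]).generate_state(1)[0])
        trial = _compact_walk(n_residues, rng, bond, min_sep)
        if trial is None:
            continue
        ca = np.array(trial)
        n_contacts = sum(
            1 for i in range(n_residues) for j in range(i + 4, n_residues)
            if np.linalg.norm(ca[i] - ca[j]) < 5.5)
        if n_contacts >= 1:        # a useful toy needs at least one contact
            pos = trial
            break
    if pos is None:
        raise RuntimeError("self-avoiding walk failed; try another seed")
    ca = np.array(pos)
    seq = "".join("AVTSLNIG"[k % 8] for k in range(n_residues))
    return NativeStructure(seq, ca, [ca[k] for k in range(n_residues)])


def make_labeled_trajectory(topology, folded_fraction: float = 0.5,
                            n_frames: int = 1000, seed: int = 0,
                            jitter: float = 0.08, expansion: float = 3.0):
    """A synthetic trajectory with known folded/unfolded labels.

    Folded frames are the native frame plus small Gaussian jitter (well
    inside the 1.2 r0 hold margin, so Q stays high); unfolded frames are
    the native frame scaled by ``expansion`` (> 1.2, so every contact is
    broken and Q = 0) plus jitter.  Frames are shuffled; returns
    ``(trajectory, labels)`` with ``labels[k]`` True for folded frames.
    """
    from .dynamics import Trajectory
    from .vtf import compute_Q

    if not 0.0 <= folded_fraction <= 1.0:
        raise ValueError("folded_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_folded = int(round(folded_fraction * n_frames))
    labels = np.zeros(n_frames, dtype=bool)
    labels[:n_folded] = True
    rng.shuffle(labels)

    native = topology.ca0
    center = native.mean(axis=0)
    frames = np.empty((n_frames, topology.n_residues, 3))
    for k in range(n_frames):
        base = native if labels[k] else center + expansion * (native - center)
        frames[k] = base + jitter * rng.standard_normal(native.shape)
    q = np.array([compute_Q(f, topology) for f in frames])
    traj = Trajectory(frames, q, np.zeros(n_frames), np.zeros(n_frames),
                      np.arange(n_frames, dtype=np.int64))
    return traj, labels
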