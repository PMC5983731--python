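"""Build a coarse-grained native topology from a structure.

A protein is reduced to its Calpha trace.  The native structure supplies
the reference geometry (bond lengths, bond angles, dihedrals), the list of
native contacts (residue pairs at least four apart in sequence whose
minimum heavy-atom distance is below a cutoff, 5.5 A by default), the
per-pair contact couplings (knowledge-based contact energies rescaled so
their mean equals a prescribed value, 0.18 eps0 by default), and the
hydrophobicity flags that decide which nonnative pairs feel the
frustration well.

Residue indices are 0-based in memory and 1-based in every serialized
file and mutation directive.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .mj import MJTable, mj_contact_energies
from .params import HYDROPHOBIC_SET

__all__ = [
    "NativeStructure",
    "NativeTopology",
    "read_pdb",
    "extract_native_contacts",
    "flavor_contacts",
    "classify_hydrophobic",
    "apply_mutation",
    "build_topology",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class NativeStructure:
    """A parsed single-chain native structure.

    ``heavy_atoms[k]`` is an (n_k, 3) array of all non-hydrogen atom
    coordinates of residue k (backbone included); ``ca`` holds the Calpha
    positions.  Residues are ordered by residue number.
    """

    sequence: str
    ca: np.ndarray                      # (N, 3) angstrom
    heavy_atoms: list                   # list of (n_k, 3) arrays
    residue_numbers: np.ndarray | None = None  # original 1-based numbering

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.heavy_atoms = [np.atleast_2d(np.asarray(h, dtype=float))
                            for h in self.heavy_atoms]
        n = len(self.sequence)
        if self.ca.shape != (n, 3):
            raise ValueError("ca must be (N, 3) matching the sequence length")
        if len(self.heavy_atoms) != n:
            raise ValueError("heavy_atoms must have one entry per residue")
        if n < 4:
            raise ValueError("a chain needs at least 4 residues")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, n + 1)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class NativeTopology:
    """The model definition derived from a native structure.

    Geometry reference values carry the native-state subscript-0 meaning:
    ``bond_r0[i]`` is the native distance between beads i and i+1,
    ``theta0[i]`` the native angle at bead i+1, ``phi0[i]`` the native
    dihedral over beads i..i+3.  Contacts are stored 0-based with native
    Calpha-Calpha distances ``contact_r0`` and couplings ``contact_eps``
    in eps0 units whose mean equals ``target_mean_eps``.
    """

    sequence: str
    ca0: np.ndarray                 # (N, 3) native Calpha coordinates
    bond_r0: np.ndarray             # (N-1,)
    theta0: np.ndarray              # (N-2,) radians
    phi0: np.ndarray                # (N-3,) radians, signed, (-pi, pi]
    contact_i: np.ndarray           # (M,) int, 0-based
    contact_j: np.ndarray           # (M,) int, 0-based, j >= i + 4
    contact_r0: np.ndarray          # (M,) angstrom
    contact_eps: np.ndarray         # (M,) eps0
    hydrophobic: np.ndarray         # (N,) bool
    ss_elements: dict = field(default_factory=dict)
    target_mean_eps: float = 0.18

    def __post_init__(self) -> None:
        self.ca0 = np.asarray(self.ca0, dtype=float)
        for name in ("bond_r0", "theta0", "phi0", "contact_r0", "contact_eps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.contact_i = np.asarray(self.contact_i, dtype=np.int64)
        self.contact_j = np.asarray(self.contact_j, dtype=np.int64)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)
        n = len(self.sequence)
        if self.ca0.shape != (n, 3) or len(self.hydrophobic) != n:
            raise ValueError("array sizes inconsistent with sequence length")
        expected = (n - 1, max(n - 2, 0), max(n - 3, 0))
        if (len(self.bond_r0), len(self.theta0), len(self.phi0)) != expected:
            raise ValueError("reference geometry lengths must be N-1, N-2, N-3")
        if self.n_contacts:
            if np.any(self.contact_j - self.contact_i < 4):
                raise ValueError("native contacts must satisfy j - i >= 4")
            if np.any(self.contact_r0 <= 0) or np.any(self.contact_eps <= 0):
                raise ValueError("contact distances and couplings must be positive")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_i)

    def native_contact_count(self, residue: int) -> int:
        """Number of native contacts involving ``residue`` (0-based)."""
        return int(np.sum(self.contact_i == residue) + np.sum(self.contact_j == residue))

    # -- serialization (1-based indices on disk) ----------------------------
    def to_json(self) -> str:
        d = {
            "sequence": self.sequence,
            "target_mean_eps": self.target_mean_eps,
            "ca0": self.ca0.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "theta0": self.theta0.tolist(),
            "phi0": self.phi0.tolist(),
            "hydrophobic": self.hydrophobic.astype(int).tolist(),
            "ss_elements": {k: [list(r) for r in v] for k, v in self.ss_elements.items()},
            "contacts": [
                [int(i) + 1, int(j) + 1, float(r), float(e)]
                for i, j, r, e in zip(self.contact_i, self.contact_j,
                                      self.contact_r0, self.contact_eps)
            ],
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NativeTopology":
        d = json.loads(text)
        contacts = np.asarray(d["contacts"], dtype=float).reshape(-1, 4)
        return cls(
            sequence=d["sequence"],
            ca0=np.asarray(d["ca0"]),
            bond_r0=np.asarray(d["bond_r0"]),
            theta0=np.asarray(d["theta0"]),
            phi0=np.asarray(d["phi0"]),
            contact_i=contacts[:, 0].astype(int) - 1,
            contact_j=contacts[:, 1].astype(int) - 1,
            contact_r0=contacts[:, 2],
            contact_eps=contacts[:, 3],
            hydrophobic=np.asarray(d["hydrophobic"], dtype=bool),
            ss_elements={k: [tuple(r) for r in v] for k, v in d["ss_elements"].items()},
            target_mean_eps=float(d["target_mean_eps"]),
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def bond_lengths(coords: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(coords, axis=0), axis=1)


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Angle at each interior bead, radians in [0, pi]."""
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident beads make an angle undefined")
    c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.arccos(c)


def dihedral_angles(coords: np.ndarray) -> np.ndarray:
    """Signed dihedral over each run of four consecutive beads, (-pi, pi]."""
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_hat = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2_hat)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_pdb(pdb_text: str, chain: str | None = None) -> NativeStructure:
    """Parse a single-model PDB into a :class:`NativeStructure`.

    Hydrogens are discarded; every non-hydrogen atom of a residue counts as
    a heavy atom.  A residue without a Calpha is a hard error.  If the file
    holds several chains a ``chain`` id must be given.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("x", io.StringIO(pdb_text)).get_models())
    chains = [c for c in model.get_chains()
              if any(res.id[0] == " " for res in c)]
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"chain {chain!r} not found")
    if len(chains) != 1:
        raise ValueError(
            f"expected a single chain, found {len(chains)}; pass chain=<id>")

    seq, cas, heavies, numbers = [], [], [], []
    residues = sorted((r for r in chains[0] if r.id[0] == " "),
                      key=lambda r: r.id[1])
    for res in residues:
        name = _THREE_TO_ONE.get(res.get_resname())
        if name is None:
            raise ValueError(f"non-standard residue {res.get_resname()} "
                             f"at position {res.id[1]}")
        atoms = [a for a in res if a.element != "H"]
        ca = [a for a in atoms if a.get_name() == "CA"]
        if not ca:
            raise ValueError(f"residue {res.get_resname()}{res.id[1]} has no Calpha")
        seq.append(name)
        cas.append(ca[0].get_coord().astype(float))
        heavies.append(np.array([a.get_coord() for a in atoms], dtype=float))
        numbers.append(res.id[1])
    return NativeStructure("".join(seq), np.array(cas), heavies,
                           np.asarray(numbers))


def extract_native_contacts(structure: NativeStructure, cutoff: float = 5.5,
                            min_seq_sep: int = 4):
    """Find native contacts: pairs with ``j - i >= min_seq_sep`` whose
    minimum heavy-atom distance is below ``cutoff``.

    Returns ``(i, j, r0)`` arrays; ``r0`` is the native Calpha-Calpha
    distance of the pair (the reference length of the 12-10 well and of
    the contact-hold criterion, both of which are Calpha-based).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = structure.n_residues
    ii, jj, rr = [], [], []
    for i in range(n):
        hi = structure.heavy_atoms[i]
        for j in range(i + min_seq_sep, n):
            hj = structure.heavy_atoms[j]
            d2 = np.sum((hi[:, None, :] - hj[None, :, :]) ** 2, axis=2)
            if d2.min() < cutoff * cutoff:
                ii.append(i)
                jj.append(j)
                rr.append(np.linalg.norm(structure.ca[i] - structure.ca[j]))
    return (np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64),
            np.asarray(rr, dtype=float))


def flavor_contacts(contact_i: np.ndarray, contact_j: np.ndarray,
                    sequence: str, mj: MJTable | None = None,
                    target_mean: float = 0.18) -> np.ndarray:
    """Assign per-contact couplings eps_ij proportional to the
    knowledge-based contact energy of the residue pair, rescaled by a single
    global factor so the arithmetic mean over the contact list equals
    ``target_mean`` (eps0 units).

    Contact energies are attractive (negative) in the raw table; their
    absolute values are used so every coupling is a positive well depth.
    """
    if len(contact_i) == 0:
        raise ValueError("cannot flavor an empty contact list")
    if mj is None:
        mj = mj_contact_energies()
    raw = np.array([abs(mj[sequence[i], sequence[j]])
                    for i, j in zip(contact_i, contact_j)], dtype=float)
    if np.any(raw <= 0):
        bad = int(np.argmax(raw <= 0))
        raise ValueError(
            f"contact ({contact_i[bad]+1},{contact_j[bad]+1}) has a "
            "non-positive contact energy; review the table's sign convention "
            "(couplings must be positive well depths)")
    return raw * (target_mean / raw.mean())


def classify_hydrophobic(sequence: str,
                         hydrophobic_set=HYDROPHOBIC_SET) -> np.ndarray:
    """Boolean flag per residue: True if the residue is hydrophobic."""
    flags = np.empty(len(sequence), dtype=bool)
    for k, aa in enumerate(sequence):
        if aa not in _THREE_TO_ONE.values():
            raise ValueError(f"unknown amino-acid letter {aa!r} at position {k+1}")
        flags[k] = aa in hydrophobic_set
    return flags


def build_topology(structure: NativeStructure, sequence: str | None = None,
                   ss_elements: dict | None = None, mj: MJTable | None = None,
                   cutoff: float = 5.5, min_seq_sep: int = 4,
                   target_mean_eps: float = 0.18,
                   hydrophobic_set=HYDROPHOBIC_SET) -> NativeTopology:
    """Full pipeline: structure -> NativeTopology.

    ``sequence`` overrides the structure's own sequence (same length
    required); ``ss_elements`` maps element names to lists of 1-based
    inclusive residue ranges.
    """
    seq = sequence if sequence is not None else structure.sequence
    if len(seq) != structure.n_residues:
        raise ValueError("sequence length does not match structure")
    ci, cj, cr = extract_native_contacts(structure, cutoff, min_seq_sep)
    eps = flavor_contacts(ci, cj, seq, mj, target_mean_eps)
    return NativeTopology(
        sequence=seq,
        ca0=structure.ca.copy(),
        bond_r0=bond_lengths(structure.ca),
        theta0=bond_angles(structure.ca),
        phi0=dihedral_angles(structure.ca),
        contact_i=ci, contact_j=cj, contact_r0=cr, contact_eps=eps,
        hydrophobic=classify_hydrophobic(seq, hydrophobic_set),
        ss_elements=ss_elements or {},
        target_mean_eps=target_mean_eps,
    )


def apply_mutation(topology: NativeTopology, directive: str,
                   mj: MJTable | None = None,
                   hydrophobic_set=HYDROPHOBIC_SET) -> NativeTopology:
    """Apply an in-silico point mutation such as ``"D43A"`` (1-based site).

    The mutant shares the wild-type native geometry and contact pair list;
    only the sequence, the hydrophobicity flags and the (renormalized)
    contact couplings change.
    """
    directive = directive.strip()
    if len(directive) < 3:
        raise ValueError(f"malformed mutation directive {directive!r}")
    wt, site_s, mut = directive[0], directive[1:-1], directive[-1]
    try:
        site = int(site_s)
    except ValueError:
        raise ValueError(f"malformed mutation directive {directive!r}") from None
    if not 1 <= site <= topology.n_residues:
        raise ValueError(f"site {site} outside 1..{topology.n_residues}")
    have = topology.sequence[site - 1]
    if have != wt:
        raise ValueError(
            f"wild-type mismatch at site {site}: directive says {wt!r} "
            f"but topology has {have!r}")
    new_seq = topology.sequence[:site - 1] + mut + topology.sequence[site:]
    eps = flavor_contacts(topology.contact_i, topology.contact_j, new_seq,
                          mj, topology.target_mean_eps)
    return NativeTopology(
        sequence=new_seq,
        ca0=topology.ca0.copy(),
        bond_r0=topology.bond_r0.copy(),
        theta0=topology.theta0.copy(),
        phi0=topology.phi0.copy(),
        contact_i=topology.contact_i.copy(),
        contact_j=topology.contact_j.copy(),
        contact_r0=topology.contact_r0.copy(),
        contact_eps=eps,
        hydrophobic=classify_hydrophobic(new_seq, hydrophobic_set),
        ss_elements=dict(topology.ss_elements),
        target_mean_eps=topology.target_mean_eps,
    )
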