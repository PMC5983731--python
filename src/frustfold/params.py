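"""Force-field and integration constants in reduced units.

Internal unit system: lengths in angstrom, energies in units of the
reference well depth ``eps0``, Boltzmann constant k_B = 1 (temperatures in
eps0), bead mass m = 1.  The internal time unit is t* = sqrt(m A^2 / eps0);
the characteristic folding time tau = l0 * t* / A, so the default time step
0.007 tau equals 0.0266 t*.  Conversions to laboratory units (ps, kcal/mol)
happen only at I/O via :func:`eps0_to_kcal` and
:func:`frustfold.dynamics.characteristic_time`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["ModelParams", "eps0_to_kcal", "kcal_to_eps0"]

#: Default hydrophobic residue classification (one-letter codes).  Chosen as
#: the standard apolar set; glycine is treated as hydrophilic, consistent
#: with labelling an Ala->Gly substitution a hydrophobic-to-hydrophilic one.
HYDROPHOBIC_SET = frozenset("AVLIMFWYC")


@dataclass(frozen=True)
class ModelParams:
    """All tunable constants of the model.

    Energies are in eps0 units, lengths in angstrom, times in tau (the
    characteristic time ``l0 * sqrt(m / eps0)``), temperature in eps0/k_B.
    """

    K_b: float = 200.0          # bond stiffness, eps0 / A^2
    K_theta: float = 40.0       # angle stiffness, eps0 / rad^2
    K_phi: float = 0.3          # dihedral strength, eps0
    C: float = 4.0              # nonnative repulsion length, A
    C_f: float = 5.5            # frustration well position, A
    sigma: float = 0.5          # frustration strength for hydrophobic NNC pairs
    eps_bar: float = 0.18       # mean native coupling / NNC coupling, eps0
    eps0_kcal: float = 1.89     # absolute energy scale, kcal/mol
    bead_mass_amu: float = 119.0  # average residue mass, a.m.u.
    l0: float = 3.8             # average Calpha-Calpha bond length, A
    dt: float = 0.007           # time step, tau units
    friction: float = 0.2       # Langevin friction, 1/tau
    model_flavor: str = "minimal"           # "minimal" | "frustrated"
    dihedral_form: str = "native_centered"  # "native_centered" | "as_printed"
    frustration_additive: bool = False      # add 12-10 well on top of repulsion
    hydrophobic_set: frozenset = field(default=HYDROPHOBIC_SET)

    def __post_init__(self) -> None:
        for name in ("K_b", "K_theta", "K_phi", "C", "C_f", "eps_bar",
                     "eps0_kcal", "bead_mass_amu", "l0", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.model_flavor not in ("minimal", "frustrated"):
            raise ValueError(f"unknown model_flavor {self.model_flavor!r}")
        if self.dihedral_form not in ("native_centered", "as_printed"):
            raise ValueError(f"unknown dihedral_form {self.dihedral_form!r}")

    # -- reduced-unit helpers -------------------------------------------------
    @property
    def tau(self) -> float:
        """Characteristic time in internal t* units (= l0 since m = eps0 = 1)."""
        return self.l0

    @property
    def dt_internal(self) -> float:
        """Time step in internal t* units."""
        return self.dt * self.tau

    @property
    def friction_internal(self) -> float:
        """Friction coefficient in 1/t* units."""
        return self.friction / self.tau

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = sorted(v) if isinstance(v, frozenset) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "hydrophobic_set" in d:
            d["hydrophobic_set"] = frozenset(d["hydrophobic_set"])
        return cls(**d)


def eps0_to_kcal(energy_eps0: float, params: ModelParams | None = None) -> float:
    """Convert an energy from eps0 units to kcal/mol."""
    scale = params.eps0_kcal if params is not None else 1.89
    return energy_eps0 * scale


def kcal_to_eps0(energy_kcal: float, params: ModelParams | None = None) -> float:
    """Convert an energy from kcal/mol to eps0 units."""
    scale = params.eps0_kcal if params is not None else 1.89
    return energy_kcal / scale
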