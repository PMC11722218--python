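"""Elements, materials and composition arithmetic.

Every scattering and stopping computation in the package consumes a
:class:`Material`: an atomic-fraction composition bound to a mass density.
The two composition edits that matter for block-face physics are provided as
pure functions: heavy-metal staining (``with_stain``) and gallium implantation
modelled as one-for-one substitution of Ga for C (``substitute_ga_for_c``).

Densities after substitution are recomputed at constant atom number density by
default: the edit changes *which* atoms sit on the lattice of the epoxy, not
how many of them there are per unit volume.  The alternative
(``density_rule="constant_mass_density"``) is available for sensitivity
studies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateMaterialError

AVOGADRO = 6.02214076e23

#: symbol -> (atomic number, molar mass g/mol)
ATOMIC_DATA: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "B": (5, 10.81),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Si": (14, 28.085),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Fe": (26, 55.845),
    "Ga": (31, 69.723),
    "Os": (76, 190.23),
    "Pt": (78, 195.08),
    "Pb": (82, 207.2),
    "U": (92, 238.03),
}

_FRACTION_TOL = 1e-9


def mean_ionization_energy(z: int) -> float:
    """Berger–Seltzer mean ionization energy J in eV.

    ``J = 11.5 Z`` for Z < 13, else ``J = 9.76 Z + 58.5 Z**-0.19``.
    """
    if z < 1:
        raise ValueError(f"atomic number must be >= 1, got {z}")
    if z < 13:
        return 11.5 * z
    return 9.76 * z + 58.5 * z ** (-0.19)


@dataclass(frozen=True)
class ElementSpec:
    """One element as the physics sees it: Z, molar mass A and mean ionization J."""

    symbol: str
    Z: int
    A: float  # g/mol
    J: float  # eV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"molar mass must be positive, got {self.A}")
        if self.J <= 0:
            raise ValueError(f"mean ionization energy must be positive, got {self.J}")

    @classmethod
    def from_symbol(cls, symbol: str, j_ev: float | None = None) -> "ElementSpec":
        try:
            z, a = ATOMIC_DATA[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None
        return cls(symbol, z, a, j_ev if j_ev is not None else mean_ionization_energy(z))


@dataclass(frozen=True)
class Material:
    """An atomic-fraction composition with a mass density.

    Parameters
    ----------
    name : str
        Label used in provenance records and error messages.
    fractions : tuple of (ElementSpec, float)
        Atomic fractions; must be nonnegative and sum to 1 within 1e-9.
    density : float
        Mass density in g/cm^3; must be positive.
    """

    name: str
    fractions: tuple[tuple[ElementSpec, float], ...]
    density: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DegenerateMaterialError(
                f"material {self.name!r}: density must be positive, got {self.density}"
            )
        if not self.fractions:
            raise DegenerateMaterialError(f"material {self.name!r}: empty composition")
        total = 0.0
        for el, f in self.fractions:
            if f < 0:
                raise DegenerateMaterialError(
                    f"material {self.name!r}: negative fraction {f} for {el.symbol}"
                )
            total += f
        if abs(total - 1.0) > _FRACTION_TOL:
            raise DegenerateMaterialError(
                f"material {self.name!r}: atomic fractions sum to {total!r}, expected 1"
            )

    @classmethod
    def from_symbols(
        cls, name: str, fractions: dict[str, float], density: float
    ) -> "Material":
        """Build from ``{symbol: atomic fraction}`` after renormalizing."""
        total = sum(fractions.values())
        if total <= 0:
            raise DegenerateMaterialError(f"material {name!r}: fractions sum to {total}")
        items = tuple(
            (ElementSpec.from_symbol(sym), f / total)
            for sym, f in fractions.items()
            if f != 0.0
        )
        return cls(name, items, density)

    # -- derived quantities ------------------------------------------------

    @property
    def mean_molar_mass(self) -> float:
        """Atomic-fraction-weighted molar mass in g/mol."""
        return sum(el.A * f for el, f in self.fractions)

    @property
    def number_density(self) -> float:
        """Total atom number density in atoms/nm^3."""
        # g/cm^3 * (atoms/mol) / (g/mol) = atoms/cm^3; 1 cm^3 = 1e21 nm^3
        return self.density * AVOGADRO / self.mean_molar_mass / 1e21

    def element_number_densities(self) -> tuple[tuple[ElementSpec, float], ...]:
        """Per-element number densities n_i in atoms/nm^3."""
        n = self.number_density
        return tuple((el, f * n) for el, f in self.fractions)

    def mass_fractions(self) -> tuple[tuple[ElementSpec, float], ...]:
        a_bar = self.mean_molar_mass
        return tuple((el, f * el.A / a_bar) for el, f in self.fractions)

    def fraction_of(self, symbol: str) -> float:
        for el, f in self.fractions:
            if el.symbol == symbol:
                return f
        return 0.0

    def mean_z(self) -> float:
        return sum(el.Z * f for el, f in self.fractions)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "elements": {el.symbol: f for el, f in self.fractions},
            "density": self.density,
        }


def _rebuild(
    base: Material, new_fractions: dict[str, float], name: str, density_rule: str
) -> Material:
    total = sum(new_fractions.values())
    fractions = {s: f / total for s, f in new_fractions.items() if f > 0}
    if density_rule == "constant_atom_density":
        # same atoms/nm^3, so rho scales with the new mean molar mass
        a_old = base.mean_molar_mass
        a_new = sum(ElementSpec.from_symbol(s).A * f for s, f in fractions.items())
        density = base.density * a_new / a_old
    elif density_rule == "constant_mass_density":
        density = base.density
    else:
        raise ValueError(f"unknown density rule {density_rule!r}")
    return Material.from_symbols(name, fractions, density)


def with_stain(
    material: Material,
    stain_fraction: float,
    element: str = "Pb",
    density_rule: str = "constant_atom_density",
) -> Material:
    """Add heavy-metal stain at a given atomic fraction.

    "3 atomic % Pb" means the stain element takes atomic fraction 0.03 and the
    host composition is rescaled by 0.97.
    """
    if not 0.0 <= stain_fraction < 1.0:
        raise ValueError(f"stain fraction must be in [0, 1), got {stain_fraction}")
    if stain_fraction == 0.0:
        return material
    host = {el.symbol: f * (1.0 - stain_fraction) for el, f in material.fractions}
    host[element] = host.get(element, 0.0) + stain_fraction
    name = f"{material.name}+{stain_fraction:.3g}{element}"
    return _rebuild(material, host, name, density_rule)


def substitute_ga_for_c(
    material: Material,
    ga_fraction: float,
    density_rule: str = "constant_atom_density",
) -> Material:
    """Implant Ga by replacing carbon atoms one-for-one.

    ``ga_fraction`` is the resulting *absolute* Ga atomic fraction (0.25 means
    25 at.% Ga overall); the carbon fraction drops by the same amount and all
    other fractions are untouched.
    """
    if not 0.0 <= ga_fraction < 1.0:
        raise ValueError(f"Ga fraction must be in [0, 1), got {ga_fraction}")
    if ga_fraction == 0.0:
        return material
    f_c = material.fraction_of("C")
    if ga_fraction > f_c + _FRACTION_TOL:
        raise ValueError(
            f"cannot substitute {ga_fraction} Ga for C: material "
            f"{material.name!r} has only {f_c} C"
        )
    new = {el.symbol: f for el, f in material.fractions}
    new["C"] = max(new["C"] - ga_fraction, 0.0)
    new["Ga"] = new.get("Ga", 0.0) + ga_fraction
    name = f"{material.name}+{ga_fraction:.3g}Ga"
    return _rebuild(material, new, name, density_rule)


def add_element_fraction(
    material: Material,
    element: str,
    fraction: float,
    density_rule: str = "constant_atom_density",
) -> Material:
    """Mix in an element at a given final atomic fraction, rescaling the host.

    This is the forward model used by jump-ratio inversion: the surface layer
    is the (possibly C/O-depleted) bulk with Ga added at fraction ``x``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return material
    host = {el.symbol: f * (1.0 - fraction) for el, f in material.fractions}
    host[element] = host.get(element, 0.0) + fraction
    name = f"{material.name}+{fraction:.3g}{element}"
    return _rebuild(material, host, name, density_rule)


#: Default Epon Embed-812/Araldite-502/DDSA epoxy composition.  The resin's
#: exact elemental makeup is batch-dependent; this is a documented typical
#: value and every published-number computation reads composition from config
#: so a measured one can be dropped in.
EPON_DEFAULT_FRACTIONS = {"C": 0.54, "H": 0.36, "O": 0.09, "N": 0.01}
EPON_DEFAULT_DENSITY = 1.25  # g/cm^3


def epon_araldite(
    fractions: dict[str, float] | None = None, density: float | None = None
) -> Material:
    """The default embedding-resin material."""
    return Material.from_symbols(
        "epon-araldite",
        dict(fractions) if fractions else dict(EPON_DEFAULT_FRACTIONS),
        density if density is not None else EPON_DEFAULT_DENSITY,
    )
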