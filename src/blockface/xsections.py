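"""Elastic scattering cross sections and stopping power.

The default elastic model is the relativistically corrected screened
Rutherford cross section with the empirical screening parameter

    alpha(Z, E) = 3.4e-3 * Z**0.67 / E[keV]

familiar from the single-scattering Monte Carlo lineage used for SEM
simulation.  Its angular distribution has a closed-form inverse CDF,

    cos(theta) = 1 - 2 * alpha * u / (1 + alpha - u),   u ~ U[0, 1),

which is what the transport kernels sample.  Energy loss between elastic
events is continuous (CSDA) with the Joy–Luo modified Bethe formula and
Berger–Seltzer mean ionization energies.

All cross sections are in nm^2, energies in eV, lengths in nm, stopping power
in eV/nm.  Partial-wave (Mott-grade) cross sections may be supplied as
tabulated overrides on :class:`CrossSectionModel` when higher fidelity is
required; everything downstream only sees ``sigma(Z, E)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMaterialError, EnergyRangeError, GeometryError
from .materials import Material

_FOUR_PI = 4.0 * math.pi


@dataclass(frozen=True)
class CrossSectionModel:
    """Parameterization of the elastic cross section.

    Parameters
    ----------
    screening : str
        Identifier of the screening parameterization (only
        ``"rutherford-3.4e-3"`` is built in).
    relativistic : bool
        Apply the ((E+511)/(E+1024))^2 correction (E in keV).
    e_min, e_max : float
        Validity range in eV; energies outside raise
        :class:`~blockface.errors.EnergyRangeError`.
    overrides : dict
        Optional ``{Z: (energies_eV, sigmas_nm2)}`` tabulated total cross
        sections interpolated log-log in place of the analytic form.
    """

    screening: str = "rutherford-3.4e-3"
    relativistic: bool = True
    e_min: float = 50.0
    e_max: float = 300e3
    overrides: dict = field(default_factory=dict)

    def check_energy(self, e_ev: float) -> None:
        if e_ev < self.e_min:
            raise EnergyRangeError(
                f"E = {e_ev} eV below model lower bound {self.e_min} eV"
            )
        if e_ev > self.e_max:
            raise EnergyRangeError(
                f"E = {e_ev} eV above model upper bound {self.e_max} eV"
            )


DEFAULT_MODEL = CrossSectionModel()

#: Low-energy tracking cutoff for CSDA transport, eV.
DEFAULT_CUTOFF_EV = 50.0


def screening_parameter(z: int, e_ev: float) -> float:
    """Dimensionless screening parameter alpha(Z, E)."""
    return 3.4e-3 * z**0.67 / (e_ev * 1e-3)


def _relativistic_factor(e_kev: float) -> float:
    r = (e_kev + 511.0) / (e_kev + 1024.0)
    return r * r


def total_elastic_xsection(
    z: int, e_ev: float, model: CrossSectionModel = DEFAULT_MODEL
) -> float:
    """Total elastic cross section sigma_el(Z, E) in nm^2.

    Closed form of the screened Rutherford differential cross section
    integrated over all solid angle; strictly decreasing in E and increasing
    in Z over the validity range.
    """
    if z < 1:
        raise ValueError(f"Z must be >= 1, got {z}")
    model.check_energy(e_ev)
    if z in model.overrides:
        e_tab, s_tab = model.overrides[z]
        return float(
            np.exp(np.interp(np.log(e_ev), np.log(e_tab), np.log(s_tab)))
        )
    e_kev = e_ev * 1e-3
    a = screening_parameter(z, e_ev)
    sigma = 5.21e-7 * (z * z) / (e_kev * e_kev) * _FOUR_PI / (a * (1.0 + a))
    if model.relativistic:
        sigma *= _relativistic_factor(e_kev)
    return sigma


def differential_elastic_xsection(
    z: int, e_ev: float, theta: float, model: CrossSectionModel = DEFAULT_MODEL
) -> float:
    """d(sigma)/d(Omega) in nm^2/sr at polar angle theta.

    Normalized so that its integral over the full sphere equals
    :func:`total_elastic_xsection`.
    """
    sigma = total_elastic_xsection(z, e_ev, model)
    a = screening_parameter(z, e_ev)
    norm = a * (1.0 + a) / math.pi
    return sigma * norm / (1.0 - math.cos(theta) + 2.0 * a) ** 2


def sample_scatter_angle(
    z: int, e_ev: float, u: float, model: CrossSectionModel = DEFAULT_MODEL
) -> float:
    """Polar scattering angle in [0, pi) from a uniform variate.

    Implements the closed-form inverse CDF of the screened Rutherford angular
    distribution: ``cos(theta) = 1 - 2 a u / (1 + a - u)``.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError(f"uniform variate must be in [0, 1), got {u}")
    a = screening_parameter(z, e_ev)
    cos_t = 1.0 - 2.0 * a * u / (1.0 + a - u)
    return math.acos(max(-1.0, min(1.0, cos_t)))


def elastic_mfp(
    material: Material, e_ev: float, model: CrossSectionModel = DEFAULT_MODEL
) -> float:
    """Elastic mean free path in nm: 1 / sum_i n_i sigma_el(Z_i, E)."""
    if material.density <= 0:
        raise DegenerateMaterialError(f"material {material.name!r} has no density")
    total = 0.0
    for el, n_i in material.element_number_densities():
        total += n_i * total_elastic_xsection(el.Z, e_ev, model)
    if total <= 0:
        raise DegenerateMaterialError(
            f"material {material.name!r} has zero scattering power"
        )
    return 1.0 / total


def joy_luo_k(z: int) -> float:
    """Low-energy correction factor in the modified Bethe formula."""
    return 0.734 * z**0.037


def stopping_power(
    material: Material, e_ev: float, cutoff_ev: float = DEFAULT_CUTOFF_EV
) -> float:
    """CSDA energy loss rate dE/ds in eV/nm (positive).

    Joy–Luo modified Bethe formula summed over elements:

        dE/ds = 7.85 * rho / E * sum_i c_i Z_i / A_i * ln(1.166 (E + k_i J_i) / J_i)

    with E, J in keV, rho in g/cm^3 and c_i mass fractions; the prefactor
    carries the unit conversion to eV/nm.
    """
    if e_ev < cutoff_ev:
        raise EnergyRangeError(
            f"E = {e_ev} eV below the low-energy tracking cutoff {cutoff_ev} eV"
        )
    e_kev = e_ev * 1e-3
    total = 0.0
    for el, c in material.mass_fractions():
        j_kev = el.J * 1e-3
        arg = 1.166 * (e_kev + joy_luo_k(el.Z) * j_kev) / j_kev
        if arg > 1.0:
            total += c * el.Z / el.A * math.log(arg)
    return 7.85 * material.density / e_kev * total


def haadf_partial_xsection(
    z: int,
    e0_ev: float = 300e3,
    theta_in: float = 0.040,
    theta_out: float = 0.200,
    model: CrossSectionModel = DEFAULT_MODEL,
) -> float:
    """Elastic cross section into an annular detector window, nm^2.

    Integral of d(sigma)/d(Omega) * 2 pi sin(theta) over [theta_in, theta_out]
    (closed form for the screened Rutherford shape).  Defaults are a 300 keV
    beam and a 40–200 mrad annular window; the detector's true angular range
    is instrument configuration and should come from config.
    """
    if not 0.0 < theta_in < theta_out:
        raise GeometryError(
            f"need 0 < theta_in < theta_out, got ({theta_in}, {theta_out})"
        )
    if theta_out > math.pi:
        raise GeometryError(f"theta_out must be <= pi, got {theta_out}")
    sigma = total_elastic_xsection(z, e0_ev, model)
    a = screening_parameter(z, e0_ev)
    m1 = 1.0 - math.cos(theta_in)
    m2 = 1.0 - math.cos(theta_out)
    # 2 sigma a (1+a) * [1/(m1+2a) - 1/(m2+2a)]
    return 2.0 * sigma * a * (1.0 + a) * (1.0 / (m1 + 2.0 * a) - 1.0 / (m2 + 2.0 * a))


def haadf_xsections(
    material: Material,
    e0_ev: float = 300e3,
    theta_in: float = 0.040,
    theta_out: float = 0.200,
    model: CrossSectionModel = DEFAULT_MODEL,
    extra_elements: tuple[str, ...] = ("Ga",),
) -> dict[str, float]:
    """Per-element annular partial cross sections for a material.

    Includes ``extra_elements`` (default Ga) so the same table can serve a
    forward model that *adds* an implanted element absent from the bulk.
    """
    from .materials import ElementSpec

    symbols = {el.symbol for el, _ in material.fractions} | set(extra_elements)
    return {
        s: haadf_partial_xsection(
            ElementSpec.from_symbol(s).Z, e0_ev, theta_in, theta_out, model
        )
        for s in sorted(symbols)
    }
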