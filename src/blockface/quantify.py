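"""Composition quantification: HAADF jump ratios, EELS core-loss edges,
atomic-ratio arithmetic, and the optimal-implant-Z rule of thumb.

HAADF forward model
-------------------
In the thin-specimen single-scattering regime the annular dark-field signal
per unit thickness is ``sum_i n_i sigma_i`` with ``sigma_i`` the elastic
cross section into the detector's angular window.  The *jump ratio* R of the
implanted surface layer relative to the resin interior is therefore a
function of the layer's composition alone (equal thickness and atom number
density assumed), and inverting it for the Ga content is a 1-D root-find on
a monotone function.  How much C and O survived the ion beam is unknowable
from R alone, so the loss assumption is a first-class input: the two printed
bracketing cases ship as presets (:data:`NO_LOSS`, :data:`HALF_C_NO_O`).

EELS quantification
-------------------
Standard core-loss procedure: power-law background ``A * E**-r`` fitted on a
pre-edge window, extrapolated and subtracted, net counts integrated over a
100-eV post-edge window.  The effective Ga-L2,3 cross section is calibrated
against a Ga2O3 reference of known 2:3 stoichiometry (a k-factor), and chained
to the C K edge through a configured sigma(O K)/sigma(C K) ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateMaterialError,
    NoSolutionError,
    QuantificationError,
)
from .materials import Material, add_element_fraction

# -- loss assumptions --------------------------------------------------------


@dataclass(frozen=True)
class LossAssumption:
    """Retained fractions of C and O in the implanted layer."""

    carbon_retained: float
    oxygen_retained: float
    label: str

    def __post_init__(self) -> None:
        for f in (self.carbon_retained, self.oxygen_retained):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"retained fractions must be in [0, 1], got {f}")


NO_LOSS = LossAssumption(1.0, 1.0, "no-loss")
HALF_C_NO_O = LossAssumption(0.5, 0.0, "half-C-no-O")

LOSS_PRESETS = {"no-loss": NO_LOSS, "half-C-no-O": HALF_C_NO_O}


def apply_loss(bulk: Material, assumption: LossAssumption) -> Material:
    """Deplete C and O per the assumption and renormalize fractions."""
    retain = {"C": assumption.carbon_retained, "O": assumption.oxygen_retained}
    weighted = {
        el.symbol: f * retain.get(el.symbol, 1.0) for el, f in bulk.fractions
    }
    weighted = {s: f for s, f in weighted.items() if f > 0}
    if not weighted:
        raise DegenerateMaterialError("loss assumption removed every atom")
    return Material.from_symbols(
        f"{bulk.name}[{assumption.label}]", weighted, bulk.density
    )


# -- results -----------------------------------------------------------------


@dataclass(frozen=True)
class QuantResult:
    """A Ga:C atomic ratio with its at.% conversion on the Ga+C basis."""

    ga_c_ratio: float
    assumption: LossAssumption
    method: str  # "haadf" | "eels"
    details: dict = field(default_factory=dict)

    @property
    def ga_atomic_percent(self) -> float:
        return ratio_to_atomic_percent(self.ga_c_ratio)


# -- ratio arithmetic --------------------------------------------------------


def ratio_to_atomic_percent(r: float) -> float:
    """Ga:C atomic ratio -> at.% Ga on the Ga+C basis: 100 r / (1 + r)."""
    if r < 0:
        raise ValueError(f"atomic ratio must be nonnegative, got {r}")
    return 100.0 * r / (1.0 + r)


def atomic_percent_to_ratio(p: float) -> float:
    """Inverse of :func:`ratio_to_atomic_percent`."""
    if not 0.0 <= p < 100.0:
        raise ValueError(f"atomic percent must be in [0, 100), got {p}")
    return p / (100.0 - p)


def optimal_implant_z(z_org: float, z_stain: float) -> float:
    """Optimal implanted-ion atomic number: geometric mean of the light-matrix
    and stain atomic numbers, sqrt(Z_org * Z_stain)."""
    if z_org <= 0 or z_stain <= 0:
        raise ValueError(f"atomic numbers must be positive, got ({z_org}, {z_stain})")
    return math.sqrt(z_org * z_stain)


# -- HAADF -------------------------------------------------------------------


def haadf_intensity(material: Material, xs: dict[str, float]) -> float:
    """Relative HAADF signal per unit thickness: sum_i n_i sigma_i (nm^-1 scale).

    ``xs`` maps element symbols to annular partial cross sections (nm^2), e.g.
    from :func:`blockface.xsections.haadf_xsections`.  H is included — its
    tiny cross section, not an exclusion rule, is what makes the detector
    blind to it.
    """
    total = 0.0
    for el, n_i in material.element_number_densities():
        if el.symbol not in xs:
            raise ConfigError(
                f"no HAADF cross section configured for element {el.symbol!r}"
            )
        total += n_i * xs[el.symbol]
    return total


def jump_ratio(surface: Material, bulk: Material, xs: dict[str, float]) -> float:
    """Peak-to-plateau HAADF ratio R = I(surface)/I(bulk), equal thickness."""
    denom = haadf_intensity(bulk, xs)
    if denom <= 0:
        raise DegenerateMaterialError("bulk HAADF signal is zero")
    return haadf_intensity(surface, xs) / denom


def surface_material(bulk: Material, ga_fraction: float, assumption: LossAssumption) -> Material:
    """The implanted-layer composition model: C/O-depleted bulk plus Ga at
    atomic fraction ``ga_fraction`` (constant atom number density)."""
    return add_element_fraction(apply_loss(bulk, assumption), "Ga", ga_fraction)


def invert_jump_ratio(
    r: float,
    bulk: Material,
    assumption: LossAssumption = NO_LOSS,
    xs: dict[str, float] | None = None,
    tol: float = 1e-9,
) -> QuantResult:
    """Solve the forward jump-ratio model for the Ga atomic fraction.

    Bisection on the monotone map x -> R(surface(x)); returns the Ga:C atomic
    ratio of the recovered surface composition and its at.% conversion.
    """
    if xs is None:
        from .xsections import haadf_xsections

        xs = haadf_xsections(bulk)
    if r < 1.0:
        raise NoSolutionError(
            f"jump ratio {r} < 1 has no Ga-enriched surface solution"
        )
    lo, hi = 0.0, 1.0 - 1e-9
    r_hi = jump_ratio(surface_material(bulk, hi, assumption), bulk, xs)
    if r > r_hi:
        raise NoSolutionError(
            f"jump ratio {r} exceeds the pure-Ga limit {r_hi:.3g}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if jump_ratio(surface_material(bulk, mid, assumption), bulk, xs) < r:
            lo = mid
        else:
            hi = mid
    x = 0.5 * (lo + hi)
    surf = surface_material(bulk, x, assumption)
    f_c = surf.fraction_of("C")
    if f_c <= 0:
        raise QuantificationError("surface model retains no carbon; Ga:C undefined")
    ratio = surf.fraction_of("Ga") / f_c
    return QuantResult(
        ratio,
        assumption,
        "haadf",
        {"ga_fraction": x, "jump_ratio": r, "surface": surf.as_dict()},
    )


# -- EELS --------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """A 1-D energy-loss spectrum: channel energies (eV) and counts."""

    energy: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy", np.asarray(self.energy, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        if self.energy.shape != self.counts.shape or self.energy.ndim != 1:
            raise ValueError("energy and counts must be 1-D arrays of equal length")
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy axis must be strictly increasing")


#: Core-loss edge onsets used throughout, eV.
EDGE_ONSETS = {"C_K": 284.0, "O_K": 532.0, "Ga_L23": 1140.0}

#: Integration window width for all inner-shell edges, eV.
EDGE_WINDOW_EV = 100.0


@dataclass
class BackgroundFit:
    """Power-law background fit diagnostics."""

    amplitude: float  # A in A * E**-r
    exponent: float  # r
    window: tuple[float, float]
    net: np.ndarray  # background-subtracted counts over the full axis
    residual_trend_p: float  # p-value of residual lag-1 autocorrelation in window
    contaminated: bool  # True when the fit window likely contains an edge


def eels_background_subtract(
    spectrum: Spectrum,
    fit_window: tuple[float, float],
    floor: float | None = None,
    trend_alpha: float = 0.01,
) -> BackgroundFit:
    """Fit A * E**-r on a pre-edge window and subtract the extrapolation.

    The fit is linear least squares in log-log space.  Significant lag-1
    autocorrelation of the fit residuals inside the window flags
    contamination (an edge onset inside the supposed background window
    leaves a systematic, serially correlated misfit, whereas pure shot noise
    leaves white residuals).
    """
    lo, hi = fit_window
    e, c = spectrum.energy, spectrum.counts
    if lo < e[0] or hi > e[-1] or lo >= hi:
        raise QuantificationError(
            f"fit window ({lo}, {hi}) outside spectrum range ({e[0]}, {e[-1]})"
        )
    mask = (e >= lo) & (e <= hi) & (c > 0)
    if mask.sum() < 4:
        raise QuantificationError(
            f"no usable (positive) counts in fit window ({lo}, {hi})"
        )
    x = np.log(e[mask])
    y = np.log(c[mask])
    slope, intercept = np.polyfit(x, y, 1)
    a = math.exp(intercept)
    r = -slope
    bg = a * e ** (-r)
    resid = y - (intercept + slope * x)
    rho = float(np.corrcoef(resid[:-1], resid[1:])[0, 1]) if resid.size > 4 else 0.0
    p_auto = float(stats.norm.sf(rho * math.sqrt(resid.size)))  # one-sided
    net = c - bg
    if floor is not None:
        net = np.maximum(net, floor)
    return BackgroundFit(
        a,
        r,
        (lo, hi),
        net,
        p_auto,
        bool(p_auto < trend_alpha),
    )


def edge_integral(
    spectrum: Spectrum,
    onset_ev: float,
    fit_window: tuple[float, float] | None = None,
    width_ev: float = EDGE_WINDOW_EV,
) -> tuple[float, BackgroundFit]:
    """Background-subtracted edge counts integrated over [onset, onset+width].

    Default fit window: the 100 eV immediately before the onset.
    """
    if fit_window is None:
        fit_window = (
            max(onset_ev - width_ev, float(spectrum.energy[0])),
            onset_ev - 2.0,
        )
    fit = eels_background_subtract(spectrum, fit_window)
    e = spectrum.energy
    mask = (e >= onset_ev) & (e < onset_ev + width_ev)
    if not mask.any():
        raise QuantificationError(f"edge onset {onset_ev} eV outside spectrum")
    return float(fit.net[mask].sum()), fit


def kfactor_from_integrals(i_ga: float, i_o: float) -> float:
    """k = [I(Ga L)/I(O K)] * (N_O/N_Ga) for a Ga2O3 standard (N_O/N_Ga = 3/2)."""
    if i_ga <= 0 or i_o <= 0:
        raise QuantificationError(
            f"nonpositive edge integrals (Ga L: {i_ga}, O K: {i_o})"
        )
    return (i_ga / i_o) * 1.5


def eels_kfactor_from_reference(
    reference: Spectrum,
    ga_onset: float = EDGE_ONSETS["Ga_L23"],
    o_onset: float = EDGE_ONSETS["O_K"],
    width_ev: float = EDGE_WINDOW_EV,
) -> float:
    """Effective sigma(Ga L2,3)/sigma(O K) ratio from a Ga2O3 reference."""
    i_ga, _ = edge_integral(reference, ga_onset, width_ev=width_ev)
    i_o, _ = edge_integral(reference, o_onset, width_ev=width_ev)
    return kfactor_from_integrals(i_ga, i_o)


def eels_ga_c_ratio(
    spectrum: Spectrum,
    k: float,
    sigma_ok_over_ck: float,
    ga_onset: float = EDGE_ONSETS["Ga_L23"],
    c_onset: float = EDGE_ONSETS["C_K"],
    width_ev: float = EDGE_WINDOW_EV,
    assumption: LossAssumption = NO_LOSS,
) -> QuantResult:
    """Ga:C atomic ratio of a specimen spectrum.

    The reference-derived k expresses sigma(Ga L) in units of sigma(O K);
    multiplying by the configured sigma(O K)/sigma(C K) re-expresses it in
    units of sigma(C K), so

        N_Ga / N_C = [I(Ga L) / I(C K)] / [k * sigma_OK/CK].
    """
    if k <= 0 or sigma_ok_over_ck <= 0:
        raise QuantificationError("k-factor and cross-section ratio must be positive")
    i_ga, _ = edge_integral(spectrum, ga_onset, width_ev=width_ev)
    i_c, fit_c = edge_integral(spectrum, c_onset, width_ev=width_ev)
    if i_c <= 0:
        raise QuantificationError(f"nonpositive C K edge integral {i_c}")
    ratio = max((i_ga / i_c) / (k * sigma_ok_over_ck), 0.0)
    return QuantResult(
        ratio,
        assumption,
        "eels",
        {"i_ga": i_ga, "i_c": i_c, "k": k, "sigma_ok_over_ck": sigma_ok_over_ck},
    )
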