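"""Composition arithmetic, jump-ratio forward/inverse model, and the EELS
quantification chain on synthetic spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blockface as bf
from blockface.errors import (
    ConfigError,
    NoSolutionError,
    QuantificationError,
)
from blockface.materials import Material
from blockface.phantoms import synth_eels_spectrum
from blockface.quantify import (
    HALF_C_NO_O,
    NO_LOSS,
    apply_loss,
    atomic_percent_to_ratio,
    eels_background_subtract,
    eels_ga_c_ratio,
    eels_kfactor_from_reference,
    edge_integral,
    haadf_intensity,
    invert_jump_ratio,
    jump_ratio,
    kfactor_from_integrals,
    optimal_implant_z,
    ratio_to_atomic_percent,
    surface_material,
)
from blockface.xsections import haadf_xsections


# -- ratio arithmetic --------------------------------------------------------


@pytest.mark.parametrize(
    "ratio,percent",
    [(0.38, 28.0), (0.86, 46.0), (0.117, 10.5), (0.185, 15.6), (0.46, 31.5)],
)
def test_printed_ratio_percent_pairs(ratio, percent):
    """The five published Ga:C ratio -> at.% conversions, to their printed
    precision."""
    got = ratio_to_atomic_percent(ratio)
    decimals = 1 if percent % 1 else 0
    assert round(got, decimals) == pytest.approx(percent)


def test_ratio_percent_special_values():
    assert ratio_to_atomic_percent(0.0) == 0.0
    assert ratio_to_atomic_percent(1.0) == 50.0
    with pytest.raises(ValueError):
        ratio_to_atomic_percent(-0.1)


@settings(derandomize=True, max_examples=100)
@given(r=st.floats(0.0, 10.0))
def test_ratio_percent_roundtrip(r):
    assert atomic_percent_to_ratio(ratio_to_atomic_percent(r)) == pytest.approx(
        r, abs=1e-12
    )


def test_optimal_implant_z():
    assert round(optimal_implant_z(7, 82)) == 24
    assert optimal_implant_z(7, 82) == pytest.approx(math.sqrt(574))
    assert optimal_implant_z(5.5, 5.5) == 5.5
    assert optimal_implant_z(4, 64) == 16.0
    with pytest.raises(ValueError):
        optimal_implant_z(0, 82)


# -- HAADF forward model -----------------------------------------------------


@pytest.fixture(scope="module")
def xs(epon):
    return haadf_xsections(epon)


def test_haadf_intensity_linear(epon, xs):
    carbon = Material.from_symbols("C", {"C": 1.0}, 2.0)
    xs_c = {"C": xs["C"]}
    assert haadf_intensity(carbon, xs_c) == pytest.approx(
        carbon.number_density * xs["C"]
    )
    half = Material.from_symbols("C", {"C": 1.0}, 1.0)
    assert haadf_intensity(half, xs_c) == pytest.approx(
        haadf_intensity(carbon, xs_c) / 2
    )
    with pytest.raises(ConfigError):
        haadf_intensity(epon, {"C": 1.0})  # missing H/N/O entries


def test_ga_brightens_haadf(epon, xs):
    surf = surface_material(epon, atomic_percent_to_ratio(28.0) * 0.54, NO_LOSS)
    assert haadf_intensity(surf, xs) / haadf_intensity(epon, xs) > 1.0


def test_jump_ratio_properties(epon, xs):
    assert jump_ratio(epon, epon, xs) == pytest.approx(1.0)
    # invariant under a common density rescale of both materials
    epon2 = Material("epon2", epon.fractions, epon.density * 2)
    surf = surface_material(epon, 0.2, NO_LOSS)
    surf2 = Material(surf.name, surf.fractions, surf.density * 2)
    assert jump_ratio(surf2, epon2, xs) == pytest.approx(
        jump_ratio(surf, epon, xs), rel=1e-12
    )


def test_loss_assumption_depletes_and_renormalizes(epon):
    lost = apply_loss(epon, HALF_C_NO_O)
    assert lost.fraction_of("O") == 0.0
    total = sum(f for _, f in lost.fractions)
    assert total == pytest.approx(1.0, abs=1e-9)
    # C:H ratio halves relative to the intact resin
    assert lost.fraction_of("C") / lost.fraction_of("H") == pytest.approx(
        0.5 * 0.54 / 0.36
    )


@pytest.mark.parametrize("assumption", [NO_LOSS, HALF_C_NO_O])
@pytest.mark.parametrize("x_true", [0.1, 0.3, 0.5, 0.6])
def test_jump_ratio_inversion_roundtrip(epon, xs, assumption, x_true):
    """invert(forward(x)) = x to 1e-6 for both printed loss assumptions."""
    r = jump_ratio(surface_material(epon, x_true, assumption), epon, xs)
    res = invert_jump_ratio(r, epon, assumption, xs)
    assert res.details["ga_fraction"] == pytest.approx(x_true, abs=1e-6)
    # and the forward model reproduces the measured R
    r_back = jump_ratio(
        surface_material(epon, res.details["ga_fraction"], assumption), epon, xs
    )
    assert r_back == pytest.approx(r, abs=1e-6)


def test_inversion_edge_cases(epon, xs):
    res = invert_jump_ratio(1.0, epon, NO_LOSS, xs)
    assert res.ga_c_ratio == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(NoSolutionError):
        invert_jump_ratio(0.8, epon, NO_LOSS, xs)
    with pytest.raises(NoSolutionError):
        invert_jump_ratio(1e9, epon, NO_LOSS, xs)


def test_inferred_ga_increasing_in_r(epon, xs):
    percents = [
        invert_jump_ratio(r, epon, NO_LOSS, xs).ga_atomic_percent
        for r in (1.5, 2.5, 3.9, 6.0)
    ]
    assert all(a < b for a, b in zip(percents, percents[1:]))


def test_quantresult_percent_invariant(epon, xs):
    res = invert_jump_ratio(3.9, epon, NO_LOSS, xs)
    r = res.ga_c_ratio
    assert res.ga_atomic_percent == pytest.approx(100 * r / (1 + r), abs=1e-9)
    assert res.ga_c_ratio > 0


# -- EELS --------------------------------------------------------------------


def test_background_subtract_pure_powerlaw():
    spec = synth_eels_spectrum({}, sigmas={}, background=(1.0, 3.0), dose=1e5, seed=9)
    fit = eels_background_subtract(spec, (220.0, 320.0))
    post = (spec.energy > 320) & (spec.energy < 700)
    net = fit.net[post]
    sigma_poisson = np.sqrt(spec.counts[post]).mean()
    assert abs(net.mean()) < 2 * sigma_poisson
    assert not fit.contaminated
    assert fit.exponent == pytest.approx(3.0, abs=0.1)


def test_background_fit_flags_contaminated_window():
    spec = synth_eels_spectrum(
        {"C": 5.0}, sigmas={"C": 100.0}, background=(1.0, 3.0), dose=1e5, seed=10
    )
    fit = eels_background_subtract(spec, (240.0, 340.0))  # contains the C K onset
    assert fit.contaminated


def test_edge_recovery_at_high_dose():
    spec = synth_eels_spectrum(
        {"C": 1.0, "O": 0.5},
        sigmas={"C": 30.0, "O": 20.0},
        background=(1.0, 3.0),
        dose=1e6,
        seed=11,
    )
    i_c, _ = edge_integral(spec, 284.0)
    assert i_c == pytest.approx(1.0 * 30.0 * 1e6, rel=0.05)


def test_kfactor_arithmetic_and_roundtrip():
    assert kfactor_from_integrals(1.0, 1.0) == 1.5
    with pytest.raises(QuantificationError):
        kfactor_from_integrals(0.0, 1.0)
    # Ga2O3 reference generated with sigma(Ga L)/sigma(O K) = 0.2
    ref = synth_eels_spectrum(
        {"O": 0.6, "Ga": 0.4},
        sigmas={"O": 100.0, "Ga": 20.0},
        background=(1.0, 3.0),
        dose=1e6,
        seed=12,
    )
    k = eels_kfactor_from_reference(ref)
    assert k == pytest.approx(0.2, rel=0.05)


def test_kfactor_variance_shrinks_with_dose():
    ks = {dose: [] for dose in (1e4, 1e6)}
    for dose in ks:
        for seed in range(8):
            ref = synth_eels_spectrum(
                {"O": 0.6, "Ga": 0.4},
                sigmas={"O": 100.0, "Ga": 20.0},
                background=(1.0, 3.0),
                dose=dose,
                seed=100 + seed,
            )
            ks[dose].append(eels_kfactor_from_reference(ref))
    v_lo, v_hi = np.var(ks[1e4]), np.var(ks[1e6])
    assert v_hi < v_lo / 10  # ~x100 dose -> ~x100 variance


def _specimen(ratio, dose, seed, sigma_ok_over_ck=0.4, sigma_ck=60.0):
    """Self-consistent synthetic specimen + reference + configured ratios."""
    sigma_ok = sigma_ok_over_ck * sigma_ck
    sigma_ga = 0.25 * sigma_ok  # true k = 0.25
    spec = synth_eels_spectrum(
        {"C": 1.0, "O": 0.2, "Ga": ratio},
        sigmas={"C": sigma_ck, "O": sigma_ok, "Ga": sigma_ga},
        background=(1.0, 3.0),
        dose=dose,
        seed=seed,
    )
    ref = synth_eels_spectrum(
        {"O": 0.6, "Ga": 0.4},
        sigmas={"O": sigma_ok, "Ga": sigma_ga},
        background=(1.0, 3.0),
        dose=dose,
        seed=seed + 5000,
    )
    return spec, ref, sigma_ok_over_ck


def test_eels_ga_c_ratio_recovery():
    """Round trip at the published ratio scale: recovered Ga:C within the
    paper-scale +-0.012 of the configured 0.117."""
    spec, ref, s_ok_ck = _specimen(0.117, dose=2e5, seed=21)
    k = eels_kfactor_from_reference(ref)
    res = eels_ga_c_ratio(spec, k, s_ok_ck)
    assert res.ga_c_ratio == pytest.approx(0.117, abs=0.012)
    assert res.method == "eels"


def test_eels_ga_free_specimen():
    spec, ref, s_ok_ck = _specimen(0.0, dose=2e5, seed=22)
    k = eels_kfactor_from_reference(ref)
    res = eels_ga_c_ratio(spec, k, s_ok_ck)
    assert abs(res.ga_c_ratio) < 0.01


def test_eels_mean_recovery_over_seeds():
    """Over 20 seeded spectra at the measurement-like dose, the mean
    recovered Ga:C is within 5% of truth and region-averaging shrinks the
    standard error ~ sqrt(10)."""
    vals = []
    for seed in range(20):
        spec, ref, s_ok_ck = _specimen(0.117, dose=2e5, seed=300 + seed)
        k = eels_kfactor_from_reference(ref)
        vals.append(eels_ga_c_ratio(spec, k, s_ok_ck).ga_c_ratio)
    vals = np.asarray(vals)
    assert vals.mean() == pytest.approx(0.117, rel=0.05)
    sem10 = vals.std(ddof=1) / math.sqrt(10)
    assert sem10 < vals.std(ddof=1) / 3  # averaging 10 regions ~ sqrt(10) gain
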