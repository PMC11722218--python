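"""Monte Carlo transport: oracle cross-check, reproducibility, and the
Ga-implantation mechanism (shallower backscatter generation depths)."""

import math

import numpy as np
import pytest

import blockface as bf
from blockface.errors import EmptyDistributionError
from blockface.materials import Material
from blockface.mc import (
    ElectronState,
    HalfSpace,
    SimConfig,
    backscatter_coefficient,
    escape_depth_distribution,
    simulate_trajectory,
    trace_ensemble,
)

# ---------------------------------------------------------------------------
# Independent oracle: an array-at-a-time transport re-implementation for a
# homogeneous half-space.  Same physics, written from the formulas, sharing
# no code with the numba kernels.
# ---------------------------------------------------------------------------


def _oracle_eta(material, e0, n, seed, cutoff=50.0):
    dens = material.element_number_densities()
    zs = np.array([el.Z for el, _ in dens], float)
    ni = np.array([nd for _, nd in dens], float)
    mf = material.mass_fractions()
    czoa = np.array([c * el.Z / el.A for el, c in mf], float)
    j_kev = np.array([el.J * 1e-3 for el, _ in mf], float)
    kj = 0.734 * zs**0.037 * j_kev
    rng = np.random.default_rng(seed)

    def sigma(e_kev):  # (n_alive, n_elements)
        a = 3.4e-3 * zs[None, :] ** 0.67 / e_kev[:, None]
        rel = ((e_kev + 511.0) / (e_kev + 1024.0)) ** 2
        return (
            5.21e-7
            * zs[None, :] ** 2
            / e_kev[:, None] ** 2
            * 4
            * math.pi
            / (a * (1 + a))
            * rel[:, None]
        )

    def stop(e_kev):  # eV/nm
        arg = 1.166 * (e_kev[:, None] + kj[None, :]) / j_kev[None, :]
        terms = np.where(arg > 1.0, czoa[None, :] * np.log(np.maximum(arg, 1.0)), 0.0)
        return 7.85 * material.density / e_kev * terms.sum(axis=1)

    z = np.zeros(n)
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    e = np.full(n, float(e0))
    alive = np.ones(n, bool)
    back = np.zeros(n, bool)
    while alive.any():
        idx = np.nonzero(alive)[0]
        e_kev = e[idx] * 1e-3
        sig = sigma(e_kev)
        inv = (ni[None, :] * sig).sum(axis=1)
        lam = 1.0 / inv
        s = -lam * np.log(1.0 - rng.random(idx.size))
        dz = d[idx, 2]
        t_surf = np.where(dz < -1e-12, -z[idx] / dz, np.inf)
        de = stop(e_kev)
        budget = (e[idx] - cutoff) / de
        # who escapes: reaches the surface before scattering and before the
        # CSDA energy budget runs out
        esc = (t_surf < s) & (t_surf < budget)
        back[idx[esc]] = True
        alive[idx[esc]] = False
        # who dies mid-flight
        die = ~esc & (budget <= np.minimum(s, t_surf))
        alive[idx[die]] = False
        # survivors scatter at distance s
        sv = ~esc & ~die
        j = idx[sv]
        z[j] += d[j, 2] * s[sv]
        e[j] -= de[sv] * s[sv]
        # element choice ~ n_i sigma_i
        w = (ni[None, :] * sig[sv]) / inv[sv, None]
        cw = np.cumsum(w, axis=1)
        pick = (rng.random(j.size)[:, None] > cw).sum(axis=1).clip(0, zs.size - 1)
        a = 3.4e-3 * zs[pick] ** 0.67 / (e[j] * 1e-3)
        u = rng.random(j.size)
        ct = 1.0 - 2.0 * a * u / (1.0 + a - u)
        st = np.sqrt(np.clip(1 - ct**2, 0, 1))
        phi = 2 * np.pi * rng.random(j.size)
        cp, sp = np.cos(phi), np.sin(phi)
        dx, dy, dzv = d[j, 0], d[j, 1], d[j, 2]
        den = np.sqrt(np.clip(1 - dzv**2, 1e-12, None))
        polar = np.abs(dzv) > 0.999999
        nx = np.where(
            polar, st * cp, dx * ct + st * (dx * dzv * cp - dy * sp) / den
        )
        ny = np.where(
            polar, st * sp, dy * ct + st * (dy * dzv * cp + dx * sp) / den
        )
        nz = np.where(polar, ct * np.sign(dzv), dzv * ct - st * cp * den)
        norm = np.sqrt(nx**2 + ny**2 + nz**2)
        d[j, 0], d[j, 1], d[j, 2] = nx / norm, ny / norm, nz / norm
    return back.mean()


def test_backscatter_fraction_matches_oracle():
    """Kernel eta for bulk carbon at 1.5 keV agrees with the independent
    array-transport oracle within 3 combined standard errors."""
    carbon = Material.from_symbols("C", {"C": 1.0}, 2.0)
    n = 30_000
    res = backscatter_coefficient(carbon, 1500.0, n, seed=7)
    eta_oracle = _oracle_eta(carbon, 1500.0, n, seed=13)
    se = math.sqrt(2) * math.sqrt(res.coefficient * (1 - res.coefficient) / n)
    assert abs(res.coefficient - eta_oracle) < 3 * se


# ---------------------------------------------------------------------------


def test_trajectory_below_cutoff_absorbed(epon, rng):
    out = simulate_trajectory(
        ElectronState((0, 0, 0), (0, 0, 1), 40.0), HalfSpace(epon), SimConfig(), rng
    )
    assert out.fate == "absorbed"
    assert out.n_steps == 0


def test_trajectory_through_near_vacuum(rng):
    thin_air = Material.from_symbols("air", {"N": 1.0}, 1e-9)
    out = simulate_trajectory(
        ElectronState((0, 0, 0), (0, 0, 1), 1500.0),
        HalfSpace(thin_air, thickness=100.0),
        SimConfig(),
        rng,
    )
    assert out.fate == "transmitted"
    assert out.exit_energy == pytest.approx(1500.0, rel=1e-3)


def test_energy_non_increasing_along_paths(epon, rng):
    for _ in range(25):
        out = simulate_trajectory(
            ElectronState((0, 0, 0), (0, 0, 1), 1500.0),
            HalfSpace(epon),
            SimConfig(),
            rng,
            record_path=True,
        )
        energies = [p[3] for p in out.path]
        assert all(a >= b for a, b in zip(energies, energies[1:]))
        assert out.exit_energy <= 1500.0
        assert out.max_depth >= 0.0


def test_seeded_runs_are_bit_reproducible(epon):
    a = backscatter_coefficient(epon, 1500.0, 5000, seed=99)
    b = backscatter_coefficient(epon, 1500.0, 5000, seed=99)
    assert a.n_backscattered == b.n_backscattered
    c = backscatter_coefficient(epon, 1500.0, 5000, seed=100)
    assert c.n_backscattered != a.n_backscattered


def test_backscatter_increases_with_ga(epon, ga25, ga50):
    """eta rises with the mean atomic number of the matrix (3 sigma)."""
    n = 20_000
    etas = []
    for i, m in enumerate((epon, ga25, ga50)):
        r = backscatter_coefficient(m, 1500.0, n, seed=50 + i)
        assert 0.0 <= r.coefficient <= 1.0
        etas.append(r)
    for lo, hi in zip(etas, etas[1:]):
        sep = (hi.coefficient - lo.coefficient) / math.hypot(lo.stderr, hi.stderr)
        assert sep > 3.0


def test_escape_depth_shallower_with_ga(epon, ga50):
    d_epon = escape_depth_distribution(epon, SimConfig(seed=5), n_traj=20_000)
    d_ga = escape_depth_distribution(ga50, SimConfig(seed=5), n_traj=20_000)
    assert d_epon.median > d_ga.median
    assert d_epon.p90 > d_ga.p90
    assert d_epon.counts.sum() == d_epon.depths.size


def test_escape_depth_grows_with_beam_energy(epon):
    d15 = escape_depth_distribution(
        epon, SimConfig(beam_energy_ev=1500.0, seed=6), n_traj=20_000
    )
    d30 = escape_depth_distribution(
        epon, SimConfig(beam_energy_ev=3000.0, seed=6), n_traj=20_000
    )
    assert d30.p90 > d15.p90


def test_escape_depth_empty_when_nothing_escapes(epon):
    # a thin near-vacuum film transmits everything: no backscatter at all
    thin_air = Material.from_symbols("air", {"N": 1.0}, 1e-9)
    with pytest.raises(EmptyDistributionError):
        escape_depth_distribution(
            HalfSpace(thin_air, thickness=10.0), SimConfig(seed=1), n_traj=10_000
        )


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(beam_energy_ev=40.0, cutoff_ev=50.0)
    with pytest.raises(ValueError):
        SimConfig(trajectories_per_pixel=0)
    with pytest.raises(ValueError):
        backscatter_coefficient(bf.epon_araldite(), 1500.0, 50, seed=1)
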