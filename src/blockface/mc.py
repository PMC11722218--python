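"""Single-scattering Monte Carlo transport of low-keV electrons.

Two code paths share the same physics (:mod:`blockface.xsections`):

* :func:`simulate_trajectory` — a readable pure-Python trajectory with
  optional path recording, used for diagnostics and per-event work;
* the numba kernels in :mod:`blockface._kernels` — the vectorized path behind
  :func:`backscatter_coefficient`, :func:`escape_depth_distribution` and image
  rendering.

Both alternate exponential free flights with the local elastic mean free
path, continuous (Joy–Luo CSDA) energy loss along each flight, and screened
Rutherford deflections with uniform azimuth; flights are truncated at
material boundaries and resampled in the new material.  A trajectory ends
backscattered when it crosses z = 0 moving outward, absorbed when its energy
falls to the tracking cutoff, or transmitted past a thin phantom's far face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels
from .errors import EmptyDistributionError
from .materials import Material
from .xsections import (
    DEFAULT_CUTOFF_EV,
    elastic_mfp,
    sample_scatter_angle,
    stopping_power,
    total_elastic_xsection,
)

_BIG = 1e30


@dataclass
class SimConfig:
    """Beam and run settings for trajectory simulation.

    Defaults mirror typical FIB-SEM block-face imaging: a 1.5 keV beam and
    3000 trajectories per pixel at normal incidence.
    """

    beam_energy_ev: float = 1500.0
    trajectories_per_pixel: int = 3000
    cutoff_ev: float = DEFAULT_CUTOFF_EV
    seed: int = 0
    incidence_polar: float = 0.0  # rad from the inward surface normal

    def __post_init__(self) -> None:
        if not self.beam_energy_ev > self.cutoff_ev > 0:
            raise ValueError(
                "need beam energy > cutoff > 0, got "
                f"({self.beam_energy_ev}, {self.cutoff_ev})"
            )
        if self.trajectories_per_pixel < 1:
            raise ValueError("trajectories per pixel must be >= 1")

    def beam_direction(self) -> np.ndarray:
        t = self.incidence_polar
        return np.array([math.sin(t), 0.0, math.cos(t)])


@dataclass
class ElectronState:
    position: np.ndarray  # (x, y, z) nm
    direction: np.ndarray  # unit vector
    energy: float  # eV

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.direction = np.asarray(self.direction, float)
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {n}")
        if self.energy < 0:
            raise ValueError("energy must be nonnegative")


@dataclass
class TrajectoryOutcome:
    fate: str  # "backscattered" | "absorbed" | "transmitted"
    exit_energy: float
    exit_direction: np.ndarray
    max_depth: float
    n_steps: int
    path: list | None = None  # [(x, y, z, E), ...] when recorded


class KernelGeometry(NamedTuple):
    """Array form of a phantom for the numba kernels."""

    geom_mode: int  # 1 analytic boxes, 2 voxel grid
    boxes: np.ndarray  # (B, 7): x0 x1 y0 y1 z0 z1 material-index
    matrix_idx: int
    zmax: float
    vox: np.ndarray  # (nx, ny, nz) int64 material indices
    vx0: float
    vy0: float
    vh: float
    materials: tuple[Material, ...]


_DUMMY_VOX = np.zeros((1, 1, 1), np.int64)
_NO_BOXES = np.zeros((0, 7), np.float64)


class HalfSpace:
    """A semi-infinite homogeneous specimen: the simplest phantom."""

    def __init__(self, material: Material, thickness: float = math.inf):
        self.material = material
        self.zmax = thickness

    def material_at(self, x: float, y: float, z: float) -> Material:
        return self.material

    def distance_to_boundary(self, pos, direction) -> float:
        t = _BIG
        if direction[2] < -1e-12:
            t = min(t, -pos[2] / direction[2])
        if direction[2] > 1e-12 and self.zmax < _BIG:
            t = min(t, (self.zmax - pos[2]) / direction[2])
        return t

    def kernel_geometry(self) -> KernelGeometry:
        return KernelGeometry(
            1, _NO_BOXES, 0, min(self.zmax, _BIG), _DUMMY_VOX, 0.0, 0.0, 1.0,
            (self.material,),
        )


#: Log-energy tabulation grid for the kernels, eV.
_TAB_E_MIN = 45.0
_TAB_E_MAX = 305_000.0
_TAB_N = 1024


def pack_materials(materials) -> tuple:
    """Pack materials into the arrays the transport kernels read.

    Scattering-element selection uses the closed forms via ``alpha`` (where
    ``alpha[i, k] / E_keV`` is the screening parameter) and
    ``q[i, k] = n_k * 5.21e-7 * Z_k**2 * 4 pi``; inverse mean free paths and
    stopping powers are tabulated per material on a shared log-energy grid
    (computed from :mod:`blockface.xsections`, so both code paths share one
    set of physics functions) and interpolated in the kernel.
    """
    m = len(materials)
    k = max(len(mat.fractions) for mat in materials)
    nel = np.zeros(m, np.int64)
    alpha = np.ones((m, k), np.float64)
    q = np.zeros((m, k), np.float64)
    for i, mat in enumerate(materials):
        nel[i] = len(mat.fractions)
        for j, (el, n_i) in enumerate(mat.element_number_densities()):
            alpha[i, j] = 3.4e-3 * el.Z**0.67
            q[i, j] = n_i * 5.21e-7 * el.Z**2 * 4.0 * math.pi
    e_grid = np.geomspace(_TAB_E_MIN, _TAB_E_MAX, _TAB_N)
    inv_tab = np.zeros((m, _TAB_N), np.float64)
    stop_tab = np.zeros((m, _TAB_N), np.float64)
    from .xsections import CrossSectionModel

    wide = CrossSectionModel(e_min=_TAB_E_MIN, e_max=_TAB_E_MAX)
    for i, mat in enumerate(materials):
        for j, e in enumerate(e_grid):
            inv_tab[i, j] = 1.0 / elastic_mfp(mat, e, wide)
            stop_tab[i, j] = stopping_power(mat, e, cutoff_ev=_TAB_E_MIN)
    loge0 = math.log(_TAB_E_MIN)
    inv_dloge = (_TAB_N - 1) / (math.log(_TAB_E_MAX) - loge0)
    return nel, alpha, q, loge0, inv_dloge, inv_tab, stop_tab


def _kernel_args(target):
    geom = target.kernel_geometry()
    mats = pack_materials(geom.materials)
    return geom, mats


def _run_batch(target, e0_ev, n_traj, seed, cutoff_ev, direction=(0.0, 0.0, 1.0)):
    geom, mats = _kernel_args(target)
    dx, dy, dz = direction
    return _kernels.trace_batch(
        int(n_traj),
        0.0,
        0.0,
        float(dx),
        float(dy),
        float(dz),
        float(e0_ev),
        float(cutoff_ev),
        geom.geom_mode,
        geom.boxes,
        geom.matrix_idx,
        float(geom.zmax),
        geom.vox,
        geom.vx0,
        geom.vy0,
        geom.vh,
        *mats,
        int(seed) & 0x7FFFFFFF,
    )


def trace_ensemble(
    target,
    e0_ev: float = 1500.0,
    n_traj: int = 10_000,
    seed: int = 0,
    cutoff_ev: float = DEFAULT_CUTOFF_EV,
    direction=(0.0, 0.0, 1.0),
):
    """Trace many trajectories from the origin of ``target``'s surface.

    Returns ``(fates, exit_energy, exit_dir_z, max_depth)`` arrays; fate codes
    0 absorbed, 1 backscattered, 2 transmitted.  ``target`` is a material (a
    semi-infinite slab is assumed) or any phantom exposing
    ``kernel_geometry()``.
    """
    if isinstance(target, Material):
        target = HalfSpace(target)
    return _run_batch(target, e0_ev, n_traj, seed, cutoff_ev, direction)


@dataclass
class BackscatterResult:
    coefficient: float
    stderr: float
    n_backscattered: int
    n_trajectories: int


def backscatter_coefficient(
    material: Material,
    e_ev: float = 1500.0,
    n_traj: int = 10_000,
    seed: int = 0,
    cutoff_ev: float = DEFAULT_CUTOFF_EV,
) -> BackscatterResult:
    """Backscatter coefficient eta = k/n over a semi-infinite slab,
    with its binomial standard error; bit-reproducible for a fixed seed."""
    if n_traj < 100:
        raise ValueError(f"need at least 100 trajectories, got {n_traj}")
    fates, _, _, _ = trace_ensemble(material, e_ev, n_traj, seed, cutoff_ev)
    k = int(np.sum(fates == 1))
    eta = k / n_traj
    return BackscatterResult(
        eta, math.sqrt(max(eta * (1 - eta), 1e-12) / n_traj), k, n_traj
    )


@dataclass
class EscapeDepthResult:
    """Histogram of maximum reached depth over backscattered electrons."""

    counts: np.ndarray
    bin_edges: np.ndarray  # nm
    median: float
    p90: float
    depths: np.ndarray  # raw per-electron max depths, nm

    @property
    def n_backscattered(self) -> int:
        return int(self.counts.sum())


def escape_depth_distribution(
    target,
    cfg: SimConfig | None = None,
    n_traj: int = 10_000,
    bin_width: float = 1.0,
) -> EscapeDepthResult:
    """Distribution of generation depths of the backscattered signal.

    The depth of a backscattered electron is the deepest z it reached before
    escaping; the median and 90th percentile summarize how deep the detected
    signal originates.
    """
    cfg = cfg or SimConfig()
    if n_traj < 10_000:
        raise ValueError("need >= 1e4 trajectories for stable quantiles")
    fates, _, _, depth = trace_ensemble(
        target,
        cfg.beam_energy_ev,
        n_traj,
        cfg.seed,
        cfg.cutoff_ev,
        tuple(cfg.beam_direction()),
    )
    depths = depth[fates == 1]
    if depths.size == 0:
        raise EmptyDistributionError("no backscattered electrons")
    edges = np.arange(0.0, depths.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(depths, edges)
    return EscapeDepthResult(
        counts,
        edges,
        float(np.median(depths)),
        float(np.percentile(depths, 90)),
        depths,
    )


def simulate_trajectory(
    start: ElectronState,
    phantom,
    cfg: SimConfig,
    rng: np.random.Generator,
    record_path: bool = False,
) -> TrajectoryOutcome:
    """Trace one electron through ``phantom`` (pure-Python reference path).

    ``phantom`` must expose ``material_at(x, y, z)`` and
    ``distance_to_boundary(pos, direction)``; energies along the recorded
    path are strictly non-increasing by construction.
    """
    pos = start.position.astype(float).copy()
    d = start.direction.astype(float).copy()
    e = float(start.energy)
    max_depth = max(pos[2], 0.0)
    path = [(*pos, e)] if record_path else None
    zmax = getattr(phantom, "zmax", math.inf)
    steps = 0
    while True:
        if e <= cfg.cutoff_ev:
            return TrajectoryOutcome("absorbed", e, d, max_depth, steps, path)
        mat = phantom.material_at(*pos)
        try:
            lam = elastic_mfp(mat, e)
        except Exception:
            lam = _BIG
        if mat.density < 1e-12:
            lam = _BIG
        s = -lam * math.log(1.0 - rng.random())
        tb = phantom.distance_to_boundary(pos, d)
        scatter = s < tb
        step = s if scatter else tb + 1e-6
        de = stopping_power(mat, e, cfg.cutoff_ev) if mat.density > 1e-12 else 0.0
        if de * step >= e - cfg.cutoff_ev:
            travel = (e - cfg.cutoff_ev) / de if de > 0 else step
            pos = pos + d * min(travel, step)
            max_depth = max(max_depth, pos[2])
            if record_path:
                path.append((*pos, cfg.cutoff_ev))
            return TrajectoryOutcome("absorbed", cfg.cutoff_ev, d, max_depth, steps, path)
        pos = pos + d * step
        e -= de * step
        steps += 1
        max_depth = max(max_depth, pos[2])
        if record_path:
            path.append((*pos, e))
        if pos[2] <= 0.0:
            return TrajectoryOutcome("backscattered", e, d, max_depth, steps, path)
        if pos[2] >= zmax:
            return TrajectoryOutcome("transmitted", e, d, max_depth, steps, path)
        if scatter:
            # element choice weighted by n_i * sigma_i
            dens = mat.element_number_densities()
            weights = np.array(
                [n_i * total_elastic_xsection(el.Z, e) for el, n_i in dens]
            )
            zi = dens[int(rng.choice(len(dens), p=weights / weights.sum()))][0].Z
            theta = sample_scatter_angle(zi, e, rng.random())
            phi = 2.0 * math.pi * rng.random()
            d = _rotate(d, theta, phi)


def _rotate(d: np.ndarray, theta: float, phi: float) -> np.ndarray:
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    dx, dy, dz = d
    if abs(dz) > 0.999999:
        sign = 1.0 if dz > 0 else -1.0
        out = np.array([st * cp, st * sp, ct * sign])
    else:
        den = math.sqrt(1.0 - dz * dz)
        out = np.array(
            [
                dx * ct + st * (dx * dz * cp - dy * sp) / den,
                dy * ct + st * (dy * dz * cp + dx * sp) / den,
                dz * ct - st * cp * den,
            ]
        )
    return out / np.linalg.norm(out)
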