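"""Specimen phantoms and synthetic data generators.

Phantoms map positions to materials.  Two representations exist:

* :class:`Phantom` — a matrix half-space containing axis-aligned boxes
  (first match wins), which the transport kernels consume analytically;
* :class:`VoxelPhantom` — a 3-D grid of material indices, used for curved
  geometry such as the stained vesicle shell.

The generators emulate the three kinds of measured data the analysis stages
consume: depth-series BSE phantoms (stained squares buried at 5-nm depth
increments in resin with configurable Ga substitution), HAADF block-face
images with a sharp asymmetric implantation peak over a flat resin plateau
and shot noise, and core-loss EELS spectra with a power-law background and
sawtooth edges.  Every generator is seeded and records its parameters in the
returned object's ``meta`` so round-trip recovery tests are self-describing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, GeometryError
from .imaging import ImageRaster, ScanGrid
from .materials import Material, epon_araldite, substitute_ga_for_c, with_stain
from .mc import KernelGeometry, _DUMMY_VOX, _NO_BOXES
from .quantify import Spectrum, haadf_intensity
from .xsections import haadf_xsections

_BIG = 1e30

#: The five stain depth intervals of the depth-series study, nm.
DEFAULT_STAIN_DEPTHS = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, 25.0))


@dataclass(frozen=True)
class Box:
    """Axis-aligned box bound to a material."""

    x0: float
    x1: float
    y0: float
    y1: float
    z0: float
    z1: float
    material: Material

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1 and self.z0 < self.z1):
            raise GeometryError(f"degenerate box bounds {self}")

    def contains(self, x: float, y: float, z: float) -> bool:
        return (
            self.x0 <= x < self.x1
            and self.y0 <= y < self.y1
            and self.z0 <= z < self.z1
        )

    def overlaps(self, other: "Box") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
            and self.z0 < other.z1
            and other.z0 < self.z1
        )


def slab(z0: float, z1: float, material: Material, half_width: float = 1e8) -> Box:
    """A laterally unbounded layer as a very wide box."""
    return Box(-half_width, half_width, -half_width, half_width, z0, z1, material)


class Phantom:
    """Matrix half-space (0 <= z < zmax) with embedded boxes; first match wins."""

    def __init__(
        self,
        matrix: Material,
        regions: tuple[Box, ...] = (),
        zmax: float = math.inf,
        lateral_bounds: tuple[float, float, float, float] | None = None,
        name: str = "phantom",
    ):
        self.matrix = matrix
        self.regions = tuple(regions)
        self.zmax = zmax
        self.lateral_bounds = lateral_bounds
        self.name = name

    def material_at(self, x: float, y: float, z: float) -> Material:
        for b in self.regions:
            if b.contains(x, y, z):
                return b.material
        return self.matrix

    def distance_to_boundary(self, pos, direction) -> float:
        x, y, z = pos
        dx, dy, dz = direction
        t = _BIG
        if dz < -1e-12:
            t = min(t, -z / dz)
        if dz > 1e-12 and self.zmax < _BIG:
            t = min(t, (self.zmax - z) / dz)
        for b in self.regions:
            tin, tout = -_BIG, _BIG
            ok = True
            for p, d, lo, hi in (
                (x, dx, b.x0, b.x1),
                (y, dy, b.y0, b.y1),
                (z, dz, b.z0, b.z1),
            ):
                if abs(d) < 1e-12:
                    if p < lo or p >= hi:
                        ok = False
                        break
                else:
                    t1, t2 = (lo - p) / d, (hi - p) / d
                    if t1 > t2:
                        t1, t2 = t2, t1
                    tin, tout = max(tin, t1), min(tout, t2)
            if not ok or tin >= tout or tout <= 1e-12:
                continue
            t = min(t, tin if tin > 1e-12 else tout)
        return t

    def kernel_geometry(self) -> KernelGeometry:
        materials = [self.matrix]
        rows = []
        for b in self.regions:
            if b.material not in materials:
                materials.append(b.material)
            idx = materials.index(b.material)
            rows.append([b.x0, b.x1, b.y0, b.y1, b.z0, b.z1, float(idx)])
        boxes = np.array(rows, np.float64) if rows else _NO_BOXES
        return KernelGeometry(
            1,
            boxes,
            0,
            min(self.zmax, _BIG),
            _DUMMY_VOX,
            0.0,
            0.0,
            1.0,
            tuple(materials),
        )

    def describe(self) -> dict:
        return {
            "name": self.name,
            "matrix": self.matrix.as_dict(),
            "n_regions": len(self.regions),
            "zmax": None if math.isinf(self.zmax) else self.zmax,
        }


class VoxelPhantom:
    """3-D voxel grid of material indices; lateral lookups clamp to the edge."""

    def __init__(
        self,
        idx: np.ndarray,
        materials: tuple[Material, ...],
        voxel_size: float,
        x0: float,
        y0: float,
        name: str = "voxel-phantom",
    ):
        self.idx = np.ascontiguousarray(idx, np.int64)
        if self.idx.ndim != 3:
            raise GeometryError("voxel index grid must be 3-D")
        self.materials = tuple(materials)
        self.voxel_size = float(voxel_size)
        self.x0 = float(x0)
        self.y0 = float(y0)
        self.name = name
        self.zmax = self.idx.shape[2] * self.voxel_size

    def material_at(self, x: float, y: float, z: float) -> Material:
        h = self.voxel_size
        nx, ny, nz = self.idx.shape
        ix = min(max(int((x - self.x0) / h), 0), nx - 1)
        iy = min(max(int((y - self.y0) / h), 0), ny - 1)
        iz = min(max(int(z / h), 0), nz - 1)
        return self.materials[self.idx[ix, iy, iz]]

    def distance_to_boundary(self, pos, direction) -> float:
        h = self.voxel_size
        t = _BIG
        for p, d, o in (
            (pos[0], direction[0], self.x0),
            (pos[1], direction[1], self.y0),
            (pos[2], direction[2], 0.0),
        ):
            if d > 1e-12:
                plane = (math.floor((p - o) / h) + 1.0) * h + o
                tt = (plane - p) / d
            elif d < -1e-12:
                plane = math.floor((p - o) / h) * h + o
                tt = (plane - p) / d
            else:
                continue
            t = min(t, max(tt, 1e-9))
        return t

    def kernel_geometry(self) -> KernelGeometry:
        return KernelGeometry(
            2,
            _NO_BOXES,
            0,
            self.zmax,
            self.idx,
            self.x0,
            self.y0,
            self.voxel_size,
            self.materials,
        )

    def describe(self) -> dict:
        return {
            "name": self.name,
            "shape": list(self.idx.shape),
            "voxel_size_nm": self.voxel_size,
            "materials": [m.name for m in self.materials],
        }


# -- depth-series phantom ----------------------------------------------------


class DepthSeriesPhantom(Phantom):
    """Stained squares at stepped burial depths, laterally separated in x.

    Carries the scan layout helpers (region and background pixel masks) that
    the visibility analysis needs.
    """

    def __init__(self, matrix, regions, depths, lateral_size, spacing, name):
        super().__init__(matrix, regions, name=name)
        self.depths = tuple(depths)
        self.lateral_size = lateral_size
        self.spacing = spacing

    def default_scan(self, pixel_size: float = 3.0, height: float = 60.0) -> ScanGrid:
        l, s = self.lateral_size, self.spacing
        width = s + len(self.regions) * (l + s)
        return ScanGrid(
            nx=int(round(width / pixel_size)),
            ny=int(round(height / pixel_size)),
            pixel_size=pixel_size,
            x0=0.0,
            y0=-height / 2.0,
        )

    def region_masks(self, scan: ScanGrid, shrink_nm: float = 3.0) -> list[np.ndarray]:
        """Boolean pixel masks over the scan, one per stained square,
        shrunk by ``shrink_nm`` to exclude partial-coverage edge pixels."""
        xs, ys = scan.pixel_centers()
        masks = []
        for b in self.regions:
            m = (
                (xs >= b.x0 + shrink_nm)
                & (xs <= b.x1 - shrink_nm)
                & (ys >= b.y0 + shrink_nm)
                & (ys <= b.y1 - shrink_nm)
            )
            masks.append(m.reshape(scan.ny, scan.nx))
        return masks

    def background_mask(self, scan: ScanGrid, guard_nm: float = 6.0) -> np.ndarray:
        """Pixels guaranteed to sit over pure matrix (outside every square
        expanded by ``guard_nm``)."""
        xs, ys = scan.pixel_centers()
        bg = np.ones_like(xs, bool)
        for b in self.regions:
            near = (
                (xs >= b.x0 - guard_nm)
                & (xs <= b.x1 + guard_nm)
                & (ys >= b.y0 - guard_nm)
                & (ys <= b.y1 + guard_nm)
            )
            bg &= ~near
        return bg.reshape(scan.ny, scan.nx)


def depth_series_phantom(
    ga_fraction: float = 0.0,
    stain_fraction: float = 0.03,
    depths: tuple = DEFAULT_STAIN_DEPTHS,
    lateral_size: float = 50.0,
    spacing: float = 50.0,
    stain_element: str = "Pb",
    matrix: Material | None = None,
) -> DepthSeriesPhantom:
    """The depth-series specimen model: 5-nm-thick stained squares buried at
    successive 5-nm depth intervals in (optionally Ga-implanted) resin.

    ``ga_fraction`` is the atomic fraction of Ga substituted for C throughout
    the matrix (and inside the stained squares, whose composition is the
    local matrix plus ``stain_fraction`` of the stain element).
    """
    base = matrix if matrix is not None else epon_araldite()
    mat = substitute_ga_for_c(base, ga_fraction)
    stained = with_stain(mat, stain_fraction, stain_element)
    half = lateral_size / 2.0
    boxes = []
    for i, (top, bottom) in enumerate(depths):
        if bottom <= top:
            raise GeometryError(f"depth interval {i} is empty: ({top}, {bottom})")
        x0 = spacing + i * (lateral_size + spacing)
        boxes.append(
            Box(x0, x0 + lateral_size, -half, half, top, bottom, stained)
        )
    for i, a in enumerate(boxes):
        for b in boxes[i + 1 :]:
            if a.overlaps(b):
                raise GeometryError(f"stain boxes overlap: {a} / {b}")
    return DepthSeriesPhantom(
        mat,
        tuple(boxes),
        depths,
        lateral_size,
        spacing,
        name=f"depth-series(ga={ga_fraction:g}, stain={stain_fraction:g}{stain_element})",
    )


# -- vesicle phantom ---------------------------------------------------------


def vesicle_phantom(
    ga_fraction: float = 0.0,
    outer_diameter: float = 40.0,
    shell_thickness: float = 5.0,
    stain_fraction: float = 0.03,
    voxel_size: float = 3.0,
    burial_depth: float = 5.0,
    box_lateral: float = 90.0,
    box_depth: float = 90.0,
    matrix: Material | None = None,
) -> VoxelPhantom:
    """A stained spherical organelle membrane, voxelized.

    The membrane is a shell of the given thickness whose voxels (by center)
    carry stain at ``stain_fraction``; everything else is the (optionally
    Ga-implanted) resin matrix.  ``burial_depth`` is the depth of the top of
    the shell below the block surface.
    """
    if voxel_size > shell_thickness:
        warnings.warn(
            f"voxel size {voxel_size} nm exceeds shell thickness "
            f"{shell_thickness} nm; the shell will be poorly sampled",
            stacklevel=2,
        )
    base = matrix if matrix is not None else epon_araldite()
    mat = substitute_ga_for_c(base, ga_fraction)
    stained = with_stain(mat, stain_fraction)
    r_out = outer_diameter / 2.0
    r_in = r_out - shell_thickness
    if r_in < 0:
        raise GeometryError("shell thicker than the vesicle radius")
    nxy = int(round(box_lateral / voxel_size))
    nz = int(round(box_depth / voxel_size))
    x0 = -nxy * voxel_size / 2.0
    cz = burial_depth + r_out
    ax = x0 + (np.arange(nxy) + 0.5) * voxel_size
    az = (np.arange(nz) + 0.5) * voxel_size
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    rr = np.sqrt(gx**2 + gy**2 + (gz - cz) ** 2)
    idx = ((rr <= r_out) & (rr > r_in)).astype(np.int64)
    ph = VoxelPhantom(
        idx,
        (mat, stained),
        voxel_size,
        x0,
        x0,
        name=f"vesicle(ga={ga_fraction:g}, d={outer_diameter:g})",
    )
    ph.shell = {  # analytic parameters for geometry checks
        "r_out": r_out,
        "r_in": r_in,
        "center_depth": cz,
        "box_volume": box_lateral**2 * box_depth,
    }
    return ph


# -- synthetic HAADF images --------------------------------------------------


@dataclass(frozen=True)
class ImplantProfile:
    """1-D model of the implanted layer seen edge-on in a thin section.

    Ga atomic fraction versus distance x from the vacuum-block interface:
    linear rise from 0 to ``peak_ga_fraction`` over the onset, then
    exponential decay with ``decay_length`` down to the plateau (pure resin).
    ``onset_width`` is the 10–90% rise distance.
    """

    peak_ga_fraction: float
    onset_width: float = 6.0  # nm, 10-90% rise
    decay_length: float = 50.0  # nm
    plateau: Material = field(default_factory=epon_araldite)

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_ga_fraction <= 1.0:
            raise ValueError("peak Ga fraction must be in [0, 1]")
        if not self.onset_width < self.decay_length:
            raise ValueError("onset width must be smaller than the decay length")

    @property
    def peak_position(self) -> float:
        # linear ramp whose 10-90% width equals onset_width
        return self.onset_width / 0.8

    def ga_fraction_at(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        p = self.peak_position
        rise = np.clip(x / p, 0.0, 1.0)
        fall = np.exp(-np.maximum(x - p, 0.0) / self.decay_length)
        return np.where(x < 0, 0.0, self.peak_ga_fraction * np.where(x <= p, rise, fall))


def synth_haadf_image(
    profile: ImplantProfile,
    shape: tuple[int, int] = (64, 192),
    pixel_size: float = 2.0,
    dose: float = 1000.0,
    seed: int = 0,
    vacuum_margin: float = 30.0,
    axis: int = 1,
    flip: bool = False,
    xs: dict[str, float] | None = None,
) -> ImageRaster:
    """Synthetic HAADF image of a block-face edge with shot noise.

    Expected intensity at distance x from the interface is proportional to
    the HAADF signal of the local composition (plateau resin with the
    profile's Ga fraction mixed in); the plateau level is ``dose`` counts per
    pixel and counts are Poisson.  ``axis`` selects the profile direction
    (1: along image columns), ``flip`` reverses it.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    ny, nx = shape
    n_along = nx if axis == 1 else ny
    x = (np.arange(n_along) + 0.5) * pixel_size - vacuum_margin
    if xs is None:
        xs = haadf_xsections(profile.plateau)
    i_plateau = haadf_intensity(profile.plateau, xs)
    from .materials import add_element_fraction

    frac = profile.ga_fraction_at(x)
    rel = np.empty_like(frac)
    for i, f in enumerate(frac):
        if x[i] < 0:
            rel[i] = 0.0  # vacuum
        elif f <= 0:
            rel[i] = 1.0
        else:
            rel[i] = (
                haadf_intensity(add_element_fraction(profile.plateau, "Ga", f), xs)
                / i_plateau
            )
    if flip:
        rel = rel[::-1]
    expected = dose * (rel[None, :] if axis == 1 else rel[:, None])
    expected = np.broadcast_to(expected, shape)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    meta = {
        "generator": "synth_haadf_image",
        "peak_ga_fraction": profile.peak_ga_fraction,
        "onset_width_nm": profile.onset_width,
        "decay_length_nm": profile.decay_length,
        "plateau": profile.plateau.as_dict(),
        "dose": dose,
        "seed": seed,
        "pixel_size_nm": pixel_size,
        "vacuum_margin_nm": vacuum_margin,
        "axis": axis,
        "flip": flip,
    }
    return ImageRaster(counts, pixel_size, meta)


# -- synthetic EELS spectra --------------------------------------------------

#: Default edge set: onset (eV) for each element symbol.
DEFAULT_EDGES = {"C": 284.0, "O": 532.0, "Ga": 1140.0}


def synth_eels_spectrum(
    abundances: dict[str, float],
    sigmas: dict[str, float],
    edges: dict[str, float] | None = None,
    background: tuple[float, float] = (1.0, 3.0),
    energy_range: tuple[float, float] = (200.0, 1600.0),
    channel_ev: float = 1.0,
    dose: float = 1e4,
    seed: int = 0,
    edge_decay_exponent: float = 3.0,
    window_ev: float = 100.0,
) -> Spectrum:
    """Synthetic core-loss spectrum: power-law background plus sawtooth edges.

    The expected counts are ``dose * (A * (E/E0)**-r + edges)`` with
    ``(A, r) = background`` and ``E0`` the start of the energy axis.  Each
    edge contributes ``abundance * sigma`` counts *summed over its standard
    integration window* (so windowed quantification recovers
    abundance-times-cross-section exactly in expectation), with a
    ``(E/onset)**-q`` post-edge decay.  Counts are Poisson.
    """
    edges = dict(edges) if edges is not None else dict(DEFAULT_EDGES)
    e0, e1 = energy_range
    energy = np.arange(e0, e1 + 0.5 * channel_ev, channel_ev)
    a, r = background
    expected = a * (energy / e0) ** (-r)
    for sym, ab in abundances.items():
        if ab == 0.0:
            continue
        if sym not in edges:
            raise ConfigError(f"no edge onset configured for element {sym!r}")
        if sym not in sigmas:
            raise ConfigError(f"no cross section configured for element {sym!r}")
        onset = edges[sym]
        if not e0 <= onset <= e1 - window_ev:
            raise ConfigError(
                f"edge onset {onset} eV outside usable axis ({e0}, {e1 - window_ev})"
            )
        shape = np.where(energy >= onset, (energy / onset) ** (-edge_decay_exponent), 0.0)
        win = (energy >= onset) & (energy < onset + window_ev)
        shape /= shape[win].sum()
        expected = expected + ab * sigmas[sym] * shape
    rng = np.random.default_rng(seed)
    counts = rng.poisson(dose * expected).astype(float)
    return Spectrum(
        energy,
        counts,
        meta={
            "generator": "synth_eels_spectrum",
            "abundances": dict(abundances),
            "sigmas": dict(sigmas),
            "edges": edges,
            "background": [a, r],
            "dose": dose,
            "seed": seed,
            "edge_decay_exponent": edge_decay_exponent,
            "window_ev": window_ev,
        },
    )
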