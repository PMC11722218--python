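"""Raster-scan backscattered-electron image formation.

``render_bse_image`` launches a fixed number of trajectories at each pixel
position of a scan grid over a phantom and counts the backscattered electrons
that pass the energy-selective (ESB) detector: an electron is detected when
its exit energy is at least the grid voltage and its exit direction falls in
the detector's polar acceptance window (default: the full backward
hemisphere).  Per-pixel random streams are keyed by (seed, pixel index), so
images are bit-reproducible regardless of scan order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ContractError, GeometryError
from .mc import SimConfig, TrajectoryOutcome, pack_materials


@dataclass(frozen=True)
class ESBDetector:
    """Energy-selective backscatter detector.

    ``grid_voltage`` in volts rejects backscattered electrons with exit
    energies below e*V; ``acceptance`` is the accepted polar-angle interval
    (radians from the outward surface normal).
    """

    grid_voltage: float = 700.0
    acceptance: tuple[float, float] = (0.0, math.pi / 2)

    def __post_init__(self) -> None:
        if self.grid_voltage < 0:
            raise ValueError(f"grid voltage must be >= 0, got {self.grid_voltage}")
        lo, hi = self.acceptance
        if not 0.0 <= lo < hi <= math.pi / 2 + 1e-12:
            raise GeometryError(
                f"acceptance must satisfy 0 <= lo < hi <= pi/2, got {self.acceptance}"
            )

    def cosine_window(self) -> tuple[float, float]:
        lo, hi = self.acceptance
        return math.cos(hi), math.cos(lo)


#: Detector used for simulation-study image rendering: count every
#: backscattered electron (no energy filtering, full backward hemisphere).
OPEN_DETECTOR = ESBDetector(grid_voltage=0.0)


def esb_accept(event: TrajectoryOutcome, det: ESBDetector) -> bool:
    """Whether one backscattered electron is counted by the detector."""
    if event.fate != "backscattered":
        raise ContractError(
            f"esb_accept requires a backscattered event, got {event.fate!r}"
        )
    if event.exit_energy < det.grid_voltage:
        return False
    c = -float(event.exit_direction[2])
    cos_lo, cos_hi = det.cosine_window()
    return cos_lo <= c <= cos_hi


@dataclass(frozen=True)
class ScanGrid:
    """Pixel-center positions of a raster scan in the specimen plane."""

    nx: int
    ny: int
    pixel_size: float = 3.0  # nm
    x0: float = 0.0  # left edge, nm
    y0: float = 0.0  # top edge, nm

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.pixel_size <= 0:
            raise GeometryError("scan grid must have positive shape and pixel size")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of pixel-center (x, y), row-major (y outer)."""
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.pixel_size
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.pixel_size
        xg, yg = np.meshgrid(x, y)
        return xg.ravel(), yg.ravel()

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.x0 + self.nx * self.pixel_size,
            self.y0,
            self.y0 + self.ny * self.pixel_size,
        )


@dataclass
class ImageRaster:
    """Per-pixel detected counts plus pixel size and provenance."""

    counts: np.ndarray  # (ny, nx) nonnegative integers
    pixel_size: float  # nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def render_bse_image(
    phantom,
    scan: ScanGrid,
    det: ESBDetector = OPEN_DETECTOR,
    cfg: SimConfig | None = None,
    return_total: bool = False,
):
    """Simulate the detected BSE image of ``phantom`` over ``scan``.

    Pixel (i, j) holds the number of detector-accepted backscatter events
    among ``cfg.trajectories_per_pixel`` electrons launched at that beam
    position; reproducible for fixed (seed, pixel).
    """
    cfg = cfg or SimConfig()
    geom = phantom.kernel_geometry()
    bounds = getattr(phantom, "lateral_bounds", None)
    if bounds is not None:
        ex = scan.extent
        if ex[0] < bounds[0] - 1e-9 or ex[1] > bounds[1] + 1e-9:
            raise GeometryError(
                f"scan x-range {ex[:2]} outside phantom lateral bounds {bounds[:2]}"
            )
    mats = pack_materials(geom.materials)
    xs, ys = scan.pixel_centers()
    d = cfg.beam_direction()
    cos_lo, cos_hi = det.cosine_window()
    accepted, total = _kernels.render_counts(
        xs,
        ys,
        int(cfg.trajectories_per_pixel),
        float(d[0]),
        float(d[1]),
        float(d[2]),
        float(cfg.beam_energy_ev),
        float(cfg.cutoff_ev),
        float(det.grid_voltage),
        cos_lo,
        cos_hi,
        geom.geom_mode,
        geom.boxes,
        geom.matrix_idx,
        float(geom.zmax),
        geom.vox,
        geom.vx0,
        geom.vy0,
        geom.vh,
        *mats,
        int(cfg.seed) & 0x7FFFFFFF,
    )
    meta = {
        "beam_energy_ev": cfg.beam_energy_ev,
        "trajectories_per_pixel": cfg.trajectories_per_pixel,
        "cutoff_ev": cfg.cutoff_ev,
        "seed": cfg.seed,
        "grid_voltage": det.grid_voltage,
        "acceptance_rad": list(det.acceptance),
        "pixel_size_nm": scan.pixel_size,
        "scan_origin_nm": [scan.x0, scan.y0],
        "phantom": getattr(phantom, "describe", lambda: repr(phantom))(),
    }
    img = ImageRaster(accepted.reshape(scan.ny, scan.nx), scan.pixel_size, meta)
    if return_total:
        tot = ImageRaster(total.reshape(scan.ny, scan.nx), scan.pixel_size, dict(meta))
        return img, tot
    return img
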