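"""File round-tripping: TIFF images with JSON metadata sidecars, CSV
profiles and spectra.

Images are written as 16-bit TIFF (32-bit when counts overflow) with a
``<file>.json`` sidecar holding pixel size and provenance, so a written
image re-reads to identical counts and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FileFormatError
from .imaging import ImageRaster
from .profiles import LineProfile
from .quantify import Spectrum


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_image(image: ImageRaster, path) -> Path:
    path = Path(path)
    counts = image.counts
    dtype = np.uint16 if counts.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, counts.astype(dtype))
    meta = {"pixel_size_nm": image.pixel_size, **_jsonable(image.meta)}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_image(path) -> ImageRaster:
    path = Path(path)
    try:
        counts = tifffile.imread(path)
    except Exception as exc:
        raise FileFormatError(f"cannot read TIFF {path}: {exc}") from exc
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        try:
            meta = json.loads(sc.read_text())
        except json.JSONDecodeError as exc:
            raise FileFormatError(f"malformed sidecar {sc}: {exc}") from exc
    return ImageRaster(counts, float(meta.get("pixel_size_nm", 3.0)), meta)


def write_profile(profile: LineProfile, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"position_nm": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps(
            {"band_width_nm": profile.band_width, **_jsonable(profile.source)},
            indent=2,
            sort_keys=True,
        )
    )
    return path


def read_profile(path) -> LineProfile:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        positions = df["position_nm"].to_numpy(float)
        intensities = df["intensity"].to_numpy(float)
    except Exception as exc:
        raise FileFormatError(f"cannot parse profile CSV {path}: {exc}") from exc
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return LineProfile(
        positions, intensities, float(meta.get("band_width_nm", 0.0) or 0.0), meta
    )


def write_spectrum(spectrum: Spectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"energy_ev": spectrum.energy, "counts": spectrum.counts}
    ).to_csv(path, index=False)
    if spectrum.meta:
        _sidecar(path).write_text(
            json.dumps(_jsonable(spectrum.meta), indent=2, sort_keys=True)
        )
    return path


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        energy = df["energy_ev"].to_numpy(float)
        counts = df["counts"].to_numpy(float)
    except Exception as exc:
        raise FileFormatError(f"cannot parse spectrum CSV {path}: {exc}") from exc
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Spectrum(energy, counts, meta)
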