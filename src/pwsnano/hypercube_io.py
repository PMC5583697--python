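"""Reading, writing, and validating wavelength-resolved image cubes.

A PWS measurement is a 3D reflectance cube ``R(x, y, lambda)``: a stack of
bright-field microscope images acquired at a grid of illumination wavelengths.
On disk a cube is a multi-page TIFF (one page per wavelength, page order ==
axis order) accompanied by a JSON sidecar holding the wavelength axis in nm,
the pixel size in micrometres, and free-form metadata (optionally including
the instrument geometry).  In memory the cube is a plain ``(rows, cols, n_wl)``
float array wrapped with its axis.

Coordinates are (row, column), origin top-left, 0-based; the wavelength index
is 0-based and matches the sidecar order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

__all__ = [
    "SpectralAxis",
    "SpectralCube",
    "InstrumentModel",
    "MissingSidecarError",
    "CubeDataError",
    "AxisMismatchError",
    "read_cube",
    "write_cube",
    "validate_axis",
    "write_map",
    "read_map",
    "write_labels",
    "read_labels",
    "sidecar_path",
]

#: Advisory spectral range (nm) of the standard acquisition band.
NOMINAL_RANGE_NM = (500.0, 700.0)


class MissingSidecarError(FileNotFoundError):
    """The JSON sidecar describing the wavelength axis is absent."""


class CubeDataError(ValueError):
    """The image data itself is unreadable or malformed."""


class AxisMismatchError(ValueError):
    """Page count and sidecar wavelength count disagree."""


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered wavelength grid of a cube, in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 8:
            raise ValueError(
                f"wavelength axis must be 1-D with >= 8 samples, got shape {wl.shape}"
            )
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength axis contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def spacing_nm(self) -> float:
        """Mean grid spacing in nm."""
        return float(np.mean(np.diff(self.wavelengths_nm)))

    @property
    def center_wavelength_nm(self) -> float:
        return float(np.mean(self.wavelengths_nm))

    @property
    def center_wavenumber(self) -> float:
        """k-bar = 2*pi / mean wavelength, in 1/nm."""
        return float(2.0 * np.pi / self.center_wavelength_nm)


def default_axis() -> SpectralAxis:
    """Standard acquisition grid: 200 wavelengths, 500..699 nm at 1 nm."""
    return SpectralAxis(np.arange(500.0, 700.0, 1.0))


@dataclass(frozen=True)
class InstrumentModel:
    """Epi-illumination geometry of the spectroscopic microscope.

    Defaults follow the standard configuration: low illumination NA so the
    incident field is nearly a plane wave, moderate collection NA, 40x
    magnification.  These are carried as metadata only; the analysis itself
    is geometry-free.
    """

    na_illumination: float = 0.15
    na_collection: float = 0.6
    magnification: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 < self.na_illumination <= self.na_collection < 1.5):
            raise ValueError(
                "require 0 < na_illumination <= na_collection < 1.5, got "
                f"NAi={self.na_illumination}, NAc={self.na_collection}"
            )
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")


@dataclass
class SpectralCube:
    """A ``(rows, cols, n_wl)`` reflectance (or raw-counts) cube with its axis.

    ``metadata`` is a free key->value map; the key ``"instrument"`` may hold an
    :class:`InstrumentModel`, and ``"value_kind"`` records whether the stored
    spectra are raw counts or lamp-normalized reflectance.
    """

    values: np.ndarray
    axis: SpectralAxis
    pixel_size_um: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        if v.ndim != 3:
            raise ValueError(f"cube values must be 3-D (rows, cols, n_wl), got {v.shape}")
        if v.shape[2] != len(self.axis):
            raise AxisMismatchError(
                f"cube has {v.shape[2]} wavelength planes but axis lists "
                f"{len(self.axis)} wavelengths"
            )
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("cube values contain non-finite entries")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]


def validate_axis(axis: SpectralAxis) -> list[str]:
    """Advisory checks on a wavelength axis; returns warnings, never raises.

    Flags (a) a grid falling outside the nominal 500-700 nm acquisition band
    and (b) spacing that is non-uniform beyond 1% relative.
    """
    warnings_out: list[str] = []
    wl = axis.wavelengths_nm
    lo, hi = NOMINAL_RANGE_NM
    if wl[0] < lo or wl[-1] > hi:
        warnings_out.append(
            f"axis spans {wl[0]:.1f}-{wl[-1]:.1f} nm, outside the nominal "
            f"{lo:.0f}-{hi:.0f} nm acquisition band"
        )
    d = np.diff(wl)
    mean_d = float(np.mean(d))
    if np.max(np.abs(d - mean_d)) > 0.01 * mean_d:
        warnings_out.append(
            f"wavelength spacing non-uniform beyond 1% relative "
            f"(mean {mean_d:.4g} nm, max deviation {np.max(np.abs(d - mean_d)):.4g} nm)"
        )
    return warnings_out


def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar location for an image file: same name, ``.json`` suffix."""
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def _metadata_to_json(metadata: dict[str, Any]) -> tuple[dict[str, Any], dict | None]:
    meta = dict(metadata)
    instrument = meta.pop("instrument", None)
    inst_doc = dataclasses.asdict(instrument) if isinstance(instrument, InstrumentModel) else instrument
    return meta, inst_doc


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as a multi-page float TIFF plus JSON sidecar.

    Lossless for floating-point values (dtype preserved); the sidecar fully
    reconstructs the axis and pixel size.  Returns the image path.
    """
    if cube.values.shape[0] == 0 or cube.values.shape[1] == 0:
        raise ValueError(f"refusing to write cube with degenerate spatial extent {cube.spatial_shape}")
    if np.any(cube.values < 0):
        raise ValueError("measurement cubes must be non-negative")
    path = Path(path)
    # pages along wavelength: (n_wl, rows, cols)
    tifffile.imwrite(
        path,
        np.ascontiguousarray(np.moveaxis(cube.values, 2, 0)),
        photometric="minisblack",
    )
    meta, inst_doc = _metadata_to_json(cube.metadata)
    doc = {
        "format_version": 1,
        "kind": "spectral_cube",
        "wavelengths_nm": cube.axis.wavelengths_nm.tolist(),
        "pixel_size_um": cube.pixel_size_um,
        "instrument": inst_doc,
        "metadata": meta,
    }
    sidecar_path(path).write_text(json.dumps(doc, indent=1))
    return path


def read_cube(path: str | Path, format: str = "tiff_stack") -> SpectralCube:
    """Read a multi-page TIFF cube and its JSON sidecar.

    Raises :class:`MissingSidecarError` if the sidecar is absent,
    :class:`CubeDataError` if the image data cannot be decoded, and
    :class:`AxisMismatchError` naming both counts if the page count and the
    sidecar wavelength count disagree.
    """
    if format != "tiff_stack":
        raise ValueError(f"unsupported cube format {format!r}")
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise MissingSidecarError(f"no wavelength-axis sidecar found at {sc}")
    doc = json.loads(sc.read_text())
    axis = SpectralAxis(np.asarray(doc["wavelengths_nm"], dtype=float))
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any decode failure
        raise CubeDataError(f"could not decode image data in {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise CubeDataError(f"expected a page stack in {path}, got array of shape {pages.shape}")
    if pages.shape[0] != len(axis):
        raise AxisMismatchError(
            f"{path}: {pages.shape[0]} image pages but sidecar lists {len(axis)} wavelengths"
        )
    values = np.moveaxis(pages, 0, 2).astype(float, copy=False)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise CubeDataError(f"{path}: cube contains negative or non-finite values")
    metadata = dict(doc.get("metadata") or {})
    inst = doc.get("instrument")
    if inst is not None:
        metadata["instrument"] = InstrumentModel(**inst)
    metadata.setdefault("value_kind", "reflectance")
    return SpectralCube(values, axis, float(doc["pixel_size_um"]), metadata)


def write_map(path: str | Path, values: np.ndarray, sidecar: dict[str, Any] | None = None) -> Path:
    """Write a 2-D floating-point map as a single-page TIFF + JSON sidecar."""
    path = Path(path)
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"maps must be 2-D, got shape {arr.shape}")
    tifffile.imwrite(path, arr)
    doc = {"format_version": 1, "kind": "map"}
    doc.update(sidecar or {})
    sidecar_path(path).write_text(json.dumps(doc, indent=1, default=str))
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    sc = sidecar_path(path)
    doc = json.loads(sc.read_text()) if sc.exists() else {}
    return values, doc


def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    """Write an integer label mask as a single-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.int64)
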