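"""Reading and writing OCTA volumes and en face angiograms.

Volumes live in memory as nonnegative amplitude cubes with axis order
``(z, x, y)`` — depth first, then fast scan, then slow scan — together with
the physical voxel pitch in micrometres per axis.  On disk a volume is a
multi-page grayscale TIFF (one page per z slice) accompanied by a JSON
sidecar recording dtype, shape, axis order and pitch; a raw binary dump with
the same sidecar is accepted as an alternative.  Amplitudes are stored and
processed on a linear scale; logarithmic scaling is a display transform only
(see :mod:`octa_deshadow.projection`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_AXES = "zxy"


def _validate_amplitudes(data: np.ndarray, what: str) -> None:
    """Reject NaN/inf and negative values, naming the first offending index."""
    bad = ~np.isfinite(data)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValidationError(f"{what} contains a non-finite value at index {idx}")
    neg = data < 0
    if neg.any():
        idx = tuple(int(i) for i in np.argwhere(neg)[0])
        raise ValidationError(f"{what} contains a negative value at index {idx}")


@dataclass
class OctaVolume:
    """A 3-D OCTA amplitude cube with axes (z=depth, x=fast, y=slow).

    Parameters
    ----------
    data
        Nonnegative, finite amplitudes, shape ``(nz, nx, ny)``.
    dz_um, dx_um, dy_um
        Voxel pitch per axis in micrometres.
    surface_index
        Depth index of the tissue surface; depths in µm are measured from
        this slice.  Defaults to 0 (cube cropped to the cortical surface).
    """

    data: np.ndarray
    dz_um: float = 1.0
    dx_um: float = 1.0
    dy_um: float = 1.0
    surface_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume data must be 3-D (z, x, y); got ndim={self.data.ndim}"
            )
        _validate_amplitudes(self.data, "volume")
        if not (0 <= self.surface_index < self.nz):
            raise ValidationError(
                f"surface_index {self.surface_index} outside depth range [0, {self.nz})"
            )
        for name in ("dz_um", "dx_um", "dy_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def nz(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def ny(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "OctaVolume":
        """A new volume sharing this one's pitch and surface metadata."""
        return OctaVolume(
            data=data,
            dz_um=self.dz_um,
            dx_um=self.dx_um,
            dy_um=self.dy_um,
            surface_index=self.surface_index,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OctaVolume):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and (self.dz_um, self.dx_um, self.dy_um, self.surface_index)
            == (other.dz_um, other.dx_um, other.dy_um, other.surface_index)
        )


@dataclass
class Angiogram:
    """A 2-D en face image with axes (x, y) and its depth provenance.

    ``depth_range_um`` is the half-open slab interval [top, bottom) in µm
    below the tissue surface from which the image was projected.  ``scale``
    records whether pixel values are linear amplitudes or the [0, 1] mapped
    log-dB display scale.
    """

    data: np.ndarray
    depth_range_um: tuple = (0.0, 0.0)
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError(f"angiogram must be 2-D; got ndim={self.data.ndim}")
        if not np.isfinite(self.data).all():
            raise ValidationError("angiogram contains non-finite pixels")
        if self.scale not in ("linear", "log"):
            raise ValidationError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        top, bottom = self.depth_range_um
        if not top < bottom and (top, bottom) != (0.0, 0.0):
            raise ValidationError(
                f"depth_range_um top must be < bottom; got [{top}, {bottom})"
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(vol: OctaVolume, path) -> Path:
    """Write a volume as a multi-page TIFF (z pages) plus a JSON sidecar.

    Round-trips losslessly at the stored precision via :func:`read_volume`.
    """
    path = Path(path)
    try:
        tifffile.imwrite(
            path, np.asarray(vol.data, dtype=np.float32), photometric="minisblack"
        )
    except OSError as exc:
        raise OSError(f"failed to write volume to {path}: {exc}") from exc
    meta = {
        "dtype": "float32",
        "shape": [vol.nz, vol.nx, vol.ny],
        "axis_order": _AXES,
        "dz_um": vol.dz_um,
        "dx_um": vol.dx_um,
        "dy_um": vol.dy_um,
        "surface_index": vol.surface_index,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_volume(path, metadata_path=None) -> OctaVolume:
    """Read an OCTA volume from a multi-page TIFF or raw binary + sidecar.

    The on-disk axis order (declared in the sidecar) is normalized to
    ``(z, x, y)``.  Negative or non-finite stored voxels are an error, never
    silently clipped.
    """
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path is not None else _sidecar_path(path)
    meta = None
    if meta_path.exists():
        try:
            meta = json.loads(meta_path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"unparseable sidecar {meta_path}: {exc}") from exc

    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D page stack, got ndim={data.ndim}")
        axis_order = _AXES if meta is None else meta.get("axis_order", _AXES)
    else:
        if meta is None:
            raise FormatError(f"raw volume {path} requires a metadata sidecar")
        for key in ("dtype", "shape", "axis_order"):
            if key not in meta:
                raise FormatError(f"sidecar {meta_path} missing required key {key!r}")
        shape = tuple(meta["shape"])
        flat = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        if flat.size != int(np.prod(shape)):
            raise FormatError(
                f"{path}: sidecar declares shape {shape} "
                f"({int(np.prod(shape))} voxels) but file holds {flat.size} voxels"
            )
        data = flat.reshape(shape)
        axis_order = meta["axis_order"]

    axis_order = str(axis_order).lower()
    if sorted(axis_order) != sorted(_AXES):
        raise FormatError(f"axis_order must be a permutation of 'zxy', got {axis_order!r}")
    if meta is not None and "shape" in meta and tuple(meta["shape"]) != data.shape:
        raise FormatError(
            f"sidecar shape {tuple(meta['shape'])} contradicts stored shape {data.shape}"
        )
    data = np.transpose(data, [axis_order.index(a) for a in _AXES])

    kwargs = {}
    if meta is not None:
        for key in ("dz_um", "dx_um", "dy_um", "surface_index"):
            if key in meta:
                kwargs[key] = meta[key]
    return OctaVolume(data=data, **kwargs)


def write_angiogram(img: Angiogram, path) -> Path:
    """Write an angiogram as 16-bit grayscale TIFF or PNG.

    Pixels are linearly rescaled from [min, max] to the full uint16 range.
    A constant image maps to all zeros with a logged warning (not an error).
    A JSON sidecar records the depth range, scale and original value range.
    """
    path = Path(path)
    data = np.asarray(img.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        warnings.warn(f"constant angiogram written to {path}: all pixels map to 0")
        logger.warning("constant angiogram written to %s", path)
        out = np.zeros(data.shape, dtype=np.uint16)
    else:
        out = np.round((data - lo) / (hi - lo) * 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
    meta = {
        "depth_range_um": list(img.depth_range_um),
        "scale": img.scale,
        "value_range": [lo, hi],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
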