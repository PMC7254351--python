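"""Depth-slab extraction and en face angiogram generation.

An en face angiogram collapses a depth slab of the volume into a 2-D view
through maximum amplitude projection.  Slabs are specified in µm below the
tissue surface as half-open intervals [top, bottom), so adjacent tiled slabs
share no depth index.  Projection operates on linear amplitudes; logarithmic
scaling is applied afterwards for display only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volume_io import Angiogram, OctaVolume

logger = logging.getLogger(__name__)


@dataclass
class Slab:
    """A contiguous depth range of a volume.

    Depth bounds are µm below the surface (half-open [top, bottom)); the
    derived index interval is [z_top_idx, z_bottom_idx).
    """

    parent: OctaVolume
    z_top_um: float
    z_bottom_um: float
    z_top_idx: int
    z_bottom_idx: int


def extract_slab(vol: OctaVolume, z_top_um: float, z_bottom_um: float) -> Slab:
    """Convert a µm depth range to a slab of z indices.

    Index conversion: ``surface_index + floor(depth_um / dz_um)``; a slab
    boundary falling mid-voxel assigns that voxel to the deeper-starting
    slab.
    """
    if not z_top_um < z_bottom_um:
        raise ValidationError(f"slab top must be above bottom; got [{z_top_um}, {z_bottom_um}) um")
    top_idx = vol.surface_index + math.floor(z_top_um / vol.dz_um)
    bottom_idx = vol.surface_index + math.floor(z_bottom_um / vol.dz_um)
    if top_idx < 0 or bottom_idx > vol.nz or top_idx >= bottom_idx:
        raise ValidationError(
            f"slab [{z_top_um}, {z_bottom_um}) um maps to indices "
            f"[{top_idx}, {bottom_idx}) outside the volume's [0, {vol.nz})"
            f" (dz_um={vol.dz_um}, surface_index={vol.surface_index})"
        )
    return Slab(vol, float(z_top_um), float(z_bottom_um), top_idx, bottom_idx)


def max_amplitude_projection(slab: Slab) -> Angiogram:
    """En face angiogram: per-(x, y) maximum over the slab's depth indices."""
    data = slab.parent.data[slab.z_top_idx : slab.z_bottom_idx].max(axis=0)
    return Angiogram(
        data=data,
        depth_range_um=(slab.z_top_um, slab.z_bottom_um),
        scale="linear",
    )


def display_slab(vol: OctaVolume, z_top_um: float, z_bottom_um: float,
                 floor_db: float = -30.0) -> Angiogram:
    """Project a slab and log-scale it against the volume's own maximum.

    This is the display pipeline evaluation metrics run on: all slabs of
    one (normalized) volume share a brightness reference, so a slab whose
    signal was attenuated by processing stays dim instead of being
    auto-gained to full range.
    """
    img = max_amplitude_projection(extract_slab(vol, z_top_um, z_bottom_um))
    ref = float(vol.data.max())
    if ref <= 0:
        warnings.warn("all-zero volume: display slab is all zeros")
        return Angiogram(np.zeros_like(np.asarray(img.data, dtype=np.float64)),
                         depth_range_um=img.depth_range_um, scale="log")
    return log_scale(img, floor_db=floor_db, ref=ref)


def log_scale(img: Angiogram, floor_db: float = -30.0, ref: float | None = None) -> Angiogram:
    """Display log scaling: 20·log10(pixel / ref), floored, mapped to [0, 1].

    ``ref`` is the 0 dB reference amplitude; by default the image maximum,
    so the brightest pixel maps to 1.0.  Pass the parent volume's maximum
    instead to display several slabs of one volume on a common brightness
    scale (an image dimmer than ``ref`` then stays dim rather than being
    auto-gained).  Pixels at or below ``ref · 10^(floor_db/20)`` map to
    0.0.  Pixel ordering is preserved.
    """
    if img.scale != "linear":
        raise ValidationError("log_scale expects a linear-scale angiogram")
    if not floor_db < 0:
        raise ValidationError(f"floor_db must be negative, got {floor_db}")
    data = np.asarray(img.data, dtype=np.float64)
    peak = float(data.max()) if ref is None else float(ref)
    if peak <= 0:
        warnings.warn("all-zero angiogram: log scaling yields all zeros")
        logger.warning("all-zero angiogram: log scaling yields all zeros")
        out = np.zeros_like(data)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(data / peak)
        db = np.clip(db, floor_db, 0.0)
        out = (db - floor_db) / (-floor_db)
    return Angiogram(data=out, depth_range_um=img.depth_range_um, scale="log")
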