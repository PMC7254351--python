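"""Quantitative evaluation of de-shadowing quality.

Three image-quality measures are provided:

* **RMS contrast** of a line intensity profile — here the population
  standard deviation of the pixel intensities along the line (no mean
  normalization); higher values mean more visible vessel structure.
* **Capillary SNR** of a profile crossing a small vessel: peak amplitude
  above the local background mean, in units of background standard
  deviation.  Used to score a parameter sweep over the subtraction weight w.
* **Cross-correlation similarity** between adjacent en face angiograms:
  zero-lag Pearson correlation of the flattened pixel vectors.  Falling
  similarity with depth reflects genuine structural heterogeneity of the
  capillary network rather than projected copies of superficial vessels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .projection import extract_slab, max_amplitude_projection
from .volume_io import Angiogram, OctaVolume

logger = logging.getLogger(__name__)


@dataclass
class LineProfile:
    """A 1-D intensity profile extracted along one axis of an image/volume."""

    values: np.ndarray
    axis: str = "x"
    location: tuple = ()
    source: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("profile values must be 1-D")
        if self.axis not in ("x", "y", "z"):
            raise ValidationError(f"axis must be one of x/y/z, got {self.axis!r}")


def _values(profile) -> np.ndarray:
    v = profile.values if isinstance(profile, LineProfile) else np.asarray(profile, dtype=np.float64)
    return np.asarray(v, dtype=np.float64)


def rms_contrast(profile) -> float:
    """Population standard deviation of a line profile's pixel intensities."""
    v = _values(profile)
    if v.size < 2:
        raise ValidationError(f"profile needs at least 2 samples, got {v.size}")
    return float(v.std())


def mean_rms_contrast(img: Angiogram, axis: str = "x") -> dict:
    """RMS contrast of every line profile along ``axis`` of an angiogram.

    ``axis`` is the direction the profiles run: ``"x"`` yields ny horizontal
    profiles (one per y position).  Returns their mean, population standard
    deviation, and the full per-line vector.
    """
    if axis not in ("x", "y"):
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    data = np.asarray(img.data, dtype=np.float64)
    per_line = data.std(axis=0 if axis == "x" else 1)
    return {
        "mean": float(per_line.mean()),
        "sd": float(per_line.std()),
        "per_line": per_line,
    }


def _check_window(window, n: int, name: str) -> tuple:
    start, stop = int(window[0]), int(window[1])
    if not (0 <= start < stop <= n):
        raise ValidationError(f"{name} [{start}, {stop}) outside profile of length {n}")
    return start, stop


def profile_snr(profile, peak_window, background_windows) -> float:
    """Signal-to-noise ratio of a peak against flanking background windows.

    ``(max over peak_window − mean over background) / (σ over background)``
    with half-open index windows that must be disjoint and inside the
    profile.  Zero background σ returns +inf with a warning.
    """
    v = _values(profile)
    n = v.size
    ps, pe = _check_window(peak_window, n, "peak_window")
    covered = np.zeros(n, dtype=bool)
    covered[ps:pe] = True
    bg = []
    for i, win in enumerate(background_windows):
        bs, be = _check_window(win, n, f"background_windows[{i}]")
        if covered[bs:be].any():
            raise ValidationError("peak and background windows must be disjoint")
        covered[bs:be] = True
        bg.append(v[bs:be])
    if not bg:
        raise ValidationError("at least one background window is required")
    bg = np.concatenate(bg)
    sigma = bg.std()
    if sigma == 0:
        warnings.warn("zero background standard deviation: SNR is undefined (+inf)")
        logger.warning("zero background standard deviation: SNR is undefined (+inf)")
        return float("inf")
    return float((v[ps:pe].max() - bg.mean()) / sigma)


def slab_similarity(a: Angiogram, b: Angiogram) -> float:
    """Zero-lag Pearson correlation between two same-shape angiograms."""
    if a.data.shape != b.data.shape:
        raise ValidationError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if a.scale != b.scale:
        raise ValidationError(f"scale mismatch: {a.scale} vs {b.scale}")
    va = np.asarray(a.data, dtype=np.float64).ravel()
    vb = np.asarray(b.data, dtype=np.float64).ravel()
    for name, v in (("first", va), ("second", vb)):
        if v.std() == 0:
            raise ValidationError(f"{name} angiogram is constant: correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def similarity_vs_depth(
    vol: OctaVolume,
    slab_thickness_um: float = 20.0,
    step_um: float = 5.0,
    z_start_um: float = 0.0,
    z_end_um: float | None = None,
) -> list:
    """Similarity between consecutive slab angiograms down the cortex.

    Slabs of ``slab_thickness_um`` are tiled from ``z_start_um`` every
    ``step_um``; each adjacent pair's projection similarity is reported,
    indexed by the shallower slab's top depth.
    """
    if z_end_um is None:
        z_end_um = (vol.nz - vol.surface_index) * vol.dz_um
    if not (slab_thickness_um > 0 and step_um > 0):
        raise ValidationError("slab_thickness_um and step_um must be positive")
    n_slabs = int(np.floor((z_end_um - z_start_um - slab_thickness_um) / step_um)) + 1
    tops = [z_start_um + i * step_um for i in range(max(n_slabs, 0))]
    if len(tops) < 2:
        raise ValidationError(
            f"fewer than two slabs of {slab_thickness_um} um fit in "
            f"[{z_start_um}, {z_end_um}) um with step {step_um} um"
        )
    projections = [
        max_amplitude_projection(extract_slab(vol, t, t + slab_thickness_um)) for t in tops
    ]
    return [
        {"depth_um": float(tops[i]), "similarity": slab_similarity(projections[i], projections[i + 1])}
        for i in range(len(projections) - 1)
    ]
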