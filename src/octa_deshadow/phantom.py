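"""Synthetic cerebral-vasculature OCTA phantoms with ground-truth masks.

The phantom emulates the structures the de-shadowing algorithm targets in a
mouse-cortex OCTA cube: bright pial vessels near the surface, exponential
tail artifacts trailing beneath them to the bottom of the volume,
depth-dependent attenuation of all true signal, sparse deep capillaries
(some deliberately hidden under vessel tails), and a Rayleigh speckle noise
floor.  Ground-truth voxel masks for vessels, capillaries and pure-artifact
tails are recorded before noise is added, so suppression and visibility can
be scored exactly.

Construction, in order: (1) noise floor sampled from the seeded generator;
(2) depth attenuation exp(-z_um / attenuation_length_um) applied to every
true-signal component; (3) vessels rendered as filled balls; (4) beneath
each vessel column, a tail decaying as exp(-Δz_um / decay_length_um) scaled
by the vessel's attenuated amplitude and the tail strength, extending to the
bottom; (5) capillaries rendered as small balls; (6) masks recorded, then
noise added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .volume_io import OctaVolume

logger = logging.getLogger(__name__)


@dataclass
class Vessel:
    """A superficial (pial) vessel: a ball at (x, y) center and depth, µm."""

    center_xy_um: tuple
    radius_um: float
    depth_um: float
    amplitude: float = 1.0


@dataclass
class Capillary:
    """A small deep vessel: a ball at an (x, y, z) center, µm."""

    center_xyz_um: tuple
    radius_um: float
    amplitude: float = 1.0


@dataclass
class TailModel:
    """Exponential tail decay below vessels; strength relative to the vessel.

    Tails are dynamic-scattering residues, so they carry speckle: with
    ``speckle`` the decaying envelope is modulated voxel-wise by a unit-mean
    Rayleigh factor, as in real decorrelation artifacts.  Without it the
    tail is the bare deterministic envelope.
    """

    decay_length_um: float = 300.0
    strength: float = 0.4
    speckle: bool = True


@dataclass
class BedModel:
    """Unresolved capillary-bed speckle in a capillary-rich depth band.

    The mid-cortex holds a dense capillary plexus whose mesh is mostly below
    the lateral sampling pitch, so in OCTA it appears as diffuse perfusion
    speckle concentrated in that band rather than as resolvable tubes.
    Because the band is thin relative to the A-line, it contributes little
    to the per-line mean and so survives mean subtraction as a faint
    background texture — the behaviour real deep-slab angiograms show.
    ``scale`` is the Rayleigh scale of the speckle (relative to unit vessel
    amplitude, before depth attenuation); the band is [z_top_um,
    z_bottom_um).  ``scale=0`` disables the component.
    """

    scale: float = 0.0
    z_top_um: float = 400.0
    z_bottom_um: float = 500.0


@dataclass
class NoiseModel:
    """Speckle noise floor: Rayleigh (standard amplitude model) or folded Gaussian."""

    distribution: str = "rayleigh"
    scale: float = 0.04


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic OCTA volume."""

    shape: tuple = (256, 128, 128)
    dz_um: float = 4.0
    dx_um: float = 16.0
    dy_um: float = 16.0
    vessels: list = field(default_factory=list)
    capillaries: list = field(default_factory=list)
    tail: TailModel = field(default_factory=TailModel)
    bed: BedModel = field(default_factory=BedModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    attenuation_length_um: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, nx, ny = self.shape
        if min(nz, nx, ny) < 1:
            raise ValidationError(f"shape extents must be positive, got {self.shape}")
        if not 0.0 <= self.tail.strength <= 1.0:
            raise ValidationError(f"tail strength must be in [0, 1], got {self.tail.strength}")
        if not self.attenuation_length_um > 0:
            raise ValidationError("attenuation_length_um must be positive")
        if self.noise.distribution not in ("rayleigh", "gaussian_folded"):
            raise ValidationError(f"unknown noise distribution {self.noise.distribution!r}")
        if self.noise.scale < 0:
            raise ValidationError("noise scale must be nonnegative")
        if self.bed.scale < 0:
            raise ValidationError("bed scale must be nonnegative")
        zmax, xmax, ymax = nz * self.dz_um, nx * self.dx_um, ny * self.dy_um
        for v in self.vessels:
            if v.amplitude <= 0:
                raise ValidationError("vessel amplitude must be positive")
            cx, cy = v.center_xy_um
            if not (
                v.radius_um <= cx <= xmax - v.radius_um
                and v.radius_um <= cy <= ymax - v.radius_um
                and 0 <= v.depth_um <= zmax - v.radius_um
            ):
                raise ValidationError(f"vessel at {v.center_xy_um} extends outside the volume")
        for c in self.capillaries:
            if c.amplitude <= 0:
                raise ValidationError("capillary amplitude must be positive")
            cx, cy, cz = c.center_xyz_um
            if not (0 <= cx < xmax and 0 <= cy < ymax and 0 <= cz < zmax):
                raise ValidationError(f"capillary at {c.center_xyz_um} outside the volume")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        d["vessels"] = [
            Vessel(center_xy_um=tuple(v["center_xy_um"]), radius_um=v["radius_um"],
                   depth_um=v["depth_um"], amplitude=v.get("amplitude", 1.0))
            for v in d.get("vessels", [])
        ]
        d["capillaries"] = [
            Capillary(center_xyz_um=tuple(c["center_xyz_um"]), radius_um=c["radius_um"],
                      amplitude=c.get("amplitude", 1.0))
            for c in d.get("capillaries", [])
        ]
        d["tail"] = TailModel(**d.get("tail", {}))
        d["bed"] = BedModel(**d.get("bed", {}))
        d["noise"] = NoiseModel(**d.get("noise", {}))
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground-truth voxel masks, recorded before noise addition.

    ``tail_mask`` marks voxels whose signal is purely artifact; it is
    disjoint from the structure masks, and every tail voxel lies strictly
    below some vessel voxel in its own (x, y) column.  ``capillary_labels``
    assigns each capillary voxel the 1-based index of its capillary in the
    spec (0 elsewhere), enabling per-capillary scoring.
    """

    vessel_mask: np.ndarray
    capillary_mask: np.ndarray
    tail_mask: np.ndarray
    capillary_labels: np.ndarray


def _ball_mask(shape, pitches, center_um, radius_um) -> tuple:
    """Boolean ball within a bounding box; returns (slices, mask).

    The voxel nearest the center is always included, so structures smaller
    than a voxel are still rendered.
    """
    lo, hi, axes = [], [], []
    for n, pitch, c in zip(shape, pitches, center_um):
        i0 = max(int(np.floor((c - radius_um) / pitch)), 0)
        i1 = min(int(np.ceil((c + radius_um) / pitch)) + 1, n)
        lo.append(i0)
        hi.append(i1)
        axes.append((np.arange(i0, i1) * pitch - c) ** 2)
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    mask = d2 <= radius_um**2
    if not mask.any() and d2.size:
        mask[np.unravel_index(np.argmin(d2), d2.shape)] = True
    return tuple(slice(a, b) for a, b in zip(lo, hi)), mask


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render a phantom volume and its ground truth.

    Deterministic given ``spec.seed``.  Returns ``(OctaVolume, PhantomTruth)``.
    """
    nz, nx, ny = spec.shape
    pitches = (spec.dz_um, spec.dx_um, spec.dy_um)
    z_um = np.arange(nz) * spec.dz_um
    att = np.exp(-z_um / spec.attenuation_length_um)

    structure = np.zeros(spec.shape, dtype=np.float64)
    vessel_mask = np.zeros(spec.shape, dtype=bool)
    capillary_mask = np.zeros(spec.shape, dtype=bool)
    capillary_labels = np.zeros(spec.shape, dtype=np.int32)

    for v in spec.vessels:
        center = (v.depth_um, *v.center_xy_um)
        box, ball = _ball_mask(spec.shape, pitches, center, v.radius_um)
        value = v.amplitude * att[box[0], None, None]
        region = structure[box]
        region[ball] = np.maximum(region[ball], np.broadcast_to(value, ball.shape)[ball])
        vessel_mask[box] |= ball

    tail_rng, bed_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )
    unit_rayleigh = np.sqrt(2.0 / np.pi)  # Rayleigh scale giving mean 1

    # Tails: below the deepest vessel voxel of each shadowed column, decaying
    # from the vessel's local (attenuated) amplitude, down to the bottom.
    tail_field = np.zeros(spec.shape, dtype=np.float64)
    shadowed = vessel_mask.any(axis=0)
    if shadowed.any() and spec.tail.strength > 0:
        cols = np.argwhere(shadowed)
        vm = vessel_mask[:, cols[:, 0], cols[:, 1]]
        zb = (nz - 1) - np.argmax(vm[::-1], axis=0)  # deepest vessel voxel
        base = structure[zb, cols[:, 0], cols[:, 1]] * spec.tail.strength
        dz = (np.arange(nz)[:, None] - zb[None, :]) * spec.dz_um
        decay = np.where(dz > 0, np.exp(-dz / spec.tail.decay_length_um), 0.0)
        envelope = base[None, :] * decay
        if spec.tail.speckle:
            envelope = envelope * tail_rng.rayleigh(
                scale=unit_rayleigh, size=envelope.shape
            )
        tail_field[:, cols[:, 0], cols[:, 1]] = envelope

    for i, c in enumerate(spec.capillaries):
        cx, cy, cz = c.center_xyz_um
        box, ball = _ball_mask(spec.shape, pitches, (cz, cx, cy), c.radius_um)
        value = c.amplitude * att[box[0], None, None]
        region = structure[box]
        region[ball] = np.maximum(region[ball], np.broadcast_to(value, ball.shape)[ball])
        capillary_mask[box] |= ball
        labels = capillary_labels[box]
        labels[ball] = i + 1

    # Capillary wins overlaps; tail_mask holds only pure-artifact voxels.
    overlap = vessel_mask & capillary_mask
    if overlap.any():
        logger.info("vessel/capillary overlap at %d voxels: capillary wins", overlap.sum())
        vessel_mask &= ~capillary_mask
    tail_mask = (tail_field > 0) & ~vessel_mask & ~capillary_mask

    # Unresolved capillary-bed speckle in its depth band, attenuated with depth.
    bed_field = np.zeros(spec.shape, dtype=np.float64)
    if spec.bed.scale > 0:
        band = (z_um >= spec.bed.z_top_um) & (z_um < spec.bed.z_bottom_um)
        if band.any():
            bed_field[band] = bed_rng.rayleigh(
                scale=spec.bed.scale, size=(int(band.sum()), nx, ny)
            ) * att[band, None, None]

    if spec.noise.scale > 0:
        if spec.noise.distribution == "rayleigh":
            noise = noise_rng.rayleigh(scale=spec.noise.scale, size=spec.shape)
        else:
            noise = np.abs(noise_rng.normal(scale=spec.noise.scale, size=spec.shape))
    else:
        noise = np.zeros(spec.shape)

    data = structure + tail_field + bed_field + noise
    vol = OctaVolume(
        data=data, dz_um=spec.dz_um, dx_um=spec.dx_um, dy_um=spec.dy_um, surface_index=0
    )
    truth = PhantomTruth(vessel_mask, capillary_mask, tail_mask, capillary_labels)
    return vol, truth


def _cortex_spec(
    seed: int,
    tail_strength: float,
    tail_decay_um: float,
    bed_scale: float,
    bed_band_um: tuple,
    noise_scale: float,
    cap_amplitude: tuple,
    attenuation_length_um: float,
) -> PhantomSpec:
    """Build the cortex phantom geometry for a given artifact/noise regime."""
    shape = (256, 128, 128)
    dz, dx, dy = 4.0, 16.0, 16.0
    xmax, ymax = shape[1] * dx, shape[2] * dy
    ss = np.random.SeedSequence(seed)
    vessel_rng, cap_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    # First vessel is a dominant pial trunk (the tail source the method is
    # aimed at); the rest are smaller surface vessels.
    vessels = []
    for i in range(int(vessel_rng.integers(2, 5))):
        radius = float(
            vessel_rng.uniform(110.0, 150.0) if i == 0 else vessel_rng.uniform(40.0, 100.0)
        )
        vessels.append(
            Vessel(
                center_xy_um=(
                    float(vessel_rng.uniform(radius + 200.0, xmax - radius - 200.0)),
                    float(vessel_rng.uniform(radius + 200.0, ymax - radius - 200.0)),
                ),
                radius_um=radius,
                depth_um=float(vessel_rng.uniform(40.0, 90.0)),
                amplitude=1.0,
            )
        )

    def shadowed_by(cx, cy):
        return any(
            (cx - v.center_xy_um[0]) ** 2 + (cy - v.center_xy_um[1]) ** 2
            <= v.radius_um**2
            for v in vessels
        )

    capillaries = []

    # A capillary-rich cross-section in the mid-cortex: several capillaries
    # share one depth and one slow-axis position, so a single horizontal
    # profile crosses the shadowed target plus reference capillaries in the
    # open — mirroring intensity-profile figures through a capillary layer.
    target = vessels[0]
    line_y = target.center_xy_um[1]
    line_z = float(cap_rng.uniform(430.0, 480.0))
    for i in range(8):
        if i < 2:  # shadowed cluster members, directly beneath the vessel
            cx = float(
                np.clip(
                    target.center_xy_um[0]
                    + cap_rng.uniform(-target.radius_um / 2, target.radius_um / 2),
                    2 * dx,
                    xmax - 2 * dx,
                )
            )
        else:  # reference cluster members in the open
            for _ in range(100):
                cx = float(cap_rng.uniform(100.0, xmax - 100.0))
                if not shadowed_by(cx, line_y):
                    break
        capillaries.append(
            Capillary(
                center_xyz_um=(cx, line_y + float(cap_rng.uniform(-8.0, 8.0)),
                               line_z + float(cap_rng.uniform(-12.0, 12.0))),
                radius_um=float(cap_rng.uniform(5.0, 10.0)),
                amplitude=float(cap_rng.uniform(*cap_amplitude)),
            )
        )

    # Two more shadowed capillaries at other depths, then scattered ones in
    # the open (kept out of vessel shadows so their ground truth is clean).
    n_caps = int(cap_rng.integers(24, 41))
    for i in range(n_caps - 8):
        radius = float(cap_rng.uniform(5.0, 10.0))
        if i < 2:
            v = vessels[int(cap_rng.integers(1, len(vessels)))] if len(vessels) > 1 else vessels[0]
            jitter = cap_rng.uniform(-v.radius_um / 2, v.radius_um / 2, size=2)
            cx = float(np.clip(v.center_xy_um[0] + jitter[0], 2 * dx, xmax - 2 * dx))
            cy = float(np.clip(v.center_xy_um[1] + jitter[1], 2 * dy, ymax - 2 * dy))
            cz = float(cap_rng.uniform(350.0, 550.0))
        else:
            for _ in range(100):
                cx = float(cap_rng.uniform(100.0, xmax - 100.0))
                cy = float(cap_rng.uniform(100.0, ymax - 100.0))
                if not shadowed_by(cx, cy):
                    break
            cz = float(cap_rng.uniform(300.0, 700.0))
        capillaries.append(
            Capillary(
                center_xyz_um=(cx, cy, cz),
                radius_um=radius,
                amplitude=float(cap_rng.uniform(*cap_amplitude)),
            )
        )

    return PhantomSpec(
        shape=shape,
        dz_um=dz,
        dx_um=dx,
        dy_um=dy,
        vessels=vessels,
        capillaries=capillaries,
        tail=TailModel(decay_length_um=tail_decay_um, strength=tail_strength, speckle=True),
        bed=BedModel(scale=bed_scale, z_top_um=bed_band_um[0], z_bottom_um=bed_band_um[1]),
        noise=NoiseModel(distribution="rayleigh", scale=noise_scale),
        attenuation_length_um=attenuation_length_um,
        seed=int(seed),
    )


def default_cortex_spec(seed: int) -> PhantomSpec:
    """A mouse-cortex-like phantom: 256×128×128 voxels, ~1 mm deep, ~2 mm wide.

    2–4 pial vessels (radius 40–100 µm) within 100 µm of the surface with
    strong speckled tails, 24–40 capillaries (radius ≤ 10 µm) at 300–700 µm
    depth over an unresolved capillary-bed speckle band.  Several
    capillaries are placed directly beneath vessels (the shadowed-capillary
    scenario); all placements come from per-component substreams of the
    seed, so adding capillaries does not move vessels.
    """
    return _cortex_spec(
        seed,
        tail_strength=0.5,
        tail_decay_um=700.0,
        bed_scale=0.12,
        bed_band_um=(400.0, 500.0),
        noise_scale=0.01,
        cap_amplitude=(1.1, 1.4),
        attenuation_length_um=1500.0,
    )


def shadowed_capillary_ids(truth: PhantomTruth) -> list:
    """1-based ids of capillaries sharing an (x, y) column with a vessel."""
    shadowed_cols = truth.vessel_mask.any(axis=0)
    labels = truth.capillary_labels
    under = labels[:, shadowed_cols]
    return sorted(int(i) for i in np.unique(under) if i > 0)


def capillary_snr_windows(truth: PhantomTruth, cid: int, margin: int = 2,
                          min_run: int = 3) -> tuple:
    """Profile location and SNR windows for one capillary, from ground truth.

    Returns ``((z, y), peak_window, background_windows)`` for a horizontal
    (x) profile through capillary ``cid``.  The peak window covers the
    capillary's x extent (±1 voxel).  Background windows tile the rest of
    the line in runs of at least ``min_run`` voxels, skipping a ``margin``
    around the peak and any column holding another capillary near the
    profile plane — so the background measures shadow residue and diffuse
    speckle, not other resolved vessels.
    """
    where = np.argwhere(truth.capillary_labels == cid)
    if where.size == 0:
        raise ValidationError(f"no capillary with id {cid}")
    nx = truth.capillary_labels.shape[1]
    z = int(np.round(where[:, 0].mean()))
    y = int(np.round(where[:, 2].mean()))
    x_lo, x_hi = int(where[:, 1].min()), int(where[:, 1].max())
    peak = (max(x_lo - 1, 0), min(x_hi + 2, nx))

    zsl = slice(max(z - 3, 0), z + 4)
    ysl = slice(max(y - 2, 0), y + 3)
    cap_cols = (truth.capillary_labels[zsl, :, ysl] > 0).any(axis=(0, 2))
    allowed = ~cap_cols
    allowed[max(peak[0] - margin, 0) : peak[1] + margin] = False

    windows, start = [], None
    for x in range(nx + 1):
        ok = x < nx and allowed[x]
        if ok and start is None:
            start = x
        elif not ok and start is not None:
            if x - start >= min_run:
                windows.append((start, x))
            start = None
    if not windows:
        raise ValidationError(f"no background columns available around capillary {cid}")
    return (z, y), peak, windows


def capillary_visibility(
    processed: OctaVolume, truth: PhantomTruth, ids=None, pad_um: float = 80.0
) -> list:
    """Per-capillary peak amplitude vs. local background mean after processing.

    The local background is a box around the capillary (padded by ``pad_um``
    per axis) excluding all true-structure voxels; residual tail artifact
    counts as background.  Returns a list of dicts with keys ``id``,
    ``peak``, ``background_mean``.
    """
    data = processed.data
    labels = truth.capillary_labels
    structures = truth.vessel_mask | truth.capillary_mask
    pads = tuple(
        max(int(np.ceil(pad_um / p)), 1)
        for p in (processed.dz_um, processed.dx_um, processed.dy_um)
    )
    if ids is None:
        ids = [int(i) for i in np.unique(labels) if i > 0]
    out = []
    for cid in ids:
        where = np.argwhere(labels == cid)
        if where.size == 0:
            continue
        lo = np.maximum(where.min(axis=0) - pads, 0)
        hi = np.minimum(where.max(axis=0) + pads + 1, data.shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        bg = data[box][~structures[box]]
        out.append(
            {
                "id": int(cid),
                "peak": float(data[labels == cid].max()),
                "background_mean": float(bg.mean()) if bg.size else 0.0,
            }
        )
    return out
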