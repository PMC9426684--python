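"""Synthetic cine/LGE cardiac phantom with known ground truth.

The phantom emulates the statistical structure the pipeline assumes about a
short-axis slice: an annular myocardium around the LV blood pool contracting
and relaxing over one cardiac cycle, an optional scar sector whose local
contraction is reduced, and a single post-contrast (LGE-like) image in which
the scar is hyperintense and which is misaligned with the cine frames by a
known affine transform.

Motion model
------------
Material points move radially about the slice centre.  A point at reference
radius ``r`` and angle ``theta`` is found at radius ``r * c(r, theta, t)`` in
frame ``t`` where::

    c(r, theta, t) = 1 - amplitude * g(theta) * s(t) * w(r)
    s(t) = sin^2(pi * t / (n_frames - 1))          # the cycle closes exactly
    g(theta) = scar_contraction_factor inside the scar sector (tapered), 1 outside
    w(r) = 1 out to the epicardium, decaying to 0 a few pixels beyond

so frame 0 and the last frame are geometrically identical, the myocardium
contracts everywhere, and a scar sector moves less.  Frames are rendered by
sampling a fixed per-study reference texture through the inverse of this map,
which makes the brightness-constancy assumption of optical flow hold by
construction; the per-frame label masks are produced by the same inverse map
and are therefore exactly consistent with the images.

The image also contains static asymmetric extra-cardiac structure (a bright
chest-wall band and a dark lung field).  Real short-axis images carry such
structure, and without it an annular phantom is rotationally symmetric and
the rotation component of affine registration would be unidentifiable.

Labels: 0 background, 1 myocardium, 2 LV cavity, 3 scar (LGE mask only; in
the cine masks scar tissue is part of the myocardium, as it is anatomically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from ._utils import stage_seed
from .transforms import AffineParams, apply_affine

BACKGROUND, MYOCARDIUM, CAVITY, SCAR = 0, 1, 2, 3

# rendered intensity levels (arbitrary units in [0, 1])
_CINE_LEVELS = {"background": 0.35, "chest": 0.60, "lung": 0.08, "myo": 0.55, "cavity": 0.90}
_LGE_LEVELS = {"background": 0.35, "chest": 0.55, "lung": 0.08, "myo": 0.30, "cavity": 0.80}
_TEXTURE_SIGMA = 2.0
_TEXTURE_AMPLITUDE = 0.10  # unit-std texture field; below tissue contrast steps
_RENDER_BLUR = 0.8
_MOTION_DECAY_PX = 8.0
_SECTOR_TAPER_DEG = 10.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion, contrast and noise settings of one synthetic study."""

    image_size: int = 64
    n_frames: int = 32
    pixel_spacing_mm: float = 1.9
    frame_interval_ms: float = 30.0
    cavity_radius_px: float = 10.0
    myo_thickness_px: float = 6.0
    contraction_amplitude: float = 0.25
    scar_present: bool = False
    scar_sector_deg: tuple[float, float] = (30.0, 90.0)  # (start, extent)
    scar_contraction_factor: float = 0.4
    scar_intensity_delta: float = 0.6
    noise_sd: float = 0.03
    lge_misalignment: AffineParams = field(
        default_factory=lambda: AffineParams(
            translation=(4.0, -6.0), rotation_deg=8.0, scale=(1.02, 0.98), shear=0.02
        )
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 <= self.scar_contraction_factor < 1):
            raise ValueError("scar_contraction_factor must be in [0, 1)")
        if self.cavity_radius_px + self.myo_thickness_px >= self.image_size / 2:
            raise ValueError("myocardium does not fit inside the image")


@dataclass
class CineSequence:
    """Ordered cine frames of one slice location with trigger times."""

    frames: list
    trigger_times_ms: list
    pixel_spacing_mm: tuple[float, float]
    subject_id: str = "phantom"
    slice_id: str = "slice0"

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("a cine sequence needs at least one frame")
        if len(self.frames) != len(self.trigger_times_ms):
            raise ValueError("one trigger time per frame is required")
        tts = np.asarray(self.trigger_times_ms, dtype=float)
        if np.any(np.diff(tts) <= 0):
            raise ValueError("trigger times must be strictly increasing")
        shapes = {np.shape(f) for f in self.frames}
        if len(shapes) != 1:
            raise ValueError("all frames must share one shape")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return np.shape(self.frames[0])


@dataclass
class LgeRecord:
    """One LGE image with its trigger time, ground-truth mask and misalignment."""

    image: np.ndarray
    trigger_time_ms: float
    true_mask: np.ndarray
    true_misalignment: AffineParams = field(default_factory=AffineParams.identity)


@dataclass
class Study:
    """A full synthetic study: cine, per-frame masks, LGE record and label."""

    cine: CineSequence
    masks: list
    lge: LgeRecord
    label: int
    config: PhantomConfig


def _polar_grids(n: int):
    yy, xx = np.mgrid[:n, :n].astype(float)
    c = (n - 1) / 2.0
    dy, dx = yy - c, xx - c
    return np.hypot(dy, dx), np.arctan2(dx, dy)  # angle measured from +row axis


def _sector_weight(theta: np.ndarray, sector_deg: tuple[float, float]) -> np.ndarray:
    """1 inside the angular sector, 0 outside, cosine-tapered at the edges."""
    start, extent = sector_deg
    ang = (np.rad2deg(theta) - start) % 360.0
    # angular distance outside the sector (0 inside)
    d_out = np.where(ang <= extent, 0.0, np.minimum(ang - extent, 360.0 - ang))
    w = np.where(
        d_out < _SECTOR_TAPER_DEG,
        0.5 * (1.0 + np.cos(np.pi * np.minimum(d_out, _SECTOR_TAPER_DEG) / _SECTOR_TAPER_DEG)),
        0.0,
    )
    return w


def _contraction_field(cfg: PhantomConfig, radius, theta, phase: float):
    """Pointwise radial scale factor c(r, theta, t) of the motion model."""
    g = np.ones_like(theta)
    if cfg.scar_present:
        w_sector = _sector_weight(theta, cfg.scar_sector_deg)
        g = 1.0 - (1.0 - cfg.scar_contraction_factor) * w_sector
    r_epi = cfg.cavity_radius_px + cfg.myo_thickness_px
    w_r = np.clip(1.0 - (radius - r_epi) / _MOTION_DECAY_PX, 0.0, 1.0)
    return 1.0 - cfg.contraction_amplitude * g * phase * w_r


def _source_radius(cfg: PhantomConfig, rho, theta, phase: float, n_iter: int = 20):
    """Invert r * c(r, theta, t) = rho by bisection (c is a contraction, r >= rho)."""
    lo = rho.copy()
    hi = rho / max(1.0 - cfg.contraction_amplitude, 0.5) + 1.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f = mid * _contraction_field(cfg, mid, theta, phase)
        lo = np.where(f < rho, mid, lo)
        hi = np.where(f >= rho, mid, hi)
    return 0.5 * (lo + hi)


def _reference_scene(cfg: PhantomConfig, modality: str):
    """Reference-frame intensity image (levels + shared texture, blurred).

    The texture field is drawn from a seed shared by the cine and LGE
    renderings: both modalities image the same underlying tissue.
    """
    n = cfg.image_size
    levels = _CINE_LEVELS if modality == "cine" else _LGE_LEVELS
    radius, theta = _polar_grids(n)
    img = np.full((n, n), levels["background"])
    yy, xx = np.mgrid[:n, :n].astype(float)
    chest = (yy + 0.6 * xx) < 0.45 * n
    lung = ((yy - 0.7 * n) ** 2 / (0.35 * n) ** 2 + (xx - 0.85 * n) ** 2 / (0.25 * n) ** 2) < 1
    img[chest] = levels["chest"]
    img[lung] = levels["lung"]
    r_epi = cfg.cavity_radius_px + cfg.myo_thickness_px
    myo = (radius >= cfg.cavity_radius_px) & (radius < r_epi)
    img[myo] = levels["myo"]
    if modality == "lge" and cfg.scar_present:
        scar = myo & (_sector_weight(theta, cfg.scar_sector_deg) > 0.5)
        img[scar] = levels["myo"] + cfg.scar_intensity_delta
    img[radius < cfg.cavity_radius_px] = levels["cavity"]
    tex_rng = np.random.default_rng(stage_seed(cfg.seed, "texture"))
    texture = ndi.gaussian_filter(tex_rng.normal(0.0, 1.0, (n, n)), _TEXTURE_SIGMA)
    texture /= texture.std()  # unit std so the amplitude is meaningful
    img = img + _TEXTURE_AMPLITUDE * texture
    return ndi.gaussian_filter(img, _RENDER_BLUR)


def _mask_from_source_radius(cfg: PhantomConfig, r_src, theta, with_scar: bool):
    mask = np.zeros(r_src.shape, dtype=np.uint8)
    r_epi = cfg.cavity_radius_px + cfg.myo_thickness_px
    myo = (r_src >= cfg.cavity_radius_px) & (r_src < r_epi)
    mask[myo] = MYOCARDIUM
    mask[r_src < cfg.cavity_radius_px] = CAVITY
    if with_scar and cfg.scar_present:
        scar = myo & (_sector_weight(theta, cfg.scar_sector_deg) > 0.5)
        mask[scar] = SCAR
    return mask


def _render_phase(cfg: PhantomConfig, reference, phase: float, with_scar: bool):
    n = cfg.image_size
    radius, theta = _polar_grids(n)
    r_src = _source_radius(cfg, radius, theta, phase)
    c = (n - 1) / 2.0
    src_rows = c + r_src * np.cos(theta)
    src_cols = c + r_src * np.sin(theta)
    frame = ndi.map_coordinates(reference, [src_rows, src_cols], order=1, mode="nearest")
    mask = _mask_from_source_radius(cfg, r_src, theta, with_scar)
    return frame, mask


def contraction_phase(cfg: PhantomConfig, frame_index: int) -> float:
    """Normalised contraction drive s(t) in [0, 1] for a frame index."""
    return float(np.sin(np.pi * frame_index / (cfg.n_frames - 1)) ** 2)


def generate_cine_phantom(config: PhantomConfig):
    """Generate one cine sequence and its per-frame label masks.

    Returns ``(CineSequence, masks)`` where ``masks[t]`` labels frame ``t``
    with background/myocardium/cavity.  Determinism: identical config (same
    seed) gives bit-identical output.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "cine"))
    reference = _reference_scene(config, "cine")
    frames, masks = [], []
    for t in range(config.n_frames):
        frame, mask = _render_phase(config, reference, contraction_phase(config, t), False)
        frame = np.clip(frame + rng.normal(0.0, config.noise_sd, frame.shape), 0.0, None)
        frames.append(frame)
        masks.append(mask)
    tts = [t * config.frame_interval_ms for t in range(config.n_frames)]
    cine = CineSequence(
        frames=frames,
        trigger_times_ms=tts,
        pixel_spacing_mm=(config.pixel_spacing_mm, config.pixel_spacing_mm),
        subject_id=f"phantom-{config.seed}",
    )
    return cine, masks


def generate_lge_from_phantom(cine: CineSequence, masks, config: PhantomConfig) -> LgeRecord:
    """Render the LGE record for a phantom cine.

    One cardiac phase (late in the cycle, as LGE is acquired in diastole) is
    rendered with post-contrast intensity levels — hyperintense scar if
    present — then the configured misalignment is applied to the image
    (linear interpolation) and to the ground-truth mask (nearest neighbour).
    The LGE trigger time falls strictly between two cine trigger times.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "lge"))
    reference = _reference_scene(config, "lge")
    phase_index = int(round(0.8 * (config.n_frames - 1)))
    phase_index = min(phase_index, config.n_frames - 2)
    image, mask = _render_phase(
        config, reference, contraction_phase(config, phase_index), with_scar=True
    )
    bg = _LGE_LEVELS["background"]
    moved = apply_affine(image, config.lge_misalignment, "linear", cval=bg)
    moved = np.clip(moved + rng.normal(0.0, config.noise_sd, moved.shape), 0.0, None)
    moved_mask = apply_affine(mask, config.lge_misalignment, "nearest", cval=0)
    tts = cine.trigger_times_ms
    tt = tts[phase_index] + 0.4 * (tts[phase_index + 1] - tts[phase_index])
    return LgeRecord(
        image=moved,
        trigger_time_ms=float(tt),
        true_mask=moved_mask,
        true_misalignment=config.lge_misalignment,
    )


def generate_study(config: PhantomConfig) -> Study:
    """Generate one complete study (cine + masks + LGE + label)."""
    cine, masks = generate_cine_phantom(config)
    lge = generate_lge_from_phantom(cine, masks, config)
    return Study(cine=cine, masks=masks, lge=lge, label=int(config.scar_present), config=config)


def generate_cohort(
    n_scar: int,
    n_healthy: int,
    config_template: PhantomConfig | None = None,
    seed: int = 0,
):
    """Generate a cohort of studies with per-study parameter jitter.

    Geometry, contraction, noise, scar sector and LGE misalignment are
    jittered deterministically from ``seed``; scar studies come first in the
    returned list.  Returns ``(studies, labels)``.
    """
    if n_scar < 0 or n_healthy < 0:
        raise ValueError("cohort counts must be >= 0")
    template = config_template or PhantomConfig()
    rng = np.random.default_rng(stage_seed(seed, "cohort"))
    studies = []
    for i in range(n_scar + n_healthy):
        scar = i < n_scar
        cfg = replace(
            template,
            cavity_radius_px=template.cavity_radius_px + rng.uniform(-1.0, 1.0),
            myo_thickness_px=template.myo_thickness_px + rng.uniform(-0.75, 0.75),
            contraction_amplitude=template.contraction_amplitude + rng.uniform(-0.01, 0.01),
            noise_sd=template.noise_sd * rng.uniform(0.8, 1.2),
            scar_present=scar,
            scar_sector_deg=(rng.uniform(0.0, 360.0), rng.uniform(80.0, 140.0)),
            scar_contraction_factor=rng.uniform(0.25, 0.45),
            lge_misalignment=AffineParams(
                translation=tuple(rng.uniform(-8.0, 8.0, 2)),
                rotation_deg=rng.uniform(-12.0, 12.0),
                scale=tuple(rng.uniform(0.92, 1.08, 2)),
                shear=rng.uniform(-0.05, 0.05),
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        studies.append(generate_study(cfg))
    labels = np.array([s.label for s in studies], dtype=int)
    return studies, labels


def sector_mask(mask: np.ndarray, sector_deg: tuple[float, float], label: int = MYOCARDIUM):
    """Pixels of ``mask`` equal to ``label`` that lie in an angular sector."""
    radius, theta = _polar_grids(mask.shape[0])
    return (mask == label) & (_sector_weight(theta, sector_deg) > 0.5)


def sector_mean_radius(mask: np.ndarray, sector_deg: tuple[float, float]) -> float:
    """Mean radius of myocardium pixels inside a sector (boundary-motion probe)."""
    sel = sector_mask(mask, sector_deg)
    if not sel.any():
        return float("nan")
    radius, _ = _polar_grids(mask.shape[0])
    return float(radius[sel].mean())
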