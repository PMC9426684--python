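"""Ground-truth preparation: trigger-time matching, mutual-information affine
registration of the LGE image onto its cine frame, fixed-length stacking and
automated alignment quality control.

Registration maximises a Mattes-style mutual information metric — computed
from the joint intensity histogram of the fixed and resampled moving image —
with a (1+1) evolutionary strategy: a single-parent stochastic hill climber
whose perturbation radius grows on acceptance and shrinks on rejection.  The
search runs over (translation, rotation, per-axis log-scale, shear), coarse
to fine over a 3-level pyramid, after a deterministic initialisation from
intensity centroids and a coarse rotation sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from ._utils import as_float_image, check_same_shape
from .phantom import MYOCARDIUM, CineSequence
from .transforms import AffineParams, apply_affine

__all__ = [
    "RegistrationConfig",
    "RegistrationReport",
    "PairedSample",
    "match_frame_by_trigger_time",
    "mattes_mutual_information",
    "register_affine_mi",
    "apply_affine",
    "stack_to_fixed_length",
    "qc_alignment",
    "prepare_paired_sample",
]

STACK_LENGTH = 32


@dataclass(frozen=True)
class RegistrationConfig:
    """Metric and optimiser settings for MI affine registration.

    ``iterations_per_level`` is the (1+1)-ES budget at each pyramid level,
    coarse to fine.  ``initial_radius`` is expressed in units of the
    per-parameter steps (1 px translation, 1 degree rotation, 0.01 for
    log-scale and shear).  ``sample_fraction`` < 1 subsamples pixels when
    estimating the joint histogram.
    """

    histogram_bins: int = 50
    sample_fraction: float = 1.0
    growth_factor: float = 1.05
    epsilon: float = 1.5e-6
    initial_radius: float = 1.0
    iterations_per_level: tuple[int, ...] = (120, 200, 300)
    pyramid: tuple[tuple[int, float], ...] = ((4, 2.0), (2, 1.0), (1, 0.0))
    rotation_sweep_deg: float = 18.0
    rotation_sweep_step_deg: float = 3.0
    translation_sweep_px: float = 12.0
    translation_sweep_step_px: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if min(self.iterations_per_level) < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class RegistrationReport:
    """Best-so-far optimisation record (non-convergence is not an error)."""

    mi_before: float
    mi_after: float
    iterations: int
    accepted: int


@dataclass
class PairedSample:
    """A 32-frame cine stack paired with its registered LGE ground truth."""

    cine_stack: np.ndarray  # (32, H, W)
    matched_frame_index: int
    mask: np.ndarray  # registered LGE labels, values in {0,1,2,3}
    label: int
    qc_score: float
    qc_pass: bool
    registration: AffineParams | None = None
    qc_reason: str = ""

    def __post_init__(self):
        if len(self.cine_stack) != STACK_LENGTH:
            raise ValueError(f"cine stack must have exactly {STACK_LENGTH} frames")
        if not set(np.unique(self.mask)).issubset({0, 1, 2, 3}):
            raise ValueError("mask values must be in {0,1,2,3}")


def match_frame_by_trigger_time(cine: CineSequence, lge_tt_ms: float) -> int:
    """Index of the cine frame whose trigger time is closest to the LGE's.

    Ties are broken toward the earlier frame.
    """
    tts = np.asarray(cine.trigger_times_ms, dtype=float)
    if tts.size == 0:
        raise ValueError("empty cine sequence")
    return int(np.argmin(np.abs(tts - lge_tt_ms)))


def _joint_histogram(fixed, moving, bins, sample_idx=None):
    a = fixed.ravel()
    b = moving.ravel()
    if sample_idx is not None:
        a, b = a[sample_idx], b[sample_idx]
    amin, amax = a.min(), a.max()
    bmin, bmax = b.min(), b.max()
    if amax <= amin or bmax <= bmin:
        return None
    ai = np.minimum((a - amin) / (amax - amin) * bins, bins - 1).astype(np.intp)
    bi = np.minimum((b - bmin) / (bmax - bmin) * bins, bins - 1).astype(np.intp)
    h = np.bincount(ai * bins + bi, minlength=bins * bins).astype(float)
    return h.reshape(bins, bins)


def mattes_mutual_information(fixed, moving, cfg: RegistrationConfig | None = None) -> float:
    """Mutual information (nats) of two equally shaped images.

    Estimated from the joint histogram with ``cfg.histogram_bins`` bins per
    axis, each image binned over its own intensity range.  Images with fewer
    than two distinct values have MI defined as 0.
    """
    cfg = cfg or RegistrationConfig()
    fixed = as_float_image(fixed)
    moving = as_float_image(moving)
    check_same_shape(fixed, moving)
    idx = None
    if cfg.sample_fraction < 1.0:
        rng = np.random.default_rng(cfg.seed)
        n = fixed.size
        idx = rng.choice(n, size=max(2, int(cfg.sample_fraction * n)), replace=False)
    h = _joint_histogram(fixed, moving, cfg.histogram_bins, idx)
    if h is None:
        return 0.0
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px * py)[nz])))


_PARAM_STEPS = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01])  # px, px, deg, log-scale x2, shear


def _warp_vector(moving, vec, cval, shrink=1):
    p = AffineParams.from_vector(
        [vec[0] / shrink, vec[1] / shrink, vec[2], vec[3], vec[4], vec[5]]
    )
    return apply_affine(moving, p, "linear", cval=cval)


def register_affine_mi(fixed, moving, cfg: RegistrationConfig | None = None):
    """Register ``moving`` onto ``fixed`` by maximising mutual information.

    Returns ``(AffineParams, resampled_moving, RegistrationReport)``.  The
    returned parameters are a content transform: ``apply_affine(moving,
    params)`` is the resampled image.  The optimum is best-so-far — by
    construction ``MI(fixed, resampled) >= MI(fixed, moving)``.
    """
    cfg = cfg or RegistrationConfig()
    fixed = as_float_image(fixed)
    moving = as_float_image(moving)
    check_same_shape(fixed, moving)
    rng = np.random.default_rng(cfg.seed)
    cval = float(np.median(moving))
    mi_before = mattes_mutual_information(fixed, moving, cfg)

    # deterministic initialisation: exhaustive translation x rotation sweep at
    # the coarsest level (centroid-shift candidate included)
    shrink0, sigma0 = cfg.pyramid[0]
    f0 = ndi.zoom(ndi.gaussian_filter(fixed, sigma0), 1.0 / shrink0, order=1)
    m0 = ndi.zoom(ndi.gaussian_filter(moving, sigma0), 1.0 / shrink0, order=1)
    cf = np.array(ndi.center_of_mass(f0 - f0.min() + 1e-12))
    cm = np.array(ndi.center_of_mass(m0 - m0.min() + 1e-12))
    t_centroid = (cf - cm) * shrink0  # content shift aligning moving onto fixed
    t_grid = np.arange(
        -cfg.translation_sweep_px, cfg.translation_sweep_px + 1e-9, cfg.translation_sweep_step_px
    )
    candidates = [np.array([dr, dc]) for dr in t_grid for dc in t_grid]
    candidates.append(t_centroid)
    sweep = np.arange(
        -cfg.rotation_sweep_deg, cfg.rotation_sweep_deg + 1e-9, cfg.rotation_sweep_step_deg
    )
    best_vec, best_val = None, -np.inf
    for t_init in candidates:
        for ang in sweep:
            vec = np.array([t_init[0], t_init[1], ang, 0.0, 0.0, 0.0])
            val = mattes_mutual_information(f0, _warp_vector(m0, vec, cval, shrink0), cfg)
            if val > best_val:
                best_vec, best_val = vec, val

    vec = best_vec
    total_iters = 0
    total_accept = 0
    shrink_factor = cfg.growth_factor**-0.25
    for (shrink, sigma), n_iter in zip(cfg.pyramid, cfg.iterations_per_level):
        if shrink > 1:
            f = ndi.zoom(ndi.gaussian_filter(fixed, sigma), 1.0 / shrink, order=1)
            m = ndi.zoom(ndi.gaussian_filter(moving, sigma), 1.0 / shrink, order=1)
        else:
            f, m = fixed, moving
        current = mattes_mutual_information(f, _warp_vector(m, vec, cval, shrink), cfg)
        radius = cfg.initial_radius
        for _ in range(n_iter):
            total_iters += 1
            cand = vec + rng.normal(0.0, 1.0, 6) * _PARAM_STEPS * radius
            val = mattes_mutual_information(f, _warp_vector(m, cand, cval, shrink), cfg)
            if val > current:
                vec, current = cand, val
                radius *= cfg.growth_factor
                total_accept += 1
            else:
                radius *= shrink_factor
            if radius < cfg.epsilon:
                break

    params = AffineParams.from_vector(vec)
    resampled = apply_affine(moving, params, "linear", cval=cval)
    mi_after = mattes_mutual_information(fixed, resampled, cfg)
    if mi_after < mi_before:  # best-so-far guarantee
        params = AffineParams.identity()
        resampled = moving.copy()
        mi_after = mi_before
    return params, resampled, RegistrationReport(mi_before, mi_after, total_iters, total_accept)


def stack_to_fixed_length(frames, target: int = STACK_LENGTH) -> np.ndarray:
    """Pad with zero frames (appended) or truncate to exactly ``target`` frames."""
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if len(frames) >= target:
        return np.stack(frames[:target])
    pad = [np.zeros_like(frames[0]) for _ in range(target - len(frames))]
    return np.stack(frames + pad)


def _remove_radial_profile(values, radii, n_bins: int = 32):
    """Subtract the per-radius mean so only angular structure remains."""
    bins = np.minimum((radii / (radii.max() + 1e-9) * n_bins).astype(int), n_bins - 1)
    out = values.astype(float).copy()
    for b in np.unique(bins):
        sel = bins == b
        out[sel] -= out[sel].mean()
    return out


def qc_alignment(cine_frame, registered_lge, myocardium_mask, threshold: float = 0.5):
    """Alignment score: normalised cross-correlation over a dilated myocardial band.

    Each image's radially symmetric intensity profile (about the myocardium
    centroid) is removed before correlating, so the score measures agreement
    of the *angular* structure and drops under residual rotation or
    translation even for a near-annular heart.  Returns ``(score, passed,
    reason)``; misaligned pairs are flagged, never deleted.  An empty
    myocardium mask fails with reason ``"empty ROI"`` and a NaN score.
    """
    cine_frame = as_float_image(cine_frame)
    registered_lge = as_float_image(registered_lge)
    check_same_shape(cine_frame, registered_lge)
    from .phantom import SCAR

    labels = np.asarray(myocardium_mask)
    myo = labels == MYOCARDIUM
    # scar is enhancing in LGE only, so it is excluded from the comparison band
    band = ndi.binary_dilation(myo, iterations=3) & (labels != SCAR)
    if not band.any():
        return float("nan"), False, "empty ROI"
    heart = labels > 0  # whole-heart centroid is robust to a missing scar sector
    centre = np.argwhere(heart).mean(axis=0)
    coords = np.argwhere(band)
    radii = np.hypot(coords[:, 0] - centre[0], coords[:, 1] - centre[1])
    a = _remove_radial_profile(cine_frame[band], radii)
    b = _remove_radial_profile(registered_lge[band], radii)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan"), False, "constant intensities in ROI"
    score = float(np.mean(a * b) / (sa * sb))
    return score, bool(score >= threshold), ""


def prepare_paired_sample(
    study,
    reg_cfg: RegistrationConfig | None = None,
    qc_threshold: float = 0.5,
) -> PairedSample:
    """Run the full preparation chain on one study.

    Trigger-time matching, MI affine registration of the LGE onto the matched
    cine frame, transfer of the LGE label mask into cine coordinates, zero
    padding to 32 frames and alignment QC.
    """
    idx = match_frame_by_trigger_time(study.cine, study.lge.trigger_time_ms)
    fixed = study.cine.frames[idx]
    params, resampled, _report = register_affine_mi(fixed, study.lge.image, reg_cfg)
    mask = apply_affine(study.lge.true_mask, params, "nearest", cval=0)
    score, passed, reason = qc_alignment(fixed, resampled, mask, threshold=qc_threshold)
    stack = stack_to_fixed_length(study.cine.frames, STACK_LENGTH)
    return PairedSample(
        cine_stack=stack,
        matched_frame_index=idx,
        mask=mask,
        label=study.label,
        qc_score=score,
        qc_pass=passed,
        registration=params,
        qc_reason=reason,
    )
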