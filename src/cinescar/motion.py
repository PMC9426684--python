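"""Motion features from cine frames: Lucas-Kanade optical flow, pixel-wise
displacement maps with a frame skip interval, PCA compression of the maps,
and the rate-of-myocardial-area-change series.

The flow solver is the classic windowed least-squares Lucas-Kanade scheme:
per pixel, the 2x2 structure-tensor normal equations are accumulated over a
local neighbourhood (an 8x8 box by default) with Gaussian weights (5x5
kernel, sigma 3 per axis), using central-difference spatial gradients and
the plain frame difference as the temporal gradient.  Pixels whose smallest
structure-tensor eigenvalue falls below a floor (the aperture problem) get
zero velocity and a low-confidence flag.

Displacement follows r = v * k * dt: the raw inter-frame LK displacement is
converted to a velocity per millisecond using the trigger-time difference of
the frame pair, so r recovers the pixel displacement while v is a physical
rate.  The magnitude is Euclidean, sqrt(vx^2 + vy^2); a literal component
sum |vx| + |vy| is available behind ``magnitude="sum"`` for strict
reproduction of the printed formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from ._utils import as_float_image, check_same_shape
from .phantom import MYOCARDIUM


@dataclass(frozen=True)
class FlowConfig:
    """Lucas-Kanade window/weighting settings and the frame skip interval."""

    window: int = 8
    gaussian_kernel: int = 5
    gaussian_sigma: float = 3.0
    skip_interval: int = 3
    eigenvalue_floor: float = 1e-3
    magnitude: str = "euclidean"  # or "sum"

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.gaussian_kernel % 2 != 1:
            raise ValueError("gaussian kernel size must be odd")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian sigma must be > 0")
        if self.skip_interval < 1:
            raise ValueError("skip interval must be >= 1")
        if self.magnitude not in ("euclidean", "sum"):
            raise ValueError("magnitude must be 'euclidean' or 'sum'")


@dataclass
class FlowField:
    """Per-pixel flow of one frame pair.

    ``vx``/``vy`` are column/row velocity components in px/ms; ``raw_dx``/
    ``raw_dy`` are the LK displacements in px between the two frames;
    ``confident`` flags pixels where the normal equations were well
    conditioned.  ``dt_ms`` is the trigger-time difference of the pair
    divided by ``k`` (the per-unit-skip interval), so that the displacement
    ``r = |v| * k * dt`` recovers the raw pixel displacement.
    """

    vx: np.ndarray
    vy: np.ndarray
    raw_dx: np.ndarray
    raw_dy: np.ndarray
    confident: np.ndarray
    dt_ms: float
    k: int


def lucas_kanade_flow(frame_a, frame_b, cfg: FlowConfig | None = None) -> FlowField:
    """Dense LK optical flow from ``frame_a`` to ``frame_b`` (velocities only).

    The returned field has unit time: ``raw_dx``/``raw_dy`` are displacements
    in pixels between the two frames, with ``dt_ms`` unset (1.0).  Use
    :func:`scale_flow_to_time` or :func:`displacement_magnitude` to apply the
    acquisition timing.
    """
    cfg = cfg or FlowConfig()
    a = as_float_image(frame_a)
    b = as_float_image(frame_b)
    check_same_shape(a, b)
    gy, gx = np.gradient(a)  # central differences; gx along columns
    gt = b - a

    def accumulate(img):
        sm = ndi.gaussian_filter(
            img, cfg.gaussian_sigma, truncate=(cfg.gaussian_kernel // 2) / cfg.gaussian_sigma
        )
        return ndi.uniform_filter(sm, size=cfg.window)

    sxx = accumulate(gx * gx)
    syy = accumulate(gy * gy)
    sxy = accumulate(gx * gy)
    sxt = accumulate(gx * gt)
    syt = accumulate(gy * gt)

    # eigenvalues of the symmetric 2x2 structure tensor
    tr = sxx + syy
    det = sxx * syy - sxy * sxy
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    lam_min = tr / 2.0 - disc
    confident = lam_min >= cfg.eigenvalue_floor

    # solve  [sxx sxy; sxy syy] [dx; dy] = -[sxt; syt]
    safe_det = np.where(confident, det, 1.0)
    dx = np.where(confident, (-sxt * syy + syt * sxy) / safe_det, 0.0)
    dy = np.where(confident, (-syt * sxx + sxt * sxy) / safe_det, 0.0)
    return FlowField(
        vx=dx.copy(), vy=dy.copy(), raw_dx=dx, raw_dy=dy, confident=confident, dt_ms=1.0, k=1
    )


def scale_flow_to_time(field: FlowField, dt_ms: float, k: int) -> FlowField:
    """Convert raw per-pair displacements into velocities per millisecond."""
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    scale = 1.0 / (k * dt_ms)
    return FlowField(
        vx=field.raw_dx * scale,
        vy=field.raw_dy * scale,
        raw_dx=field.raw_dx,
        raw_dy=field.raw_dy,
        confident=field.confident,
        dt_ms=float(dt_ms),
        k=int(k),
    )


def velocity_magnitude(field: FlowField, magnitude: str = "euclidean") -> np.ndarray:
    """Per-pixel |v| in px/ms (Euclidean by default, component sum optionally)."""
    if magnitude == "euclidean":
        return np.hypot(field.vx, field.vy)
    if magnitude == "sum":
        return np.abs(field.vx) + np.abs(field.vy)
    raise ValueError("magnitude must be 'euclidean' or 'sum'")


def displacement_magnitude(
    field: FlowField, dt_ms: float | None = None, k: int | None = None, magnitude: str = "euclidean"
) -> np.ndarray:
    """Pixel-wise displacement r = |v| * k * dt for a frame pair k apart.

    ``field.vx``/``vy`` are read as velocities; ``dt_ms`` and ``k`` default
    to the values stored on the field.
    """
    dt = field.dt_ms if dt_ms is None else dt_ms
    kk = field.k if k is None else k
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return velocity_magnitude(field, magnitude) * kk * dt


def enumerate_frame_pairs(n_frames: int, k: int) -> list[tuple[int, int]]:
    """Frame pairs (i, min(i+k, n-1)) for start indices i = 0, k, 2k, ...

    Start indices run while i <= n_frames - 2; the partner frame is clipped
    to the last frame.  For 32 frames and k=3 this yields 11 pairs.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if k < 1:
        raise ValueError("skip interval must be >= 1")
    return [(i, min(i + k, n_frames - 1)) for i in range(0, n_frames - 1, k)]


def displacement_maps(cine, cfg: FlowConfig | None = None) -> np.ndarray:
    """Stack of displacement-magnitude maps over the canonical pair enumeration.

    Returns an array of shape (n_pairs, H, W); with 32 frames and the default
    skip interval 3 that is 11 maps.
    """
    cfg = cfg or FlowConfig()
    pairs = enumerate_frame_pairs(cine.n_frames, cfg.skip_interval)
    tts = np.asarray(cine.trigger_times_ms, dtype=float)
    maps = []
    for i, j in pairs:
        field = lucas_kanade_flow(cine.frames[i], cine.frames[j], cfg)
        dt = (tts[j] - tts[i]) / (j - i)
        field = scale_flow_to_time(field, dt, j - i)
        maps.append(displacement_magnitude(field, magnitude=cfg.magnitude))
    return np.stack(maps)


class FlowPCAFeaturizer:
    """PCA compression of displacement maps into a per-study feature row.

    sklearn-style transformer: ``fit`` learns one PCA per frame-pair position
    over the vectorised maps of the training studies (to avoid leakage, fit
    on the training split only); ``transform`` projects each study's maps and
    concatenates the projections into a row vector of length
    ``n_pairs * n_components``.
    """

    def __init__(self, n_components: int = 8):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "FlowPCAFeaturizer":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, maps: np.ndarray, y=None) -> "FlowPCAFeaturizer":
        """``maps`` has shape (n_studies, n_pairs, H, W)."""
        from sklearn.decomposition import PCA

        maps = np.asarray(maps, dtype=float)
        if maps.ndim != 4:
            raise ValueError("expected (n_studies, n_pairs, H, W) displacement maps")
        n_studies, n_pairs = maps.shape[:2]
        flat = maps.reshape(n_studies, n_pairs, -1)
        n_comp = min(self.n_components, n_studies, flat.shape[2])
        self.pcas_ = [PCA(n_components=n_comp, random_state=0).fit(flat[:, p]) for p in range(n_pairs)]
        self.n_pairs_ = n_pairs
        self.n_components_ = n_comp
        self.map_shape_ = maps.shape[2:]
        return self

    def transform(self, maps: np.ndarray) -> np.ndarray:
        if not hasattr(self, "pcas_"):
            raise RuntimeError("FlowPCAFeaturizer must be fitted before transform")
        maps = np.asarray(maps, dtype=float)
        flat = maps.reshape(maps.shape[0], maps.shape[1], -1)
        if flat.shape[1] != self.n_pairs_:
            raise ValueError("pair count differs from the fitted layout")
        parts = [self.pcas_[p].transform(flat[:, p]) for p in range(self.n_pairs_)]
        return np.concatenate(parts, axis=1)

    def fit_transform(self, maps: np.ndarray, y=None) -> np.ndarray:
        return self.fit(maps).transform(maps)

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        """Reconstruct displacement maps from projections (for diagnostics)."""
        rows = np.asarray(rows, dtype=float)
        n = self.n_components_
        recon = [
            self.pcas_[p].inverse_transform(rows[:, p * n : (p + 1) * n])
            for p in range(self.n_pairs_)
        ]
        return np.stack(recon, axis=1).reshape(rows.shape[0], self.n_pairs_, *self.map_shape_)

    def feature_names(self) -> list[str]:
        return [
            f"flow_pc_{p}_{c}" for p in range(self.n_pairs_) for c in range(self.n_components_)
        ]


def flow_feature_vector(displacement_maps_one_study, featurizer: FlowPCAFeaturizer) -> np.ndarray:
    """Project one study's displacement maps with a fitted featurizer."""
    maps = np.asarray(displacement_maps_one_study, dtype=float)[None]
    return featurizer.transform(maps)[0]


def save_displacement_maps(maps: np.ndarray, path, pixel_spacing_mm=(1.0, 1.0)) -> None:
    """Export a (n_pairs, H, W) displacement stack as a NIfTI volume."""
    import nibabel as nib

    vol = np.moveaxis(np.asarray(maps, dtype=np.float32), 0, -1)
    affine = np.diag([pixel_spacing_mm[0], pixel_spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


@dataclass
class AreaChangeSeries:
    """Rate of myocardial area change a_i = (A_{i+k} - A_i) / (k * dt) per pair."""

    values: np.ndarray  # mm^2/ms (or px^2/ms with unit spacing)
    frame_pairs: list
    areas: np.ndarray
    undefined: np.ndarray  # True where the myocardium label was missing


def area_change_series(
    masks, trigger_times_ms, k: int = 3, spacing_mm: tuple[float, float] = (1.0, 1.0)
) -> AreaChangeSeries:
    """Myocardial area-change rate over the canonical frame-pair enumeration.

    ``A_i`` is the myocardium pixel count times the pixel area; each pair
    contributes ``(A_j - A_i) / (t_j - t_i)``, which is ΔA/(kΔt) under
    uniform frame spacing.  Pairs whose frames lack the myocardium label are
    flagged undefined (NaN), not dropped.
    """
    masks = [np.asarray(m) for m in masks]
    tts = np.asarray(trigger_times_ms, dtype=float)
    if len(masks) != len(tts):
        raise ValueError("one trigger time per mask is required")
    pairs = enumerate_frame_pairs(len(masks), k)
    pixel_area = float(spacing_mm[0]) * float(spacing_mm[1])
    areas = np.array([float(np.sum(m == MYOCARDIUM)) * pixel_area for m in masks])
    values, undefined = [], []
    for i, j in pairs:
        missing = areas[i] == 0 or areas[j] == 0
        undefined.append(missing)
        values.append(np.nan if missing else (areas[j] - areas[i]) / (tts[j] - tts[i]))
    return AreaChangeSeries(
        values=np.asarray(values),
        frame_pairs=pairs,
        areas=areas,
        undefined=np.asarray(undefined),
    )
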