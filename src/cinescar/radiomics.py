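"""From-scratch 2D radiomics on the myocardium mask plus feature filtering.

The extraction chain mirrors common radiomics practice on short-axis CMR:
resample in-plane to a common pixel spacing (1.9 mm) with separable area
(box) interpolation, normalise intensities to the 1-99 percentile window
quantised to 256 levels, then compute shape, first-order and gray-level
run-length matrix (GLRLM) texture features on three frames of the cycle
(end-diastole, end-systole and the frame midway between them).

Feature selection is two-stage: a greedy redundancy filter drops any feature
whose absolute Pearson correlation with an already-kept feature exceeds 0.9
(canonical sorted-name order makes the pass deterministic), then a
significance filter keeps features whose point-biserial correlation with the
binary outcome has p < 0.001 (t distribution, n-2 df).  Both are exposed as
sklearn-style transformers over pandas feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import perimeter_crofton

from .phantom import CAVITY

GLRLM_ANGLES_DEG = (0, 45, 90, 135)


@dataclass(frozen=True)
class RadiomicsConfig:
    target_spacing_mm: float = 1.9
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    n_levels: int = 256
    glrlm_angles: tuple[int, ...] = GLRLM_ANGLES_DEG

    def __post_init__(self):
        if self.norm_percentiles[0] >= self.norm_percentiles[1]:
            raise ValueError("low percentile must be below high percentile")
        if self.n_levels < 2:
            raise ValueError("need at least 2 intensity levels")
        if self.target_spacing_mm <= 0:
            raise ValueError("target spacing must be > 0")


def _area_resample_1d(arr: np.ndarray, axis: int, spacing: float, target: float) -> np.ndarray:
    """Area (box) interpolation along one axis, treating pixels as constant cells."""
    arr = np.moveaxis(np.asarray(arr, dtype=float), axis, 0)
    n = arr.shape[0]
    extent = n * spacing
    n_out = max(1, int(round(extent / target)))
    # cumulative integral of the piecewise-constant profile at cell edges
    flat = arr.reshape(n, -1)
    cum = np.vstack([np.zeros((1, flat.shape[1])), np.cumsum(flat * spacing, axis=0)])
    edges_in = np.arange(n + 1) * spacing
    edges_out = np.minimum(np.arange(n_out + 1) * target, extent)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        c = np.interp(edges_out, edges_in, cum[:, j])
        out[:, j] = np.diff(c) / np.diff(edges_out)
    out = out.reshape((n_out,) + arr.shape[1:])
    return np.moveaxis(out, 0, axis)


def resample_inplane(image, mask, spacing_mm, target_mm: float = 1.9):
    """Resample an image/mask pair to an isotropic in-plane target spacing.

    The image uses separable area interpolation (conserves total intensity x
    area for interior content); the mask uses nearest-neighbour sampling at
    the output pixel centres so labels are preserved.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be > 0")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (2,))
    img = np.asarray(image, dtype=float)
    out = _area_resample_1d(img, 0, spacing[0], target_mm)
    out = _area_resample_1d(out, 1, spacing[1], target_mm)
    msk = np.asarray(mask)
    idx = []
    for ax in range(2):
        centres = (np.arange(out.shape[ax]) + 0.5) * target_mm
        src = np.clip(np.floor(centres / spacing[ax]).astype(int), 0, msk.shape[ax] - 1)
        idx.append(src)
    out_mask = msk[np.ix_(idx[0], idx[1])]
    return out, out_mask


def normalize_intensity(image, mask, cfg: RadiomicsConfig | None = None):
    """Clip to the masked percentile window and quantise to level indices.

    Returns ``(levels, degenerate_flag)`` where ``levels`` is an integer
    image over ``{0, ..., n_levels-1}``.  A degenerate window (equal
    percentiles) maps everything to level 0 and sets the flag.
    """
    cfg = cfg or RadiomicsConfig()
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask) > 0
    if not msk.any():
        raise ValueError("empty mask")
    lo, hi = np.percentile(img[msk], cfg.norm_percentiles)
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.int64), True
    clipped = np.clip(img, lo, hi)
    levels = np.rint((clipped - lo) / (hi - lo) * (cfg.n_levels - 1)).astype(np.int64)
    return levels, False


def shape2d_features(mask, spacing_mm: float = 1.0) -> dict:
    """2D shape features of a binary mask (physical units via ``spacing_mm``).

    Axis lengths use the 4*sqrt(eigenvalue) second-central-moment convention;
    the maximum diameter is the largest pairwise distance between boundary
    pixel centres; the perimeter is the Crofton estimate; sphericity is
    2*sqrt(pi*A)/P (1 for a disk).
    """
    msk = np.asarray(mask) > 0
    coords = np.argwhere(msk).astype(float)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    major = 4.0 * np.sqrt(max(eig[0], 0.0)) * spacing_mm
    minor = 4.0 * np.sqrt(max(eig[1], 0.0)) * spacing_mm
    if coords.shape[0] >= 4:
        try:
            hull_pts = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (collinear) point sets
            hull_pts = coords
    else:
        hull_pts = coords
    max_diam = float(pdist(hull_pts).max()) * spacing_mm if len(hull_pts) > 1 else 0.0
    perim = float(perimeter_crofton(msk, directions=4)) * spacing_mm
    if perim == 0.0:
        perim = 4.0 * spacing_mm  # single-pixel contour fallback
    area = float(msk.sum()) * spacing_mm**2
    sphericity = 2.0 * np.sqrt(np.pi * area) / perim
    return {
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "maximum_diameter": max_diam,
        "perimeter": perim,
        "sphericity": float(sphericity),
    }


def firstorder_features(image, mask, pixel_area_mm2: float = 1.0) -> dict:
    """First-order intensity statistics over the masked pixels.

    Percentiles use the linear-interpolation (between closest ranks)
    convention of ``numpy.percentile``.
    """
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask) > 0
    if not msk.any():
        raise ValueError("empty mask")
    x = img[msk]
    energy = float(np.sum(x**2))
    return {
        "energy": energy,
        "total_energy": energy * pixel_area_mm2,
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "maximum": float(np.max(x)),
        "range": float(np.max(x) - np.min(x)),
        "rms": float(np.sqrt(energy / x.size)),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _lines_along(shape, angle: int):
    """Index lines covering the grid along one GLRLM direction."""
    rows, cols = shape
    dr, dc = _ANGLE_STEPS[angle]
    if angle == 0:
        for r in range(rows):
            yield r * np.ones(cols, dtype=int), np.arange(cols)
    elif angle == 90:
        for c in range(cols):
            yield np.arange(rows), c * np.ones(rows, dtype=int)
    else:
        # diagonals: start from every border cell and walk (dr, dc)
        starts = [(rows - 1, c) for c in range(cols)]
        starts += [(r, 0 if dc > 0 else cols - 1) for r in range(rows - 1)]
        for r0, c0 in starts:
            rr, cc = [], []
            r, c = r0, c0
            while 0 <= r < rows and 0 <= c < cols:
                rr.append(r)
                cc.append(c)
                r += dr
                c += dc
            yield np.asarray(rr), np.asarray(cc)


def glrlm_matrix(levels, mask, angle: int) -> dict:
    """Run-length counts {(gray, length): count} along one direction.

    Runs are maximal stretches of equal quantised level among consecutive
    in-mask pixels; leaving the mask breaks a run.
    """
    lv = np.asarray(levels)
    msk = np.asarray(mask) > 0
    counts: dict = {}
    for rr, cc in _lines_along(lv.shape, angle):
        vals = lv[rr, cc]
        inside = msk[rr, cc]
        run_val, run_len = None, 0
        for v, ok in zip(vals, inside):
            if ok and v == run_val:
                run_len += 1
            else:
                if run_len:
                    counts[(run_val, run_len)] = counts.get((run_val, run_len), 0) + 1
                run_val, run_len = (v, 1) if ok else (None, 0)
        if run_len:
            counts[(run_val, run_len)] = counts.get((run_val, run_len), 0) + 1
    return counts


def _glrlm_features_single(counts: dict) -> dict:
    n_z = sum(counts.values())
    by_gray: dict = {}
    by_len: dict = {}
    for (g, l), c in counts.items():
        by_gray[g] = by_gray.get(g, 0) + c
        by_len[l] = by_len.get(l, 0) + c
    gln = sum(v**2 for v in by_gray.values()) / n_z
    rln = sum(v**2 for v in by_len.values()) / n_z
    p = np.array(list(counts.values()), dtype=float) / n_z
    run_entropy = float(-np.sum(p * np.log2(p)))
    return {
        "gray_level_nonuniformity": float(gln),
        "run_length_nonuniformity": float(rln),
        "run_length_nonuniformity_normalized": float(rln / n_z),
        "run_entropy": run_entropy,
    }


def glrlm_features(levels, mask, angles=GLRLM_ANGLES_DEG) -> dict:
    """GLRLM texture features averaged over the four 2D directions."""
    if not (np.asarray(mask) > 0).any():
        raise ValueError("empty mask")
    per_angle = [_glrlm_features_single(glrlm_matrix(levels, mask, a)) for a in angles]
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


def select_frames_ed_es_mid(masks) -> tuple[int, int, int, bool]:
    """End-diastolic, end-systolic and middle frame indices from cavity area.

    ED is the argmax of the cavity area, ES the argmin (first occurrence
    each); the middle frame is floor((ED+ES)/2).  Returns
    ``(i_ed, i_es, i_mid, ambiguous)`` with ``ambiguous`` set when all areas
    are equal.
    """
    areas = np.array([float(np.sum(np.asarray(m) == CAVITY)) for m in masks])
    if np.all(areas == areas[0]):
        return 0, 0, 0, True
    i_ed = int(np.argmax(areas))
    i_es = int(np.argmin(areas))
    i_mid = (i_ed + i_es) // 2
    return i_ed, i_es, i_mid, False


FRAME_TAGS = ("ed", "es", "mid")


def extract_radiomics_row(
    cine, masks, cfg: RadiomicsConfig | None = None, spacing_mm: float | None = None
) -> dict:
    """Shape + first-order + GLRLM features at the ED, ES and middle frames.

    Column names follow ``<frame>_<family>_<name>``, e.g.
    ``es_shape_sphericity``.  Only the myocardium mask is used.
    """
    cfg = cfg or RadiomicsConfig()
    spacing = spacing_mm if spacing_mm is not None else float(cine.pixel_spacing_mm[0])
    i_ed, i_es, i_mid, _amb = select_frames_ed_es_mid(masks)
    row: dict = {}
    for tag, idx in zip(FRAME_TAGS, (i_ed, i_es, i_mid)):
        img, msk = resample_inplane(
            cine.frames[idx], masks[idx], (spacing, spacing), cfg.target_spacing_mm
        )
        myo = msk == 1
        levels, _degenerate = normalize_intensity(img, myo, cfg)
        area = cfg.target_spacing_mm**2
        for name, value in shape2d_features(myo, cfg.target_spacing_mm).items():
            row[f"{tag}_shape_{name}"] = value
        for name, value in firstorder_features(levels, myo, area).items():
            row[f"{tag}_firstorder_{name}"] = value
        for name, value in glrlm_features(levels, myo, cfg.glrlm_angles).items():
            row[f"{tag}_glrlm_{name}"] = value
    return row


@dataclass
class SelectedFeatures:
    """Outcome of a filtering pass: kept names plus per-drop bookkeeping."""

    kept_names: list
    dropped: dict = field(default_factory=dict)  # name -> {"reason", "partner"/"r"/"p"}
    r_threshold: float | None = None
    alpha: float | None = None

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept_names),
            "dropped": self.dropped,
            "r_threshold": self.r_threshold,
            "alpha": self.alpha,
        }


class RedundancyFilter:
    """Drop features highly correlated with an already-kept feature.

    Greedy pass over columns in canonical sorted-name order: a column is
    dropped iff its absolute Pearson correlation with any already-kept column
    exceeds ``threshold``.  Zero-variance columns are dropped with reason
    ``"constant"``.  sklearn-style: ``fit`` on the training table,
    ``transform`` selects the kept columns.
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "RedundancyFilter":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, table: pd.DataFrame, y=None) -> "RedundancyFilter":
        if len(table) < 3:
            raise ValueError("need at least 3 rows to estimate correlations")
        kept: list = []
        dropped: dict = {}
        for name in sorted(table.columns):
            col = table[name].to_numpy(dtype=float)
            if np.std(col) == 0:
                dropped[name] = {"reason": "constant"}
                continue
            partner, worst = None, 0.0
            for k in kept:
                r = np.corrcoef(col, table[k].to_numpy(dtype=float))[0, 1]
                if abs(r) > worst:
                    partner, worst = k, abs(r)
            if worst > self.threshold:
                dropped[name] = {"reason": "redundant", "partner": partner, "r": float(worst)}
            else:
                kept.append(name)
        self.selection_ = SelectedFeatures(kept, dropped, r_threshold=self.threshold)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.selection_.kept_names]

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table, y).transform(table)


class SignificanceFilter:
    """Keep features whose point-biserial correlation with the binary outcome
    is significant at ``alpha`` (default 0.001, no multiplicity correction).
    """

    def __init__(self, alpha: float = 0.001):
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha}

    def set_params(self, **params) -> "SignificanceFilter":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, table: pd.DataFrame, y) -> "SignificanceFilter":
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("both outcome classes must be present")
        kept: list = []
        dropped: dict = {}
        pvalues: dict = {}
        for name in table.columns:
            col = table[name].to_numpy(dtype=float)
            if np.std(col) == 0:
                dropped[name] = {"reason": "zero variance"}
                continue
            r, p = stats.pointbiserialr(y, col)
            pvalues[name] = float(p)
            if p < self.alpha:
                kept.append(name)
            else:
                dropped[name] = {"reason": "insignificant", "p": float(p)}
        self.selection_ = SelectedFeatures(kept, dropped, alpha=self.alpha)
        self.pvalues_ = pvalues
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.selection_.kept_names]

    def fit_transform(self, table: pd.DataFrame, y) -> pd.DataFrame:
        return self.fit(table, y).transform(table)


def redundancy_filter(table: pd.DataFrame, r_threshold: float = 0.9) -> SelectedFeatures:
    """Functional wrapper over :class:`RedundancyFilter`."""
    return RedundancyFilter(r_threshold).fit(table).selection_


def significance_filter(table: pd.DataFrame, labels, alpha: float = 0.001) -> SelectedFeatures:
    """Functional wrapper over :class:`SignificanceFilter`."""
    return SignificanceFilter(alpha).fit(table, labels).selection_
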