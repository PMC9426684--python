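"""2D affine transforms shared by the phantom generator and the prep pipeline.

Conventions (used everywhere in this package):

* coordinates are 0-based ``(row, col)``;
* the rotation is about the image centre, counter-clockwise positive
  (in the row/col frame);
* :class:`AffineParams` describes a *content* transform: applying it to an
  image moves the image content by ``translation`` pixels, rotates it by
  ``rotation_deg`` and scales it by ``scale`` about the centre.  Resampling
  pulls intensities from the source image through the inverse map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from ._utils import as_float_image


@dataclass(frozen=True)
class AffineParams:
    """Affine transform parameters: translation, rotation, scale and shear.

    The linear part is composed as ``R(rotation) @ diag(scale) @ Shear``
    with ``Shear = [[1, shear], [0, 1]]``.
    """

    translation: tuple[float, float] = (0.0, 0.0)  # (d_row, d_col) px
    rotation_deg: float = 0.0
    scale: tuple[float, float] = (1.0, 1.0)
    shear: float = 0.0

    def __post_init__(self):
        if min(self.scale) <= 0:
            raise ValueError("scale components must be > 0")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    @property
    def is_identity(self) -> bool:
        return (
            self.translation == (0.0, 0.0)
            and self.rotation_deg == 0.0
            and self.scale == (1.0, 1.0)
            and self.shear == 0.0
        )

    def matrix(self) -> np.ndarray:
        """The 2x2 linear part, acting on (row, col) offsets from the centre."""
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return rot @ np.diag(self.scale) @ np.array([[1.0, self.shear], [0.0, 1.0]])

    def to_vector(self) -> np.ndarray:
        """Optimisation vector (dr, dc, rot_deg, log sr, log sc, shear)."""
        return np.array(
            [
                self.translation[0],
                self.translation[1],
                self.rotation_deg,
                np.log(self.scale[0]),
                np.log(self.scale[1]),
                self.shear,
            ]
        )

    @classmethod
    def from_vector(cls, v) -> "AffineParams":
        v = np.asarray(v, dtype=float)
        return cls(
            translation=(float(v[0]), float(v[1])),
            rotation_deg=float(v[2]),
            scale=(float(np.exp(v[3])), float(np.exp(v[4]))),
            shear=float(v[5]),
        )


def params_point_map(params: AffineParams, shape) -> np.ndarray:
    """Homogeneous 3x3 map from output (fixed) coords to source (moving) coords.

    ``apply_affine`` evaluates ``out(o) = src(H @ (o, 1))``.
    """
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    minv = np.linalg.inv(params.matrix())
    h = np.eye(3)
    h[:2, :2] = minv
    h[:2, 2] = centre - minv @ (centre + np.asarray(params.translation, dtype=float))
    return h


def decompose_matrix(m: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """Decompose a 2x2 matrix into (rotation_deg, (sr, sc), shear).

    Inverse of :meth:`AffineParams.matrix`: ``M = R @ diag(s) @ Shear``.
    """
    m = np.asarray(m, dtype=float)
    rot = np.arctan2(m[1, 0], m[0, 0])
    r = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    upper = r.T @ m  # [[sr, sr*shear], [0, sc]]
    sr = upper[0, 0]
    sc = upper[1, 1]
    shear = upper[0, 1] / sr
    return float(np.rad2deg(rot)), (float(sr), float(sc)), float(shear)


def compose(outer: AffineParams, inner: AffineParams, shape) -> np.ndarray:
    """Point map of applying ``inner`` to an image then ``outer`` to the result.

    Returns the homogeneous fixed->source map of the composite content
    transform (useful to measure registration residuals).
    """
    return params_point_map(inner, shape) @ params_point_map(outer, shape)


def residual_misalignment(
    true_params: AffineParams, recovered: AffineParams, shape
) -> tuple[float, float]:
    """Residual (translation px at centre, rotation deg) after registration.

    If ``recovered`` undoes ``true_params`` exactly, both residuals are 0.
    """
    h = compose(recovered, true_params, shape)
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    dt = h[:2, 2] + (h[:2, :2] - np.eye(2)) @ centre
    drot = np.rad2deg(np.arctan2(h[1, 0], h[0, 0]))
    return float(np.hypot(*dt)), float(abs(drot))


def apply_affine(
    image: np.ndarray,
    params: AffineParams,
    interpolation: str = "linear",
    cval: float = 0.0,
) -> np.ndarray:
    """Apply an affine content transform to an image or a label mask.

    ``interpolation`` is ``"linear"`` for intensity images and ``"nearest"``
    for label masks (labels are preserved; no new values appear).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("apply_affine expects a 2D array")
    if params.is_identity:
        return arr.copy()
    order = 1 if interpolation == "linear" else 0
    h = params_point_map(params, arr.shape)
    out = ndi.affine_transform(
        as_float_image(arr), h[:2, :2], offset=h[:2, 2], order=order, mode="constant", cval=cval
    )
    if interpolation == "nearest":
        out = out.astype(arr.dtype)
    return out
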