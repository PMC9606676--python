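"""Rigid roto-translation estimation and application across staining rounds.

Sequential staining moves the slide between rounds, so every round's
images are related to the first by a small rigid transform (a rotation
plus a translation — the slide neither scales nor shears).  This module
defines that transform, estimates it between nuclear-stain images with a
coarse-to-fine pyramid (translation by phase correlation, rotation by a
bounded 1D search, iterated to convergence), rescales it between
magnifications, applies it to intensity images and label masks, and
aligns Z-stacks laterally and axially.

Conventions (fixed, serialized with every transform):

* pixel indices are 0-based, pixel-center; x = column rightward,
  y = row downward;
* rotation is counter-clockwise in (x, y) about the image center
  ``((W-1)/2, (H-1)/2)``;
* the transform maps *moving-image* coordinates into *reference-image*
  coordinates: content at moving pixel ``p`` lands at reference pixel
  ``T(p) = R(p - c) + c + t``;
* ``scale_of_definition`` records the resolution the parameters are
  expressed at (1.0 = full resolution); rescaling by a factor ``f``
  multiplies the translation by ``f`` and leaves the angle unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.registration import phase_cross_correlation
from skimage.transform import rescale as _sk_rescale

ROTATION_CENTER_CONVENTION = "image-center,0-based,pixel-center,x=col,y=row,ccw"


class RegistrationError(RuntimeError):
    """Registration could not produce a confident estimate."""


# --------------------------------------------------------------------------
# the transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    angle_deg: float
    translation_px: tuple[float, float]  # (dx, dy)
    scale_of_definition: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale_of_definition > 0:
            raise ValueError("scale_of_definition must be positive")
        object.__setattr__(self, "translation_px",
                           (float(self.translation_px[0]),
                            float(self.translation_px[1])))

    # -- group operations ---------------------------------------------------
    @classmethod
    def identity(cls, scale: float = 1.0) -> "RigidTransform":
        return cls(0.0, (0.0, 0.0), scale)

    def _rot(self) -> np.ndarray:
        th = math.radians(self.angle_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])  # acts on (x, y)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        if not math.isclose(self.scale_of_definition, other.scale_of_definition,
                            rel_tol=1e-9):
            raise ValueError("cannot compose transforms at different scales")
        t = self._rot() @ np.asarray(other.translation_px) \
            + np.asarray(self.translation_px)
        return RigidTransform(self.angle_deg + other.angle_deg,
                              (t[0], t[1]), self.scale_of_definition)

    def invert(self) -> "RigidTransform":
        inv = RigidTransform(-self.angle_deg, (0.0, 0.0),
                             self.scale_of_definition)
        t = -(inv._rot() @ np.asarray(self.translation_px))
        return replace(inv, translation_px=(t[0], t[1]))

    def rescale(self, factor: float) -> "RigidTransform":
        """Re-express the transform at ``factor`` times its current scale."""
        if not factor > 0:
            raise ValueError("rescale factor must be positive")
        dx, dy = self.translation_px
        return RigidTransform(self.angle_deg, (dx * factor, dy * factor),
                              self.scale_of_definition * factor)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"angle_deg": self.angle_deg,
                "dx": self.translation_px[0], "dy": self.translation_px[1],
                "scale_of_definition": self.scale_of_definition,
                "rotation_center": ROTATION_CENTER_CONVENTION}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(float(d["angle_deg"]), (float(d["dx"]), float(d["dy"])),
                   float(d.get("scale_of_definition", 1.0)))

    def write_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
        return Path(path)

    @classmethod
    def read_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rescale_transform(t: RigidTransform, factor: float) -> RigidTransform:
    """Functional alias for :meth:`RigidTransform.rescale`."""
    return t.rescale(factor)


# --------------------------------------------------------------------------
# application
# --------------------------------------------------------------------------

def _inverse_affine(t: RigidTransform, shape: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(matrix, offset) mapping output (y, x) -> input (y, x) for ndimage."""
    th = math.radians(t.angle_deg)
    c, s = math.cos(th), math.sin(th)
    # forward in (y, x): [[c, s], [-s, c]] about the center, then +(dy, dx)
    ainv = np.array([[c, s], [-s, c]]).T
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    center = np.array([cy, cx])
    tr = np.array([t.translation_px[1], t.translation_px[0]])
    offset = center - ainv @ (center + tr)
    return ainv, offset


def apply_to_image(image: np.ndarray, t: RigidTransform,
                   interpolation: str = "linear") -> np.ndarray:
    """Resample an image under a rigid transform; out-of-field pixels are 0.

    ``interpolation`` is ``"linear"`` for intensity channels or
    ``"nearest"``; the output keeps the input dtype and dimensions.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    image = np.asarray(image)
    matrix, offset = _inverse_affine(t, image.shape)
    if interpolation == "nearest":
        return ndi.affine_transform(image, matrix, offset=offset, order=0,
                                    mode="constant", cval=0)
    out = ndi.affine_transform(image.astype(np.float64), matrix, offset=offset,
                               order=1, mode="constant", cval=0.0)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def apply_to_mask(mask: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Transform a label mask with nearest-neighbor resampling only.

    Labels are never interpolated to new values; the output label set is a
    subset of the input's (labels may fall off-field).
    """
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("label mask must have an integer dtype")
    return apply_to_image(mask, t, interpolation="nearest")


def transform_points(points_xy: np.ndarray, t: RigidTransform,
                     shape: tuple[int, int]) -> np.ndarray:
    """Forward-map (x, y) points the same way :func:`apply_to_image` maps
    content: a feature at moving pixel ``p`` appears at ``T(p)`` in the
    output frame of ``shape``."""
    p = np.atleast_2d(np.asarray(points_xy, dtype=np.float64))
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    c = np.array([cx, cy])
    out = (t._rot() @ (p - c).T).T + c + np.asarray(t.translation_px)
    return out if np.asarray(points_xy).ndim == 2 else out[0]


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

def _float_resize(img: np.ndarray, factor: float) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if factor == 1.0:
        return img
    return _sk_rescale(img, factor, order=1, anti_aliasing=factor < 1,
                       preserve_range=True)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation over the central 3/4 of the frame."""
    h, w = a.shape
    sl = (slice(h // 8, h - h // 8), slice(w // 8, w - w // 8))
    av = a[sl] - a[sl].mean()
    bv = b[sl] - b[sl].mean()
    denom = np.linalg.norm(av) * np.linalg.norm(bv)
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def _warp_float(img: np.ndarray, t: RigidTransform) -> np.ndarray:
    matrix, offset = _inverse_affine(t, img.shape)
    return ndi.affine_transform(img, matrix, offset=offset, order=1,
                                mode="constant", cval=0.0, prefilter=False)


def _refine_level(ref: np.ndarray, mov: np.ndarray, t: RigidTransform,
                  angle_span_deg: float, max_iter: int, tol_deg: float,
                  tol_px: float, upsample: int) -> RigidTransform:
    span = angle_span_deg
    for _ in range(max_iter):
        warped = _warp_float(mov, t)
        shift, _, _ = phase_cross_correlation(ref, warped,
                                              upsample_factor=upsample)
        dx, dy = float(shift[1]), float(shift[0])
        t = replace(t, translation_px=(t.translation_px[0] + dx,
                                       t.translation_px[1] + dy))

        def neg_ncc(angle: float) -> float:
            cand = replace(t, angle_deg=float(angle))
            return -_ncc(ref, _warp_float(mov, cand))

        res = minimize_scalar(neg_ncc, bounds=(t.angle_deg - span,
                                               t.angle_deg + span),
                              method="bounded",
                              options={"xatol": min(0.002, tol_deg / 2)})
        dtheta = float(res.x) - t.angle_deg
        t = replace(t, angle_deg=float(res.x))
        span = max(1.0, abs(dtheta) * 4)
        if abs(dtheta) < tol_deg and math.hypot(dx, dy) < tol_px:
            break
    return t


def _coarse_angle_init(ref: np.ndarray, mov: np.ndarray, bound: float,
                       step: float = 1.0) -> RigidTransform:
    """Scan candidate angles, estimating the best shift at each, and keep
    the (angle, shift) pair with the highest correlation."""
    best = (-np.inf, RigidTransform.identity())
    for angle in np.arange(-bound, bound + step / 2, step):
        t = RigidTransform(float(angle), (0.0, 0.0))
        warped = _warp_float(mov, t)
        shift, _, _ = phase_cross_correlation(ref, warped, upsample_factor=4)
        t = replace(t, translation_px=(float(shift[1]), float(shift[0])))
        score = _ncc(ref, _warp_float(mov, t))
        if score > best[0]:
            best = (score, t)
    return best[1]


def estimate_rigid(reference: np.ndarray, moving: np.ndarray,
                   downscale_factors: Sequence[float] = (0.25, 1.0),
                   angle_bound_deg: float = 12.0, max_iter: int = 50,
                   tol_deg: float = 0.01, tol_px: float = 0.1,
                   upsample: int = 20) -> RigidTransform:
    """Estimate the rigid transform mapping ``moving`` onto ``reference``.

    Estimation runs coarse-to-fine through ``downscale_factors`` (e.g.
    ``(0.25, 1.0)``: quarter resolution first, then full).  At the
    coarsest level an exhaustive 1-degree angle scan seeds the iterative
    refinement (phase-correlation translation, bounded golden-section
    rotation search), so no initial guess is needed.  Whatever the
    coarsest factor, the result is re-expressed at full resolution
    (``scale_of_definition = 1.0``).

    Raises :class:`RegistrationError` on degenerate (near-constant)
    inputs rather than silently returning the identity.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving images must share a shape")
    if ref.std() < 1e-8 or mov.std() < 1e-8:
        raise RegistrationError(
            "degenerate (near-constant) image: registration has no signal")
    factors = sorted(set(float(f) for f in downscale_factors))
    if not factors or factors[0] <= 0:
        raise ValueError("downscale factors must be positive")

    t: RigidTransform | None = None
    prev_f = None
    for f in factors:
        rf, mf = _float_resize(ref, f), _float_resize(mov, f)
        if t is None:
            t = _coarse_angle_init(rf, mf, angle_bound_deg)
            t = replace(t, scale_of_definition=f)
            span = 2.0
        else:
            t = t.rescale(f / prev_f)
            span = 1.0
        t = _refine_level(rf, mf, t, span, max_iter, tol_deg, tol_px, upsample)
        prev_f = f
    return t.rescale(1.0 / prev_f)


# --------------------------------------------------------------------------
# cross-magnification and 3D
# --------------------------------------------------------------------------

def _pad_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float64)
    h = min(img.shape[0], shape[0])
    w = min(img.shape[1], shape[1])
    out[:h, :w] = img[:h, :w]
    return out


def register_cross_magnification(low, high, channel: str | None = None,
                                 **estimate_kwargs) -> tuple[RigidTransform, float]:
    """Register a high-magnification image into a low-magnification one.

    The low image is first resampled by ``pixel_size_low / pixel_size_high``
    so both share a pixel size, then the rigid estimate is run.  Returns
    ``(transform, resampling_factor)``; the transform maps high-image
    coordinates into rescaled-low coordinates (both expressed at the high
    image's pixel size).
    """
    for img, which in ((low, "low"), (high, "high")):
        if getattr(img, "pixel_size_um", None) is None or img.pixel_size_um <= 0:
            from .io import MetadataError
            raise MetadataError(f"{which} image is missing pixel_size_um")
    if channel is None:
        common = [c for c in low.channel_names if c in high.channel_names]
        if not common:
            raise ValueError("no common channel between the two images")
        channel = common[0]
    factor = low.pixel_size_um / high.pixel_size_um
    low_up = _float_resize(np.asarray(low.get(channel), np.float64), factor)
    hi = np.asarray(high.get(channel), np.float64)
    shape = (max(low_up.shape[0], hi.shape[0]), max(low_up.shape[1], hi.shape[1]))
    t = estimate_rigid(_pad_to(low_up, shape), _pad_to(hi, shape),
                       **estimate_kwargs)
    return t, factor


def register_stacks(reference_stack: np.ndarray, moving_stack: np.ndarray,
                    max_z_offset: int | None = None, **estimate_kwargs
                    ) -> tuple[RigidTransform, int]:
    """Align two Z-stacks of the same field across rounds.

    The lateral rigid transform is estimated on the sum projections; the
    integer plane offset is then found by exhaustive search, maximizing
    the mean plane-wise correlation after lateral alignment.  Returns
    ``(transform, z_offset)`` where moving plane ``i + z_offset``
    corresponds to reference plane ``i``.
    """
    ref = np.asarray(reference_stack, dtype=np.float64)
    mov = np.asarray(moving_stack, dtype=np.float64)
    if ref.ndim != 3 or mov.ndim != 3:
        raise ValueError("stacks must be 3D (planes, rows, cols)")
    t = estimate_rigid(ref.sum(axis=0), mov.sum(axis=0), **estimate_kwargs)
    warped = np.stack([_warp_float(p, t) for p in mov])
    nz_ref, nz_mov = ref.shape[0], warped.shape[0]
    bound = max_z_offset if max_z_offset is not None else max(nz_ref, nz_mov) - 1
    best_o, best_score = None, -np.inf
    for o in range(-bound, bound + 1):
        scores = []
        for i in range(nz_ref):
            j = i + o
            if 0 <= j < nz_mov:
                scores.append(_ncc(ref[i], warped[j]))
        if not scores:
            continue
        score = float(np.mean(scores))
        if score > best_score:  # ties broken by the smallest offset scanned
            best_score, best_o = score, o
    if best_o is None:
        raise RegistrationError("stacks have no overlapping planes in the "
                                "admissible offset range")
    return t, best_o
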