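"""Image <-> stage coordinate conversion, TMA dearraying, ROI propagation,
focus-surface interpolation, and position-list export.

The pipeline's closing step turns analysis results back into microscope
actions: cell centers gated in one round are converted to stage
micrometers, corrected for the slide misplacement measured on the
low-magnification maps, and written as a position list the next
acquisition can consume.  The stage/camera orientation (axis signs,
transposition) is explicit, vendor-neutral data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_triangle
from skimage.morphology import closing, disk

from .io import AxisConvention, MetadataError, MultichannelImage, Position, \
    PositionList, write_label_mask
from .registration import RigidTransform, apply_to_mask, transform_points


# --------------------------------------------------------------------------
# stage mapping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageMapping:
    """Affine contract between image pixels and stage micrometers.

    ``stage = origin + signed (and possibly transposed) pixel offset x
    pixel size``.  ``image_to_stage`` and ``stage_to_image`` are exact
    inverses.
    """

    pixel_size_um: float
    stage_origin_um: tuple[float, float] = (0.0, 0.0)
    axis: AxisConvention = field(default_factory=AxisConvention)

    @classmethod
    def for_image(cls, image: MultichannelImage) -> "StageMapping":
        if image.pixel_size_um is None or image.pixel_size_um <= 0:
            raise MetadataError("image has no valid pixel_size_um")
        return cls(image.pixel_size_um, image.stage_origin_um,
                   image.axis_convention)

    def image_to_stage(self, points_px) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_px, dtype=np.float64))
        u, v = p[:, 0], p[:, 1]
        if self.axis.transpose:
            u, v = v, u
        sx = self.stage_origin_um[0] + self.axis.x_sign * u * self.pixel_size_um
        sy = self.stage_origin_um[1] + self.axis.y_sign * v * self.pixel_size_um
        out = np.column_stack([sx, sy])
        return out if np.asarray(points_px).ndim == 2 else out[0]

    def stage_to_image(self, points_um) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=np.float64))
        u = (p[:, 0] - self.stage_origin_um[0]) / (self.axis.x_sign
                                                   * self.pixel_size_um)
        v = (p[:, 1] - self.stage_origin_um[1]) / (self.axis.y_sign
                                                   * self.pixel_size_um)
        if self.axis.transpose:
            u, v = v, u
        out = np.column_stack([u, v])
        return out if np.asarray(points_um).ndim == 2 else out[0]


# --------------------------------------------------------------------------
# TMA dearraying
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreDetectionParams:
    channel: str | None = None            # None -> sum of all channels
    expected_diameter_um: float = 1200.0  # study-like core size
    diameter_tolerance: tuple[float, float] = (0.4, 1.6)
    closing_radius_frac: float = 0.05     # of the expected diameter


@dataclass
class ROISet:
    """Label mask at map scale plus per-ROI boxes in px and stage um."""
    mask: np.ndarray
    mapping: StageMapping
    table: pd.DataFrame  # roi_id, bbox px, stage rectangle, center

    def __len__(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> list[int]:
        return self.table["roi_id"].tolist()

    def write(self, outdir: str | Path, stem: str = "rois") -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_label_mask(self.mask, outdir / f"{stem}.tif")
        doc = {"pixel_size_um": self.mapping.pixel_size_um,
               "stage_origin_um": list(self.mapping.stage_origin_um),
               "rois": self.table.to_dict(orient="records")}
        (outdir / f"{stem}.json").write_text(json.dumps(doc, indent=1))
        return outdir


def _roi_table(mask: np.ndarray, mapping: StageMapping) -> pd.DataFrame:
    rows = []
    for rid in np.unique(mask):
        if rid == 0:
            continue
        ys, xs = np.nonzero(mask == rid)
        x0, x1 = int(xs.min()), int(xs.max())
        y0, y1 = int(ys.min()), int(ys.max())
        c0 = mapping.image_to_stage((x0, y0))
        c1 = mapping.image_to_stage((x1, y1))
        cx, cy = float(xs.mean()), float(ys.mean())
        cs = mapping.image_to_stage((cx, cy))
        rows.append({"roi_id": int(rid),
                     "bbox_min_col": x0, "bbox_min_row": y0,
                     "bbox_max_col": x1, "bbox_max_row": y1,
                     "stage_x0_um": float(min(c0[0], c1[0])),
                     "stage_y0_um": float(min(c0[1], c1[1])),
                     "stage_x1_um": float(max(c0[0], c1[0])),
                     "stage_y1_um": float(max(c0[1], c1[1])),
                     "center_x_um": float(cs[0]), "center_y_um": float(cs[1])})
    return pd.DataFrame(rows)


def segment_cores(map_image: MultichannelImage,
                  params: CoreDetectionParams = CoreDetectionParams(),
                  manual_mask: np.ndarray | None = None) -> ROISet:
    """Detect TMA cores on the low-magnification map.

    Triangle threshold on the total signal (robust for sparse bright disks
    on a dark background) -> morphological closing -> connected components
    -> equivalent-diameter filter around the expected core diameter.
    ``manual_mask`` bypasses detection with a user-drawn label mask.
    """
    mapping = StageMapping.for_image(map_image)
    if manual_mask is not None:
        mask = np.asarray(manual_mask).astype(np.int32)
        return ROISet(mask, mapping, _roi_table(mask, mapping))
    if params.channel is not None:
        total = np.asarray(map_image.get(params.channel), np.float64)
    else:
        total = sum(np.asarray(c, np.float64)
                    for c in map_image.channels.values())
    if np.ptp(total) == 0:
        warnings.warn("blank map: no cores found")
        empty = np.zeros(total.shape, dtype=np.int32)
        return ROISet(empty, mapping, _roi_table(empty, mapping))
    thr = threshold_triangle(total)
    fg = total > thr
    d_px = params.expected_diameter_um / mapping.pixel_size_um
    close_r = max(1, int(round(params.closing_radius_frac * d_px)))
    fg = closing(fg, disk(close_r))
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    lo, hi = params.diameter_tolerance
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for rid in range(1, n + 1):
        area = int((labels == rid).sum())
        eq_d = 2 * np.sqrt(area / np.pi)
        if lo * d_px <= eq_d <= hi * d_px:
            out[labels == rid] = nxt
            nxt += 1
    if nxt == 1:
        warnings.warn("no cores matched the expected diameter")
    return ROISet(out, mapping, _roi_table(out, mapping))


def transform_rois(rois: ROISet, t: RigidTransform) -> ROISet:
    """Propagate ROIs through a round-to-round rigid transform.

    The mask is resampled nearest-neighbor (labels preserved or dropped
    off-field, never invented); stage rectangles are recomputed.
    """
    mask = apply_to_mask(rois.mask, t)
    return ROISet(mask, rois.mapping, _roi_table(mask, rois.mapping))


# --------------------------------------------------------------------------
# focus surface
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FocusMap:
    """Least-squares focus plane z = a x + b y + c over support points."""
    points: tuple[tuple[float, float, float], ...]
    coeffs: tuple[float, float, float]
    rms_residual_um: float

    def in_hull(self, x: float, y: float) -> bool:
        from scipy.spatial import Delaunay
        pts = np.array([(p[0], p[1]) for p in self.points])
        try:
            tri = Delaunay(pts)
        except Exception:
            return False
        return bool(tri.find_simplex([x, y]) >= 0)


def build_focus_map(points: Sequence[tuple[float, float, float]]) -> FocusMap:
    """Fit the focus plane through autofocus support points.

    Requires at least 3 non-collinear (x, y) support points; with exactly
    3 the plane interpolates them exactly.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need >= 3 (x, y, z) support points")
    xy = pts[:, :2] - pts[:, :2].mean(axis=0)
    if np.linalg.matrix_rank(xy, tol=1e-9 * max(1.0, np.abs(xy).max())) < 2:
        raise ValueError("support points are collinear: focus plane is "
                         "underdetermined")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    resid = A @ coef - pts[:, 2]
    return FocusMap(tuple(map(tuple, pts)), tuple(float(c) for c in coef),
                    float(np.sqrt(np.mean(resid ** 2))))


def interpolate_focus(fmap: FocusMap, x: float, y: float,
                      warn_extrapolation: bool = True) -> float:
    """Evaluate the focus surface; warns when (x, y) is outside the convex
    hull of the support points (extrapolation)."""
    a, b, c = fmap.coeffs
    if warn_extrapolation and not fmap.in_hull(x, y):
        warnings.warn(f"focus evaluated outside the support hull at "
                      f"({x:.1f}, {y:.1f}): extrapolating")
    return a * x + b * y + c


# --------------------------------------------------------------------------
# relocation and export
# --------------------------------------------------------------------------

def predict_relocated_positions(points_px, map_transform: RigidTransform,
                                map_shape: tuple[int, int],
                                resolution_ratio: float = 1.0) -> np.ndarray:
    """Where will round-1 pixels be found in round 2?

    ``map_transform`` maps round-2 map coordinates onto round-1 map
    coordinates (the registration output); its inverse sends round-1
    targets into the round-2 frame.  ``resolution_ratio`` re-expresses the
    result at a finer pixel size (e.g. map -> cell-resolution); points are
    given and returned at that finer scale.
    """
    t = RigidTransform(map_transform.angle_deg,
                       (map_transform.translation_px[0] * resolution_ratio,
                        map_transform.translation_px[1] * resolution_ratio))
    shape = (int(round(map_shape[0] * resolution_ratio)),
             int(round(map_shape[1] * resolution_ratio)))
    return transform_points(np.asarray(points_px, dtype=np.float64),
                            t.invert(), shape)


def export_position_list(source, path: str | Path, fmt: str = "json") -> Path:
    """Write a deterministic, row-major-ordered position list.

    ``source`` is a PositionList or an ROISet (one position per ROI, at
    the stage-rectangle center).  Ordering is by stage y, then x — stable
    under any input permutation.  An empty input is an error.
    """
    if isinstance(source, ROISet):
        positions = PositionList([
            Position(f"roi_{int(r.roi_id)}",
                     (r.stage_x0_um + r.stage_x1_um) / 2,
                     (r.stage_y0_um + r.stage_y1_um) / 2)
            for r in source.table.itertuples(index=False)])
    elif isinstance(source, PositionList):
        positions = source
    else:
        raise TypeError("source must be a PositionList or ROISet")
    if len(positions) == 0:
        raise ValueError("refusing to export an empty position list")
    ordered = positions.sorted()
    if fmt == "json":
        return ordered.write_json(path)
    if fmt == "csv":
        return ordered.write_csv(path)
    raise ValueError(f"unknown format {fmt!r}")
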