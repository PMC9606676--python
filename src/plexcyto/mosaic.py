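"""Multipoint tile planning and stitching.

The acquisition protocol covers each region of interest with a grid of
overlapping fields of view (10% overlap by default) and reconstructs the
full field by stitching.  Planning is pure stage-space arithmetic; the
stitcher places tiles at their nominal stage coordinates, optionally
refines the placement by estimating pairwise translation offsets on the
overlaps (translation only — there is no rotation within one mosaic), and
blends overlaps with linear feathering whose weights sum to one, so
identical overlapping content is conserved and non-overlap regions
reproduce the tiles bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

from .io import MultichannelImage

DEFAULT_OVERLAP = 0.10


@dataclass(frozen=True)
class TilePlan:
    """A grid of nominal tile positions in stage space (um)."""
    positions: tuple[tuple[int, int, float, float], ...]  # (row, col, x_um, y_um)
    fov_um: tuple[float, float]
    overlap_fraction: float
    origin_um: tuple[float, float]

    @property
    def n_rows(self) -> int:
        return max(p[0] for p in self.positions) + 1

    @property
    def n_cols(self) -> int:
        return max(p[1] for p in self.positions) + 1

    @property
    def extent_um(self) -> tuple[float, float]:
        step_x = self.fov_um[0] * (1 - self.overlap_fraction)
        step_y = self.fov_um[1] * (1 - self.overlap_fraction)
        return (step_x * (self.n_cols - 1) + self.fov_um[0],
                step_y * (self.n_rows - 1) + self.fov_um[1])

    def to_json(self, path: str | Path) -> Path:
        doc = {"fov_um": list(self.fov_um),
               "overlap_fraction": self.overlap_fraction,
               "origin_um": list(self.origin_um),
               "positions": [list(p) for p in self.positions]}
        Path(path).write_text(json.dumps(doc, indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "TilePlan":
        d = json.loads(Path(path).read_text())
        return cls(tuple((int(r), int(c), float(x), float(y))
                         for r, c, x, y in d["positions"]),
                   tuple(d["fov_um"]), float(d["overlap_fraction"]),
                   tuple(d["origin_um"]))


def _n_steps(extent: float, fov: float, step: float) -> int:
    if extent <= fov:
        return 1
    return int(math.ceil((extent - fov) / step)) + 1


def plan_tiles(region_um: tuple[float, float, float, float],
               fov_um: tuple[float, float],
               overlap_fraction: float = DEFAULT_OVERLAP) -> TilePlan:
    """Minimal tile grid covering a stage-space rectangle.

    ``region_um`` is (x0, y0, x1, y1); spacing is ``fov * (1 - overlap)``.
    The last row/column may extend past the region — coverage, not fit, is
    the contract.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if fov_um[0] <= 0 or fov_um[1] <= 0:
        raise ValueError("fov must be positive")
    x0, y0, x1, y1 = region_um
    if x1 < x0 or y1 < y0:
        raise ValueError("region must have nonnegative extent")
    step_x = fov_um[0] * (1 - overlap_fraction)
    step_y = fov_um[1] * (1 - overlap_fraction)
    nx = _n_steps(x1 - x0, fov_um[0], step_x)
    ny = _n_steps(y1 - y0, fov_um[1], step_y)
    positions = tuple((r, c, x0 + c * step_x, y0 + r * step_y)
                      for r in range(ny) for c in range(nx))
    return TilePlan(positions, tuple(fov_um), overlap_fraction, (x0, y0))


def cut_tiles(source: MultichannelImage, plan: TilePlan,
              jitter_px: float = 0.0, rng: np.random.Generator | None = None
              ) -> list[MultichannelImage]:
    """Cut a tile set out of one source image (test/demo utility).

    With ``jitter_px`` the actual cut positions deviate from the nominal
    plan by a uniform integer jitter, emulating stage positioning error.
    The first (top-left) tile is never jittered: it is the mosaic's
    anchor, and stage error accumulates relative to it.
    """
    ps = source.pixel_size_um
    ox, oy = source.stage_origin_um
    h, w = source.shape
    th = int(round(plan.fov_um[1] / ps))
    tw = int(round(plan.fov_um[0] / ps))
    rng = rng or np.random.default_rng(0)
    tiles = []
    for k, (r, c, x_um, y_um) in enumerate(plan.positions):
        px = int(round((x_um - ox) / ps))
        py = int(round((y_um - oy) / ps))
        if jitter_px and k > 0:
            px += int(rng.integers(-int(jitter_px), int(jitter_px) + 1))
            py += int(rng.integers(-int(jitter_px), int(jitter_px) + 1))
        px = min(max(px, 0), w - tw)
        py = min(max(py, 0), h - th)
        tiles.append(MultichannelImage(
            {n: np.ascontiguousarray(a[py:py + th, px:px + tw])
             for n, a in source.channels.items()},
            pixel_size_um=ps, stage_origin_um=(x_um, y_um),
            round_id=source.round_id))
    return tiles


def _feather_weight(shape: tuple[int, int], margin: int) -> np.ndarray:
    """Separable linear ramp: 1 in the interior, down to ~0 at the border."""
    def ramp(n: int) -> np.ndarray:
        i = np.arange(n, dtype=np.float64)
        return np.minimum.reduce([np.ones(n), (i + 1) / max(margin, 1),
                                  (n - i) / max(margin, 1)])
    return np.outer(ramp(shape[0]), ramp(shape[1]))


def stitch(tiles: Sequence[MultichannelImage], plan: TilePlan,
           refine: bool = False) -> MultichannelImage:
    """Assemble tiles into one field.

    Tiles are placed at their nominal plan coordinates; with ``refine``
    the pairwise translation offsets between grid neighbors are measured
    on the overlap strips by phase correlation and propagated from the
    top-left anchor tile along the grid.  Overlaps are blended with
    normalized linear feathering.
    """
    if len(tiles) != len(plan.positions):
        raise ValueError(
            f"plan has {len(plan.positions)} tiles but {len(tiles)} were given")
    ps = tiles[0].pixel_size_um
    names = tiles[0].channel_names
    th, tw = tiles[0].shape
    x0, y0 = plan.origin_um
    nominal = {}
    index = {}
    for k, (r, c, x_um, y_um) in enumerate(plan.positions):
        nominal[(r, c)] = np.array([(y_um - y0) / ps, (x_um - x0) / ps])
        index[(r, c)] = k

    pos = dict(nominal)
    if refine:
        ref_channel = names[0]
        corrections = {key: None for key in nominal}
        corrections[(0, 0)] = np.zeros(2)
        order = sorted(nominal)  # row-major: parents are always visited first
        for (r, c) in order:
            if corrections[(r, c)] is not None:
                continue
            for pr, pc in ((r, c - 1), (r - 1, c)):
                if (pr, pc) in nominal and corrections[(pr, pc)] is not None:
                    shift = _overlap_shift(
                        tiles[index[(pr, pc)]].get(ref_channel),
                        tiles[index[(r, c)]].get(ref_channel),
                        nominal[(pr, pc)], nominal[(r, c)], (th, tw))
                    corrections[(r, c)] = corrections[(pr, pc)] + shift
                    break
            if corrections[(r, c)] is None:
                corrections[(r, c)] = np.zeros(2)
        pos = {k: nominal[k] + corrections[k] for k in nominal}

    ext_w, ext_h = plan.extent_um
    H, W = int(round(ext_h / ps)), int(round(ext_w / ps))
    margin = max(1, int(round(plan.overlap_fraction * min(th, tw))))
    weight = _feather_weight((th, tw), margin)
    out = {}
    for name in names:
        num = np.zeros((H, W))
        den = np.zeros((H, W))
        for key, k in index.items():
            py, px = int(round(pos[key][0])), int(round(pos[key][1]))
            py = min(max(py, 0), H - th)
            px = min(max(px, 0), W - tw)
            tile = np.asarray(tiles[k].get(name), dtype=np.float64)
            num[py:py + th, px:px + tw] += weight * tile
            den[py:py + th, px:px + tw] += weight
        img = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        out[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return MultichannelImage(out, pixel_size_um=ps, stage_origin_um=(x0, y0),
                             round_id=tiles[0].round_id)


def _overlap_shift(parent: np.ndarray, child: np.ndarray,
                   parent_pos: np.ndarray, child_pos: np.ndarray,
                   tile_shape: tuple[int, int]) -> np.ndarray:
    """Translation correction for ``child`` measured on the nominal overlap."""
    th, tw = tile_shape
    py0, px0 = parent_pos
    cy0, cx0 = child_pos
    oy0, oy1 = max(py0, cy0), min(py0 + th, cy0 + th)
    ox0, ox1 = max(px0, cx0), min(px0 + tw, cx0 + tw)
    if oy1 - oy0 < 4 or ox1 - ox0 < 4:
        return np.zeros(2)
    a = parent[int(oy0 - py0):int(oy1 - py0), int(ox0 - px0):int(ox1 - px0)]
    b = child[int(oy0 - cy0):int(oy1 - cy0), int(ox0 - cx0):int(ox1 - cx0)]
    shift, _, _ = phase_cross_correlation(a.astype(np.float64),
                                          b.astype(np.float64),
                                          upsample_factor=10)
    return np.asarray(shift, dtype=np.float64)
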