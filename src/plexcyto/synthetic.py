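"""Synthetic multi-round, multi-magnification tissue images with ground truth.

No public image set exists for this kind of sequential-staining experiment,
so the package carries its own generator.  A scene is a field of nuclei
(DAPI-like channel) with membrane/cytokeratin-delimited cell bodies,
nuclear marker channels with bimodal positive/negative intensity, punctate
DNA-damage-foci channels (including a nuclear-diffuse high-intensity
phenotype with few foci), punctate cytoplasmic RNA-spot channels,
autofluorescent background, and Poisson + Gaussian read noise on a 16-bit
scale.  Each staining round can be rendered with a known rigid
misplacement (the slide is removed and repositioned between rounds), at
any pixel size (magnification), and as a Z-stack with a known axial
offset — so registration, segmentation, cytometry, gating and relocation
can all be tested against exact ground truth.

Geometry model: nuclei are disks with mild sinusoidal boundary
irregularity; cell bodies are the nearest-nucleus partition of the plane
clipped at a maximum distance from the nucleus (a Voronoi-bounded
dilation).  Foci are 2D Gaussians clipped to their nucleus; RNA spots are
2D Gaussians clipped to their cell body.  Identical (spec, seed) yields
bit-identical images and ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import yaml

from .io import MultichannelImage
from .registration import RigidTransform, _warp_float, _float_resize

UNASSIGNED = "unassigned"


class PlacementError(RuntimeError):
    """Requested cell count cannot be placed at the given density."""


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Poisson photon statistics followed by additive Gaussian read noise."""
    poisson_gain: float = 1.0       # counts per photon-equivalent
    read_sigma: float = 8.0         # additive Gaussian sigma, counts

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MarkerSpec:
    """A per-cell marker channel with a bimodal intensity model.

    Each cell is positive with probability ``positive_fraction``; its
    rendered intensity is lognormal around the class mean (``sigma`` on
    the log scale) and fills the stated compartment
    (``nucleus`` | ``cell`` | ``cytoplasm``).
    """
    name: str
    positive_fraction: float
    negative_mean: float
    positive_mean: float
    sigma: float = 0.25
    compartment: str = "nucleus"


@dataclass(frozen=True)
class PunctaSpec:
    """A punctate channel: per-cell Poisson object counts, Gaussian shape.

    ``diffuse_fraction`` of cells instead show a uniform compartment-wide
    elevation with zero puncta — the high-intensity, few-foci phenotype
    that makes per-nucleus mean intensity decorrelate from foci count.
    """
    name: str
    mean_count: float
    sigma_px: float
    amp_range: tuple[float, float]
    diffuse_fraction: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.325
    n_cells: int = 120
    nucleus_radius_px: tuple[float, float] = (7.0, 11.0)
    touching_fraction: float = 0.15
    cell_max_radius_px: float = 8.0   # cell-body reach beyond the nucleus
    marker_specs: tuple[MarkerSpec, ...] = ()
    foci_specs: tuple[PunctaSpec, ...] = ()
    spot_specs: tuple[PunctaSpec, ...] = ()
    background_level: float = 150.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.touching_fraction <= 1):
            raise ValueError("touching_fraction must be in [0, 1]")
        for m in self.marker_specs:
            if not (0 <= m.positive_fraction <= 1):
                raise ValueError(f"{m.name}: positive_fraction must be in [0, 1]")
        if self.background_level < 0:
            raise ValueError("background_level must be nonnegative")
        if not (self.nucleus_radius_px[0] > 0
                and self.nucleus_radius_px[1] >= self.nucleus_radius_px[0]):
            raise ValueError("nucleus_radius_px must be a positive (lo, hi) range")

    # YAML round trip ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = self.noise.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["field_size_px"] = tuple(d["field_size_px"])
        d["nucleus_radius_px"] = tuple(d["nucleus_radius_px"])
        d["noise"] = NoiseModel(**d.get("noise", {}))
        d["marker_specs"] = tuple(MarkerSpec(**m) for m in d.get("marker_specs", ()))
        for key in ("foci_specs", "spot_specs"):
            d[key] = tuple(
                PunctaSpec(**{**p, "amp_range": tuple(p["amp_range"])})
                for p in d.get(key, ()))
        return cls(**d)

    def write_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return Path(path)

    @classmethod
    def read_yaml(cls, path: str | Path) -> "SceneSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """The study-like default scene: DAPI + cytokeratin + a proliferation
    marker, a DNA-damage foci channel pair, and two RNA-spot channels."""
    base = dict(
        marker_specs=(
            MarkerSpec("DAPI", 1.0, 0.0, 9000.0, 0.15, "nucleus"),
            MarkerSpec("CK8", 1.0, 0.0, 4500.0, 0.30, "cytoplasm"),
            MarkerSpec("KI67", 0.35, 250.0, 7000.0, 0.30, "nucleus"),
        ),
        foci_specs=(
            PunctaSpec("gH2AX", 5.0, 1.4, (3000.0, 9000.0), 0.08),
            PunctaSpec("53BP1", 2.0, 1.4, (2000.0, 6000.0), 0.0),
        ),
        spot_specs=(
            PunctaSpec("ACTB1", 7.0, 1.2, (3000.0, 8000.0)),
            PunctaSpec("BRAF", 3.0, 1.2, (2500.0, 7000.0)),
        ),
        seed=seed,
    )
    base.update(overrides)
    return SceneSpec(**base)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    spec: SceneSpec
    nuclei: np.ndarray                  # int32 label image, 0 = background
    cells: np.ndarray                   # int32 label image, ids match nuclei
    table: pd.DataFrame                 # one row per cell
    foci: dict[str, pd.DataFrame]       # channel -> object table
    spots: dict[str, pd.DataFrame]
    applied_transforms: dict[int, RigidTransform] = field(default_factory=dict)
    pixel_size_ratios: dict[int, float] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def channel_names(self) -> list[str]:
        return ([m.name for m in self.spec.marker_specs]
                + [f.name for f in self.spec.foci_specs]
                + [s.name for s in self.spec.spot_specs])

    def intensity_lut(self, marker: str) -> np.ndarray:
        lut = np.zeros(self.n_cells + 1)
        lut[self.table["cell_id"].to_numpy()] = \
            self.table[f"{marker}__intensity"].to_numpy()
        return lut

    # -- noiseless expected image (float, background excluded) -------------
    def expected_channel(self, name: str) -> np.ndarray:
        if name in self._cache:
            return self._cache[name]
        spec = self.spec
        markers = {m.name: m for m in spec.marker_specs}
        foci = {f.name: f for f in spec.foci_specs}
        spots = {s.name: s for s in spec.spot_specs}
        if name in markers:
            comp = markers[name].compartment
            if comp == "nucleus":
                labels = self.nuclei
            elif comp == "cell":
                labels = self.cells
            elif comp == "cytoplasm":
                labels = np.where(self.nuclei > 0, 0, self.cells)
            else:
                raise ValueError(f"unknown compartment {comp!r}")
            img = self.intensity_lut(name)[labels]
        elif name in foci:
            img = self._render_puncta(self.foci[name], clip_to=self.nuclei)
            col = f"{name}__diffuse_level"
            if col in self.table:
                lut = np.zeros(self.n_cells + 1)
                lut[self.table["cell_id"].to_numpy()] = self.table[col].to_numpy()
                img = img + lut[self.nuclei] * self._edge_taper()
        elif name in spots:
            img = self._render_puncta(self.spots[name], clip_to=self.cells)
        else:
            raise KeyError(
                f"unknown channel {name!r}; scene defines {self.channel_names}")
        self._cache[name] = img
        return img

    def _edge_taper(self, ramp_px: float = 3.0) -> np.ndarray:
        """Smooth falloff of nuclear-diffuse signal toward the envelope,
        emulating the optical blur a real stain shows at the boundary."""
        if "_edge_taper" not in self._cache:
            dist_in = ndi.distance_transform_edt(self.nuclei > 0)
            self._cache["_edge_taper"] = np.minimum(dist_in / ramp_px, 1.0)
        return self._cache["_edge_taper"]

    def _render_puncta(self, objects: pd.DataFrame, clip_to: np.ndarray,
                       z_weight: np.ndarray | None = None) -> np.ndarray:
        h, w = self.nuclei.shape
        img = np.zeros((h, w))
        if objects.empty:
            return img
        weights = (np.ones(len(objects)) if z_weight is None else z_weight)
        for (x, y, amp, sig, owner), wt in zip(
                objects[["x", "y", "amplitude", "sigma_px", "owner"]
                        ].itertuples(index=False), weights):
            if wt <= 1e-12:
                continue
            r = int(math.ceil(4 * sig))
            y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
            x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            g = amp * wt * np.exp(-((xx - x) ** 2 + (yy - y) ** 2)
                                  / (2 * sig ** 2))
            img[y0:y1, x0:x1] += g * (clip_to[y0:y1, x0:x1] == owner)
        return img


# --------------------------------------------------------------------------
# scene generation
# --------------------------------------------------------------------------

def _place_centers(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample nucleus centers: touching pairs first, then
    well-separated singles.  Raises PlacementError at unsatisfiable density."""
    h, w = spec.field_size_px
    rlo, rhi = spec.nucleus_radius_px
    margin = rhi + 3
    n = spec.n_cells
    n_pairs = int(round(spec.touching_fraction * n / 2))
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    budget = 400 * n + 400

    def ok(cx, cy, r, skip_last=0):
        if not (margin <= cx <= w - margin and margin <= cy <= h - margin):
            return False
        upto = len(centers) - skip_last
        for (ox, oy), orad in zip(centers[:upto], radii[:upto]):
            if math.hypot(cx - ox, cy - oy) < r + orad + 4:
                return False
        return True

    attempts = 0
    for _ in range(n_pairs):
        placed = False
        while attempts < budget and not placed:
            attempts += 1
            r1, r2 = rng.uniform(rlo, rhi, 2)
            cx, cy = rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)
            if not ok(cx, cy, r1):
                continue
            ang = rng.uniform(0, 2 * math.pi)
            d = r1 + r2 - 0.5  # masks overlap by a hair -> 8-connected touch
            px, py = cx + d * math.cos(ang), cy + d * math.sin(ang)
            centers.append((cx, cy))
            radii.append(r1)
            if ok(px, py, r2, skip_last=1):
                centers.append((px, py))
                radii.append(r2)
                placed = True
            else:
                centers.pop()
                radii.pop()
        if not placed:
            raise PlacementError(
                f"could not place {n} nuclei of radius {rlo}-{rhi} px in a "
                f"{w}x{h} px field")
    while len(centers) < n:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n} nuclei of radius {rlo}-{rhi} px in a "
                f"{w}x{h} px field")
        attempts += 1
        r = rng.uniform(rlo, rhi)
        cx, cy = rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)
        if ok(cx, cy, r):
            centers.append((cx, cy))
            radii.append(r)
    return np.array(centers), np.array(radii)


def _rasterize_nuclei(spec: SceneSpec, centers: np.ndarray, radii: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    h, w = spec.field_size_px
    labels = np.zeros((h, w), dtype=np.int32)
    # mild boundary irregularity: low-order sinusoidal radius modulation
    phases = rng.uniform(0, 2 * math.pi, (len(centers), 2))
    for i, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        rad = int(math.ceil(r * 1.25)) + 2
        y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
        x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        phi = np.arctan2(dy, dx)
        rb = r * (1 + 0.06 * np.sin(2 * phi + phases[i - 1, 0])
                  + 0.05 * np.sin(3 * phi + phases[i - 1, 1]))
        disk = dy ** 2 + dx ** 2 <= rb ** 2
        region = labels[y0:y1, x0:x1]
        region[disk & (region == 0)] = i
    return labels


def generate_scene(spec: SceneSpec) -> GroundTruth:
    """Generate a scene's complete ground truth (masks, classes, objects)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_centers(spec, rng)
    nuclei = _rasterize_nuclei(spec, centers, radii, rng)

    # Voronoi-bounded dilation: nearest nucleus, clipped at max radius
    dist, (iy, ix) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
    cells = np.where(dist <= spec.cell_max_radius_px, nuclei[iy, ix], 0)
    cells = cells.astype(np.int32)
    cells[nuclei > 0] = nuclei[nuclei > 0]

    n = spec.n_cells
    table = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "x": centers[:, 0], "y": centers[:, 1], "radius_px": radii,
        "z_um": rng.normal(0.0, 0.8, n),
    })

    for m in spec.marker_specs:
        pos = rng.random(n) < m.positive_fraction
        mean = np.where(pos, m.positive_mean, m.negative_mean)
        inten = mean * np.exp(rng.normal(0.0, m.sigma, n))
        table[f"{m.name}__class"] = pos
        table[f"{m.name}__intensity"] = np.clip(inten, 0, 45000.0)

    truth = GroundTruth(spec=spec, nuclei=nuclei, cells=cells, table=table,
                        foci={}, spots={})

    def draw_puncta(p: PunctaSpec, support: np.ndarray, diffuse: bool,
                    interior_margin_px: float = 0.0):
        if interior_margin_px > 0:
            # foci sit in the compartment interior: keep them clear of the
            # boundary so their shape is not dominated by mask clipping
            dist_in = ndi.distance_transform_edt(support > 0)
            support = np.where(dist_in >= interior_margin_px, support, 0)
        slices = ndi.find_objects(support)
        if diffuse:
            is_diff = rng.random(n) < p.diffuse_fraction
            level = rng.uniform(*p.amp_range, n) * is_diff
            table[f"{p.name}__diffuse"] = is_diff
            table[f"{p.name}__diffuse_level"] = level
        counts = rng.poisson(p.mean_count, n)
        if diffuse:
            counts = np.where(is_diff, 0, counts)
        # puncta are discrete objects: keep a minimum separation so the
        # per-cell count is well defined at the rendering resolution
        min_sep = max(5.0, 3.0 * p.sigma_px)
        rows = []
        for cid in range(1, n + 1):
            k = int(counts[cid - 1])
            if k == 0 or cid - 1 >= len(slices) or slices[cid - 1] is None:
                continue
            sl = slices[cid - 1]
            ys, xs = np.nonzero(support[sl] == cid)
            if ys.size == 0:
                continue
            placed: list[tuple[float, float]] = []
            tries = 0
            while len(placed) < k and tries < 40 * k:
                tries += 1
                j = int(rng.integers(0, ys.size))
                ox = xs[j] + sl[1].start + rng.uniform(-0.5, 0.5)
                oy = ys[j] + sl[0].start + rng.uniform(-0.5, 0.5)
                if all((ox - qx) ** 2 + (oy - qy) ** 2 >= min_sep ** 2
                       for qx, qy in placed):
                    placed.append((ox, oy))
            for ox, oy in placed:
                rows.append((ox, oy, float(rng.uniform(*p.amp_range)),
                             p.sigma_px, cid,
                             float(table.loc[cid - 1, "z_um"]
                                   + rng.normal(0.0, 0.4))))
        return pd.DataFrame(rows, columns=["x", "y", "amplitude", "sigma_px",
                                           "owner", "z_um"])

    cytoplasm = np.where(nuclei > 0, 0, cells).astype(np.int32)
    for p in spec.foci_specs:
        truth.foci[p.name] = draw_puncta(p, nuclei, diffuse=True,
                                         interior_margin_px=2.0)
    for p in spec.spot_specs:
        support = cytoplasm if (cytoplasm > 0).any() else cells
        truth.spots[p.name] = draw_puncta(p, support, diffuse=False)
    return truth


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _channel_seed(spec_seed: int, round_id: int, name: str, plane: int) -> list[int]:
    return [spec_seed & 0x7FFFFFFF, round_id,
            zlib.crc32(name.encode()) & 0x7FFFFFFF, plane]


def _finalize(expected: np.ndarray, spec: SceneSpec, noise: bool,
              rng: np.random.Generator | None) -> np.ndarray:
    if noise:
        lam = np.clip(expected, 0, None) * spec.noise.poisson_gain
        out = rng.poisson(lam) / spec.noise.poisson_gain \
            + rng.normal(0.0, spec.noise.read_sigma, expected.shape)
    else:
        out = expected
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def rasterize_channel(truth: GroundTruth, name: str) -> np.ndarray:
    """Direct noise-free rasterization of a channel at the base pixel size."""
    exp = truth.expected_channel(name) + truth.spec.background_level
    return np.clip(np.rint(exp), 0, 65535).astype(np.uint16)


def render_round(truth: GroundTruth, channels: Sequence[str],
                 transform: RigidTransform | None = None,
                 pixel_size_um: float | None = None, noise: bool = True,
                 round_id: int = 0, stage_origin_um: tuple[float, float] = (0.0, 0.0),
                 magnification_tag: str = "") -> MultichannelImage:
    """Render one staining round of the scene.

    ``transform`` is the slide misplacement for this round, expressed as
    the rigid mapping from this round's image coordinates back to the
    scene (round-1) frame — exactly what registering this round onto the
    first recovers.  It is stated at the scene's base pixel size and is
    rescaled automatically when rendering at a different
    ``pixel_size_um``.  The image metadata records the *nominal* stage
    origin — the misplacement is what registration must recover.
    """
    spec = truth.spec
    ps = pixel_size_um if pixel_size_um is not None else spec.pixel_size_um
    scale = spec.pixel_size_um / ps
    out: dict[str, np.ndarray] = {}
    for name in channels:
        exp = truth.expected_channel(name) + spec.background_level
        if scale != 1.0:
            exp = _float_resize(exp, scale)
        if transform is not None:
            t = transform.rescale(scale) if scale != 1.0 else transform
            exp = _warp_float(exp, t.invert())
        rng = (np.random.default_rng(_channel_seed(spec.seed, round_id, name, 0))
               if noise else None)
        out[name] = _finalize(exp, spec, noise, rng)
    truth.applied_transforms[round_id] = (transform if transform is not None
                                          else RigidTransform.identity())
    truth.pixel_size_ratios[round_id] = scale
    return MultichannelImage(out, pixel_size_um=ps,
                             stage_origin_um=stage_origin_um,
                             round_id=round_id,
                             magnification_tag=magnification_tag)


def render_stack(truth: GroundTruth, channels: Sequence[str], z_planes: int,
                 z_step_um: float, transform: RigidTransform | None = None,
                 axial_offset_planes: int = 0,
                 pixel_size_um: float | None = None, noise: bool = True,
                 round_id: int = 0, sigma_z_um: float = 1.2,
                 ) -> list[MultichannelImage]:
    """Render a Z-stack: each object carries a Gaussian axial profile
    centered on its ground-truth z; a per-round axial offset shifts the
    sampled grid by whole planes.

    Axial weights are normalized over the offset-0 grid, so with one plane
    the stack degenerates to :func:`render_round` and, with zero noise, a
    sum projection conserves each object's rendered amplitude.
    """
    if z_planes < 1:
        raise ValueError("z_planes must be >= 1")
    if not z_step_um > 0:
        raise ValueError("z_step_um must be positive")
    spec = truth.spec
    ps = pixel_size_um if pixel_size_um is not None else spec.pixel_size_um
    scale = spec.pixel_size_um / ps
    grid0 = (np.arange(z_planes) - (z_planes - 1) / 2.0) * z_step_um
    grid = grid0 - axial_offset_planes * z_step_um

    def axial_weights(z_obj: np.ndarray) -> np.ndarray:
        """(n_obj, z_planes) weights, unit-sum over the offset-0 grid."""
        g = np.exp(-((grid[None, :] - z_obj[:, None]) ** 2) / (2 * sigma_z_um ** 2))
        norm = np.exp(-((grid0[None, :] - z_obj[:, None]) ** 2)
                      / (2 * sigma_z_um ** 2)).sum(axis=1)
        return g / np.maximum(norm[:, None], 1e-300)

    markers = {m.name for m in spec.marker_specs}
    cell_w = axial_weights(truth.table["z_um"].to_numpy())
    planes: list[MultichannelImage] = []
    for k in range(z_planes):
        out: dict[str, np.ndarray] = {}
        for name in channels:
            if name in markers:
                lut = truth.intensity_lut(name) \
                    * np.concatenate([[0.0], cell_w[:, k]])
                m = next(m for m in spec.marker_specs if m.name == name)
                labels = {"nucleus": truth.nuclei, "cell": truth.cells,
                          "cytoplasm": np.where(truth.nuclei > 0, 0, truth.cells)
                          }[m.compartment]
                exp = lut[labels]
            else:
                table = (truth.foci.get(name) if name in truth.foci
                         else truth.spots.get(name))
                if table is None:
                    raise KeyError(f"unknown channel {name!r}")
                clip_to = truth.nuclei if name in truth.foci else truth.cells
                w = (axial_weights(table["z_um"].to_numpy())[:, k]
                     if len(table) else np.zeros(0))
                exp = truth._render_puncta(table, clip_to, z_weight=w)
                if name in truth.foci and f"{name}__diffuse_level" in truth.table:
                    lut = np.zeros(truth.n_cells + 1)
                    lut[truth.table["cell_id"].to_numpy()] = \
                        truth.table[f"{name}__diffuse_level"].to_numpy()
                    exp = exp + (lut * np.concatenate(
                        [[0.0], cell_w[:, k]]))[truth.nuclei] \
                        * truth._edge_taper()
            exp = exp + spec.background_level
            if scale != 1.0:
                exp = _float_resize(exp, scale)
            if transform is not None:
                t = transform.rescale(scale) if scale != 1.0 else transform
                exp = _warp_float(exp, t.invert())
            rng = (np.random.default_rng(
                _channel_seed(spec.seed, round_id, name, k)) if noise else None)
            out[name] = _finalize(exp, spec, noise, rng)
        planes.append(MultichannelImage(out, pixel_size_um=ps,
                                        round_id=round_id))
    return planes


def stack_channel(stack: Sequence[MultichannelImage], name: str) -> np.ndarray:
    """Collect one channel of a rendered stack into a (Z, Y, X) array."""
    return np.stack([plane.get(name) for plane in stack])


# --------------------------------------------------------------------------
# TMA overview map
# --------------------------------------------------------------------------

def generate_tma_map(n_rows: int = 3, n_cols: int = 4,
                     core_diameter_um: float = 1200.0,
                     pitch_um: float = 1800.0, pixel_size_um: float = 10.0,
                     margin_um: float = 1200.0, intensity: float = 3000.0,
                     background: float = 100.0, read_sigma: float = 8.0,
                     seed: int = 0) -> tuple[MultichannelImage, pd.DataFrame]:
    """A low-magnification overview of a tissue microarray: bright textured
    disk cores on a dark background.  Returns the map and the ground-truth
    core centers (stage um, with the map's origin at stage (0, 0))."""
    rng = np.random.default_rng(seed)
    w_um = 2 * margin_um + (n_cols - 1) * pitch_um
    h_um = 2 * margin_um + (n_rows - 1) * pitch_um
    w, h = int(round(w_um / pixel_size_um)), int(round(h_um / pixel_size_um))
    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    centers = []
    r_px = core_diameter_um / 2 / pixel_size_um
    for i in range(n_rows):
        for j in range(n_cols):
            cx_um = margin_um + j * pitch_um + rng.uniform(-0.04, 0.04) * pitch_um
            cy_um = margin_um + i * pitch_um + rng.uniform(-0.04, 0.04) * pitch_um
            cx, cy = cx_um / pixel_size_um, cy_um / pixel_size_um
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img += intensity * np.clip(1 - d2 / r_px ** 2, 0, None) ** 0.3 \
                * (d2 <= r_px ** 2)
            centers.append((f"core_{i}_{j}", cx_um, cy_um))
    # mild multiplicative texture so registration has structure to lock onto
    texture = ndi.gaussian_filter(rng.normal(0, 1, img.shape), 4)
    img = img * (1 + 0.15 * texture) + background
    img = img + rng.normal(0, read_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    table = pd.DataFrame(centers, columns=["label", "x_um", "y_um"])
    return (MultichannelImage({"DAPI": img}, pixel_size_um=pixel_size_um,
                              magnification_tag="4x"), table)


# --------------------------------------------------------------------------
# ground-truth export
# --------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> Path:
    """Persist ground truth as CSV object tables + label-mask TIFFs + YAML."""
    from .io import write_label_mask
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.spec.write_yaml(outdir / "scene_spec.yaml")
    write_label_mask(truth.nuclei, outdir / "truth_nuclei.tif")
    write_label_mask(truth.cells, outdir / "truth_cells.tif")
    truth.table.to_csv(outdir / "truth_cells.csv", index=False)
    for kind, tables in (("foci", truth.foci), ("spots", truth.spots)):
        for name, tab in tables.items():
            tab.to_csv(outdir / f"truth_{kind}_{name}.csv", index=False)
    return outdir
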