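"""Nucleus segmentation, cell-body delineation, and spot/foci detection.

The measurement stage needs three label layers: nuclei from the DNA
channel (with decomposition of touching clusters), cell bodies grown from
each nucleus and bounded by the membrane/cytokeratin signal, and
subcellular punctate objects (DNA-damage foci, RNA-FISH spots) measured
on the raw channel and assigned to the cell containing their centroid.

All operators are classical and deterministic: Gaussian smoothing, global
thresholding (Otsu by default, manual override), Euclidean distance
transform, seeded watershed (ties resolved in a fixed scan order by the
watershed implementation), and a median/opening-envelope band-pass for
puncta.  Identical inputs and parameters always give identical masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_holes
from skimage.segmentation import watershed


@dataclass(frozen=True)
class SegmentationParams:
    """Free parameters of DNA-based segmentation and cell delineation."""
    threshold: float | None = None        # None -> Otsu on the smoothed image
    min_nucleus_area_px: int = 60
    max_nucleus_area_px: int = 2500
    smoothing_sigma_px: float = 2.0
    decompose_clusters: bool = True
    min_seed_distance_px: int = 6
    cell_max_radius_px: float = 8.0       # growth beyond the nucleus

    def __post_init__(self) -> None:
        if self.min_nucleus_area_px >= self.max_nucleus_area_px:
            raise ValueError("min nucleus area must be < max nucleus area")


@dataclass(frozen=True)
class SpotDetectionParams:
    """Free parameters of punctate-object detection."""
    tophat_radius_px: int = 4
    threshold_abs: float | None = None    # None -> k_sigma x robust background
    k_sigma: float = 5.0
    min_spot_area_px: int = 2
    max_spot_area_px: int = 400
    merge_distance_px: float = 0.0
    min_separation_px: float = 2.0        # deblend peaks farther apart than this

    def __post_init__(self) -> None:
        if self.tophat_radius_px <= 0 or self.min_spot_area_px <= 0:
            raise ValueError("radii and areas must be positive")


@dataclass
class SpotRecord:
    """One detected subcellular object, measured on the raw channel."""
    spot_id: int
    channel: str
    x: float
    y: float
    area_px: int
    total_intensity: int
    mean_intensity: float
    secondary_mean: float | None = None
    owner_cell_id: int | None = None      # None = unassigned


# --------------------------------------------------------------------------
# nuclei
# --------------------------------------------------------------------------

def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n in order of first (row-major) appearance."""
    out = np.zeros_like(labels, dtype=np.int32)
    flat = labels.ravel()
    order = {}
    nxt = 1
    for v in flat[flat > 0]:
        if v not in order:
            order[v] = nxt
            nxt += 1
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    for v, k in order.items():
        lut[v] = k
    out = lut[labels]
    return out


def segment_nuclei(dapi: np.ndarray, params: SegmentationParams = SegmentationParams()
                   ) -> np.ndarray:
    """Label nuclei in a DNA channel; split touching clusters on request.

    Pipeline: Gaussian smoothing -> global threshold (Otsu unless a manual
    value is given) -> hole filling -> [distance transform -> local-maxima
    seeds -> watershed on the inverted distance] -> area filter.  An
    all-background threshold result yields an empty mask with a warning,
    not an error.
    """
    img = gaussian(np.asarray(dapi, dtype=np.float64),
                   sigma=params.smoothing_sigma_px, preserve_range=True)
    if params.threshold is not None:
        thr = float(params.threshold)
    else:
        if np.ptp(img) == 0:
            warnings.warn("constant image: no nuclei found")
            return np.zeros(img.shape, dtype=np.int32)
        thr = float(threshold_otsu(img))
    fg = img > thr
    if not fg.any():
        warnings.warn("threshold produced an empty foreground")
        return np.zeros(img.shape, dtype=np.int32)
    fg = remove_small_holes(fg, max_size=params.min_nucleus_area_px)

    if params.decompose_clusters:
        dist = ndi.distance_transform_edt(fg)
        coords = peak_local_max(dist, min_distance=params.min_seed_distance_px,
                                labels=fg, exclude_border=False)
        # fixed row-major seed numbering so masks are reproducible
        coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
        markers = np.zeros(fg.shape, dtype=np.int32)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        labels = watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < params.min_nucleus_area_px)
                         | (areas > params.max_nucleus_area_px))
    keep = labels.copy()
    keep[np.isin(labels, bad[bad > 0])] = 0
    return _relabel_sequential(keep)


# --------------------------------------------------------------------------
# cell bodies
# --------------------------------------------------------------------------

def delineate_cells(nuclei: np.ndarray, boundary_channel: np.ndarray | None,
                    params: SegmentationParams = SegmentationParams()
                    ) -> np.ndarray:
    """Grow one cell body per nucleus, bounded by the membrane signal.

    Cells keep their nucleus id and contain their nucleus.  With an
    informative boundary channel, the boundary-positive territory (robust
    background threshold, so dim cells are kept) is partitioned among the
    nuclei by proximity, clipped at a maximum radius around each nucleus.
    With a flat (or absent) boundary channel the fallback is the same
    nearest-nucleus partition clipped at the radius alone.
    """
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        raise ValueError("nuclei mask is empty")
    dist, (iy, ix) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
    nearest = nuclei[iy, ix]
    reach = dist <= params.cell_max_radius_px

    flat = boundary_channel is None
    if not flat:
        boundary_channel = np.asarray(boundary_channel, dtype=np.float64)
        if boundary_channel.shape != nuclei.shape:
            raise ValueError("boundary channel and nuclei mask shapes differ")
        flat = float(boundary_channel.std()) < 1e-6
    if flat:
        cells = np.where(reach, nearest, 0).astype(np.int32)
    else:
        smoothed = gaussian(boundary_channel, sigma=1.0, preserve_range=True)
        med = float(np.median(smoothed))
        sigma_rb = 1.4826 * float(np.median(np.abs(smoothed - med)))
        thr = med + 5.0 * max(sigma_rb, 1e-6)
        territory = (smoothed > thr) | (nuclei > 0)
        cells = np.where(reach & territory, nearest, 0).astype(np.int32)
    cells[nuclei > 0] = nuclei[nuclei > 0]
    return cells


# --------------------------------------------------------------------------
# puncta
# --------------------------------------------------------------------------

def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy ** 2 + xx ** 2 <= radius ** 2)


def detect_spots(channel: np.ndarray,
                 params: SpotDetectionParams = SpotDetectionParams(),
                 restrict_to: np.ndarray | None = None,
                 secondary_channel: np.ndarray | None = None,
                 channel_name: str = "") -> list[SpotRecord]:
    """Detect punctate objects in a channel.

    The local background is the upper envelope of two estimators — a
    rolling median (window ``4 x tophat_radius_px + 1``) and a grayscale
    opening with a ``tophat_radius_px`` disk: the opening tracks sharp
    compartment edges, the median ignores clustered puncta, and taking
    their maximum suppresses both smooth structure and uniformly bright
    nuclear-diffuse compartments.  The residue is thresholded at
    ``k_sigma`` times the robust background sigma, scaled locally by the
    Poisson square-root law, unless an absolute threshold is given.  Blended objects are deblended
    by a watershed seeded at intensity peaks at least
    ``min_separation_px`` apart; the resulting components are
    area-filtered, and components whose intensity-weighted centroids are
    closer than ``merge_distance_px`` are merged back.  Intensities are
    measured on the raw channel within the spot mask; a secondary channel
    (e.g. a co-localization read-out) is averaged over the same mask.
    Spots whose centroid falls outside ``restrict_to`` are dropped.
    """
    raw = np.asarray(channel)
    img = raw.astype(np.float64)
    win = 4 * params.tophat_radius_px + 1
    local_bg = np.maximum(
        ndi.median_filter(img, size=win),
        ndi.grey_opening(img, footprint=_disk_footprint(params.tophat_radius_px)))
    th = np.clip(img - local_bg, 0.0, None)
    if params.threshold_abs is not None:
        mask = th > float(params.threshold_abs)
    else:
        # robust background sigma of the residue, scaled locally by the
        # Poisson square-root law: photon noise grows with the local
        # signal, so bright diffuse compartments need a higher bar while
        # dim foci on dark background stay detectable
        resid = img - local_bg
        global_sigma = 1.4826 * float(np.median(np.abs(resid)))
        if global_sigma == 0:
            global_sigma = max(float(resid.std()), 1e-6)
        med_raw = max(float(np.median(img)), 1.0)
        scale = np.sqrt(np.maximum(local_bg, med_raw) / med_raw)
        mask = th > params.k_sigma * global_sigma * scale
    if params.min_separation_px > 0 and mask.any():
        # light smoothing stabilizes the maxima of blended, noisy pairs
        th_s = gaussian(th, sigma=0.8, preserve_range=True)
        sep = max(1, int(round(params.min_separation_px)))
        coords = peak_local_max(th_s, min_distance=sep,
                                labels=mask, exclude_border=False)
        coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        labels = watershed(-th_s, markers, mask=mask)
        n = int(labels.max())
    else:
        labels, n = ndi.label(mask)
    if n == 0:
        return []

    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = [i + 1 for i in range(n)
            if params.min_spot_area_px <= areas[i] <= params.max_spot_area_px]
    if not keep:
        return []
    # intensity-weighted centroids on the background-subtracted signal
    cent = ndi.center_of_mass(th, labels, index=keep)
    ids = list(keep)

    if params.merge_distance_px > 0 and len(ids) > 1:
        parent = list(range(len(ids)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                dy = cent[i][0] - cent[j][0]
                dx = cent[i][1] - cent[j][1]
                if dy * dy + dx * dx <= params.merge_distance_px ** 2:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(ids)):
            groups.setdefault(find(i), []).append(ids[i])
        merged = np.zeros_like(labels)
        new_ids = []
        for k, members in enumerate(sorted(groups.values(), key=min), start=1):
            merged[np.isin(labels, members)] = k
            new_ids.append(k)
        labels, ids = merged, new_ids
        cent = ndi.center_of_mass(th, labels, index=ids)

    records: list[SpotRecord] = []
    for sid, (cy, cx) in zip(ids, cent):
        m = labels == sid
        if restrict_to is not None:
            ry, rx = int(round(cy)), int(round(cx))
            if not (0 <= ry < restrict_to.shape[0]
                    and 0 <= rx < restrict_to.shape[1]
                    and restrict_to[ry, rx] > 0):
                continue
        total = int(raw[m].astype(np.int64).sum())
        area = int(m.sum())
        rec = SpotRecord(
            spot_id=len(records) + 1, channel=channel_name,
            x=float(cx), y=float(cy), area_px=area,
            total_intensity=total, mean_intensity=total / area,
            secondary_mean=(float(np.asarray(secondary_channel,
                                             np.float64)[m].mean())
                            if secondary_channel is not None else None))
        records.append(rec)
    return records


def assign_spots_to_cells(spots: Sequence[SpotRecord], cells: np.ndarray
                          ) -> list[SpotRecord]:
    """Set each spot's owner to the cell label at its centroid pixel.

    A centroid on background leaves the owner unassigned; the spot is kept
    for population-level statistics.
    """
    cells = np.asarray(cells)
    out = []
    for s in spots:
        ry, rx = int(round(s.y)), int(round(s.x))
        if not (0 <= ry < cells.shape[0] and 0 <= rx < cells.shape[1]):
            raise ValueError(f"spot centroid ({s.x}, {s.y}) outside image bounds")
        label = int(cells[ry, rx])
        out.append(replace(s, owner_cell_id=label if label > 0 else None))
    return out
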