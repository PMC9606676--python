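"""Per-cell and per-spot measurement database, and cross-round merging.

Each segmented cell becomes one database row: an integer id tag, image
localization (core/round/bounding box), physical size (Cell Area in
pixels), shape (Circularity = 4*pi*Area/Perimeter^2, 1 for a perfect
circle, toward 0 for elongated objects), the cell-center ("baricentrum")
coordinates in image pixels and stage micrometers, per-channel Total and
Mean Intensity over the cell mask, and per spot-channel statistics
(number of spots, sum of the spots' total intensities, average of the
spots' mean intensities).  Totals accumulate in integer arithmetic —
16-bit data never incur floating drift.

Rounds measured in their own frames are merged by mapping each round's
cell centers through its rigid transform into the anchor round's frame
and assigning to the anchor cell whose mask contains the transformed
center; unmatched measurements are flagged, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .registration import RigidTransform, transform_points
from .segmentation import SpotRecord
from .targeting import StageMapping

UNASSIGNED = "unassigned"


def circularity(area_px: float, perimeter_px: float) -> float:
    """Shape descriptor ``4*pi*A / P**2``.

    Evaluates to exactly 1 for an analytic circle (A = pi r^2, P = 2 pi r)
    and decreases toward 0 for elongated shapes.  On rasterized masks the
    perimeter estimator can overshoot slightly for small round objects, so
    the value is capped at 1.0.
    """
    if not (area_px > 0 and perimeter_px > 0):
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * math.pi * area_px / perimeter_px ** 2)


@dataclass
class CellRecord:
    cell_id: int
    core_id: str
    round_id: int
    bbox: tuple[int, int, int, int]            # (min_row, min_col, max_row, max_col)
    centroid_image_px: tuple[float, float]     # (x, y) baricentrum
    centroid_stage_um: tuple[float, float] | None
    area_px: int
    circularity: float
    intensity: dict[str, tuple[int, float]] = field(default_factory=dict)
    spots: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    # intensity: channel -> (total, mean); spots: channel -> (n, total, mean_per_spot)


def _check_record_invariants(rec: CellRecord) -> None:
    for ch, (total, mean) in rec.intensity.items():
        assert abs(total - mean * rec.area_px) < 0.5 + 1e-6 * abs(total), \
            f"{ch}: total != mean * area"


def measure_cells(cells: np.ndarray, image, spots: Sequence[SpotRecord] = (),
                  mapping: StageMapping | None = None, core_id: str = "",
                  round_id: int | None = None) -> list[CellRecord]:
    """Measure every labeled cell on every channel of ``image``.

    ``spots`` must already be owner-assigned; spot statistics are grouped
    per channel.  ``mapping`` converts the cell center to stage um.
    Intensities are measured on the raw 16-bit values, never on
    display-scaled data.
    """
    cells = np.asarray(cells)
    channels: Mapping[str, np.ndarray] = image.channels
    for name, ch in channels.items():
        if ch.shape != cells.shape:
            raise ValueError(f"channel {name!r} shape {ch.shape} does not "
                             f"match mask shape {cells.shape}")
    if round_id is None:
        round_id = image.round_id
    n = int(cells.max())
    if n == 0:
        return []

    # integer accumulation of totals and areas per label
    flat = cells.ravel()
    areas = np.bincount(flat, minlength=n + 1)
    totals = {}
    for name, ch in channels.items():
        acc = np.zeros(n + 1, dtype=np.int64)
        np.add.at(acc, flat, np.asarray(ch).ravel().astype(np.int64))
        totals[name] = acc

    spot_groups: dict[str, dict[int, list[SpotRecord]]] = {}
    spot_channels = sorted({s.channel for s in spots})
    for s in spots:
        if s.owner_cell_id is not None:
            spot_groups.setdefault(s.channel, {}).setdefault(
                s.owner_cell_id, []).append(s)

    records: list[CellRecord] = []
    for prop in regionprops(cells):
        cid = int(prop.label)
        cy, cx = prop.centroid
        stage = (tuple(mapping.image_to_stage((cx, cy)))
                 if mapping is not None else None)
        perim = float(prop.perimeter)
        circ = circularity(prop.area, perim) if perim > 0 else 1.0
        rec = CellRecord(
            cell_id=cid, core_id=core_id, round_id=round_id,
            bbox=tuple(int(b) for b in prop.bbox),
            centroid_image_px=(float(cx), float(cy)),
            centroid_stage_um=stage,
            area_px=int(areas[cid]), circularity=circ)
        for name in channels:
            total = int(totals[name][cid])
            rec.intensity[name] = (total, total / rec.area_px)
        for name in spot_channels:
            group = spot_groups.get(name, {}).get(cid, [])
            ns = len(group)
            rec.spots[name] = (
                ns,
                int(sum(s.total_intensity for s in group)),
                (sum(s.mean_intensity for s in group) / ns) if ns else 0.0)
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# tabular form
# --------------------------------------------------------------------------

def cell_table(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Flatten CellRecords into the database schema.

    Column convention: ``{channel}__total``, ``{channel}__mean``,
    ``{spotchannel}__nspots``, ``{spotchannel}__spots_total``,
    ``{spotchannel}__mean_per_spot``.
    """
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id, "core_id": r.core_id, "round_id": r.round_id,
            "bbox_min_row": r.bbox[0], "bbox_min_col": r.bbox[1],
            "bbox_max_row": r.bbox[2], "bbox_max_col": r.bbox[3],
            "x_px": r.centroid_image_px[0], "y_px": r.centroid_image_px[1],
            "x_um": (r.centroid_stage_um[0] if r.centroid_stage_um else np.nan),
            "y_um": (r.centroid_stage_um[1] if r.centroid_stage_um else np.nan),
            "area_px": r.area_px, "circularity": r.circularity,
        }
        for ch, (total, mean) in r.intensity.items():
            row[f"{ch}__total"] = total
            row[f"{ch}__mean"] = mean
        for ch, (ns, total, mps) in r.spots.items():
            row[f"{ch}__nspots"] = ns
            row[f"{ch}__spots_total"] = total
            row[f"{ch}__mean_per_spot"] = mps
        rows.append(row)
    return pd.DataFrame(rows)


def spot_table(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    rows = []
    for s in spots:
        rows.append({
            "spot_id": s.spot_id, "channel": s.channel,
            "owner_cell_id": (UNASSIGNED if s.owner_cell_id is None
                              else s.owner_cell_id),
            "x": s.x, "y": s.y, "area_px": s.area_px,
            "total_intensity": s.total_intensity,
            "mean_intensity": s.mean_intensity,
            "secondary_mean": (np.nan if s.secondary_mean is None
                               else s.secondary_mean),
        })
    return pd.DataFrame(rows)


def measure_spot_population(spots: Sequence[SpotRecord]
                            ) -> tuple[pd.DataFrame, dict]:
    """Spots as an independent population, owners or not.

    Returns the per-spot table (unassigned owners included) and summary
    statistics: count, assigned/unassigned split, and intensity quantiles.
    """
    table = spot_table(spots)
    if table.empty:
        return table, {"count": 0, "assigned": 0, "unassigned": 0}
    assigned = int((table["owner_cell_id"] != UNASSIGNED).sum())
    q = table["total_intensity"].quantile([0.25, 0.5, 0.75]).to_dict()
    summary = {
        "count": int(len(table)),
        "assigned": assigned,
        "unassigned": int(len(table)) - assigned,
        "total_intensity_quantiles": {str(k): float(v) for k, v in q.items()},
        "mean_intensity_mean": float(table["mean_intensity"].mean()),
    }
    return table, summary


# --------------------------------------------------------------------------
# cross-round merge
# --------------------------------------------------------------------------

def merge_rounds(tables: Mapping[int, pd.DataFrame],
                 transforms: Mapping[int, RigidTransform],
                 anchor_round: int, anchor_cells: np.ndarray
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-round measurement tables onto the anchor round's cells.

    ``transforms[r]`` maps round-``r`` image coordinates into the anchor
    frame.  A measurement is assigned to the anchor cell whose mask
    contains the transformed cell center; measurements landing on
    background are returned in the ``unmatched`` table, never silently
    dropped.  Merged columns get the suffix ``__r{round}``.
    """
    if anchor_round not in tables:
        raise ValueError(f"anchor round {anchor_round} not among tables")
    anchor_cells = np.asarray(anchor_cells)
    merged = tables[anchor_round].copy()
    unmatched_rows = []
    meta_cols = {"cell_id", "core_id", "round_id", "x_px", "y_px", "x_um",
                 "y_um", "bbox_min_row", "bbox_min_col", "bbox_max_row",
                 "bbox_max_col"}
    for r, tab in tables.items():
        if r == anchor_round:
            continue
        if r not in transforms:
            raise ValueError(f"missing transform for round {r}")
        t = transforms[r]
        pts = tab[["x_px", "y_px"]].to_numpy()
        mapped = transform_points(pts, t, anchor_cells.shape)
        ry = np.clip(np.rint(mapped[:, 1]).astype(int), 0,
                     anchor_cells.shape[0] - 1)
        rx = np.clip(np.rint(mapped[:, 0]).astype(int), 0,
                     anchor_cells.shape[1] - 1)
        owner = anchor_cells[ry, rx]
        inb = ((np.rint(mapped[:, 1]) >= 0)
               & (np.rint(mapped[:, 1]) < anchor_cells.shape[0])
               & (np.rint(mapped[:, 0]) >= 0)
               & (np.rint(mapped[:, 0]) < anchor_cells.shape[1]))
        owner = np.where(inb, owner, 0)
        matched = owner > 0
        sub = tab.loc[matched].copy()
        sub["anchor_cell_id"] = owner[matched]
        # a cell may in principle receive several measurements; keep the first
        sub = sub.drop_duplicates(subset="anchor_cell_id", keep="first")
        data_cols = [c for c in tab.columns if c not in meta_cols]
        renamed = sub[["anchor_cell_id"] + data_cols].rename(
            columns={c: f"{c}__r{r}" for c in data_cols})
        merged = merged.merge(renamed, how="left", left_on="cell_id",
                              right_on="anchor_cell_id").drop(
            columns="anchor_cell_id")
        un = tab.loc[~matched].copy()
        un["source_round"] = r
        unmatched_rows.append(un)
    unmatched = (pd.concat(unmatched_rows, ignore_index=True)
                 if unmatched_rows else pd.DataFrame())
    return merged, unmatched
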