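"""The measurement database: shape descriptors, intensity accounting,
spot aggregation, population statistics, cross-round merging."""

import math

import numpy as np
import pandas as pd
import pytest

import plexcyto as px
from plexcyto.cytometry import circularity, measure_cells, cell_table, \
    measure_spot_population, merge_rounds
from plexcyto.segmentation import SpotRecord, assign_spots_to_cells, \
    detect_spots
from plexcyto.targeting import StageMapping


# ---------------------------------------------------------------------------
# circularity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r", [0.5, 1.0, 3.7, 120.0])
def test_circularity_of_analytic_circle_is_one(r):
    value = circularity(math.pi * r ** 2, 2 * math.pi * r)
    assert value == pytest.approx(1.0, abs=1e-12)


def test_circularity_of_square_is_pi_over_4():
    s = 7.0
    assert circularity(s * s, 4 * s) == pytest.approx(math.pi / 4, abs=1e-12)


def test_circularity_of_bars_decreases_with_elongation():
    def bar(n):  # n x 1 rectangle: A = n, P = 2n + 2
        return circularity(n, 2 * n + 2)
    values = [bar(n) for n in (5, 10, 25, 50)]
    assert bar(25) < 0.3
    assert all(a > b for a, b in zip(values, values[1:]))
    for n in (5, 10, 25, 50):
        assert bar(n) == pytest.approx(4 * math.pi * n / (2 * n + 2) ** 2)


def test_circularity_rejects_nonpositive_inputs():
    for a, p in ((0, 1), (1, 0), (-1, 5), (5, -1)):
        with pytest.raises(ValueError):
            circularity(a, p)


def test_circularity_is_capped_at_one():
    assert circularity(100.0, 10.0) == 1.0   # estimator overshoot case


# ---------------------------------------------------------------------------
# per-cell measurement
# ---------------------------------------------------------------------------

def test_uniform_intensity_definitionally_correct():
    cells = np.zeros((20, 20), dtype=np.int32)
    cells[5:10, 5:12] = 1                      # area 35
    img = px.MultichannelImage(
        {"M": np.where(cells > 0, 120, 0).astype(np.uint16)},
        pixel_size_um=1.0)
    rec = measure_cells(cells, img)[0]
    assert rec.area_px == 35
    assert rec.intensity["M"] == (120 * 35, 120.0)


def test_measurements_equal_brute_force_per_pixel_accumulation(truth,
                                                               noisy_image):
    """Totals, means, and spot counts must match an independent pure-Python
    per-pixel / per-point accumulation, bit-exactly in integer space."""
    cells = truth.cells
    spots = assign_spots_to_cells(
        detect_spots(noisy_image.get("ACTB1"), restrict_to=cells,
                     channel_name="ACTB1"), cells)
    recs = measure_cells(cells, noisy_image, spots)
    # brute force, deliberately simple and independent of numpy grouping
    totals: dict[tuple[str, int], int] = {}
    areas: dict[int, int] = {}
    arrs = {n: noisy_image.get(n) for n in noisy_image.channel_names}
    h, w = cells.shape
    for y in range(h):
        row = cells[y]
        for x in range(w):
            lab = int(row[x])
            if lab == 0:
                continue
            areas[lab] = areas.get(lab, 0) + 1
            for name, arr in arrs.items():
                key = (name, lab)
                totals[key] = totals.get(key, 0) + int(arr[y, x])
    counts: dict[int, int] = {}
    for s in spots:
        if s.owner_cell_id is not None:
            counts[s.owner_cell_id] = counts.get(s.owner_cell_id, 0) + 1
    assert len(recs) == len(areas)
    for rec in recs:
        assert rec.area_px == areas[rec.cell_id]
        for name in arrs:
            total, mean = rec.intensity[name]
            assert total == totals[(name, rec.cell_id)]
            assert mean == pytest.approx(total / rec.area_px)
        assert rec.spots["ACTB1"][0] == counts.get(rec.cell_id, 0)


def test_spot_statistics_arithmetic():
    cells = np.zeros((16, 16), dtype=np.int32)
    cells[2:14, 2:14] = 3
    img = px.MultichannelImage({"S": np.zeros((16, 16), np.uint16)},
                               pixel_size_um=1.0)
    spots = [SpotRecord(1, "S", 5, 5, 10, 50, 5.0, owner_cell_id=3),
             SpotRecord(2, "S", 9, 9, 10, 70, 7.0, owner_cell_id=3)]
    rec = measure_cells(cells, img, spots)[0]
    n, total, mean_per_spot = rec.spots["S"]
    assert (n, total, mean_per_spot) == (2, 120, 6.0)


def test_total_equals_mean_times_area_invariant(truth, noisy_image):
    for rec in measure_cells(truth.cells, noisy_image):
        for total, mean in rec.intensity.values():
            assert total == pytest.approx(mean * rec.area_px)


def test_foreground_totals_bounded_by_image_total(truth, noisy_image):
    recs = measure_cells(truth.cells, noisy_image)
    img_total = int(noisy_image.get("DAPI").astype(np.int64).sum())
    cell_sum = sum(r.intensity["DAPI"][0] for r in recs)
    assert cell_sum <= img_total


def test_zero_noise_mean_recovers_generator_intensity(clean_flat_truth):
    t = clean_flat_truth
    img = px.render_round(t, ["DAPI"], noise=False)
    recs = measure_cells(t.nuclei, img)
    lut = {int(r.cell_id): r["DAPI__intensity"]
           for _, r in t.table.iterrows()}
    for rec in recs:
        assert rec.intensity["DAPI"][1] == pytest.approx(
            lut[rec.cell_id], rel=0.02)


def test_stage_centroid_uses_mapping(truth, clean_image):
    mapping = StageMapping(pixel_size_um=0.325, stage_origin_um=(100.0, 50.0))
    recs = measure_cells(truth.cells, clean_image, mapping=mapping)
    r = recs[0]
    ex = 100.0 + r.centroid_image_px[0] * 0.325
    ey = 50.0 + r.centroid_image_px[1] * 0.325
    assert r.centroid_stage_um == pytest.approx((ex, ey))


def test_dimension_mismatch_rejected(truth):
    img = px.MultichannelImage({"M": np.zeros((10, 10), np.uint16)},
                               pixel_size_um=1.0)
    with pytest.raises(ValueError, match="shape"):
        measure_cells(truth.cells, img)


# ---------------------------------------------------------------------------
# spot population
# ---------------------------------------------------------------------------

def test_empty_population():
    table, summary = measure_spot_population([])
    assert summary["count"] == 0 and table.empty


def test_population_partitions_into_assigned_and_unassigned():
    spots = [SpotRecord(1, "S", 1, 1, 2, 10, 5.0, owner_cell_id=4),
             SpotRecord(2, "S", 2, 2, 2, 12, 6.0, owner_cell_id=None),
             SpotRecord(3, "S", 3, 3, 2, 14, 7.0, owner_cell_id=9)]
    table, summary = measure_spot_population(spots)
    assert summary["count"] == summary["assigned"] + summary["unassigned"]
    assert summary["count"] == 3 and summary["unassigned"] == 1


def test_secondary_channel_mean_matches_brute_force():
    """A secondary channel equal to the raw channel must reproduce the
    spot's own mean intensity (same mask, same pixels)."""
    rng = np.random.default_rng(8)
    img = np.full((100, 100), 100.0)
    yy, xx = np.mgrid[0:100, 0:100]
    for cx, cy in ((30, 30), (70, 60)):
        img += 3000.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.3 ** 2))
    img = rng.poisson(img).astype(np.uint16)
    spots = detect_spots(img, secondary_channel=img)
    assert len(spots) == 2
    for s in spots:
        assert s.secondary_mean == pytest.approx(s.mean_intensity)


# ---------------------------------------------------------------------------
# cross-round merge
# ---------------------------------------------------------------------------

def _tables_for_merge(truth, image, mask):
    recs = measure_cells(mask, image)
    tab = cell_table(recs)
    tab["truth_id"] = tab["cell_id"]
    return tab


def test_identity_merge_concatenates_columns(truth, clean_image):
    tab = _tables_for_merge(truth, clean_image, truth.cells)
    merged, unmatched = merge_rounds(
        {1: tab, 2: tab}, {2: px.RigidTransform.identity()}, 1, truth.cells)
    assert len(unmatched) == 0
    assert len(merged) == len(tab)
    assert "DAPI__mean__r2" in merged.columns
    assert (merged["truth_id__r2"] == merged["cell_id"]).all()


def test_merge_reidentifies_cells_across_known_transform(truth, clean_image):
    t = px.RigidTransform(2.0, (9.0, -6.0))
    # round 2: same scene, slide misplaced; its cell mask and channels live
    # in the round-2 frame (content moved by the inverse mapping)
    mask2 = px.apply_to_mask(truth.cells, t.invert())
    img2 = clean_image.with_channels(
        {n: px.apply_to_image(c, t.invert())
         for n, c in clean_image.channels.items()})
    tab1 = _tables_for_merge(truth, clean_image, truth.cells)
    tab2 = _tables_for_merge(truth, img2, mask2)
    merged, unmatched = merge_rounds({1: tab1, 2: tab2}, {2: t}, 1,
                                     truth.cells)
    ok = merged["truth_id__r2"] == merged["cell_id"]
    assert ok.sum() / len(merged) >= 0.95
    assert len(unmatched) <= 0.05 * len(tab2)


def test_unmatched_measurements_are_flagged(truth, clean_image):
    tab1 = _tables_for_merge(truth, clean_image, truth.cells)
    ghost = tab1.iloc[[0]].copy()
    ghost["cell_id"] = 999
    ghost["x_px"] = 1.0      # background corner
    ghost["y_px"] = 1.0
    tab2 = pd.concat([tab1, ghost], ignore_index=True)
    merged, unmatched = merge_rounds(
        {1: tab1, 2: tab2}, {2: px.RigidTransform.identity()}, 1, truth.cells)
    assert len(unmatched) == 1
    assert unmatched.iloc[0]["cell_id"] == 999
    with pytest.raises(ValueError, match="transform"):
        merge_rounds({1: tab1, 2: tab2}, {}, 1, truth.cells)
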