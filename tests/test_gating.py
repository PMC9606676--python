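"""Gate algebra, brute-force reproducibility, population outputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plexcyto as px
from plexcyto.gating import (PolygonGate, RectangleGate, ThresholdGate,
                             apply_gate, crosstab, make_population_mask,
                             read_gate, select_coordinates,
                             threshold_positive, write_gate)


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(17)
    n = 400
    pos = rng.random(n) < 0.4
    return pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "KI67__mean": np.where(pos, rng.normal(5000, 700, n),
                               rng.normal(400, 120, n)),
        "area_px": rng.integers(80, 400, n),
        "ACTB1__nspots": rng.poisson(6, n),
        "x_um": rng.uniform(0, 1000, n),
        "y_um": rng.uniform(0, 1000, n),
    })


def test_full_range_gate_selects_everything(table):
    g = ThresholdGate("KI67__mean", low=table["KI67__mean"].min(),
                      high=table["KI67__mean"].max(), high_inclusive=True)
    _, sub, fraction = apply_gate(table, g)
    assert fraction == 1.0 and len(sub) == len(table)


def test_contradiction_is_empty(table):
    g = ThresholdGate("KI67__mean", low=1000.0)
    members, _, _ = apply_gate(table, g & ~g)
    assert members.sum() == 0


def test_unknown_parameter_is_an_error(table):
    with pytest.raises(KeyError, match="missing_param"):
        apply_gate(table, ThresholdGate("missing_param", low=0))


def test_rectangle_gate_matches_brute_force_row_counting(table):
    g = RectangleGate("KI67__mean", "area_px", (1000.0, 6000.0),
                      (100.0, 300.0))
    members, _, fraction = apply_gate(table, g)
    brute = sum(1 for _, r in table.iterrows()
                if 1000 <= r["KI67__mean"] < 6000 and 100 <= r["area_px"] < 300)
    assert members.sum() == brute
    assert fraction == brute / len(table)


def test_polygon_gate_matches_point_in_polygon_brute_force(table):
    verts = [(0, 0), (800, 0), (800, 600), (0, 900)]
    g = PolygonGate("x_um", "y_um", verts)
    members, _, _ = apply_gate(table, g)
    from shapely.geometry import Point, Polygon
    poly = Polygon(verts)
    brute = np.array([poly.covers(Point(x, y))
                      for x, y in zip(table["x_um"], table["y_um"])])
    assert np.array_equal(members, brute)
    with pytest.raises(ValueError, match="polygon"):
        PolygonGate("x_um", "y_um", [(0, 0), (1, 1), (1, 0), (0, 1)])


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_de_morgan_identities(seed):
    rng = np.random.default_rng(seed)
    tab = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
    ga = ThresholdGate("a", low=-0.3)
    gb = ThresholdGate("b", high=0.5)
    lhs = (~(ga & gb)).evaluate(tab)
    rhs = ((~ga) | (~gb)).evaluate(tab)
    assert np.array_equal(lhs, rhs)
    lhs2 = (~(ga | gb)).evaluate(tab)
    rhs2 = ((~ga) & (~gb)).evaluate(tab)
    assert np.array_equal(lhs2, rhs2)


def test_membership_invariant_to_row_order(table):
    g = ThresholdGate("KI67__mean", low=1500.0)
    _, sub, _ = apply_gate(table, g)
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    _, sub_s, _ = apply_gate(shuffled, g)
    assert set(sub["cell_id"]) == set(sub_s["cell_id"])


def test_gate_serialization_round_trip(table, tmp_path):
    expr = (ThresholdGate("KI67__mean", low=1500.0)
            & ~RectangleGate("KI67__mean", "area_px", (0.0, 2000.0),
                             (0.0, 200.0))) \
        | PolygonGate("x_um", "y_um", [(0, 0), (10, 0), (5, 8)])
    path = write_gate(expr, tmp_path / "gate.json")
    back = read_gate(path)
    assert np.array_equal(expr.evaluate(table), back.evaluate(table))


# ---------------------------------------------------------------------------
# spot-count positivity (strict > rule)
# ---------------------------------------------------------------------------

def test_spot_positivity_is_strictly_greater_than():
    tab = pd.DataFrame({"ACTB1__nspots": [9, 10, 11, 0, 25]})
    members = threshold_positive(tab, "ACTB1", 10)
    assert members.tolist() == [False, False, True, False, True]


def test_spot_positivity_matches_brute_force(table):
    members = threshold_positive(table, "ACTB1", 5)
    brute = np.array([n > 5 for n in table["ACTB1__nspots"]])
    assert np.array_equal(members, brute)
    with pytest.raises(ValueError):
        threshold_positive(table, "ACTB1", -1)
    with pytest.raises(KeyError):
        threshold_positive(table, "NOPE", 3)


# ---------------------------------------------------------------------------
# cross-tabulation
# ---------------------------------------------------------------------------

def test_crosstab_counts_partition_the_table(table):
    rows = ThresholdGate("ACTB1__nspots", low=6.0)
    cols = ThresholdGate("KI67__mean", low=1500.0)
    counts, fractions = crosstab(table, rows, cols)
    assert counts.to_numpy().sum() == len(table)
    assert np.allclose(fractions.sum(axis=1), 1.0)


def test_crosstab_independent_labels_have_equal_conditionals():
    rng = np.random.default_rng(23)
    n = 4000
    tab = pd.DataFrame({"u": (rng.random(n) < 0.3).astype(float),
                        "v": (rng.random(n) < 0.45).astype(float)})
    counts, fractions = crosstab(tab, ThresholdGate("u", low=0.5),
                                 ThresholdGate("v", low=0.5))
    marginal = tab["v"].mean()
    for row in ("rows+", "rows-"):
        p = fractions.loc[row, "cols+"]
        nrow = counts.loc[row].sum()
        ci = 3 * np.sqrt(marginal * (1 - marginal) / nrow)
        assert abs(p - marginal) <= ci


def test_crosstab_perfect_correlation_has_empty_off_diagonal():
    tab = pd.DataFrame({"a": [0, 0, 1, 1, 1], "b": [0, 0, 1, 1, 1]},
                       dtype=float)
    counts, _ = crosstab(tab, ThresholdGate("a", low=0.5),
                         ThresholdGate("b", low=0.5))
    assert counts.loc["rows+", "cols-"] == 0
    assert counts.loc["rows-", "cols+"] == 0
    with pytest.raises(ValueError):
        crosstab(tab.iloc[:0], ThresholdGate("a", low=0.5),
                 ThresholdGate("b", low=0.5))


# ---------------------------------------------------------------------------
# coordinates and masks
# ---------------------------------------------------------------------------

def test_select_coordinates_projects_member_rows(table):
    g = ThresholdGate("KI67__mean", low=1500.0)
    plist = select_coordinates(table, g)
    _, sub, _ = apply_gate(table, g)
    assert len(plist) == len(sub)
    by_label = {p.label: (p.x_um, p.y_um) for p in plist.positions}
    for _, r in sub.iterrows():
        assert by_label[f"cell_{int(r.cell_id)}"] == (r.x_um, r.y_um)
    empty = select_coordinates(table, ThresholdGate("KI67__mean", low=1e12))
    assert len(empty) == 0
    with pytest.raises(KeyError):
        select_coordinates(table.drop(columns=["x_um"]), g)


def test_gated_positions_land_on_generator_cell_centers(clean_flat_truth):
    t = clean_flat_truth
    img = px.render_round(t, ["DAPI"], noise=False)
    mapping = px.StageMapping(pixel_size_um=t.spec.pixel_size_um)
    recs = px.measure_cells(t.nuclei, img, mapping=mapping)
    tab = px.cell_table(recs)
    plist = select_coordinates(tab, ThresholdGate("area_px", low=0.0))
    truth_xy = {int(r.cell_id): (r.x, r.y) for _, r in t.table.iterrows()}
    tol = t.spec.pixel_size_um  # 1 px equivalent
    for p in plist.positions:
        cid = int(p.label.split("_")[1])
        tx, ty = truth_xy[cid]
        d = np.hypot(p.x_um - tx * t.spec.pixel_size_um,
                     p.y_um - ty * t.spec.pixel_size_um)
        assert d <= tol


def test_population_mask_outputs(truth, clean_image):
    recs = px.measure_cells(truth.cells, clean_image)
    tab = px.cell_table(recs)
    full = make_population_mask(truth.cells, tab,
                                ThresholdGate("area_px", low=0.0))
    assert np.array_equal(full, truth.cells)
    empty = make_population_mask(truth.cells, tab,
                                 ThresholdGate("area_px", low=1e9))
    assert empty.sum() == 0
    g = ThresholdGate("DAPI__mean", low=float(tab["DAPI__mean"].median()))
    mask = make_population_mask(truth.cells, tab, g)
    _, sub, _ = apply_gate(tab, g)
    areas = dict(zip(sub["cell_id"], sub["area_px"]))
    for cid, area in areas.items():
        assert (mask == cid).sum() == area
    with pytest.raises(ValueError, match="absent"):
        make_population_mask(truth.cells, tab.iloc[:-5], g)
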