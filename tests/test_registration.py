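"""Rigid-transform group laws, parameter recovery, mask propagation, 3D."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plexcyto as px
from plexcyto.registration import RegistrationError

angles = st.floats(-30, 30, allow_nan=False)
shifts = st.floats(-80, 80, allow_nan=False)


def _params_close(t: px.RigidTransform, angle, dx, dy, tol=1e-9):
    assert abs(t.angle_deg - angle) < tol
    assert abs(t.translation_px[0] - dx) < tol
    assert abs(t.translation_px[1] - dy) < tol


# ---------------------------------------------------------------------------
# group laws
# ---------------------------------------------------------------------------

@settings(max_examples=30, derandomize=True)
@given(angles, shifts, shifts)
def test_compose_with_inverse_is_identity(a, dx, dy):
    t = px.RigidTransform(a, (dx, dy))
    _params_close(t.compose(t.invert()), 0, 0, 0)
    _params_close(t.invert().compose(t), 0, 0, 0)


@settings(max_examples=30, derandomize=True)
@given(angles, shifts, shifts, st.floats(0.05, 8))
def test_rescale_scales_translation_only_and_round_trips(a, dx, dy, f):
    t = px.RigidTransform(a, (dx, dy))
    s = t.rescale(f)
    assert s.angle_deg == t.angle_deg
    assert s.translation_px[0] == pytest.approx(dx * f)
    assert s.scale_of_definition == pytest.approx(f)
    _params_close(s.rescale(1 / f), a, dx, dy, tol=1e-9 * max(1, abs(dx), abs(dy)))


@settings(max_examples=20, derandomize=True)
@given(angles, angles, angles, shifts, shifts, shifts)
def test_compose_is_associative(a1, a2, a3, d1, d2, d3):
    t1 = px.RigidTransform(a1, (d1, d2))
    t2 = px.RigidTransform(a2, (d2, d3))
    t3 = px.RigidTransform(a3, (d3, d1))
    left = t1.compose(t2).compose(t3)
    right = t1.compose(t2.compose(t3))
    _params_close(left, right.angle_deg, *right.translation_px, tol=1e-8)


def test_rescale_examples():
    ident = px.RigidTransform.identity(0.5).rescale(2.0)
    _params_close(ident, 0, 0, 0)
    assert ident.scale_of_definition == 1.0
    t = px.RigidTransform(2.0, (5.0, 5.0), 0.5)
    up = px.rescale_transform(t, 2.0)
    assert up.angle_deg == 2.0 and up.translation_px == (10.0, 10.0)
    with pytest.raises(ValueError):
        t.rescale(0.0)


def test_transform_json_round_trip(tmp_path):
    t = px.RigidTransform(1.25, (3.5, -2.25))
    path = t.write_json(tmp_path / "t.json")
    assert px.RigidTransform.read_json(path) == t


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def test_identity_nearest_is_bit_exact(noisy_image):
    img = noisy_image.get("DAPI")
    out = px.apply_to_image(img, px.RigidTransform.identity(), "nearest")
    assert np.array_equal(out, img)


def test_pure_translation_moves_single_pixel():
    img = np.zeros((32, 32), dtype=np.uint16)
    img[7, 5] = 1000
    out = px.apply_to_image(img, px.RigidTransform(0.0, (10.0, 0.0)), "nearest")
    assert out[7, 15] == 1000 and out.sum() == 1000


def test_warp_then_inverse_recovers_interior(clean_image):
    img = clean_image.get("DAPI")
    t = px.RigidTransform(3.0, (12.0, -7.0))
    back = px.apply_to_image(px.apply_to_image(img, t), t.invert())
    interior = (slice(60, -60), slice(60, -60))
    rng_span = float(img.max()) - float(img.min())
    err = np.abs(back[interior].astype(float) - img[interior].astype(float))
    assert err.mean() <= 0.01 * rng_span


def test_mask_propagation_contract(truth):
    mask = truth.nuclei
    ident = px.apply_to_mask(mask, px.RigidTransform.identity())
    assert np.array_equal(ident, mask)
    shifted = px.apply_to_mask(mask, px.RigidTransform(0.0, (2.5, -1.5)))
    before = np.bincount(mask.ravel())
    after = np.bincount(shifted.ravel(), minlength=before.size)
    for lab in range(1, before.size):
        assert after[lab] == pytest.approx(before[lab], rel=0.05)
    rot = px.apply_to_mask(mask, px.RigidTransform(8.0, (120.0, 0.0)))
    assert set(np.unique(rot)) <= set(np.unique(mask))
    with pytest.raises(TypeError):
        px.apply_to_mask(mask.astype(float), px.RigidTransform.identity())


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def test_estimate_identity(clean_image):
    img = clean_image.get("DAPI")
    t = px.estimate_rigid(img, img)
    assert abs(t.angle_deg) <= 0.05
    assert np.hypot(*t.translation_px) <= 0.5


def test_estimate_recovers_known_transform(truth):
    ref = px.render_round(truth, ["DAPI"], noise=False).get("DAPI")
    true = px.RigidTransform(3.0, (12.0, -7.0))
    mov = px.render_round(truth, ["DAPI"], transform=true,
                          noise=False).get("DAPI")
    est = px.estimate_rigid(ref, mov)
    resid = est.compose(true.invert())
    assert abs(resid.angle_deg) <= 0.2
    assert np.hypot(*resid.translation_px) <= 2.0


def test_coarse_only_estimate_matches_full_resolution(truth):
    ref = px.render_round(truth, ["DAPI"], noise=False).get("DAPI")
    true = px.RigidTransform(-2.0, (25.0, 14.0))
    mov = px.render_round(truth, ["DAPI"], transform=true,
                          noise=False).get("DAPI")
    coarse = px.estimate_rigid(ref, mov, downscale_factors=(0.25,))
    full = px.estimate_rigid(ref, mov, downscale_factors=(1.0,))
    assert coarse.scale_of_definition == pytest.approx(1.0)
    assert abs(coarse.angle_deg - full.angle_deg) <= 0.2
    assert abs(coarse.translation_px[0] - full.translation_px[0]) <= 2.0
    assert abs(coarse.translation_px[1] - full.translation_px[1]) <= 2.0


def test_degenerate_images_raise():
    flat = np.full((64, 64), 5.0)
    with pytest.raises(RegistrationError):
        px.estimate_rigid(flat, flat)


# ---------------------------------------------------------------------------
# cross-magnification
# ---------------------------------------------------------------------------

def test_cross_magnification_resampling_factor(truth):
    low = px.render_round(truth, ["DAPI"], noise=False,
                          pixel_size_um=0.33)
    high = px.render_round(truth, ["DAPI"], noise=False,
                           pixel_size_um=0.11)
    t, factor = px.register_cross_magnification(low, high)
    assert factor == pytest.approx(3.0)
    # same full scene at both scales: transform near identity
    assert abs(t.angle_deg) <= 0.2
    assert np.hypot(*t.translation_px) <= 2.0


def test_cross_magnification_recovers_crop_origin(truth):
    base = truth.spec.pixel_size_um
    low = px.render_round(truth, ["DAPI"], noise=False)
    hi_full = px.render_round(truth, ["DAPI"], noise=False,
                              pixel_size_um=base / 2)
    oy, ox = 160, 240          # crop origin, high-res pixels
    crop = hi_full.get("DAPI")[oy:oy + 256, ox:ox + 256]
    high = px.MultichannelImage({"DAPI": crop}, pixel_size_um=base / 2)
    t, factor = px.register_cross_magnification(low, high)
    assert factor == pytest.approx(2.0)
    origin = px.transform_points(np.array([[0.0, 0.0]]), t,
                                 (low.shape[0] * 2, low.shape[1] * 2))[0]
    assert abs(origin[0] - ox) <= 1.0
    assert abs(origin[1] - oy) <= 1.0


def test_cross_magnification_equal_pixel_sizes_degenerates(truth):
    img = px.render_round(truth, ["DAPI"], noise=False)
    t, factor = px.register_cross_magnification(img, img)
    assert factor == pytest.approx(1.0)
    assert abs(t.angle_deg) <= 0.05 and np.hypot(*t.translation_px) <= 0.5


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def test_identical_stacks_align_at_zero(clean_flat_truth):
    stack = px.stack_channel(
        px.render_stack(clean_flat_truth, ["DAPI"], 4, 0.6, noise=False),
        "DAPI")
    t, z = px.register_stacks(stack, stack)
    assert z == 0
    assert abs(t.angle_deg) <= 0.05 and np.hypot(*t.translation_px) <= 0.5


def test_stack_offsets_recovered(truth):
    lateral = px.RigidTransform(0.0, (5.0, 5.0))
    ref = px.stack_channel(px.render_stack(truth, ["DAPI"], 5, 0.6,
                                           noise=True, round_id=8), "DAPI")
    mov = px.stack_channel(px.render_stack(truth, ["DAPI"], 5, 0.6,
                                           noise=True, round_id=9,
                                           transform=lateral,
                                           axial_offset_planes=2), "DAPI")
    t, z = px.register_stacks(ref, mov)
    assert z == 2
    assert np.hypot(t.translation_px[0] - 5.0, t.translation_px[1] - 5.0) <= 2.0
    # the chosen offset is the argmax of the exhaustive plane-wise search
    from plexcyto.registration import _ncc, _warp_float
    warped = np.stack([_warp_float(p.astype(float), t) for p in mov])
    scores = {}
    for o in range(-4, 5):
        vals = [_ncc(ref[i].astype(float), warped[i + o])
                for i in range(5) if 0 <= i + o < 5]
        if vals:
            scores[o] = float(np.mean(vals))
    assert z == max(scores, key=scores.get)
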