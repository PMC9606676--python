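"""Shared fixtures: one synthetic scene generated once per session.

The scene uses the generator's study-like defaults (nuclear stain,
cytokeratin cell-body marker, bimodal proliferation marker, DNA-damage
foci with a nuclear-diffuse phenotype, cytoplasmic RNA spots) at a field
size small enough to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import plexcyto as px

SCENE_SEED = 11
ALL_CHANNELS = ["DAPI", "CK8", "KI67", "gH2AX", "53BP1", "ACTB1", "BRAF"]


@pytest.fixture(scope="session")
def scene_spec() -> px.SceneSpec:
    return px.default_scene_spec(seed=SCENE_SEED, n_cells=80,
                                 field_size_px=(448, 448),
                                 touching_fraction=0.2)


@pytest.fixture(scope="session")
def truth(scene_spec) -> px.GroundTruth:
    return px.generate_scene(scene_spec)


@pytest.fixture(scope="session")
def noisy_image(truth):
    return px.render_round(truth, ALL_CHANNELS, noise=True, round_id=1)


@pytest.fixture(scope="session")
def clean_image(truth):
    return px.render_round(truth, ALL_CHANNELS, noise=False, round_id=1)


@pytest.fixture(scope="session")
def clean_flat_truth():
    """Zero-background, zero-noise scene for conservation checks."""
    spec = px.default_scene_spec(seed=5, n_cells=40, field_size_px=(320, 320),
                                 touching_fraction=0.0, background_level=0.0)
    return px.generate_scene(spec)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One small end-to-end demo run shared by pipeline and acceptance tests."""
    outdir = tmp_path_factory.mktemp("demo")
    report = px.demo(seed=3, outdir=outdir, n_cells=90,
                     field_size_px=(384, 384), stack_planes=3)
    return outdir, report


def iou_match(detected: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Best IoU against ``detected`` for every reference label (1..n)."""
    best = np.zeros(int(reference.max()))
    for rid in range(1, int(reference.max()) + 1):
        rmask = reference == rid
        cands = np.unique(detected[rmask])
        for did in cands[cands > 0]:
            dmask = detected == did
            iou = (dmask & rmask).sum() / (dmask | rmask).sum()
            best[rid - 1] = max(best[rid - 1], iou)
    return best
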