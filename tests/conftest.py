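import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import focikit as fk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Three well-separated nuclei, noiseless, deterministic."""
    spec = fk.SceneSpec(
        image_shape=(160, 160),
        n_nuclei=3,
        nucleus_radius_range=(16, 22),
        seed=11,
    )
    image, truth = fk.generate_nuclei_scene(spec)
    return spec, image, truth


def collect_traces(kinetics, n_cells, snr=None, seed0=0, baseline=range(0, 5)):
    """Simulate n stripe movies and return normalized traces (shared helper)."""
    traces = []
    for i in range(n_cells):
        scene = fk.default_stripe_scene(seed0 + i, snr=snr)
        movie, truth = fk.generate_stripe_movie(kinetics, scene)
        nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
        pair = fk.auto_place_control(
            truth.nucleus_masks == nid, truth.damage_roi, nucleus_id=nid
        )
        trace = fk.extract_traces(movie, pair)
        traces.append(fk.normalize_trace(trace, baseline))
    return traces
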