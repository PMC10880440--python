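import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sand2p.scenes import (SceneConfig, easy_scene_config, hard_scene_config,
                           generate_scene)
from sand2p.train import desk_train_config
from sand2p.pipeline import run_on_scene, run_baseline_from_artifacts


@pytest.fixture(scope="session")
def tiny_scene():
    """Small, fast scene with clearly separated bright neurons."""
    cfg = SceneConfig(field_height=32, field_width=32, n_frames=120, n_neurons=4,
                      soma_radius_range=(2.5, 3.5), transient_amplitude_range=(6, 8),
                      spike_rate=0.03, noise_sigma=0.5, seed=11)
    scene, video = generate_scene(cfg)
    return cfg, scene, video


@pytest.fixture(scope="session")
def easy_runs():
    """Full pipeline on the easy scene (peak SNR ~10) for three seeds."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in (0, 1, 2):
            out[seed] = run_on_scene(easy_scene_config(seed), n_labeled_frames=10,
                                     train_cfg=desk_train_config(seed=seed),
                                     seed=seed, return_artifacts=True)
    return out


@pytest.fixture(scope="session")
def hard_runs(request):
    """Pipeline + paired naive-grid-search baseline on the hard scene (~5)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in (0, 1, 2):
            metrics, art = run_on_scene(hard_scene_config(seed), n_labeled_frames=10,
                                        train_cfg=desk_train_config(seed=seed),
                                        seed=seed, return_artifacts=True)
            baseline = run_baseline_from_artifacts(art)
            out[seed] = (metrics, baseline)
    return out
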