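from dataclasses import replace

import numpy as np
import pytest

import eyesvd


@pytest.fixture(scope="session")
def scene_params():
    return eyesvd.EyeSceneParams()


@pytest.fixture(scope="session")
def focus_sequence():
    """One default Focus sequence (600 frames, 4 blinks, active saccades)."""
    params = replace(eyesvd.EyeSceneParams(), seed=0)
    frames, log, label = eyesvd.generate_sequence(eyesvd.FOCUS, params)
    return frames, log, label, params


@pytest.fixture(scope="session")
def pupil_only_sequence():
    """Noise-free sequence with saccades but no blinks: the case the EAR
    baseline is blind to."""
    regime = replace(eyesvd.FOCUS, blink_rate=0.0)
    params = eyesvd.EyeSceneParams(seed=5, noise_sigma=0.0)
    frames, log, label = eyesvd.generate_sequence(regime, params)
    return frames, log, label, params


@pytest.fixture(scope="session")
def static_sequence():
    """Fully static, noise-free sequence: no blinks, no saccades."""
    regime = replace(eyesvd.NONFOCUS_FIXATION, blink_rate=0.0)
    params = eyesvd.EyeSceneParams(seed=7, noise_sigma=0.0)
    frames, log, label = eyesvd.generate_sequence(regime, params)
    return frames, log, label, params


def make_separable_table(n=40, seed=0):
    """Linearly separable two-feature table."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x1 = y * 8.0  # exactly separated cluster feature
    x2 = rng.normal(0, 1, n)
    return pd.DataFrame({"f1": x1.astype(float), "f2": x2, "label": y})
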