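import numpy as np
import pandas as pd
import pytest

import iainmap as im


@pytest.fixture(scope="session")
def two_class_gaussian():
    """Well-separated two-class Gaussian data (means 0.2/0.8, sd 0.05)."""
    rng = np.random.default_rng(11)
    p = 10
    X_train = np.vstack(
        [rng.normal(0.2, 0.05, (20, p)), rng.normal(0.8, 0.05, (20, p))]
    )
    y_train = np.array(["low"] * 20 + ["high"] * 20, dtype=object)
    X_test = np.vstack(
        [rng.normal(0.2, 0.05, (100, p)), rng.normal(0.8, 0.05, (100, p))]
    )
    y_test = np.array(["low"] * 100 + ["high"] * 100, dtype=object)
    return X_train, y_train, X_test, y_test


@pytest.fixture(scope="session")
def synthetic_scene():
    """Default 4-crop scene: 100 pixels/class, 20 % period-correlated cloud."""
    spec = im.SceneSpec(n_per_class=100, missing_prob=0.2, seed=42)
    obs, truth = im.simulate_scene(spec)
    return spec, obs, truth


@pytest.fixture(scope="session")
def scene_samples(synthetic_scene):
    """Held-out-half train/validation split of the default scene."""
    _, _, truth = synthetic_scene
    rng = np.random.default_rng(7)
    roles = np.where(rng.random(len(truth)) < 0.5, "train", "validation")
    return pd.DataFrame(
        {"pixel_id": truth.index, "label": truth.values, "role": roles}
    )


@pytest.fixture(scope="session")
def small_cube():
    """Tiny composited cube from a handful of hand-written observations."""
    rows = []
    for pid in range(3):
        for day, nir, red in [(3, 0.5, 0.1), (9, 0.4, 0.2), (20, 0.6, 0.1)]:
            rows.append((pid, f"2017-04-{day:02d}", "NIR", nir + 0.01 * pid, True))
            rows.append((pid, f"2017-04-{day:02d}", "RED", red, True))
        rows.append((pid, "2017-04-05", "VV", -12.0 - pid, True))
        rows.append((pid, "2017-04-10", "VV", -10.0 - pid, True))
    obs = pd.DataFrame(rows, columns=["pixel_id", "date", "band", "value", "valid"])
    return im.build_cube(obs)
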