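import numpy as np
import pandas as pd
import pytest

from cowseg.features import FEATURE_COLUMNS, FeatureTable
from cowseg.scene_sim import BODY_PARTS, build_cow, preset_pose, render_depth


def make_table(X, y, camera_position=None) -> FeatureTable:
    """Wrap an arbitrary feature matrix and class indices in a FeatureTable.

    X is padded with zero columns to the five predictors; class index i
    maps to the i-th body-part indicator.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 5:
        X = np.hstack([X, np.zeros((len(X), 5 - X.shape[1]))])
    df = pd.DataFrame(X[:, :5], columns=list(FEATURE_COLUMNS))
    names = BODY_PARTS[:7] if camera_position == "U" else BODY_PARTS
    for p in BODY_PARTS:
        df[p] = 0
    for i in range(y.max() + 1 if len(y) else 0):
        df.loc[y == i, names[i]] = 1
    return FeatureTable(df, camera_position)


@pytest.fixture(scope="session")
def cow():
    return build_cow(1.46, 2.4, seed=7)


@pytest.fixture(scope="session")
def scene_s(cow):
    return render_depth(cow, pose=preset_pose("S"), noise_sigma=2.0, seed=11)


@pytest.fixture(scope="session")
def scene_u(cow):
    return render_depth(cow, pose=preset_pose("U"), noise_sigma=2.0, seed=12)


@pytest.fixture(scope="session")
def scene_n(cow):
    return render_depth(cow, pose=preset_pose("N"), noise_sigma=2.0, seed=13)
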