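import math

import numpy as np
import pandas as pd
import pytest

from harbourcam.simulate import SimulationConfig, simulate_scene


@pytest.fixture(scope="session")
def small_cfg():
    """A short two-block campaign, enough for geometric and flow tests."""
    return SimulationConfig(seed=7, block1_days=6, block2_days=4)


@pytest.fixture(scope="session")
def scene(small_cfg):
    return simulate_scene(small_cfg)


@pytest.fixture(scope="session")
def video_rig(scene):
    return scene.rig


@pytest.fixture(scope="session")
def tide(scene):
    return scene.tide


@pytest.fixture(scope="session")
def still_scene():
    cfg = SimulationConfig(seed=7, camera_kind="still", block1_days=6, block2_days=4)
    return simulate_scene(cfg)


@pytest.fixture
def mid_time(small_cfg):
    return pd.Timestamp(small_cfg.block1_start) + pd.Timedelta(hours=34)


def haversine_oracle(lat1, lon1, lat2, lon2, radius=6_371_008.8):
    """Independent great-circle distance for checking planar positioning."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


@pytest.fixture(scope="session")
def haversine():
    return haversine_oracle


def hourly_fixture():
    """389 one-per-hour records, 46 of which sit on sparse covariate levels.

    Glare levels 2 (20 rows) and 3 (14 rows) and Beaufort level 0 (12 rows)
    are at or below the 20-observation cutoff and disjoint, so one filtering
    pass removes exactly 46 rows and leaves a stable 343-row table.
    """
    n = 389
    glare = np.array([0] * 242 + [1] * 113 + [2] * 20 + [3] * 14)
    beaufort = np.array([0] * 12 + [1] * 188 + [2] * 189)
    days = np.arange(n) // 12
    hours = 6 + np.arange(n) % 12
    base = pd.Timestamp("2010-04-16")
    ts = [base + pd.Timedelta(days=int(d), hours=int(h)) for d, h in zip(days, hours)]
    rng = np.random.default_rng(8)
    return pd.DataFrame(
        {
            "time_block_id": np.where(days < 17, "block1", "block2"),
            "timestamp": ts,
            "presence": rng.integers(0, 2, n),
            "glare": glare,
            "beaufort": beaufort,
        }
    )
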