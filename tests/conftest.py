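import numpy as np
import pandas as pd
import pytest

from botoclick.synthgen import ParamDist, TrainSpec


@pytest.fixture
def small_train_spec():
    """A 10-click train at easy SNR with moderate parameters."""
    return TrainSpec(
        n_clicks=10,
        ici_ms=ParamDist(20.0, 5.0, 5.0, 100.0),
        f0_hz=ParamDist(50e3, 5e3, 30e3, 100e3),
        bw_hz=ParamDist(60e3, 10e3, 20e3, 150e3),
        bw_level_db=10.0,
        snr_db=30.0,
    )


def make_feature_table(rng, n_per_class, centers, sd=2.0):
    """Separable 3-feature table for classifier/cluster tests.

    ``centers``: dict label -> (fp, bw3, bw10) mean in kHz.
    """
    rows = []
    for label, mu in centers.items():
        X = rng.normal(mu, sd, size=(n_per_class, 3))
        for x in X:
            rows.append(
                {"label": label, "lineage": label,
                 "fp_khz": x[0], "bw3_khz": x[1], "bw10_khz": x[2]}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def separable_table():
    rng = np.random.default_rng(42)
    return make_feature_table(
        rng,
        80,
        {"A": (30.0, 10.0, 20.0), "B": (60.0, 30.0, 55.0), "C": (90.0, 55.0, 95.0)},
        sd=2.0,
    )
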