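import numpy as np
import pandas as pd
import pytest

import accelbehave as ab

TOY_CSV = "1,2,3,1,2,3,STND\n4,5,6,4,5,6,WALK\n"


@pytest.fixture()
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture()
def toy_dataset():
    return ab.SegmentDataset(
        values=np.array([[1, 2, 3, 1, 2, 3], [4, 5, 6, 4, 5, 6]], dtype=float),
        labels=np.array(["STND", "WALK"], dtype=object),
        n_axes=3,
        samp_freq=10.0,
    )


@pytest.fixture(scope="session")
def stork_like():
    """Full five-class synthetic ethogram at field geometry (1746 x 40 x 3)."""
    return ab.generate_dataset(
        ab.default_specs(), seg_len=40, samp_freq=10.54, seed=1
    )


@pytest.fixture(scope="session")
def stork_features(stork_like):
    """Combined time + frequency feature table (28 columns) of the ethogram."""
    time = ab.time_domain_features(stork_like, winlen_dba=11)
    freq = ab.freq_domain_features(stork_like)
    return ab.combine_features(time, freq)


@pytest.fixture(scope="session")
def small_separable():
    """Three well-separated classes on one informative feature plus noise."""
    rng = np.random.default_rng(7)
    n = 40
    labels = np.repeat(["A", "B", "C"], n)
    ft = pd.DataFrame(
        {
            "signal": np.repeat([0.0, 5.0, 10.0], n) + rng.normal(0, 0.1, 3 * n),
            "noise1": rng.normal(size=3 * n),
            "noise2": rng.normal(size=3 * n),
        }
    )
    return ft, labels
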