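import numpy as np
import pytest

from padseg.io import CountTrack, FragmentEndMap


@pytest.fixture
def tiny_map() -> FragmentEndMap:
    """Two chromosomes, 4 + 3 fragment ends with irregular spacing."""
    return FragmentEndMap(
        starts={"chr1": np.array([100, 200, 300, 400]),
                "chr2": np.array([50, 500, 900])},
        ends={"chr1": np.array([150, 250, 350, 450]),
              "chr2": np.array([100, 550, 950])},
        chrom_lengths={"chr1": 1000, "chr2": 1200},
    )


@pytest.fixture
def tiny_track(tiny_map) -> CountTrack:
    return CountTrack(tiny_map, np.array([3.0, 0.0, 7.0, 2.0, 1.0, 5.0, 0.0]),
                      label="toy")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
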