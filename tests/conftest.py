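import numpy as np
import pytest

from cagegrn.ctss_clustering import CtssProfile
from cagegrn.fixtures import FixtureSpec


@pytest.fixture
def spec():
    return FixtureSpec(seed=7)


def profile_from_positions(entries, is_tpm=True, sample_id=None):
    """entries: list of (chrom, pos, strand, value)."""
    data = {}
    for chrom, pos, strand, value in entries:
        data.setdefault((chrom, strand), []).append((pos, value))
    arrays = {
        key: (
            np.array([p for p, _ in vals], dtype=np.int64),
            np.array([v for _, v in vals], dtype=float),
        )
        for key, vals in data.items()
    }
    return CtssProfile(arrays, is_tpm=is_tpm, sample_id=sample_id)


@pytest.fixture
def make_profile():
    return profile_from_positions
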