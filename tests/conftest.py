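import numpy as np
import pytest

from cghkit.core import GroupLabels, Segment, SegmentMatrix, SegmentedProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_matrix():
    """3 regions x 4 samples, one missing cell."""
    segments = [
        Segment("chr1", 0, 100),
        Segment("chr1", 100, 300),
        Segment("chr2", 0, 150),
    ]
    values = np.array(
        [
            [0.5, -0.2, 0.0, 1.1],
            [0.1, 0.3, -0.9, 0.0],
            [0.0, np.nan, 0.4, -0.4],
        ]
    )
    return SegmentMatrix(segments, ["a", "b", "c", "d"], values)


@pytest.fixture
def two_profiles():
    a = SegmentedProfile(
        "A", [Segment("chr1", 0, 10, 0.5), Segment("chr1", 10, 30, -0.2)]
    )
    b = SegmentedProfile(
        "B", [Segment("chr1", 0, 20, 0.1), Segment("chr1", 20, 30, 0.3)]
    )
    return [a, b]


@pytest.fixture
def labels_pq():
    return GroupLabels({"a": "P", "b": "P", "c": "Q", "d": "Q"})


def random_profiles(rng, n_samples=4, chrom_len=1000, max_segs=6, gap_prob=0.2):
    """Random per-sample segmentations, possibly with coverage gaps."""
    profiles = []
    for i in range(n_samples):
        k = int(rng.integers(1, max_segs + 1))
        cuts = np.sort(rng.choice(np.arange(1, chrom_len), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), chrom_len]
        segs = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if rng.random() < gap_prob:
                continue  # leave an uncovered hole
            segs.append(Segment("chr1", int(a), int(b), float(rng.normal())))
        if not segs:
            segs = [Segment("chr1", 0, chrom_len, float(rng.normal()))]
        profiles.append(SegmentedProfile(f"S{i}", segs))
    return profiles
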