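import numpy as np
import pytest

from enhancerkit import Config, CoverageTrack, Genome, Interval
from enhancerkit import simulate as sim


@pytest.fixture
def toy_genome():
    return Genome([("chrT", 10_000), ("chrU", 7_500)])


@pytest.fixture
def uniform_track(toy_genome):
    """Value 1.0 everywhere."""
    return CoverageTrack.from_segments(
        toy_genome, [(c, 0, L, 1.0) for c, L in toy_genome.chroms]
    )


def random_track(genome, rng, n_segments=50, max_value=10.0):
    """Random non-overlapping step-function track."""
    segments = []
    for chrom, L in genome.chroms:
        cuts = np.sort(rng.choice(L, size=min(2 * n_segments, L // 2), replace=False))
        for i in range(0, len(cuts) - 1, 2):
            if rng.random() < 0.7:
                segments.append((chrom, int(cuts[i]), int(cuts[i + 1]), float(np.round(rng.uniform(0, max_value), 4))))
    return CoverageTrack.from_segments(genome, segments)


def per_base_array(track, chrom):
    """Brute-force per-base expansion of a track on one chromosome."""
    arr = np.zeros(track.genome.length(chrom))
    for c, s, e, v in track.segments():
        if c == chrom:
            arr[s:e] = v
    return arr


def random_interval(genome, rng, max_width=None):
    chrom, L = genome.chroms[rng.integers(0, len(genome.chroms))]
    width = int(rng.integers(1, max_width or L // 4))
    start = int(rng.integers(0, L - width))
    return Interval(chrom, start, start + width)


@pytest.fixture(scope="session")
def bench():
    """One seed-1 simulation shared across tests: truth, tracks, peaks."""
    truth = sim.simulate_truth(seed=1)
    tracks = sim.simulate_tracks(truth, seed=1)
    peaks = sim.simulate_dhs_peaks(truth, seed=1)
    return truth, tracks, peaks


@pytest.fixture(scope="session")
def noise_free():
    """Noise-off simulation: signal shape assertions are exact."""
    truth = sim.simulate_truth(seed=3)
    tracks = sim.simulate_tracks(truth, snr=np.inf, seed=3)
    return truth, tracks
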