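import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cistrio as c

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_peaks(label, triples):
    """PeakSet from (chrom, start, end[, score]) tuples."""
    ivs = []
    for t in triples:
        chrom, start, end = t[:3]
        score = t[3] if len(t) > 3 else None
        ivs.append(c.GenomicInterval(chrom, start, end, score=score))
    return c.PeakSet(label, ivs)


def make_track(label, tags_by_chrom, total_mapped=None):
    return c.TagTrack(
        label,
        {k: np.asarray(v, dtype=np.int64) for k, v in tags_by_chrom.items()},
        total_mapped,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim():
    """A small full cistrome simulation shared across tests."""
    cfg = c.SimulationConfig(
        seed=5,
        genome=(("chr1", 20_000_000), ("chr2", 15_000_000)),
        n_latent_sites=3000,
        background_rate=0.01,
    )
    return cfg, c.simulate_cistromes(cfg)


def random_peakset(rng, n, label="rand", chroms=("chr1",), span=5000, max_len=300):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    chrom = rng.choice(chroms, size=n)
    return make_peaks(
        label, [(str(c_), int(s), int(s + l)) for c_, s, l in zip(chrom, starts, lengths)]
    )


def brute_force_overlap_count(a, b, min_bp=1):
    """O(n*m) all-pairs overlap oracle, independent of the sweep code."""
    count = 0
    b_rows = list(b.df.itertuples(index=False))
    for ra in a.df.itertuples(index=False):
        for rb in b_rows:
            if ra.chrom != rb.chrom:
                continue
            ov = min(ra.end, rb.end) - max(ra.start, rb.start)
            if ov >= min_bp:
                count += 1
                break
    return count
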