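import numpy as np
import pytest

from bvcrkit.genomic_io import GenomicInterval, Peak


class StubModel:
    """Predictor with a fixed answer (or per-call sequence of answers)."""

    def __init__(self, value=True, sequence=None):
        self.value = value
        self.sequence = sequence

    def predict(self, tiles):
        n = len(tiles)
        if self.sequence is not None:
            out, self.sequence = self.sequence[:n], self.sequence[n:]
            return np.asarray(out, dtype=bool)
        return np.full(n, self.value, dtype=bool)


def random_peaks(rng, n, chrom="c", genome_len=50_000, mark="other",
                 max_width=2_000):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, genome_len - max_width))
        width = int(rng.integers(1, max_width))
        tags = float(rng.integers(0, 200))
        peaks.append(Peak(GenomicInterval(chrom, start, start + width), mark,
                          raw_tags=tags, norm_tags=tags, score=tags))
    return peaks


def per_base_components(peaks, genome_len=None):
    """Brute-force oracle: quadratic pairwise >=1-bp-overlap graph, then
    union-find components. Touching-but-not-overlapping peaks stay apart,
    matching the zero-maximum-gap contract."""
    peaks = list(peaks)
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if peaks[i].interval.overlap_len(peaks[j].interval) >= 1:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    components = []
    for members in groups.values():
        start = min(p.interval.start for p in members)
        end = max(p.interval.end for p in members)
        components.append(((start, end), frozenset(members)))
    return components


def brute_count_overlaps(query, catalog, min_fraction=0.10):
    """Quadratic oracle for the fractional-overlap query count."""
    count = 0
    for q in query:
        qlen = q.end - q.start
        for c in catalog:
            if c.chrom != q.chrom:
                continue
            shared = min(q.end, c.end) - max(q.start, c.start)
            if shared >= min_fraction * qlen:
                count += 1
                break
    return count


def by_stepup_oracle(p):
    """Hand-rolled Benjamini–Yekutieli step-up, independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    adj = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


@pytest.fixture
def stub_model_factory():
    return StubModel
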