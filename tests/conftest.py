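"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from peakdiff.intervals import GenomicInterval, Peak, PeakSet, ReferenceRegions
from peakdiff.reads import CountMatrix


def make_peakset(label: str, triples) -> PeakSet:
    """PeakSet from (chrom, start, end) triples."""
    return PeakSet(label, [Peak(interval=GenomicInterval(c, s, e)) for c, s, e in triples])


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), span=2000):
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, span))
        e = s + int(rng.integers(1, 120))
        out.append((c, s, e))
    return out


def brute_force_merge(triples):
    """Union-find over all pairwise >=1-base overlaps; independent of the sweep."""
    n = len(triples)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = triples[i]
            cj, sj, ej = triples[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(triples[i])
    merged = sorted(
        (g[0][0], min(t[1] for t in g), max(t[2] for t in g)) for g in groups.values()
    )
    return merged


def brute_force_shared(a_triples, b_triples):
    """Per-peak shared flags for a vs b by quadratic scan."""
    flags = []
    for ca, sa, ea in a_triples:
        flags.append(
            any(ca == cb and sa < eb and sb < ea for cb, sb, eb in b_triples)
        )
    return np.asarray(flags, dtype=bool)


def small_count_matrix(counts, conditions, full_sizes=None, input_ids=None) -> CountMatrix:
    """CountMatrix on synthetic regions from a counts array and condition labels."""
    counts = np.asarray(counts)
    g, s = counts.shape
    regions = ReferenceRegions(
        [GenomicInterval("chrT", i * 1000, i * 1000 + 500) for i in range(g)]
    )
    if full_sizes is None:
        full_sizes = counts.sum(axis=0).astype(float)
    reps: dict[str, int] = {}
    sids = []
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        sids.append(f"{c}{reps[c]}")
    samples = pd.DataFrame(
        {
            "sample_id": sids,
            "condition": list(conditions),
            "replicate": [int(x[-1]) for x in sids],
            "full_library_size": np.asarray(full_sizes, dtype=float),
            "input_sample_id": input_ids if input_ids is not None else [None] * s,
        }
    )
    return CountMatrix(regions=regions, samples=samples, counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
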