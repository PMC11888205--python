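"""Shared fixtures and brute-force bp-bitmap oracles.

The oracles deliberately work at single-base resolution on small toy
genomes: they paint intervals onto a boolean array, dilate by the merge
gap, and read runs back off the bitmap. They share no code with the
package's sweep-line implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from enhancerkit.intervals import Interval, IntervalSet
from enhancerkit.simulate import SimulationConfig, simulate_to_dir


def bitmap_merge(intervals: list[Interval], gap: int,
                 chrom_len: int = 100_000) -> list[Interval]:
    """Merge-with-gap oracle: paint, bridge gaps <= gap, extract runs."""
    out: list[Interval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        covered = np.zeros(chrom_len, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                covered[iv.start:iv.end] = True
        # bridge gaps of length <= gap between covered runs
        runs = _runs(covered)
        bridged = []
        for s, e in runs:
            if bridged and s - bridged[-1][1] <= gap:
                bridged[-1] = (bridged[-1][0], e)
            else:
                bridged.append((s, e))
        out.extend(Interval(chrom, s, e) for s, e in bridged)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def bitmap_overlaps(a: Interval, b: Interval, chrom_len: int = 100_000) -> bool:
    """Overlap oracle via explicit bp-set intersection."""
    if a.chrom != b.chrom:
        return False
    sa = set(range(a.start, a.end))
    sb = set(range(b.start, b.end))
    return bool(sa & sb)


def brute_support(merged: IntervalSet,
                  sources: list[IntervalSet]) -> list[tuple[tuple[bool, ...], int]]:
    """Quadratic any-overlap support oracle."""
    out = []
    for iv in merged.intervals:
        flags = tuple(
            any(s.chrom == iv.chrom and s.start < iv.end and iv.start < s.end
                for s in src.intervals)
            for src in sources)
        out.append((flags, sum(flags)))
    return out


def brute_bh(pvals: np.ndarray) -> np.ndarray:
    """Direct step-up BH: adj_i = min_{j >= i} (m * p_(j) / rank_j), clipped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    best = np.inf
    for k in range(m - 1, -1, -1):
        i = order[k]
        best = min(best, m * pvals[i] / (k + 1))
        adj[i] = min(best, 1.0)
    return adj


def random_interval_set(rng: np.random.Generator, n: int, chrom_len: int,
                        chroms=("chrA",), max_width: int = 2000,
                        label: str = "rand") -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - max_width))
        width = int(rng.integers(1, max_width))
        ivs.append(Interval(chrom, start, start + width))
    return IntervalSet(label, ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast, moderately sized simulation shared by read-only tests."""
    return SimulationConfig(seed=11, n_cells=800, n_loops=5, n_genes=200)


@pytest.fixture(scope="session")
def sim_dir(small_cfg, tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    simulate_to_dir(small_cfg, d)
    return d
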