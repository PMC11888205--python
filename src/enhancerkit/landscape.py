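"""Enhancer, super-enhancer and consensus calling from histone-mark peaks.

A putative enhancer is a region carrying both H3K27ac and H3K4me1 marks in
the same sample ("double positive"). Super enhancers are clusters of
H3K27ac peaks stitched over a 12.5 kb merge distance whose combined span
strictly exceeds 15 kb — a purely geometric rule (no signal ranking).
Consensus sets are union-merged regions supported by peaks in at least a
required number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .intervals import (Interval, IntervalSet, _OverlapIndex, merge_with_gap,
                        support_counts)

logger = logging.getLogger(__name__)


@dataclass
class LandscapeConfig:
    """Geometric thresholds for super-enhancer and consensus calling.

    se_merge_gap: peaks at most this many bp apart are stitched (inclusive).
    se_min_size: stitched spans strictly larger than this are super enhancers.
    consensus_min_support: samples required for a consensus element;
        None means all samples.
    """

    se_merge_gap: int = 12500
    se_min_size: int = 15000
    consensus_min_support: int | None = None

    def __post_init__(self) -> None:
        if self.se_merge_gap < 0 or self.se_min_size <= 0:
            raise ValueError("se_merge_gap must be >= 0 and se_min_size > 0")
        if self.consensus_min_support is not None and self.consensus_min_support < 1:
            raise ValueError("consensus_min_support must be >= 1")


@dataclass
class EnhancerSet:
    """Double-positive enhancers for one sample, with per-element mark support."""

    sample_id: str
    elements: list[Interval] = field(default_factory=list)
    k27_support: list[bool] = field(default_factory=list)
    k4me1_support: list[bool] = field(default_factory=list)

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet(self.sample_id, list(self.elements))

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class SuperEnhancerSet:
    """Super enhancers for one sample, with stitched-peak counts."""

    sample_id: str
    elements: list[Interval] = field(default_factory=list)
    constituent_counts: list[int] = field(default_factory=list)

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet(self.sample_id, list(self.elements))

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class ConsensusSet:
    """Union-merged elements supported by >= min_support of the source sets."""

    source_labels: list[str]
    min_support: int
    elements: list[Interval] = field(default_factory=list)
    support: list[int] = field(default_factory=list)

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet("+".join(self.source_labels), list(self.elements))

    def __len__(self) -> int:
        return len(self.elements)


def call_double_positive(k27: IntervalSet, k4me1: IntervalSet,
                         sample_id: str | None = None) -> EnhancerSet:
    """Call putative enhancers as regions with overlapping H3K27ac and H3K4me1.

    The union of both peak sets is merged (gap 0); a merged region is an
    enhancer iff it overlaps at least one peak of each mark.
    """
    sample_id = sample_id or k27.label or k4me1.label
    if len(k27) == 0 or len(k4me1) == 0:
        logger.warning("sample %s: an input mark set is empty; no double-positive "
                       "enhancers can be called", sample_id)
        return EnhancerSet(sample_id)
    union = IntervalSet(sample_id, list(k27.intervals) + list(k4me1.intervals))
    merged = merge_with_gap(union, 0)
    out = EnhancerSet(sample_id)
    for iv, (has_k27, has_k4), _n in support_counts(merged, [k27, k4me1]):
        if has_k27 and has_k4:
            out.elements.append(iv)
            out.k27_support.append(True)
            out.k4me1_support.append(True)
    return out


def call_super_enhancers(k27: IntervalSet,
                         cfg: LandscapeConfig | None = None,
                         sample_id: str | None = None) -> SuperEnhancerSet:
    """Stitch H3K27ac peaks within ``se_merge_gap`` and keep spans > ``se_min_size``."""
    cfg = cfg or LandscapeConfig()
    merged, counts = merge_with_gap(k27, cfg.se_merge_gap, return_counts=True)
    out = SuperEnhancerSet(sample_id or k27.label)
    for iv, n in zip(merged.intervals, counts):
        if iv.length() > cfg.se_min_size:
            out.elements.append(iv)
            out.constituent_counts.append(n)
    return out


def consensus(sets: Sequence[IntervalSet | EnhancerSet],
              min_support: int | None = None) -> ConsensusSet:
    """Union-merge all sets and keep elements supported by >= min_support of them."""
    isets = [s.as_interval_set() if isinstance(s, EnhancerSet) else s for s in sets]
    if len(isets) < 2:
        raise ValueError("consensus requires at least two sets")
    if min_support is None:
        min_support = len(isets)
    if not (1 <= min_support <= len(isets)):
        raise ValueError(f"min_support must be in [1, {len(isets)}], got {min_support}")
    union = IntervalSet("union", [iv for s in isets for iv in s.intervals])
    merged = merge_with_gap(union, 0)
    out = ConsensusSet([s.label for s in isets], min_support)
    for iv, _flags, n in support_counts(merged, isets):
        if n >= min_support:
            out.elements.append(iv)
            out.support.append(n)
    return out


@dataclass
class SupportPartition:
    """Venn-style decomposition of a union peak set across samples.

    combination_counts: union intervals per supporting label combination.
    support_level_counts: union intervals per support count (1 = distinct,
        n_sets = common).
    fraction_common: per source set, the fraction of its own intervals
        overlapping full-consensus (all-sample) regions.
    fraction_at_least: per source set and support level k, the fraction of
        its own intervals overlapping union regions supported by >= k sets.
    """

    labels: list[str]
    combination_counts: dict[tuple[str, ...], int]
    support_level_counts: dict[int, int]
    fraction_common: dict[str, float]
    fraction_at_least: dict[str, dict[int, float]]


def support_partition(sets: Sequence[IntervalSet]) -> SupportPartition:
    """Decompose the union of the sets by which samples support each region."""
    if len(sets) < 2:
        raise ValueError("support_partition requires at least two sets")
    labels = [s.label for s in sets]
    union = IntervalSet("union", [iv for s in sets for iv in s.intervals])
    merged = merge_with_gap(union, 0)
    rows = support_counts(merged, sets)

    combo_counts: dict[tuple[str, ...], int] = {}
    level_counts: dict[int, int] = {}
    for _iv, flags, n in rows:
        combo = tuple(lab for lab, f in zip(labels, flags) if f)
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
        level_counts[n] = level_counts.get(n, 0) + 1

    frac_common: dict[str, float] = {}
    frac_at_least: dict[str, dict[int, float]] = {}
    for k in range(1, len(sets) + 1):
        regions = IntervalSet("consensus", [iv for iv, _f, n in rows if n >= k])
        idx = _OverlapIndex(regions.intervals)
        for s in sets:
            if len(s) == 0:
                frac = float("nan")
            else:
                frac = sum(idx.any_overlap(iv) for iv in s.intervals) / len(s)
            frac_at_least.setdefault(s.label, {})[k] = frac
            if k == len(sets):
                frac_common[s.label] = frac
    return SupportPartition(labels, combo_counts, level_counts, frac_common, frac_at_least)


def pairwise_shared_fractions(sets: Sequence[IntervalSet]) -> dict[tuple[str, str], float]:
    """For each ordered pair (a, b): fraction of a's intervals overlapping any of b's."""
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(sets, 2):
        ia, ib = _OverlapIndex(a.intervals), _OverlapIndex(b.intervals)
        if len(a):
            out[(a.label, b.label)] = sum(ib.any_overlap(iv) for iv in a.intervals) / len(a)
        if len(b):
            out[(b.label, a.label)] = sum(ia.any_overlap(iv) for iv in b.intervals) / len(b)
    return out
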