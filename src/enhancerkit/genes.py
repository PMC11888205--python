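"""Expression normalization and strata, enhancer-gene association, occupancy
colocalization, loop-scoped candidate selection, and activity correlation.

Expression strata follow the FPKM bins used for the myometrial landscape:
inactive (< 1), low ([1, 5)), mid ([5, 15)) and high (>= 15). Raw RNA-seq
counts are scaled per sample by the ratio of a reference sequencing depth
(56.5 million mapped read pairs) to the sample's own depth. Elements are
associated with every gene whose TSS lies within a fixed window (default
100 kb) of the element edge, on the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (Interval, IntervalSet, _OverlapIndex, distance_to_point,
                        read_bedpe)

logger = logging.getLogger(__name__)

REFERENCE_PAIRS = 56.5e6
STRATA = ("inactive", "low", "mid", "high")
STRATUM_BOUNDS = {"inactive": (0.0, 1.0), "low": (1.0, 5.0),
                  "mid": (5.0, 15.0), "high": (15.0, float("inf"))}


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS: id, chromosome, strand and start position."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: TSS must be >= 0")


@dataclass(frozen=True)
class Loop:
    """A cis chromatin contact: two anchors on one chromosome, anchor1 first."""

    anchor1: Interval
    anchor2: Interval

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must be cis (same chromosome)")
        if self.anchor1.start > self.anchor2.start:
            object.__setattr__(self, "anchor1", self.anchor2)
            object.__setattr__(self, "anchor2", self.anchor1)

    @property
    def span(self) -> Interval:
        return Interval(self.anchor1.chrom, self.anchor1.start, self.anchor2.end)


@dataclass(frozen=True)
class Association:
    """An element-gene link: the element, the gene, and the edge-to-TSS distance."""

    element: Interval
    gene_id: str
    distance: int


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from TSV.

    Accepts columns (gene_id, chrom, strand, tss) or spans
    (gene_id, chrom, strand, start, end); for spans the TSS is the start for
    '+' genes and ``end - 1`` for '-' genes. A precomputed tss column wins.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    if "tss" in cols:
        tss = df["tss"].astype(int)
    elif {"start", "end"} <= cols:
        tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1).astype(int)
    else:
        raise ValueError(f"{path}: need a 'tss' column or 'start'/'end' columns")
    return [GeneModel(str(g), str(c), str(s), int(t))
            for g, c, s, t in zip(df["gene_id"], df["chrom"], df["strand"], tss)]


def read_loops(path: str | Path) -> list[Loop]:
    """Read cis loops from BEDPE; trans pairs raise."""
    return [Loop(a, b) for a, b in read_bedpe(path)]


class ExpressionTable:
    """Gene x sample expression values (FPKM and/or normalized counts).

    The FPKM table drives stratum classification; the counts table drives
    the mean-normalized-count activity filter. Either may be absent.
    """

    def __init__(self, fpkm: pd.DataFrame | None = None,
                 counts: pd.DataFrame | None = None):
        if fpkm is None and counts is None:
            raise ValueError("ExpressionTable needs fpkm and/or counts")
        if fpkm is not None and (fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.fpkm = fpkm
        self.counts = counts

    @classmethod
    def from_tsv(cls, fpkm_path: str | Path | None = None,
                 counts_path: str | Path | None = None) -> "ExpressionTable":
        read = lambda p: pd.read_csv(p, sep="\t", index_col=0, comment="#")
        return cls(fpkm=read(fpkm_path) if fpkm_path else None,
                   counts=read(counts_path) if counts_path else None)

    def mean_fpkm(self) -> pd.Series:
        if self.fpkm is None:
            raise ValueError("no FPKM table loaded")
        return self.fpkm.mean(axis=1)

    def strata(self) -> pd.Series:
        """Per-gene stratum from the cross-sample mean FPKM."""
        return self.mean_fpkm().map(classify_stratum)


def normalize_counts(raw_counts: pd.DataFrame, total_pairs: pd.Series | dict,
                     reference: float = REFERENCE_PAIRS) -> pd.DataFrame:
    """Scale each sample's counts by reference_depth / sample_depth."""
    totals = pd.Series(total_pairs)
    missing = [c for c in raw_counts.columns if c not in totals.index]
    if missing:
        raise ValueError(f"no total mapped pairs for samples: {missing}")
    totals = totals.loc[list(raw_counts.columns)].astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"total mapped pairs must be positive; offending samples: {bad}")
    return raw_counts * (reference / totals)


def classify_stratum(fpkm: float) -> str:
    """Map an FPKM value to its expression stratum.

    < 1 inactive; [1, 5) low; [5, 15) mid; >= 15 high. The bin edges are
    inclusive on the left, so FPKM exactly 1 is active (low) and exactly 15
    is high.
    """
    if fpkm < 0 or not np.isfinite(fpkm):
        raise ValueError(f"FPKM must be finite and non-negative, got {fpkm}")
    if fpkm < 1:
        return "inactive"
    if fpkm < 5:
        return "low"
    if fpkm < 15:
        return "mid"
    return "high"


def filter_active_genes(expr: ExpressionTable, mode: str = "fpkm",
                        sample: str | None = None) -> list[str]:
    """Active-gene filter.

    ``fpkm`` mode keeps genes with FPKM >= 1 (inclusive) — in the named
    ``sample`` if given, else in the cross-sample mean. ``mean_count`` mode
    keeps genes with cross-sample mean normalized count strictly > 1.
    Genes with missing values are dropped with a log entry.
    """
    if mode == "fpkm":
        if expr.fpkm is None:
            raise ValueError("fpkm mode requires an FPKM table")
        table = expr.fpkm if sample is None else expr.fpkm[[sample]]
    elif mode == "mean_count":
        if expr.counts is None:
            raise ValueError("mean_count mode requires a counts table")
        table = expr.counts
    else:
        raise ValueError(f"unknown mode {mode!r}")
    has_na = table.isna().any(axis=1)
    if has_na.any():
        logger.info("dropping %d genes with missing values", int(has_na.sum()))
        table = table.loc[~has_na]
    means = table.mean(axis=1)
    keep = means >= 1 if mode == "fpkm" else means > 1
    return list(table.index[keep])


def associate_elements_to_genes(elements: IntervalSet, genes: Sequence[GeneModel],
                                window: int = 100_000) -> list[Association]:
    """All (element, gene) pairs with edge-to-TSS distance <= window, same chrom.

    Every qualifying gene is reported, not only the nearest.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.tss)
    import bisect
    out: list[Association] = []
    for iv in elements.intervals:
        lst = by_chrom.get(iv.chrom, [])
        tss_list = [g.tss for g in lst]
        lo = bisect.bisect_left(tss_list, iv.start - window)
        hi = bisect.bisect_right(tss_list, iv.end - 1 + window)
        for g in lst[lo:hi]:
            d = distance_to_point(iv, g.tss)
            if d <= window:
                out.append(Association(iv, g.gene_id, d))
    return out


def stratum_association_fractions(elements: IntervalSet,
                                  associations: Sequence[Association],
                                  strata: pd.Series | dict) -> dict[str, float]:
    """Per stratum: fraction of elements with >= 1 associated gene in that stratum.

    An element near both a high and a low gene counts in both strata.
    """
    n = len(elements)
    if n == 0:
        raise ValueError("no elements")
    strata = pd.Series(strata)
    hit: dict[str, set[Interval]] = {s: set() for s in STRATA}
    for assoc in associations:
        s = strata.get(assoc.gene_id)
        if s is None:
            logger.info("gene %s has no stratum; association skipped", assoc.gene_id)
            continue
        hit[s].add(assoc.element)
    return {s: len(hit[s]) / n for s in STRATA}


def colocalization_fraction(elements: IntervalSet, occupancy: IntervalSet) -> float:
    """Percentage of elements overlapping >= 1 TF-occupancy interval."""
    if len(elements) == 0:
        raise ValueError("no elements")
    idx = _OverlapIndex(occupancy.intervals)
    return 100.0 * sum(idx.any_overlap(iv) for iv in elements.intervals) / len(elements)


def loop_candidates(loops: Sequence[Loop], gene: GeneModel,
                    peaks: IntervalSet) -> tuple[list[Loop], IntervalSet]:
    """Candidate cis-elements for a gene: peaks inside loops anchored at its TSS.

    A loop is selected iff the gene's TSS falls within either anchor;
    candidates are all peaks overlapping a selected loop's full span
    (anchor1 start to anchor2 end).
    """
    selected = [lp for lp in loops
                if lp.anchor1.chrom == gene.chrom
                and (lp.anchor1.start <= gene.tss < lp.anchor1.end
                     or lp.anchor2.start <= gene.tss < lp.anchor2.end)]
    if not selected:
        logger.info("no loop has an anchor on the TSS of %s", gene.gene_id)
        return [], IntervalSet(f"{gene.gene_id}_candidates")
    span_idx = _OverlapIndex([lp.span for lp in selected])
    cands = [iv for iv in peaks.intervals if span_idx.any_overlap(iv)]
    return selected, IntervalSet(f"{gene.gene_id}_candidates", cands)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    return float(stats.pearsonr(x, y).statistic)


def read_activity_scores(path: str | Path) -> pd.Series:
    """Read per-specimen inferred activity scores (e.g. T-scores) from TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    s = pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))
    if not np.isfinite(s.values).all():
        raise ValueError(f"{path}: activity scores must be finite")
    return s
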