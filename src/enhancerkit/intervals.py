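"""Genomic coordinate model, BED/BEDPE I/O and interval algebra.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` base pairs. "Overlap" always means
at least one shared base pair; book-ended intervals ([0,10) vs [10,20)) do
not overlap. ``merge_with_gap`` copies the semantics of ``bedtools merge
-d``: two intervals on the same chromosome are stitched when the distance
``next.start - prev.end`` between them is at most ``gap`` (so ``gap=0``
merges overlapping and book-ended intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


class Interval(NamedTuple):
    """A genomic interval: chromosome, 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int

    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> "Interval":
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end} "
                             "(need 0 <= start < end)")
        return self


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths; the coordinate frame for a simulation or dataset."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass
class IntervalSet:
    """A labelled collection of intervals (one sample's peaks, one mark, one dataset).

    ``extras`` optionally carries unparsed BED columns 4+ aligned with
    ``intervals``; it is preserved by I/O but dropped by any operation that
    changes interval identity (normalize, merge).
    """

    label: str = ""
    intervals: list[Interval] = field(default_factory=list)
    extras: list[tuple[str, ...]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "IntervalSet":
        order = sorted(range(len(self.intervals)),
                       key=lambda i: (self.intervals[i].chrom, self.intervals[i].start,
                                      self.intervals[i].end))
        extras = [self.extras[i] for i in order] if self.extras is not None else None
        return IntervalSet(self.label, [self.intervals[i] for i in order], extras)

    def normalize(self) -> "IntervalSet":
        """Sorted, pairwise non-overlapping representation (merge at gap 0)."""
        return merge_with_gap(self, 0)

    def is_normalized(self) -> bool:
        prev: Interval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start < prev.end or (prev.start, prev.end) > (iv.start, iv.end):
                    return False
            elif prev is not None and prev.chrom > iv.chrom:
                return False
            prev = iv
        return True

    def total_bp(self) -> int:
        return sum(iv.length() for iv in self.normalize())


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def distance_to_point(iv: Interval, pos: int) -> int:
    """bp distance from an interval to a genomic position on the same chromosome.

    0 if the position falls inside the interval; otherwise the distance to
    the nearest covered base (``end - 1`` is the last covered base).
    """
    if pos < 0:
        raise ValueError("position must be non-negative")
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - (iv.end - 1)), abs(pos - iv.start))


def merge_with_gap(s: IntervalSet, gap: int,
                   return_counts: bool = False) -> IntervalSet | tuple[IntervalSet, list[int]]:
    """Stitch intervals separated by at most ``gap`` bp (``bedtools merge -d`` semantics).

    Input need not be sorted. Output is sorted by (chrom, start) and pairwise
    non-overlapping. With ``return_counts`` also returns, per output interval,
    the number of input intervals stitched into it.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    ivs = sorted(s.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    counts: list[int] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
            counts[-1] += 1
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
            counts.append(1)
    out = IntervalSet(s.label, merged)
    if return_counts:
        return out, counts
    return out


class _OverlapIndex:
    """Per-chromosome sorted starts with running max end, for any-overlap queries."""

    def __init__(self, ivs: Iterable[Interval]):
        by_chrom: dict[str, list[Interval]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._cummax_end: dict[str, list[int]] = {}
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda iv: (iv.start, iv.end))
            self._starts[chrom] = [iv.start for iv in lst]
            cm, m = [], 0
            for iv in lst:
                m = max(m, iv.end)
                cm.append(m)
            self._cummax_end[chrom] = cm

    def any_overlap(self, query: Interval) -> bool:
        import bisect
        starts = self._starts.get(query.chrom)
        if not starts:
            return False
        i = bisect.bisect_left(starts, query.end)  # intervals with start < query.end
        return i > 0 and self._cummax_end[query.chrom][i - 1] > query.start


def support_counts(merged: IntervalSet,
                   sources: Sequence[IntervalSet]) -> list[tuple[Interval, tuple[bool, ...], int]]:
    """Per merged interval: which sources overlap it, and how many.

    A source supports a merged interval iff at least one of its intervals
    shares >= 1 bp with it.
    """
    if not sources:
        raise ValueError("support_counts requires at least one source set")
    indexes = [_OverlapIndex(src.intervals) for src in sources]
    out = []
    for iv in merged.intervals:
        flags = tuple(idx.any_overlap(iv) for idx in indexes)
        out.append((iv, flags, sum(flags)))
    return out


# ---------------------------------------------------------------------------
# BED / BEDPE I/O
# ---------------------------------------------------------------------------

def _strip_prefix(chrom: str, chrom_prefix: str | None) -> str:
    if chrom_prefix == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    if chrom_prefix == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def read_bed(path: str | Path, layout: GenomeLayout | None = None, *,
             label: str | None = None, out_of_bounds: str = "error",
             chrom_prefix: str | None = None) -> IntervalSet:
    """Read a BED3+ file into an IntervalSet.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped. Columns
    beyond the third are preserved in ``extras``. With a ``layout``,
    intervals beyond the chromosome end either raise (default) or are
    dropped with a log entry (``out_of_bounds="drop"``). ``chrom_prefix``
    may be ``"strip"`` or ``"add"`` to harmonise ``chr`` naming.
    """
    path = Path(path)
    intervals: list[Interval] = []
    extras: list[tuple[str, ...]] = []
    any_extra = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = _strip_prefix(fields[0], chrom_prefix)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            if layout is not None:
                if chrom not in layout:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > layout.length_of(chrom):
                    if out_of_bounds == "drop":
                        logger.warning("%s:%d: interval %s:%d-%d beyond chromosome end; dropped",
                                       path, lineno, chrom, start, end)
                        continue
                    raise ValueError(f"{path}:{lineno}: interval beyond chromosome end")
            intervals.append(Interval(chrom, start, end))
            extras.append(tuple(fields[3:]))
            any_extra = any_extra or len(fields) > 3
    return IntervalSet(label if label is not None else path.stem,
                       intervals, extras if any_extra else None)


def write_bed(s: IntervalSet, path: str | Path,
              extra_columns: Sequence[Sequence] | None = None) -> None:
    """Write an IntervalSet as BED (tab-separated, no header).

    ``extra_columns`` (aligned with intervals) or the set's own ``extras``
    are appended after the three coordinate fields.
    """
    cols = extra_columns if extra_columns is not None else s.extras
    with open(path, "w") as fh:
        for i, iv in enumerate(s.intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if cols is not None:
                fields.extend(str(x) for x in cols[i])
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path: str | Path) -> list[tuple[Interval, Interval]]:
    """Read a BEDPE file into (anchor1, anchor2) interval pairs.

    Six coordinate fields per line; extra columns ignored. Comment/track
    lines are skipped.
    """
    path = Path(path)
    pairs: list[tuple[Interval, Interval]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 tab-separated fields")
            try:
                a = Interval(f[0], int(f[1]), int(f[2])).validate()
                b = Interval(f[3], int(f[4]), int(f[5])).validate()
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            pairs.append((a, b))
    return pairs


def write_bedpe(pairs: Sequence[tuple[Interval, Interval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")
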