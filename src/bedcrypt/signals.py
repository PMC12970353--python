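"""Interval model and the per-chromosome signal arrays.

The database track is reduced to four integer arrays per chromosome so every
supported query becomes a handful of point reads:

* ``P_cov``  (length L+1): exclusive prefix sum of the binary coverage
  indicator; covered bases of [s, e) = P_cov[e] - P_cov[s].
* ``P_start`` (length L+1): number of intervals with start < x.
* ``P_end``  (length L+1): number of intervals with end <= x.  With half-open
  intervals, #{j : s_j < e and e_j > s} = P_start[e] - P_end[s].
* ``D``      (length L): per-base depth.

Start/end indicators accumulate counts at duplicated boundaries so overlap
counting stays exact for duplicated intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BedParseError

SEGMENT_ORDER = ("S1", "S2", "S3", "S4")
SEGMENT_ARRAYS = {"S1": "p_cov", "S2": "p_start", "S3": "p_end", "S4": "depth"}


@dataclass(frozen=True)
class Interval:
    """0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Ordered chromosome names with lengths (bases)."""

    lengths: dict[str, int]

    def __post_init__(self):
        for name, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise BedParseError("genome file needs 'chrom<TAB>length'",
                                        lineno)
                try:
                    lengths[parts[0]] = int(parts[1])
                except ValueError:
                    raise BedParseError(f"bad length {parts[1]!r}", lineno) from None
        return cls(lengths)

    def to_file(self, path: str | Path):
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class IntervalSet:
    intervals: list[Interval] = field(default_factory=list)
    sorted: bool = False
    merged: bool = False

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def write_bed(self, path: str | Path):
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def parse_bed(path: str | Path, layout: GenomeLayout) -> IntervalSet:
    """Parse a BED file (>=3 tab-separated columns) against a genome layout.

    Extra columns are ignored; ``track``/``browser``/comment/blank lines are
    skipped.  Zero-length intervals are rejected: coverage fractions and
    overlap semantics are undefined for them.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            if stripped.startswith(("#", "track", "browser")):
                continue
            parts = stripped.split("\t")
            if len(parts) < 3:
                raise BedParseError(
                    f"expected >=3 tab-separated columns, got {len(parts)}", lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"non-integer coordinates {parts[1]!r}/{parts[2]!r}",
                    lineno) from None
            if chrom not in layout:
                raise BedParseError(f"unknown chromosome {chrom!r}", lineno)
            if start < 0:
                raise BedParseError(f"negative start {start}", lineno)
            if start == end:
                raise BedParseError(
                    f"zero-length interval {chrom}:{start}-{end}", lineno)
            if start > end:
                raise BedParseError(f"start {start} >= end {end}", lineno)
            if end > layout[chrom]:
                raise BedParseError(
                    f"end {end} exceeds length of {chrom} ({layout[chrom]})", lineno)
            intervals.append(Interval(chrom, start, end))
    return IntervalSet(intervals)


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Sort and merge; touching intervals ([0,1),[1,2)) coalesce."""
    by_chrom = s.by_chrom()
    out: list[Interval] = []
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = None, None
        for iv in ivs:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(Interval(chrom, cur_s, cur_e))
    return IntervalSet(out, sorted=True, merged=True)


@dataclass
class SignalArrays:
    """The four derived arrays for every chromosome in the layout."""

    layout: GenomeLayout
    p_cov: dict[str, np.ndarray]
    p_start: dict[str, np.ndarray]
    p_end: dict[str, np.ndarray]
    depth: dict[str, np.ndarray]
    n_intervals: int

    def segment(self, seg: str, chrom: str) -> np.ndarray:
        return getattr(self, SEGMENT_ARRAYS[seg])[chrom]

    def segment_length(self, seg: str, chrom: str) -> int:
        L = self.layout[chrom]
        return L if seg == "S4" else L + 1

    def max_value(self) -> int:
        mx = 0
        for chrom in self.layout.chroms:
            for seg in SEGMENT_ORDER:
                arr = self.segment(seg, chrom)
                if arr.size:
                    mx = max(mx, int(arr.max()))
        return mx


def build_signals(b: IntervalSet, layout: GenomeLayout) -> SignalArrays:
    by_chrom = b.by_chrom()
    p_cov, p_start, p_end, depth = {}, {}, {}, {}
    for chrom in layout.chroms:
        L = layout[chrom]
        ivs = by_chrom.get(chrom, [])
        starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64,
                             count=len(ivs))
        ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
        delta = np.zeros(L + 1, dtype=np.int64)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        d = np.cumsum(delta[:L])
        depth[chrom] = d
        cov = (d > 0).astype(np.int64)
        p_cov[chrom] = np.concatenate([[0], np.cumsum(cov)])
        start_cnt = np.bincount(starts, minlength=L)
        p_start[chrom] = np.concatenate([[0], np.cumsum(start_cnt[:L])])
        end_cnt = np.bincount(ends, minlength=L + 1)
        p_end[chrom] = np.cumsum(end_cnt[:L + 1])
    return SignalArrays(layout, p_cov, p_start, p_end, depth, len(b))
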