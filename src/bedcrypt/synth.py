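"""Seeded synthetic BED generation and the naive plaintext oracle.

The oracle is the independent ground truth for every operation: it works
per base and per interval pair, with no prefix sums and no code shared with
the production signal/compiler modules.  Keep it that way — its value is
exactly its independence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .signals import GenomeLayout, Interval, IntervalSet


@dataclass
class SynthConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000})
    n_intervals: int = 100
    #: ("uniform", min_len, max_len) or ("geometric", mean_len)
    length_dist: tuple = ("uniform", 10, 100)

    def __post_init__(self):
        for name, L in self.chrom_lengths.items():
            if L < 1:
                raise ConfigError(f"chromosome {name} length must be >= 1")
            if self._mean_length() >= L:
                raise ConfigError(
                    f"mean interval length {self._mean_length()} >= L({name})={L}")
        if self.n_intervals < 0:
            raise ConfigError("n_intervals must be >= 0")

    def _mean_length(self) -> float:
        if self.length_dist[0] == "uniform":
            return (self.length_dist[1] + self.length_dist[2]) / 2
        if self.length_dist[0] == "geometric":
            return float(self.length_dist[1])
        raise ConfigError(f"unknown length distribution {self.length_dist[0]!r}")


def generate_bed(cfg: SynthConfig) -> IntervalSet:
    """Deterministic given the seed; intervals clipped to [0, L); sorted."""
    rng = random.Random(cfg.seed)
    chroms = list(cfg.chrom_lengths)
    intervals = []
    for _ in range(cfg.n_intervals):
        chrom = chroms[rng.randrange(len(chroms))]
        L = cfg.chrom_lengths[chrom]
        if cfg.length_dist[0] == "uniform":
            length = rng.randint(cfg.length_dist[1], cfg.length_dist[2])
        else:
            length = 1 + int(rng.expovariate(1.0 / max(1, cfg.length_dist[1] - 1)))
        length = max(1, min(length, L))
        start = rng.randrange(L - length + 1)
        intervals.append(Interval(chrom, start, start + length))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return IntervalSet(intervals, sorted=True)


def layout_of(cfg: SynthConfig) -> GenomeLayout:
    return GenomeLayout(dict(cfg.chrom_lengths))


# -------------------------------------------------------------------- oracle

def _coverage_mask(intervals, L: int) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    for iv in intervals:
        mask[iv.start:iv.end] = True
    return mask


def _overlaps(a: Interval, b: Interval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def oracle_coverage(a: IntervalSet, b: IntervalSet, layout: GenomeLayout):
    """Rows of (chrom, start, end, overlap count, covered bases, length,
    fraction), one per A interval, by pairwise tests and per-base scans."""
    masks = {c: _coverage_mask([iv for iv in b if iv.chrom == c], layout[c])
             for c in layout.chroms}
    rows = []
    for qa in a:
        count = sum(1 for qb in b if _overlaps(qa, qb))
        covered = int(masks[qa.chrom][qa.start:qa.end].sum())
        rows.append((qa.chrom, qa.start, qa.end, count, covered, qa.length,
                     covered / qa.length))
    return rows


def oracle_intersect(a: IntervalSet, b: IntervalSet, mode: str):
    out = []
    for qa in a:
        hit = any(_overlaps(qa, qb) for qb in b)
        if (mode == "u" and hit) or (mode == "v" and not hit):
            out.append((qa.chrom, qa.start, qa.end))
    return out


def oracle_window(a: IntervalSet, b: IntervalSet, layout: GenomeLayout,
                  w: int, mode: str):
    out = []
    for qa in a:
        ex = Interval(qa.chrom, max(0, qa.start - w),
                      min(layout[qa.chrom], qa.end + w))
        count = sum(1 for qb in b if _overlaps(ex, qb))
        if mode == "c":
            out.append((qa.chrom, qa.start, qa.end, count))
        elif (mode == "u" and count > 0) or (mode == "v" and count == 0):
            out.append((qa.chrom, qa.start, qa.end))
    return out


def oracle_depth(a: IntervalSet, b: IntervalSet, layout: GenomeLayout):
    """(chrom, pos, depth) per base of each A interval, interval-major."""
    rows = []
    for qa in a:
        for x in range(qa.start, qa.end):
            d = sum(1 for qb in b if qb.chrom == qa.chrom and qb.start <= x < qb.end)
            rows.append((qa.chrom, x, d))
    return rows


def oracle_jaccard(a: IntervalSet, b: IntervalSet, layout: GenomeLayout):
    inter = union = 0
    for c in layout.chroms:
        ma = _coverage_mask([iv for iv in a if iv.chrom == c], layout[c])
        mb = _coverage_mask([iv for iv in b if iv.chrom == c], layout[c])
        inter += int((ma & mb).sum())
        union += int((ma | mb).sum())
    return inter, union, (0.0 if union == 0 else inter / union)


def oracle(op: str, a: IntervalSet, b: IntervalSet, layout: GenomeLayout,
           w: int = 0, mode: str = "none"):
    if op == "coverage":
        return oracle_coverage(a, b, layout)
    if op == "intersect":
        return oracle_intersect(a, b, mode)
    if op == "window":
        return oracle_window(a, b, layout, w, mode)
    if op == "depth":
        return oracle_depth(a, b, layout)
    if op == "jaccard":
        return oracle_jaccard(a, b, layout)
    raise ValueError(f"unknown op {op!r}")


# ------------------------------------------------------------------ fixture

def make_fixture(name: str = "worked"):
    """The worked two-interval fixture with oracle-computed expectations."""
    if name != "worked":
        raise ValueError(f"unknown fixture {name!r}")
    layout = GenomeLayout({"chr1": 10})
    b = IntervalSet([Interval("chr1", 2, 5), Interval("chr1", 4, 8)])
    a = IntervalSet([Interval("chr1", 3, 6), Interval("chr1", 0, 1),
                     Interval("chr1", 8, 10)])
    expected = {
        "coverage": oracle_coverage(a, b, layout),
        "intersect_u": oracle_intersect(a, b, "u"),
        "intersect_v": oracle_intersect(a, b, "v"),
        "window_c_w2": oracle_window(a, b, layout, 2, "c"),
        "depth": oracle_depth(a, b, layout),
        "jaccard": oracle_jaccard(a, b, layout),
    }
    return a, b, layout, expected
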