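"""Query compilation: lower an operation over query set A into an ordered
list of logical scalar reads, then into server selectors.

Read counts per operation (the plan-size law):

=========  =======================================
coverage   4 * |A|      (S1@s, S1@e, S2@e, S3@s)
intersect  2 * |A|      (S2@e, S3@s)
window     2 * |A|      on the expanded intervals
depth      sum of interval lengths (one S4 read per base)
jaccard    2 * |merged A| + one S1@L per chromosome
=========  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .dbstore import LayoutManifest, PermutationMap, Selector, logical_to_selector
from .errors import PlanSizeError, QuerySpecError
from .signals import GenomeLayout, Interval, IntervalSet, merge_intervals

OPS = ("coverage", "intersect", "window", "depth", "jaccard")
_VALID_MODES = {
    "coverage": {"none"},
    "intersect": {"u", "v"},
    "window": {"c", "u", "v"},
    "depth": {"none"},
    "jaccard": {"none"},
}

DEFAULT_DEPTH_CAP = 1_000_000


@dataclass(frozen=True)
class QuerySpec:
    op: str
    a: IntervalSet
    mode: str = "none"
    window_margin: int = 0

    def __post_init__(self):
        if self.op not in OPS:
            raise QuerySpecError(f"unknown operation {self.op!r}")
        if self.mode not in _VALID_MODES[self.op]:
            raise QuerySpecError(
                f"mode {self.mode!r} not valid for {self.op} "
                f"(allowed: {sorted(_VALID_MODES[self.op])})")
        if self.window_margin < 0:
            raise QuerySpecError("window margin must be >= 0")


class LogicalRead(NamedTuple):
    segment: str
    chrom: str
    coordinate: int
    tag: tuple  # (interval index, role)


@dataclass
class QueryPlan:
    spec: QuerySpec
    reads: list[LogicalRead]
    epoch: int = 0
    #: original (unexpanded) A intervals, indexed by tag interval index
    intervals: list[Interval] = field(default_factory=list)
    #: merged intervals (jaccard only)
    merged: list[Interval] = field(default_factory=list)
    unique_reads: list[LogicalRead] | None = None
    fanout: list[int] | None = None  # position in unique_reads per read


def compile_plan(spec: QuerySpec, layout: GenomeLayout,
                 depth_cap: int = DEFAULT_DEPTH_CAP) -> QueryPlan:
    if len(spec.a) == 0:
        raise QuerySpecError("empty query set A: nothing to compile")
    for iv in spec.a:
        if iv.chrom not in layout:
            raise QuerySpecError(f"query chromosome {iv.chrom!r} not in layout")
        if iv.end > layout[iv.chrom]:
            raise QuerySpecError(
                f"query interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {layout[iv.chrom]}")
    if spec.op == "coverage":
        return _compile_coverage(spec, layout)
    if spec.op == "intersect":
        return _compile_intersect_window(spec, layout, window=0)
    if spec.op == "window":
        return _compile_intersect_window(spec, layout, window=spec.window_margin)
    if spec.op == "depth":
        return _compile_depth(spec, layout, depth_cap)
    return _compile_jaccard(spec, layout)


def _compile_coverage(spec: QuerySpec, layout: GenomeLayout) -> QueryPlan:
    reads = []
    ivs = list(spec.a)
    for i, iv in enumerate(ivs):
        reads.append(LogicalRead("S1", iv.chrom, iv.start, (i, "Pcov@s")))
        reads.append(LogicalRead("S1", iv.chrom, iv.end, (i, "Pcov@e")))
        reads.append(LogicalRead("S2", iv.chrom, iv.end, (i, "Pstart@e")))
        reads.append(LogicalRead("S3", iv.chrom, iv.start, (i, "Pend@s")))
    return QueryPlan(spec, reads, intervals=ivs)


def _compile_intersect_window(spec: QuerySpec, layout: GenomeLayout,
                              window: int) -> QueryPlan:
    reads = []
    ivs = list(spec.a)
    for i, iv in enumerate(ivs):
        s = max(0, iv.start - window)
        e = min(layout[iv.chrom], iv.end + window)
        reads.append(LogicalRead("S2", iv.chrom, e, (i, "Pstart@e")))
        reads.append(LogicalRead("S3", iv.chrom, s, (i, "Pend@s")))
    return QueryPlan(spec, reads, intervals=ivs)


def _compile_depth(spec: QuerySpec, layout: GenomeLayout,
                   depth_cap: int) -> QueryPlan:
    total = spec.a.total_length()
    if total > depth_cap:
        raise PlanSizeError(
            f"depth plan would need {total} reads, above the cap {depth_cap}")
    reads = []
    ivs = list(spec.a)
    for i, iv in enumerate(ivs):
        for x in range(iv.start, iv.end):
            reads.append(LogicalRead("S4", iv.chrom, x, (i, f"D@{x}")))
    return QueryPlan(spec, reads, intervals=ivs)


def _compile_jaccard(spec: QuerySpec, layout: GenomeLayout) -> QueryPlan:
    merged = merge_intervals(spec.a)
    reads = []
    for i, iv in enumerate(merged):
        reads.append(LogicalRead("S1", iv.chrom, iv.start, (i, "Pcov@s")))
        reads.append(LogicalRead("S1", iv.chrom, iv.end, (i, "Pcov@e")))
    for j, chrom in enumerate(layout.chroms):
        reads.append(LogicalRead("S1", chrom, layout[chrom], (-1 - j, "Pcov@L")))
    return QueryPlan(spec, reads, intervals=list(spec.a),
                     merged=list(merged))


def dedupe(plan: QueryPlan, enabled: bool = True) -> QueryPlan:
    """Collapse duplicate (segment, chrom, coordinate) reads.

    Unique reads keep first-occurrence order; ``fanout[i]`` maps read i of
    the full plan to its position in the unique list, so the original
    ordered scalar stream is reproducible exactly.  Deduplication reveals
    read-multiplicity structure to no one (it only shrinks the request), but
    it is configurable off to keep request shape independent of content.
    """
    if not enabled:
        plan.unique_reads = None
        plan.fanout = None
        return plan
    seen: dict[tuple, int] = {}
    unique: list[LogicalRead] = []
    fanout: list[int] = []
    for r in plan.reads:
        key = (r.segment, r.chrom, r.coordinate)
        if key not in seen:
            seen[key] = len(unique)
            unique.append(r)
        fanout.append(seen[key])
    plan.unique_reads = unique
    plan.fanout = fanout
    return plan


def plan_to_selectors(plan: QueryPlan, manifest: LayoutManifest,
                      perm: PermutationMap) -> list[Selector]:
    """Translate the (deduplicated) plan into server selectors."""
    plan.epoch = manifest.epoch
    reads = plan.unique_reads if plan.unique_reads is not None else plan.reads
    return [logical_to_selector(manifest, perm, r.segment, r.chrom,
                                r.coordinate, ordinal)
            for ordinal, r in enumerate(reads)]


def expand_scalars(plan: QueryPlan, unique_scalars: list[int]) -> list[int]:
    """Fan deduplicated scalars back out to the full ordered read stream."""
    if plan.fanout is None:
        return list(unique_scalars)
    return [unique_scalars[j] for j in plan.fanout]
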