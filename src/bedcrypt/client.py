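"""Client orchestration: compile, extract, decrypt, reassemble, format.

``run_query`` drives the full three-stage workflow against any transport and
returns typed rows; ``format_output`` renders them in bedtools-style TSV
dialects (documented in the README: coverage mirrors ``bedtools coverage``
column order, window/intersect emit the original A interval plus a count for
``-c``, depth uses a local ``chrom pos depth`` dialect, jaccard mirrors the
``bedtools jaccard`` header minus ``n_intersections``).
"""

from __future__ import annotations

import resource
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .compiler import (QueryPlan, QuerySpec, compile_plan, dedupe,
                       expand_scalars, plan_to_selectors, DEFAULT_DEPTH_CAP)
from .dbstore import LayoutManifest, PermutationMap
from .errors import CorruptionError, ProtocolError, StalePlanError
from .he import HEBackend, KeyMaterial
from .server import ExtractionRequest
from .signals import GenomeLayout, Interval


@dataclass(frozen=True)
class CoverageRow:
    chrom: str
    start: int
    end: int
    overlap_count: int
    covered_bases: int
    interval_length: int
    fraction: float


@dataclass(frozen=True)
class DepthRow:
    chrom: str
    pos: int
    depth: int


@dataclass(frozen=True)
class JaccardResult:
    intersection_bases: int
    union_bases: int
    jaccard: float


@dataclass(frozen=True)
class AnnotatedInterval:
    chrom: str
    start: int
    end: int
    count: int | None = None  # populated for -c


# ------------------------------------------------------------ reconstruction

def reconstruct_coverage(plan: QueryPlan, scalars: list[int]) -> list[CoverageRow]:
    _expect(len(scalars), 4 * len(plan.intervals))
    rows = []
    for i, iv in enumerate(plan.intervals):
        pcov_s, pcov_e, pstart_e, pend_s = scalars[4 * i:4 * i + 4]
        covered = pcov_e - pcov_s
        count = pstart_e - pend_s
        if not 0 <= covered <= iv.length or count < 0:
            raise CorruptionError(
                f"impossible coverage reconstruction for {iv.chrom}:"
                f"{iv.start}-{iv.end}: covered={covered}, count={count}")
        rows.append(CoverageRow(iv.chrom, iv.start, iv.end, count, covered,
                                iv.length, covered / iv.length))
    return rows


def reconstruct_intersect_window(plan: QueryPlan,
                                 scalars: list[int]) -> list[AnnotatedInterval]:
    _expect(len(scalars), 2 * len(plan.intervals))
    mode = plan.spec.mode
    out = []
    for i, iv in enumerate(plan.intervals):
        pstart_e, pend_s = scalars[2 * i:2 * i + 2]
        count = pstart_e - pend_s
        if count < 0:
            raise CorruptionError("negative overlap count")
        if mode == "c":
            out.append(AnnotatedInterval(iv.chrom, iv.start, iv.end, count))
        elif mode == "u" and count > 0:
            out.append(AnnotatedInterval(iv.chrom, iv.start, iv.end))
        elif mode == "v" and count == 0:
            out.append(AnnotatedInterval(iv.chrom, iv.start, iv.end))
    return out


def reconstruct_depth(plan: QueryPlan, scalars: list[int]) -> list[DepthRow]:
    _expect(len(scalars), len(plan.reads))
    return [DepthRow(r.chrom, r.coordinate, int(v))
            for r, v in zip(plan.reads, scalars)]


def reconstruct_jaccard(plan: QueryPlan, scalars: list[int]) -> JaccardResult:
    n_merged = len(plan.merged)
    _expect(len(scalars), len(plan.reads))
    intersection = 0
    for i in range(n_merged):
        lo, hi = scalars[2 * i], scalars[2 * i + 1]
        if hi < lo:
            raise CorruptionError("decreasing coverage prefix")
        intersection += hi - lo
    b_total = sum(scalars[2 * n_merged:])
    a_total = sum(iv.length for iv in plan.merged)
    union = a_total + b_total - intersection
    return JaccardResult(intersection, union,
                         0.0 if union == 0 else intersection / union)


def _expect(got: int, want: int):
    if got != want:
        raise ProtocolError(f"scalar stream length {got}, expected {want}")


# ------------------------------------------------------------------ runner

def run_query(spec: QuerySpec, layout: GenomeLayout, manifest: LayoutManifest,
              perm: PermutationMap, transport, keys: KeyMaterial,
              backend: HEBackend, dedupe_enabled: bool = True,
              depth_cap: int = DEFAULT_DEPTH_CAP):
    """Compile -> extract -> decrypt -> reassemble.  Returns typed rows."""
    if perm.epoch != manifest.epoch:
        raise StalePlanError("manifest/permutation epoch mismatch")
    plan = compile_plan(spec, layout, depth_cap=depth_cap)
    dedupe(plan, dedupe_enabled)
    selectors = plan_to_selectors(plan, manifest, perm)
    resp = transport.query(ExtractionRequest(manifest.epoch, selectors))
    if resp.epoch != manifest.epoch:
        raise StalePlanError("response epoch does not match the plan epoch")
    scalars = decrypt_scalars(resp, keys, backend, expected=len(selectors))
    full = expand_scalars(plan, scalars)
    return reconstruct(plan, full)


def decrypt_scalars(resp, keys: KeyMaterial, backend: HEBackend,
                    expected: int | None = None) -> list[int]:
    """Decrypt slot 0 of every returned ciphertext, in ordinal order."""
    if expected is not None and len(resp.results) != expected:
        raise ProtocolError(
            f"response carries {len(resp.results)} scalars, expected {expected}")
    by_ordinal = sorted(resp.results, key=lambda r: r[0])
    scalars = []
    for _, chunk in by_ordinal:
        vec = backend.decrypt_chunk(chunk, keys)
        if np.any(vec[1:] != 0):
            warnings.warn("mask contract violation: nonzero slot beyond 0",
                          RuntimeWarning, stacklevel=2)
        scalars.append(int(vec[0]))
    return scalars


def reconstruct(plan: QueryPlan, scalars: list[int]):
    op = plan.spec.op
    if op == "coverage":
        return reconstruct_coverage(plan, scalars)
    if op in ("intersect", "window"):
        return reconstruct_intersect_window(plan, scalars)
    if op == "depth":
        return reconstruct_depth(plan, scalars)
    return reconstruct_jaccard(plan, scalars)


# --------------------------------------------------------------- formatting

def format_output(op: str, result) -> str:
    lines = []
    if op == "coverage":
        for r in result:
            lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{r.overlap_count}\t"
                         f"{r.covered_bases}\t{r.interval_length}\t"
                         f"{_sig7(r.fraction)}")
    elif op in ("intersect", "window"):
        for r in result:
            if r.count is not None:
                lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{r.count}")
            else:
                lines.append(f"{r.chrom}\t{r.start}\t{r.end}")
    elif op == "depth":
        for r in result:
            lines.append(f"{r.chrom}\t{r.pos}\t{r.depth}")
    elif op == "jaccard":
        lines.append("intersection\tunion\tjaccard")
        lines.append(f"{result.intersection_bases}\t{result.union_bases}\t"
                     f"{_sig7(result.jaccard)}")
    return "\n".join(lines) + ("\n" if lines else "")


def _sig7(x: float) -> str:
    return f"{x:.7g}"


# -------------------------------------------------------------------- bench

def bench(spec: QuerySpec, layout: GenomeLayout, signals, keys: KeyMaterial,
          backend: HEBackend, secret_seed: int = 0,
          chunk_size: int | None = None) -> dict:
    """Measure per-phase wall time, peak RSS, bytes moved, and the
    noise-budget trace along the extraction circuit.  Values are reported,
    never asserted against any reference hardware."""
    from . import dbstore
    from .server import LoopbackTransport, host_db

    report: dict = {"op": spec.op, "mode": spec.mode, "phases": {}}

    t0, rss0 = time.monotonic(), _rss_mb()
    db, manifest, perm = dbstore.build_database(
        signals, keys, backend, secret_seed, chunk_size=chunk_size)
    upload = sum(len(c.to_bytes()) for c in db.chunks)
    report["phases"]["encrypt"] = {
        "wall_s": time.monotonic() - t0, "peak_rss_mb": _rss_mb() - rss0,
        "io_bytes": upload}

    handle = host_db(db, keys)
    transport = LoopbackTransport(handle)
    plan = compile_plan(spec, layout)
    dedupe(plan, True)
    selectors = plan_to_selectors(plan, manifest, perm)

    t0, rss0 = time.monotonic(), _rss_mb()
    resp = transport.query(ExtractionRequest(manifest.epoch, selectors))
    download = sum(len(c.to_bytes()) for _, c in resp.results)
    report["phases"]["server"] = {
        "wall_s": time.monotonic() - t0, "peak_rss_mb": _rss_mb() - rss0,
        "io_bytes": download, "selectors": len(selectors)}

    t0, rss0 = time.monotonic(), _rss_mb()
    scalars = decrypt_scalars(resp, keys, backend, expected=len(selectors))
    result = reconstruct(plan, expand_scalars(plan, scalars))
    report["phases"]["decrypt"] = {
        "wall_s": time.monotonic() - t0, "peak_rss_mb": _rss_mb() - rss0}

    report["noise_trace"] = noise_trace(signals, keys, backend)
    report["rows"] = (1 if spec.op == "jaccard" else len(result))
    return report


def noise_trace(signals, keys: KeyMaterial, backend: HEBackend,
                probe_offset: int = 1) -> dict:
    """(fresh, after rotation, after masking) budgets on a probe chunk."""
    n = keys.params.slot_count
    probe = np.arange(n, dtype=np.int64) % keys.params.plain_modulus
    fresh = backend.encrypt_chunk(probe % min(keys.params.plain_modulus, 10 ** 6),
                                  keys)
    rotated = backend.bring_to_front(fresh, probe_offset, keys)
    masked = backend.mask_front(rotated, keys)
    return {
        "fresh_bits": backend.noise_budget(fresh, keys),
        "after_rotation_bits": backend.noise_budget(rotated, keys),
        "after_masking_bits": backend.noise_budget(masked, keys),
    }


def _rss_mb() -> float:
    return resource.getrusage(resource.RUSAGE_SELF).ru_maxrss / 1024.0
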