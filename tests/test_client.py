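import numpy as np
import pytest

from bedcrypt.client import (format_output, reconstruct_coverage,
                             reconstruct_jaccard)
from bedcrypt.compiler import QuerySpec, compile_plan
from bedcrypt.errors import CorruptionError, ProtocolError, StalePlanError
from bedcrypt.signals import GenomeLayout, Interval, IntervalSet
from bedcrypt import synth

from conftest import Pipeline, random_instance


@pytest.fixture(scope="module")
def fixture_pipeline(mock_backend, mock_keys):
    _, b, layout, _ = synth.make_fixture()
    return Pipeline(b, layout, mock_backend, mock_keys, chunk_size=8)


class TestWorkedFixture:
    def test_coverage_row(self, fixture_pipeline, worked_fixture):
        a, _, _, expected = worked_fixture
        rows = fixture_pipeline.run(QuerySpec("coverage", a))
        got = [(r.chrom, r.start, r.end, r.overlap_count, r.covered_bases,
                r.interval_length, r.fraction) for r in rows]
        assert got == expected["coverage"]
        assert got[0] == ("chr1", 3, 6, 2, 3, 3, 1.0)

    def test_depth_rows(self, fixture_pipeline, worked_fixture):
        a, _, _, expected = worked_fixture
        rows = fixture_pipeline.run(QuerySpec("depth", a))
        assert [(r.chrom, r.pos, r.depth) for r in rows] == expected["depth"]

    def test_intersect_complementarity(self, fixture_pipeline, worked_fixture):
        a, _, _, _ = worked_fixture
        u = fixture_pipeline.run(QuerySpec("intersect", a, "u"))
        v = fixture_pipeline.run(QuerySpec("intersect", a, "v"))
        got = sorted((r.chrom, r.start, r.end) for r in u + v)
        assert got == sorted((iv.chrom, iv.start, iv.end) for iv in a)
        assert not set((r.start, r.end) for r in u) & \
            set((r.start, r.end) for r in v)

    def test_disjoint_a_all_in_v(self, mock_backend, mock_keys):
        layout = GenomeLayout({"chr1": 20})
        b = IntervalSet([Interval("chr1", 0, 3)])
        a = IntervalSet([Interval("chr1", 10, 12), Interval("chr1", 15, 18)])
        pipe = Pipeline(b, layout, mock_backend, mock_keys, chunk_size=16)
        assert pipe.run(QuerySpec("intersect", a, "u")) == []
        v = pipe.run(QuerySpec("intersect", a, "v"))
        assert len(v) == 2

    def test_window_modes(self, fixture_pipeline, worked_fixture):
        a, _, _, expected = worked_fixture
        rows = fixture_pipeline.run(QuerySpec("window", a, "c", 2))
        assert [(r.chrom, r.start, r.end, r.count) for r in rows] == \
            expected["window_c_w2"]
        u = fixture_pipeline.run(QuerySpec("window", a, "u", 2))
        assert ("chr1", 0, 1) in [(r.chrom, r.start, r.end) for r in u]
        v = fixture_pipeline.run(QuerySpec("window", a, "v", 2))
        assert ("chr1", 0, 1) not in [(r.chrom, r.start, r.end) for r in v]

    def test_jaccard(self, fixture_pipeline, worked_fixture):
        a, _, _, expected = worked_fixture
        res = fixture_pipeline.run(QuerySpec("jaccard", a))
        assert (res.intersection_bases, res.union_bases, res.jaccard) == \
            expected["jaccard"]


class TestJaccardAlgebra:
    def test_identical_sets(self, mock_backend, mock_keys):
        layout = GenomeLayout({"chr1": 50})
        ivs = [Interval("chr1", 5, 15), Interval("chr1", 30, 40)]
        pipe = Pipeline(IntervalSet(ivs), layout, mock_backend, mock_keys,
                        chunk_size=64)
        res = pipe.run(QuerySpec("jaccard", IntervalSet(list(ivs))))
        assert res.jaccard == 1.0

    def test_disjoint_sets(self, mock_backend, mock_keys):
        layout = GenomeLayout({"chr1": 50})
        pipe = Pipeline(IntervalSet([Interval("chr1", 0, 5)]), layout,
                        mock_backend, mock_keys, chunk_size=64)
        res = pipe.run(QuerySpec("jaccard", IntervalSet([Interval("chr1", 20, 25)])))
        assert res.jaccard == 0.0

    def test_known_value(self, mock_backend, mock_keys):
        # A={[0,4)}, B={[2,6)}: intersection 2, union 6
        layout = GenomeLayout({"chr1": 10})
        pipe = Pipeline(IntervalSet([Interval("chr1", 2, 6)]), layout,
                        mock_backend, mock_keys, chunk_size=16)
        res = pipe.run(QuerySpec("jaccard", IntervalSet([Interval("chr1", 0, 4)])))
        assert (res.intersection_bases, res.union_bases) == (2, 6)
        assert res.jaccard == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, mock_backend, mock_keys, seed):
        a, b, layout = random_instance(seed + 100, L=2000, max_n=30)
        ab = Pipeline(b, layout, mock_backend, mock_keys).run(
            QuerySpec("jaccard", a))
        ba = Pipeline(a, layout, mock_backend, mock_keys).run(
            QuerySpec("jaccard", b))
        assert ab.jaccard == pytest.approx(ba.jaccard, abs=1e-12)


class TestOracleEquivalence:
    """Encrypted pipeline vs naive oracle on seeded random instances (the
    full 100-pair sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_all_ops(self, mock_backend, mock_keys, seed):
        a, b, layout = random_instance(seed, L=3000, max_n=40, max_len=25)
        pipe = Pipeline(b, layout, mock_backend, mock_keys, seed=seed)
        rows = pipe.run(QuerySpec("coverage", a))
        assert [(r.chrom, r.start, r.end, r.overlap_count, r.covered_bases,
                 r.interval_length, r.fraction) for r in rows] == \
            synth.oracle("coverage", a, b, layout)
        for mode in "uv":
            got = [(r.chrom, r.start, r.end)
                   for r in pipe.run(QuerySpec("intersect", a, mode))]
            assert got == synth.oracle("intersect", a, b, layout, mode=mode)
        for w in (0, 5):
            got = [(r.chrom, r.start, r.end, r.count)
                   for r in pipe.run(QuerySpec("window", a, "c", w))]
            assert got == synth.oracle("window", a, b, layout, w=w, mode="c")
        got = [(r.chrom, r.pos, r.depth)
               for r in pipe.run(QuerySpec("depth", a))]
        assert got == synth.oracle("depth", a, b, layout)
        res = pipe.run(QuerySpec("jaccard", a))
        oi, ou, oj = synth.oracle("jaccard", a, b, layout)
        assert (res.intersection_bases, res.union_bases) == (oi, ou)
        assert res.jaccard == pytest.approx(oj, abs=1e-12)

    def test_bfv_end_to_end(self, bfv_backend, bfv_keys):
        """Same equivalence through the real lattice backend (small ring)."""
        a, b, layout = random_instance(1, L=400, max_n=6, min_len=3, max_len=8)
        pipe = Pipeline(b, layout, bfv_backend, bfv_keys, seed=3)
        rows = pipe.run(QuerySpec("coverage", a))
        assert [(r.chrom, r.start, r.end, r.overlap_count, r.covered_bases,
                 r.interval_length, r.fraction) for r in rows] == \
            synth.oracle("coverage", a, b, layout)
        res = pipe.run(QuerySpec("jaccard", a))
        oi, ou, oj = synth.oracle("jaccard", a, b, layout)
        assert (res.intersection_bases, res.union_bases) == (oi, ou)


class TestReconstructionGuards:
    def test_scalar_stream_length_mismatch(self):
        layout = GenomeLayout({"chr1": 10})
        plan = compile_plan(
            QuerySpec("coverage", IntervalSet([Interval("chr1", 3, 6)])), layout)
        with pytest.raises(ProtocolError):
            reconstruct_coverage(plan, [1, 2, 3])

    def test_covered_above_length_detected(self):
        layout = GenomeLayout({"chr1": 10})
        plan = compile_plan(
            QuerySpec("coverage", IntervalSet([Interval("chr1", 3, 6)])), layout)
        with pytest.raises(CorruptionError):
            reconstruct_coverage(plan, [0, 9, 1, 0])  # covered=9 > len=3

    def test_epoch_mismatch_raises(self, fixture_pipeline, worked_fixture):
        a, _, _, _ = worked_fixture
        import copy
        stale = copy.deepcopy(fixture_pipeline.perm)
        stale.epoch = 99
        from bedcrypt.client import run_query
        with pytest.raises(StalePlanError):
            run_query(QuerySpec("coverage", a), fixture_pipeline.layout,
                      fixture_pipeline.manifest, stale,
                      fixture_pipeline.transport, fixture_pipeline.keys,
                      fixture_pipeline.backend)


class TestVolumeLaw:
    def test_download_scales_with_plan_not_db(self, mock_backend, mock_keys):
        """Bytes downloaded depend on read count, not database size."""
        from bedcrypt.server import ExtractionRequest
        from bedcrypt.compiler import dedupe, plan_to_selectors
        sizes = {}
        for n_b, tag in ((20, "small"), (400, "large")):
            cfg = synth.SynthConfig(seed=8, n_intervals=n_b,
                                    chrom_lengths={"chr1": 5000})
            b = synth.generate_bed(cfg)
            layout = synth.layout_of(cfg)
            a = IntervalSet([Interval("chr1", i * 100, i * 100 + 10)
                             for i in range(10)])
            pipe = Pipeline(b, layout, mock_backend, mock_keys)
            plan = dedupe(compile_plan(QuerySpec("coverage", a), layout),
                          False)
            sels = plan_to_selectors(plan, pipe.manifest, pipe.perm)
            resp = pipe.transport.query(ExtractionRequest(pipe.manifest.epoch,
                                                          sels))
            sizes[tag] = sum(len(c.to_bytes()) for _, c in resp.results)
        assert sizes["small"] == sizes["large"]


class TestFormatting:
    def test_coverage_tsv(self, fixture_pipeline, worked_fixture):
        a, _, _, _ = worked_fixture
        rows = fixture_pipeline.run(QuerySpec("coverage", a))
        text = format_output("coverage", rows)
        assert text.splitlines()[0] == "chr1\t3\t6\t2\t3\t3\t1"

    def test_jaccard_tsv(self):
        from bedcrypt.client import JaccardResult
        text = format_output("jaccard", JaccardResult(2, 6, 1 / 3))
        assert text == "intersection\tunion\tjaccard\n2\t6\t0.3333333\n"

    def test_empty_output(self):
        assert format_output("intersect", []) == ""


class TestBench:
    def test_report_fields_and_mock_trace(self, mock_backend, mock_keys):
        from bedcrypt.client import bench
        a, b, layout = random_instance(7, L=2000, max_n=20)
        from bedcrypt.signals import build_signals
        spec = QuerySpec("coverage", a)
        report = bench(spec, layout, build_signals(b, layout), mock_keys,
                       mock_backend, secret_seed=1)
        for phase in ("encrypt", "server", "decrypt"):
            assert "wall_s" in report["phases"][phase]
            assert "peak_rss_mb" in report["phases"][phase]
        assert report["noise_trace"] == {"fresh_bits": 136,
                                         "after_rotation_bits": 133,
                                         "after_masking_bits": 98}
        import json
        json.dumps(report)  # serializable
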