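import numpy as np
import pytest

from bedcrypt import dbstore
from bedcrypt.errors import AddressingError, CapacityError, StalePlanError
from bedcrypt.signals import (GenomeLayout, Interval, IntervalSet,
                              build_signals)

from conftest import PARAMS_4096


@pytest.fixture
def toy_signals():
    layout = GenomeLayout({"chr1": 10})
    b = IntervalSet([Interval("chr1", 2, 5), Interval("chr1", 4, 8)])
    return build_signals(b, layout)


class TestConcatAndChunk:
    def test_total_length_and_chunks(self, toy_signals):
        # segments: 3*(L+1) + L = 43 -> 11 chunks of 4
        chunks, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        assert manifest.total_length == 43
        assert manifest.chunk_count == len(chunks) == 11
        assert manifest.padding == 1

    def test_toy_global_index(self, toy_signals):
        _, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        # S1 occupies offsets [0, 11): global index 9 -> chunk 2, slot 1
        gidx = manifest.global_index("S1", "chr1", 9)
        assert gidx == 9
        assert divmod(gidx, 4) == (2, 1)

    def test_segment_order_fixed(self, toy_signals):
        _, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        offs = [manifest.segments[("chr1", s)][0] for s in ("S1", "S2", "S3", "S4")]
        assert offs == [0, 11, 22, 33]

    def test_last_chunk_zero_padded(self, toy_signals):
        chunks, _ = dbstore.concat_and_chunk(toy_signals, 4)
        assert chunks[-1][-1] == 0

    def test_round_trips_every_coordinate(self, toy_signals):
        chunks, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        flat = np.concatenate(chunks)
        for seg in ("S1", "S2", "S3", "S4"):
            arr = toy_signals.segment(seg, "chr1")
            for x in range(len(arr)):
                assert flat[manifest.global_index(seg, "chr1", x)] == arr[x]

    def test_capacity_error_names_chromosome(self, toy_signals):
        with pytest.raises(CapacityError, match="chr1"):
            dbstore.concat_and_chunk(toy_signals, 4, plain_modulus=2)

    def test_out_of_range_coordinate(self, toy_signals):
        _, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        with pytest.raises(AddressingError):
            manifest.global_index("S1", "chr1", 11)  # beyond L
        with pytest.raises(AddressingError):
            manifest.global_index("S4", "chr1", 10)  # depth is length L

    def test_manifest_json_round_trip(self, toy_signals):
        _, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        again = dbstore.LayoutManifest.from_json(manifest.to_json())
        assert again.segments == manifest.segments
        assert again.total_length == manifest.total_length


class TestPermutation:
    def test_single_chunk_identity(self):
        chunks = [np.arange(4)]
        _, perm = dbstore.permute_chunks(chunks, 123)
        assert perm.pi == [0]

    def test_reproducible_and_invertible(self):
        chunks = [np.full(4, i) for i in range(11)]
        p1, m1 = dbstore.permute_chunks(chunks, 42)
        p2, m2 = dbstore.permute_chunks(chunks, 42)
        assert m1.pi == m2.pi
        inv = m1.inverse()
        assert [inv[m1.pi[k]] for k in range(11)] == list(range(11))
        # physical position pi[k] holds logical chunk k
        for k in range(11):
            assert p1[m1.pi[k]][0] == k

    def test_distinct_seeds_differ(self):
        chunks = [np.full(4, i) for i in range(11)]
        _, m1 = dbstore.permute_chunks(chunks, 1)
        _, m2 = dbstore.permute_chunks(chunks, 2)
        assert m1.pi != m2.pi

    def test_contents_untouched(self):
        chunks = [np.arange(4) + 10 * i for i in range(5)]
        permuted, perm = dbstore.permute_chunks(chunks, 3)
        assert sorted(int(c[0]) for c in permuted) == [0, 10, 20, 30, 40]


class TestEncryptedDatabase:
    def test_mock_round_trip(self, toy_signals, mock_backend, mock_keys):
        db, manifest, perm = dbstore.build_database(
            toy_signals, mock_keys, mock_backend, secret_seed=5, chunk_size=4)
        flat = np.concatenate(dbstore.concat_and_chunk(toy_signals, 4)[0])
        for k in range(manifest.chunk_count):
            dec = mock_backend.decrypt_chunk(db.chunks[perm.pi[k]], mock_keys)
            assert np.array_equal(dec[:4], flat[4 * k:4 * k + 4])

    def test_bfv_round_trip(self, toy_signals, bfv_backend, bfv_keys):
        db, manifest, perm = dbstore.build_database(
            toy_signals, bfv_keys, bfv_backend, secret_seed=5, chunk_size=4)
        flat = np.concatenate(dbstore.concat_and_chunk(toy_signals, 4)[0])
        for k in range(manifest.chunk_count):
            dec = bfv_backend.decrypt_chunk(db.chunks[perm.pi[k]], bfv_keys)
            assert np.array_equal(dec[:4], flat[4 * k:4 * k + 4])
            assert np.all(dec[4:] == 0)  # padding slots decrypt to zero

    def test_selector_addressing_exhaustive(self, toy_signals, mock_backend,
                                            mock_keys):
        db, manifest, perm = dbstore.build_database(
            toy_signals, mock_keys, mock_backend, secret_seed=9, chunk_size=4)
        for seg in ("S1", "S2", "S3", "S4"):
            arr = toy_signals.segment(seg, "chr1")
            for x in range(len(arr)):
                sel = dbstore.logical_to_selector(manifest, perm, seg, "chr1",
                                                  x, ordinal=0)
                dec = mock_backend.decrypt_chunk(
                    db.chunks[sel.physical_chunk_id], mock_keys)
                assert dec[sel.slot_offset] == arr[x]

    def test_permuted_addressing(self, toy_signals):
        _, manifest = dbstore.concat_and_chunk(toy_signals, 4)
        perm = dbstore.PermutationMap(0, [2, 0, 1] + list(range(3, 11)))
        sel = dbstore.logical_to_selector(manifest, perm, "S1", "chr1", 9, 0)
        assert (sel.physical_chunk_id, sel.slot_offset) == (1, 1)


class TestRefresh:
    def test_refresh_changes_layout_not_content(self, toy_signals, mock_backend,
                                                mock_keys):
        db1, man1, perm1 = dbstore.build_database(
            toy_signals, mock_keys, mock_backend, secret_seed=1, chunk_size=4)
        db2, man2, perm2 = dbstore.refresh_database(
            toy_signals, mock_keys, mock_backend, new_seed=2,
            old_epoch=man1.epoch, chunk_size=4)
        assert man2.epoch == man1.epoch + 1
        assert perm1.pi != perm2.pi
        flat = np.concatenate(dbstore.concat_and_chunk(toy_signals, 4)[0])
        for k in range(man2.chunk_count):
            dec = mock_backend.decrypt_chunk(db2.chunks[perm2.pi[k]], mock_keys)
            assert np.array_equal(dec[:4], flat[4 * k:4 * k + 4])

    def test_refresh_freshens_ciphertexts(self, bfv_backend, bfv_keys):
        layout = GenomeLayout({"chr1": 5})
        sig = build_signals(IntervalSet([Interval("chr1", 1, 3)]), layout)
        db1, man1, _ = dbstore.build_database(sig, bfv_keys, bfv_backend, 1)
        db2, _, _ = dbstore.refresh_database(sig, bfv_keys, bfv_backend, 1,
                                             man1.epoch)
        assert db1.chunk_count == db2.chunk_count == 1
        assert not np.array_equal(db1.chunks[0].payload[0],
                                  db2.chunks[0].payload[0])

    def test_stale_plan_rejected(self, toy_signals, mock_backend, mock_keys):
        from bedcrypt.server import ExtractionRequest, extract_batch, host_db
        db2, _, _ = dbstore.refresh_database(
            toy_signals, mock_keys, mock_backend, new_seed=2, old_epoch=0,
            chunk_size=4)
        handle = host_db(db2, mock_keys)
        req = ExtractionRequest(0, [dbstore.Selector(0, 0, 0)])  # old epoch
        with pytest.raises(StalePlanError):
            extract_batch(handle, req)


class TestStoreIO:
    def test_save_load_round_trip(self, toy_signals, mock_backend, mock_keys,
                                  tmp_path):
        from bedcrypt.server import load_db
        db, _, _ = dbstore.build_database(toy_signals, mock_keys, mock_backend,
                                          secret_seed=5, chunk_size=4)
        dbstore.save_store(db, mock_keys.params, tmp_path / "store")
        handle = load_db(tmp_path / "store", mock_keys)
        assert handle.chunk_count == db.chunk_count
        assert handle.epoch == db.epoch
        got = mock_backend.decrypt_chunk(handle.chunk(0), mock_keys)
        want = mock_backend.decrypt_chunk(db.chunks[0], mock_keys)
        assert np.array_equal(got, want)

    def test_missing_chunk_detected(self, toy_signals, mock_backend, mock_keys,
                                    tmp_path):
        from bedcrypt.errors import StoreError
        from bedcrypt.server import load_db
        db, _, _ = dbstore.build_database(toy_signals, mock_keys, mock_backend,
                                          secret_seed=5, chunk_size=4)
        dbstore.save_store(db, mock_keys.params, tmp_path / "store")
        (tmp_path / "store" / "chunk_00001.bin").unlink()
        with pytest.raises(StoreError, match="missing chunk 1"):
            load_db(tmp_path / "store", mock_keys)

    def test_params_mismatch_detected(self, toy_signals, mock_backend,
                                      mock_keys, tmp_path):
        from bedcrypt.errors import StoreError
        from bedcrypt.he import HEParams
        from bedcrypt.server import load_db
        db, _, _ = dbstore.build_database(toy_signals, mock_keys, mock_backend,
                                          secret_seed=5, chunk_size=4)
        dbstore.save_store(db, mock_keys.params, tmp_path / "store")
        other = mock_backend.keygen(HEParams(poly_degree=8192), seed=1)
        with pytest.raises(StoreError, match="does not match"):
            load_db(tmp_path / "store", other)

    def test_no_secret_material_in_store(self, toy_signals, bfv_backend,
                                         bfv_keys, tmp_path):
        """Obliviousness surrogate: the server artifact contains neither the
        secret key bytes nor the permutation/manifest."""
        db, manifest, perm = dbstore.build_database(
            toy_signals, bfv_keys, bfv_backend, secret_seed=5, chunk_size=4)
        dbstore.save_store(db, bfv_keys.params, tmp_path / "store")
        secret_bytes = bfv_keys.secret_part.tobytes()
        for f in (tmp_path / "store").iterdir():
            blob = f.read_bytes()
            assert secret_bytes not in blob
            assert b"permutation" not in blob and b'"pi"' not in blob
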