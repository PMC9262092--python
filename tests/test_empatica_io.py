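"""Archive dialect parsing, writing, merging."""

import numpy as np
import pytest

from e4physio import (
    SynthSpec,
    merge_same_day,
    parse_ibi_csv,
    parse_signal_csv,
    read_session,
    synth_session,
    synth_session_zip,
    write_session,
)
from e4physio.empatica_io import parse_tags, unix_to_local
from e4physio.errors import (
    BadDialect,
    BadInterval,
    NonMonotoneBeats,
    NotSameDay,
    OverlapError,
    UnreadableArchive,
)


class TestParseSignalCsv:
    def test_header_rows_and_sample_timing(self):
        text = "1581000000\n4\n" + "\n".join(str(v) for v in range(8))
        stream = parse_signal_csv(text)
        assert stream.start_unix == 1581000000
        assert stream.fs == 4
        assert stream.n_samples == 8
        assert stream.duration == pytest.approx(2.0)
        # a 4 Hz file advances 250 ms per row: sample 3 sits at +0.75 s
        assert stream.timestamps()[3] - stream.start_unix == pytest.approx(0.75)

    def test_three_channel_acc_layout(self):
        text = "1581000000, 1581000000, 1581000000\n32, 32, 32\n1, 2, 3\n4, 5, 6"
        stream = parse_signal_csv(text, n_channels=3, channel_names=("x", "y", "z"))
        assert stream.fs == 32
        assert stream.samples.shape == (2, 3)

    def test_headers_only_is_a_valid_empty_stream(self):
        stream = parse_signal_csv("1581000000\n4\n")
        assert stream.n_samples == 0

    @pytest.mark.parametrize(
        "text",
        [
            "1581000000\n0\n1\n2",  # zero fs
            "1581000000\n-4\n1\n2",  # negative fs
            "1581000000\n4\n1\nfoo",  # non-numeric payload
            "1581000000\n",  # missing frequency row
        ],
    )
    def test_bad_dialect_rejected(self, text):
        with pytest.raises(BadDialect):
            parse_signal_csv(text)

    def test_span_matches_sample_count(self):
        rng = np.random.default_rng(0)
        for fs in (1.0, 4.0, 32.0):
            n = int(rng.integers(2, 200))
            text = f"1000\n{fs:g}\n" + "\n".join("0.5" for _ in range(n))
            stream = parse_signal_csv(text)
            ts = stream.timestamps()
            assert ts[-1] - ts[0] == pytest.approx((n - 1) / fs)


class TestParseIbiCsv:
    def test_regular_beats(self):
        rr = parse_ibi_csv("1581000000, IBI\n10.0, 1.0\n11.0, 1.0")
        assert rr.start_unix == 1581000000
        assert list(rr.beat_offsets) == [10.0, 11.0]
        assert list(rr.intervals) == [1.0, 1.0]
        assert rr.accepted.all()

    def test_gap_from_discarded_beats_is_legal(self):
        rr = parse_ibi_csv("0, IBI\n10.0, 1.0\n14.0, 0.9")
        assert rr.n_beats == 2

    def test_empty_payload(self):
        assert parse_ibi_csv("1581000000, IBI\n").n_beats == 0

    def test_decreasing_offsets_rejected(self):
        with pytest.raises(NonMonotoneBeats):
            parse_ibi_csv("0, IBI\n10.0, 1.0\n9.0, 1.0")

    def test_non_positive_interval_rejected(self):
        with pytest.raises(BadInterval):
            parse_ibi_csv("0, IBI\n10.0, 0.0")

    def test_reserialization_reproduces_to_6_decimals(self):
        from e4physio.empatica_io import _ibi_csv

        rng = np.random.default_rng(3)
        offs = np.cumsum(rng.uniform(0.5, 1.5, 20))
        ibis = rng.uniform(0.5, 1.5, 20)
        text = "0, IBI\n" + "\n".join(f"{o}, {i}" for o, i in zip(offs, ibis))
        rr = parse_ibi_csv(text)
        rr2 = parse_ibi_csv(_ibi_csv(rr))
        assert np.allclose(rr2.beat_offsets, rr.beat_offsets, atol=1e-6)
        assert np.allclose(rr2.intervals, rr.intervals, atol=1e-6)


def test_parse_tags_skips_non_numeric_lines():
    assert parse_tags("100.5\nnot-a-number\n101\n") == [100.5, 101.0]


class TestArchives:
    def test_minimal_archive_has_only_eda(self, tmp_path):
        import zipfile

        path = tmp_path / "mini.zip"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("EDA.csv", "1581000000\n4\n1.0\n1.1\n")
        session = read_session(path)
        assert session.eda is not None
        assert session.bvp is None and session.acc is None and session.ibi is None

    def test_missing_archive_unreadable(self, tmp_path):
        with pytest.raises(UnreadableArchive):
            read_session(tmp_path / "absent.zip")

    def test_garbage_zip_unreadable(self, tmp_path):
        path = tmp_path / "corrupt.zip"
        path.write_bytes(b"this is not a zip")
        with pytest.raises(UnreadableArchive):
            read_session(path)

    def test_round_trip_preserves_everything(self, tmp_path, eventful_spec):
        session, _ = synth_session(eventful_spec)
        path = write_session(session, tmp_path / "s.zip")
        back = read_session(path)
        for name, stream in session.signal_streams():
            other = getattr(back, name)
            assert other.fs == stream.fs
            assert other.start_unix == stream.start_unix
            assert np.allclose(other.samples, stream.samples, atol=1e-6)
        assert np.allclose(back.ibi.beat_offsets, session.ibi.beat_offsets, atol=1e-6)

    def test_write_is_canonical(self, tmp_path, quiet_spec):
        # writing the read-back session reproduces the archive text exactly
        import zipfile

        session, _ = synth_session(quiet_spec)
        p1 = write_session(session, tmp_path / "a.zip")
        p2 = write_session(read_session(p1), tmp_path / "b.zip")
        with zipfile.ZipFile(p1) as z1, zipfile.ZipFile(p2) as z2:
            for name in z1.namelist():
                assert z1.read(name) == z2.read(name), name

    def test_session_without_ibi_lacks_member(self, tmp_path, quiet_spec):
        import zipfile

        session, _ = synth_session(quiet_spec)
        session.ibi = None
        path = write_session(session, tmp_path / "noibi.zip")
        with zipfile.ZipFile(path) as zf:
            assert "IBI.csv" not in zf.namelist()
        assert read_session(path).ibi is None

    def test_tags_round_trip(self, tmp_path):
        session, _ = synth_session(SynthSpec(duration=30, tags_at=(10.0, 20.0)))
        path = write_session(session, tmp_path / "tagged.zip")
        assert read_session(path).tags == session.tags


class TestMergeSameDay:
    def _session_at(self, start, duration=600.0, seed=0):
        session, _ = synth_session(
            SynthSpec(duration=duration, seed=seed, start_unix=start)
        )
        return session

    def test_single_session_identity(self):
        s = self._session_at(1581000000)
        assert merge_same_day([s]) is s

    def test_merge_order_insensitive(self, tmp_path):
        a = self._session_at(1581000000.0)
        b = self._session_at(1581004000.0, seed=1)
        m1 = merge_same_day([a, b])
        m2 = merge_same_day([b, a])
        assert m1.start_unix == a.start_unix
        assert np.array_equal(m1.eda.samples, m2.eda.samples)
        assert m1.eda.gaps == m2.eda.gaps

    def test_gap_preserved_not_fabricated(self):
        a = self._session_at(1581000000.0, duration=600)
        b = self._session_at(1581000000.0 + 4200, duration=600, seed=1)  # 1 h gap
        merged = merge_same_day([a, b])
        # span covers first start to last end; samples only cover 2 x 600 s
        assert merged.eda.end_unix - merged.eda.start_unix == pytest.approx(4800)
        assert merged.eda.n_samples == a.eda.n_samples + b.eda.n_samples
        assert len(merged.eda.gaps) == 1

    def test_ibi_offsets_rebased_to_merged_start(self):
        a = self._session_at(1581000000.0, duration=600)
        b = self._session_at(1581004000.0, duration=600, seed=1)
        merged = merge_same_day([a, b])
        expected_first_b = 4000 + b.ibi.beat_offsets[0]
        later = merged.ibi.beat_offsets[merged.ibi.beat_offsets > 3000]
        assert later[0] == pytest.approx(expected_first_b)

    def test_overlap_rejected(self):
        a = self._session_at(1581000000.0, duration=600)
        b = self._session_at(1581000300.0, duration=600, seed=1)
        with pytest.raises(OverlapError):
            merge_same_day([a, b])

    def test_different_days_rejected(self):
        a = self._session_at(1581000000.0)
        b = self._session_at(1581000000.0 + 86400 * 2, seed=1)
        with pytest.raises(NotSameDay):
            merge_same_day([a, b])

    def test_two_archives_read_together(self, tmp_path):
        a = self._session_at(1581000000.0)
        b = self._session_at(1581004000.0, seed=1)
        pa = write_session(a, tmp_path / "a.zip")
        pb = write_session(b, tmp_path / "b.zip")
        m1 = read_session([pa, pb])
        m2 = read_session([pb, pa])
        assert m1.start_unix == m2.start_unix == 1581000000.0
        assert m1.eda.n_samples == m2.eda.n_samples


def test_synth_zip_dialect_and_sidecar(tmp_path):
    path, sidecar = synth_session_zip(SynthSpec(duration=60), tmp_path / "s.zip")
    session = read_session(path)
    assert all(
        getattr(session, n) is not None for n in ("eda", "bvp", "hr", "temp", "acc")
    )
    assert session.ibi is not None
    assert sidecar.exists()


def test_unix_to_local_applies_offset():
    assert unix_to_local(0, 60).hour == 1
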