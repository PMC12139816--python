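"""Consensus peak building: picking, median-scan normalization, matching, IO."""

import itertools
import json

import numpy as np
import pytest

from lipidvote.consensus import (
    export_peak_characteristics,
    import_peak_characteristics,
    match_peaks_across_scans,
    normalize_to_median_scan,
    pick_peaks,
    SampleSpectrum,
    ConsensusPeak,
)
from lipidvote.study import PeaklistParseError, SampleMeta, Scan


def scan(sid, mz, intensity):
    return Scan(sid, np.asarray(mz, float), np.asarray(intensity, float))


class TestPickPeaks:
    def test_zero_threshold_keeps_everything(self):
        s = scan("a", [100, 200, 300], [10, 5, 1])
        assert len(pick_peaks(s, 0.0)) == 3

    def test_threshold_is_inclusive(self):
        s = scan("a", [100, 200, 300], [10, 5, 1])
        out = pick_peaks(s, 5.0)
        assert list(out.intensity) == [10, 5]

    def test_empty_scan(self):
        assert len(pick_peaks(scan("a", [], []), 3.0)) == 0


class TestMedianScanNormalization:
    def test_identical_scans_unchanged(self):
        scans = [scan(f"s{i}", [100.0], [50.0]) for i in range(3)]
        out = normalize_to_median_scan(scans)
        assert all(s.tic == pytest.approx(50.0) for s in out)

    def test_scale_factors_follow_tic_ratio(self):
        scans = [
            scan("a", [100.0], [100.0]),
            scan("b", [100.0], [200.0]),
            scan("c", [100.0], [400.0]),
        ]
        out = {s.scan_id: s for s in normalize_to_median_scan(scans)}
        # reference is the median-TIC scan (200)
        assert out["a"].intensity[0] == pytest.approx(200.0)  # factor 2
        assert out["b"].intensity[0] == pytest.approx(200.0)  # factor 1
        assert out["c"].intensity[0] == pytest.approx(200.0)  # factor 0.5

    def test_even_count_uses_lower_median(self):
        scans = [scan(s, [100.0], [t]) for s, t in zip("abcd", [100, 200, 300, 400])]
        out = normalize_to_median_scan(scans)
        assert all(s.tic == pytest.approx(200.0) for s in out)

    def test_all_tics_equal_reference(self, rng):
        scans = [
            scan(f"s{i}", np.sort(rng.uniform(100, 900, 20)), rng.uniform(1, 100, 20))
            for i in range(5)
        ]
        out = normalize_to_median_scan(scans)
        tics = [s.tic for s in out]
        assert np.allclose(tics, tics[0], rtol=1e-9)

    def test_zero_tic_scan_excluded(self, caplog):
        scans = [scan("a", [100.0], [10.0]), scan("z", [], [])]
        with caplog.at_level("WARNING"):
            out = normalize_to_median_scan(scans)
        assert [s.scan_id for s in out] == ["a"]
        assert any("zero TIC" in r.message for r in caplog.records)


def brute_force_single_linkage(points, ppm_tol):
    """Oracle: single-linkage clusters where neighbors within ppm_tol link."""
    points = sorted(points)
    clusters, cur = [], [points[0]]
    for p in points[1:]:
        if (p - cur[-1]) / cur[-1] * 1e6 <= ppm_tol:
            cur.append(p)
        else:
            clusters.append(cur)
            cur = [p]
    clusters.append(cur)
    return clusters


class TestMatchPeaks:
    def test_close_peaks_merge(self):
        scans = [scan("a", [500.000000], [10]), scan("b", [500.001000], [10])]
        out = match_peaks_across_scans(scans, ppm_tol=5.0)
        assert len(out) == 1
        assert out[0].presence_count == 2

    def test_distant_peaks_stay_separate(self):
        scans = [scan("a", [500.00], [10]), scan("b", [500.01], [10])]
        out = match_peaks_across_scans(scans, ppm_tol=5.0)
        assert len(out) == 2

    def test_matches_single_linkage_oracle_on_separated_data(self, rng):
        # peaks are generated either well within or well beyond tolerance so
        # greedy weighted-mean clustering and single-linkage provably agree
        tol = 5.0
        for _ in range(20):
            centers = np.cumsum(rng.uniform(0.05, 1.0, rng.integers(2, 8))) + 400.0
            points = []
            for c in centers:
                for _ in range(int(rng.integers(1, 4))):
                    points.append(c * (1 + rng.uniform(-0.2, 0.2) * tol * 1e-6))
            points = points[:20]
            scans = [scan("s", np.sort(points), np.ones(len(points)))]
            got = [len(p.per_scan_intensity) for p in match_peaks_across_scans(scans, tol)]
            oracle = brute_force_single_linkage(points, tol)
            assert len(got) == len(oracle)

    def test_invariant_to_scan_order(self, rng):
        scans = [
            scan(f"s{i}", np.sort(rng.uniform(100, 900, 15)), rng.uniform(1, 100, 15))
            for i in range(4)
        ]
        base = match_peaks_across_scans(scans, 5.0)
        for perm in itertools.permutations(scans):
            out = match_peaks_across_scans(list(perm), 5.0)
            assert [p.mz for p in out] == [p.mz for p in base]

    def test_member_count_conservation(self, rng):
        scans = [
            scan(f"s{i}", np.sort(rng.uniform(100, 900, 25)), rng.uniform(1, 100, 25))
            for i in range(3)
        ]
        out = match_peaks_across_scans(scans, 5.0)
        total_members = sum(len(p.per_scan_intensity) for p in out)
        # every raw peak lands in exactly one consensus peak (same-scan
        # duplicates within a cluster collapse into one entry)
        assert total_members <= 75
        assert sum(p.presence_count for p in out) == total_members

    def test_aggregate_mz_within_member_span(self, rng):
        # well-separated clusters so membership is unambiguous
        tol = 5.0
        centers = np.cumsum(rng.uniform(0.5, 2.0, 10)) + 400.0
        scans = []
        for i in range(3):
            mz = np.sort(centers * (1 + rng.uniform(-0.3, 0.3, 10) * tol * 1e-6))
            scans.append(scan(f"s{i}", mz, rng.uniform(1, 100, 10)))
        all_mz = np.concatenate([s.mz for s in scans])
        out = match_peaks_across_scans(scans, tol)
        assert len(out) == 10
        for c, p in zip(np.sort(centers), out):
            members = all_mz[np.abs(all_mz - c) / c * 1e6 <= tol]
            assert members.min() <= p.mz <= members.max()


class TestPeakCharacteristicsIO:
    def make_spectrum(self):
        meta = SampleMeta("s1", "case", 1, "unlabeled", 2)
        peaks = [
            ConsensusPeak(0, 500.0, 10.0, {"a": 10.0, "b": 10.0}),
            ConsensusPeak(1, 600.0, 5.0, {"a": 5.0}),
        ]
        return SampleSpectrum(meta, peaks)

    def test_roundtrip(self, tmp_path):
        spec = self.make_spectrum()
        p = tmp_path / "peaks.json"
        export_peak_characteristics(spec, p)
        back = import_peak_characteristics(p)
        assert back.meta == spec.meta
        for a, b in zip(spec.peaks, back.peaks):
            assert (a.peak_id, a.presence_count) == (b.peak_id, b.presence_count)
            assert a.mz == pytest.approx(b.mz, abs=1e-6)
            assert a.per_scan_intensity == b.per_scan_intensity

    def test_presence_count_consistency_enforced(self, tmp_path):
        spec = self.make_spectrum()
        p = tmp_path / "peaks.json"
        export_peak_characteristics(spec, p)
        doc = json.loads(p.read_text())
        doc["peaks"][0]["presence_count"] = 7
        p.write_text(json.dumps(doc))
        with pytest.raises(PeaklistParseError):
            import_peak_characteristics(p)

    def test_missing_per_scan_intensity_is_parse_error(self, tmp_path):
        spec = self.make_spectrum()
        p = tmp_path / "peaks.json"
        export_peak_characteristics(spec, p)
        doc = json.loads(p.read_text())
        del doc["peaks"][0]["per_scan_intensity"]
        p.write_text(json.dumps(doc))
        with pytest.raises(PeaklistParseError, match="per_scan_intensity"):
            import_peak_characteristics(p)


def minimal_mzml(spectra, compress=False):
    """Build a minimal mzML document for reader tests.

    spectra: list of (mz list, intensity list, mode) with mode in
    {"centroid", "profile"}.
    """
    import base64
    import struct
    import zlib

    def enc(values):
        raw = struct.pack(f"<{len(values)}d", *values)
        if compress:
            raw = zlib.compress(raw)
        return base64.b64encode(raw).decode()

    comp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        if compress
        else '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
    )
    mode_cv = {
        "centroid": '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
        "profile": '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>',
    }
    parts = []
    for i, (mz, inten, mode) in enumerate(spectra):
        arrays = ""
        for accession, name, values in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            arrays += f"""
     <binaryDataArray encodedLength="{len(enc(values))}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      {comp_cv}
      <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>
      <binary>{enc(values)}</binary>
     </binaryDataArray>"""
        parts.append(f"""
   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    {mode_cv[mode]}
    <binaryDataArrayList count="2">{arrays}
    </binaryDataArrayList>
   </spectrum>""")
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f' <run id="r">\n  <spectrumList count="{len(spectra)}">{"".join(parts)}\n'
        "  </spectrumList>\n </run>\n</mzML>\n"
    )


class TestMzmlReader:
    meta = SampleMeta("s1", "case", 1, "unlabeled", 1)

    @pytest.mark.parametrize("compress", [False, True])
    def test_reads_centroided_spectra(self, tmp_path, compress):
        from lipidvote.consensus import read_mzml

        mz1, i1 = [400.1, 500.2, 600.3], [10.0, 20.0, 30.0]
        mz2, i2 = [410.5, 510.6], [5.0, 7.0]
        p = tmp_path / "sample.mzML"
        p.write_text(
            minimal_mzml([(mz1, i1, "centroid"), (mz2, i2, "centroid")], compress)
        )
        sample = read_mzml(p, self.meta)
        assert len(sample.scans) == 2
        assert np.allclose(sample.scans[0].mz, mz1)
        assert np.allclose(sample.scans[0].intensity, i1)
        assert np.allclose(sample.scans[1].mz, mz2)

    def test_profile_spectra_rejected(self, tmp_path):
        from lipidvote.consensus import read_mzml

        p = tmp_path / "profile.mzML"
        p.write_text(minimal_mzml([([400.0], [1.0], "profile")]))
        with pytest.raises(ValueError, match="profile"):
            read_mzml(p, self.meta)
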