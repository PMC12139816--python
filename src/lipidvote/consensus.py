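"""Cross-scan consensus peak lists for one infused sample.

Direct-infusion FTMS acquires many nominally identical scans per sample.  The
stages here (1) threshold-filter each scan, (2) rescale every scan to the
median-TIC scan so scan-to-scan infusion drift cancels, (3) match peaks across
scans into *consensus peaks* by greedy ascending-m/z clustering against a
running intensity-weighted mean, and (4) serialize the per-scan plus aggregate
peak characteristics to JSON.

Aggregate statistics use only the scans in which a peak was actually detected:
the consensus m/z is the intensity-weighted mean and the consensus intensity
the plain mean over non-zero scans.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .study import PeaklistParseError, Sample, SampleMeta, Scan, _require

logger = logging.getLogger(__name__)


@dataclass
class ConsensusPeak:
    peak_id: int
    mz: float
    intensity: float
    per_scan_intensity: dict[str, float]
    presence_count: int = 0

    def __post_init__(self):
        nz = sum(1 for v in self.per_scan_intensity.values() if v > 0)
        if self.presence_count == 0:
            self.presence_count = nz
        elif self.presence_count != nz:
            raise ValueError(
                f"peak {self.peak_id}: presence_count {self.presence_count} "
                f"!= non-zero scans {nz}"
            )


@dataclass
class SampleSpectrum:
    meta: SampleMeta
    peaks: list[ConsensusPeak] = field(default_factory=list)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def pick_peaks(scan: Scan, min_intensity: float = 0.0) -> Scan:
    """Keep peaks with intensity >= min_intensity (inclusive), order preserved."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    keep = scan.intensity >= min_intensity
    return Scan(scan.scan_id, scan.mz[keep], scan.intensity[keep])


def normalize_to_median_scan(scans: list[Scan]) -> list[Scan]:
    """Rescale every scan's intensities to the TIC of the median-TIC scan.

    The reference is the scan whose TIC is the (lower, for even counts) median
    of all TICs; each scan is multiplied by reference_tic / own_tic, so all
    scaled TICs equal the reference TIC and the reference itself is unchanged.
    Zero-TIC scans are dropped with a warning.
    """
    if not scans:
        raise ValueError("need at least one scan")
    live = [s for s in scans if s.tic > 0]
    for s in scans:
        if s.tic <= 0:
            logger.warning("scan %s has zero TIC; excluded from normalization", s.scan_id)
    if not live:
        return []
    tics = np.array([s.tic for s in live])
    ref_tic = float(np.sort(tics)[(len(live) - 1) // 2])
    return [
        Scan(s.scan_id, s.mz.copy(), s.intensity * (ref_tic / s.tic)) for s in live
    ]


def match_peaks_across_scans(scans: list[Scan], ppm_tol: float = 5.0) -> list[ConsensusPeak]:
    """Cluster peaks across scans into consensus peaks.

    All peaks are pooled and sorted by m/z (so the result is invariant to scan
    order); walking in ascending order, a peak joins the current cluster when
    it lies within ``ppm_tol`` of the cluster's running intensity-weighted
    mean m/z, otherwise it opens a new cluster.  Two same-scan peaks landing
    in one cluster have their intensities summed.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    rows = [
        (m, i, s.scan_id)
        for s in scans
        for m, i in zip(s.mz, s.intensity)
        if i > 0
    ]
    rows.sort(key=lambda r: (r[0], r[2]))
    peaks: list[ConsensusPeak] = []
    cur: list[tuple[float, float, str]] = []
    wsum = msum = 0.0

    def flush():
        if not cur:
            return
        per_scan: dict[str, float] = {}
        for m, i, sid in cur:
            per_scan[sid] = per_scan.get(sid, 0.0) + i
        mz = msum / wsum
        vals = [v for v in per_scan.values() if v > 0]
        peaks.append(
            ConsensusPeak(
                peak_id=len(peaks),
                mz=mz,
                intensity=float(np.mean(vals)),
                per_scan_intensity=per_scan,
            )
        )

    for m, i, sid in rows:
        if cur:
            center = msum / wsum
            if abs(m - center) / center * 1e6 > ppm_tol:
                flush()
                cur, wsum, msum = [], 0.0, 0.0
        cur.append((m, i, sid))
        wsum += i
        msum += m * i
    flush()
    return peaks


def build_sample_spectrum(
    sample: Sample,
    min_intensity: float = 0.0,
    ppm_tol: float = 5.0,
) -> SampleSpectrum:
    """Full per-sample stage: pick -> normalize to median scan -> match."""
    picked = [pick_peaks(s, min_intensity) for s in sample.scans]
    normalized = normalize_to_median_scan(picked) if picked else []
    return SampleSpectrum(sample.meta, match_peaks_across_scans(normalized))


def export_peak_characteristics(spectrum: SampleSpectrum, path: str | Path) -> None:
    """Write aggregate + per-scan peak characteristics for one sample as JSON."""
    doc = {
        "sample_id": spectrum.meta.sample_id,
        "condition": spectrum.meta.condition,
        "block_group": spectrum.meta.block_group,
        "labeling": spectrum.meta.labeling,
        "n_scans": spectrum.meta.n_scans,
        "peaks": [
            {
                "peak_id": p.peak_id,
                "mz": round(p.mz, 6),
                "intensity": p.intensity,
                "presence_count": p.presence_count,
                "per_scan_intensity": p.per_scan_intensity,
            }
            for p in spectrum.peaks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def import_peak_characteristics(path: str | Path) -> SampleSpectrum:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise PeaklistParseError(f"{path}: not valid JSON ({e})") from e
    where = str(path)
    meta = SampleMeta(
        sample_id=_require(doc, "sample_id", where),
        condition=_require(doc, "condition", where),
        block_group=int(_require(doc, "block_group", where)),
        labeling=_require(doc, "labeling", where),
        n_scans=int(_require(doc, "n_scans", where)),
    )
    peaks = []
    for prec in _require(doc, "peaks", where):
        pwhere = f"{where}: peak {prec.get('peak_id', '?')}"
        per_scan = _require(prec, "per_scan_intensity", pwhere)
        try:
            peaks.append(
                ConsensusPeak(
                    peak_id=int(_require(prec, "peak_id", pwhere)),
                    mz=float(_require(prec, "mz", pwhere)),
                    intensity=float(_require(prec, "intensity", pwhere)),
                    per_scan_intensity={str(k): float(v) for k, v in per_scan.items()},
                    presence_count=int(_require(prec, "presence_count", pwhere)),
                )
            )
        except ValueError as e:
            raise PeaklistParseError(f"{pwhere}: {e}") from e
    return SampleSpectrum(meta, peaks)


_MZML_ACCESSIONS = {
    "MS:1000511": "ms level",
    "MS:1000127": "centroid",
    "MS:1000128": "profile",
    "MS:1000514": "mz_array",
    "MS:1000515": "intensity_array",
    "MS:1000523": "f64",
    "MS:1000521": "f32",
    "MS:1000574": "zlib",
    "MS:1000576": "raw",
}


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    import base64
    import zlib

    flags = {
        _MZML_ACCESSIONS[cv.get("accession")]
        for cv in bda.iter("{*}cvParam")
        if cv.get("accession") in _MZML_ACCESSIONS
    }
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "")
    if "zlib" in flags:
        raw = zlib.decompress(raw)
    dtype = np.float32 if "f32" in flags else np.float64
    values = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"))
    name = "mz_array" if "mz_array" in flags else (
        "intensity_array" if "intensity_array" in flags else None
    )
    return name, values.astype(float)


def read_mzml(path: str | Path, meta: SampleMeta) -> Sample:
    """Read centroided MS1 scans from an mzML file.

    Minimal self-contained reader (lxml + base64/zlib) for centroided MS1
    spectra with 32/64-bit little-endian arrays and optional zlib
    compression.  Profile-mode spectra are rejected with a clear error.
    """
    from lxml import etree

    scans = []
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spectrum.iter("{*}cvParam")
            if cv.get("accession")
        }
        sid = spectrum.get("id", f"scan={len(scans) + 1}")
        if int(params.get("MS:1000511", 1)) != 1:
            spectrum.clear()
            continue
        if "MS:1000128" in params:
            raise ValueError(
                f"{path}: spectrum {sid} is profile mode; centroided data required"
            )
        arrays = {}
        for bda in spectrum.iter("{*}binaryDataArray"):
            name, values = _decode_binary_array(bda)
            if name:
                arrays[name] = values
        if "mz_array" not in arrays or "intensity_array" not in arrays:
            raise ValueError(f"{path}: spectrum {sid} lacks m/z or intensity arrays")
        scans.append(Scan(str(sid), arrays["mz_array"], arrays["intensity_array"]))
        spectrum.clear()
    return Sample(meta, scans)
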