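"""Study containers: samples, scans, metadata, and the JSON peak-list dialect.

A *study* is a set of infused samples, each measured as a series of centroided
scans.  Sample metadata carries the experimental condition (case/control), the
acquisition block group (1/2/3) and the stable-isotope labeling scheme, which
downstream stages use both as model covariates and to decide which
isotopologue series to search.

On disk a study is a single JSON document::

    {"study_id": ..., "samples": [{"sample_id", "condition", "block_group",
     "labeling", "scans": [{"scan_id", "peaks": [{"mz", "intensity"}, ...]}]}]}

with m/z written to six fractional digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .isotopes import LABELING_SCHEMES

logger = logging.getLogger(__name__)

CONDITIONS: tuple[str, ...] = ("case", "control")
BLOCK_GROUPS: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    block_group: int
    labeling: str
    n_scans: int = 5

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.block_group not in BLOCK_GROUPS:
            raise ValueError(f"block_group must be in {BLOCK_GROUPS}, got {self.block_group}")
        if self.labeling not in LABELING_SCHEMES:
            raise ValueError(f"labeling must be one of {LABELING_SCHEMES}")
        if self.n_scans < 1:
            raise ValueError("n_scans must be positive")


@dataclass
class Scan:
    """One centroided scan: parallel m/z and intensity arrays, m/z ascending."""

    scan_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(f"scan {self.scan_id}: mz/intensity shape mismatch")
        if self.mz.size and np.any(self.mz <= 0):
            raise ValueError(f"scan {self.scan_id}: non-positive m/z")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensity")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class Sample:
    meta: SampleMeta
    scans: list[Scan] = field(default_factory=list)


@dataclass
class Study:
    study_id: str
    samples: list[Sample]

    def __post_init__(self):
        ids = [s.meta.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in study")

    def __iter__(self):
        return iter(self.samples)

    def metas(self) -> list[SampleMeta]:
        return [s.meta for s in self.samples]


class PeaklistParseError(ValueError):
    """Raised when a peak-list JSON document violates the schema."""


def _require(record: dict, key: str, where: str):
    if key not in record:
        raise PeaklistParseError(f"{where}: missing required field {key!r}")
    return record[key]


def write_peaklists(study: Study, path: str | Path) -> None:
    """Serialize a study to the JSON peak-list dialect (m/z to 1e-6 Da)."""
    doc = {
        "study_id": study.study_id,
        "samples": [
            {
                "sample_id": s.meta.sample_id,
                "condition": s.meta.condition,
                "block_group": s.meta.block_group,
                "labeling": s.meta.labeling,
                "scans": [
                    {
                        "scan_id": scan.scan_id,
                        "peaks": [
                            {"mz": round(float(m), 6), "intensity": float(i)}
                            for m, i in zip(scan.mz, scan.intensity)
                        ],
                    }
                    for scan in s.scans
                ],
            }
            for s in study.samples
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_peaklists(path: str | Path) -> Study:
    """Parse the JSON peak-list dialect back into a :class:`Study`.

    Malformed records raise :class:`PeaklistParseError` naming the offending
    record; a sample with no scans is accepted with a logged warning.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise PeaklistParseError(f"{path}: not valid JSON ({e})") from e
    samples = []
    for i, rec in enumerate(_require(doc, "samples", str(path))):
        where = f"{path}: samples[{i}]"
        sid = _require(rec, "sample_id", where)
        meta = SampleMeta(
            sample_id=sid,
            condition=_require(rec, "condition", where),
            block_group=int(_require(rec, "block_group", where)),
            labeling=_require(rec, "labeling", where),
            n_scans=max(1, len(rec.get("scans", []))),
        )
        scans = []
        for srec in _require(rec, "scans", where):
            swhere = f"{where}({sid}).scan {srec.get('scan_id', '?')}"
            peaks = _require(srec, "peaks", swhere)
            mz = np.array([_require(p, "mz", swhere) for p in peaks], dtype=float)
            inten = np.array([_require(p, "intensity", swhere) for p in peaks], dtype=float)
            scans.append(Scan(str(_require(srec, "scan_id", swhere)), mz, inten))
        if not scans:
            logger.warning("sample %s has no scans", sid)
        samples.append(Sample(meta, scans))
    return Study(str(_require(doc, "study_id", str(path))), samples)
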