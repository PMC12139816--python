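"""Pre-enumerated elemental-formula caches for exact-mass search.

A cache holds every C/H/N/O/P count tuple within per-element limits whose
[M+H]+ m/z does not exceed ``mz_max``, sorted by neutral monoisotopic mass so
candidate lookup is a binary search.  Caches persist as TSV with a header
recording the limits; loading with mismatched limits fails rather than
silently reusing a stale cache.

Optional chemical-plausibility filters (ring-plus-double-bond equivalents
>= 0 and H <= 2C + N + 2) are available but off by default, so the search
space — and hence the e-value competition — is the full combinatorial one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import ADDUCT_DELTA, ELEMENTS, MONO_MASS

DEFAULT_CACHE_LIMITS: dict[str, int] = {"C": 130, "H": 230, "N": 7, "O": 28, "P": 3}


@dataclass(frozen=True)
class AssignmentConfig:
    """Knobs for cache enumeration, peak matching, and assignment scoring.

    ppm_tol is the match window for peaks; ppm_sigma0 the e-value calibration
    width (a deviation of ppm_sigma0 scores z = 1).  The default sets
    ppm_sigma0 equal to ppm_tol so a match at the window edge contributes
    e^(-1/2) to the survival product — the e-value is calibrated to the match
    window, not to the raw per-scan mass precision, because consensus m/z
    values are scan-averaged.
    """

    cache_limits: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CACHE_LIMITS))
    mz_max: float = 1400.0
    evalue_max: float = 0.1
    ppm_tol: float = 5.0
    ppm_sigma0: float = 5.0
    classified_weight: float = 2.0
    missing_alpha: float = 0.5
    detection_floor: float = 0.05
    max_isotopologue_shift: int = 3
    plausibility_filters: bool = False

    def __post_init__(self):
        if not 0.0 < self.evalue_max <= 1.0:
            raise ValueError("evalue_max must be in (0, 1]")
        for name in ("mz_max", "ppm_tol", "ppm_sigma0", "classified_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v < 0 for v in self.cache_limits.values()):
            raise ValueError("cache limits must be >= 0")


class FormulaCache:
    """Mass-sorted formula table: ``counts`` (n, 5) int32 and ``mass`` (n,)."""

    def __init__(self, counts: np.ndarray, limits: dict[str, int], mz_max: float):
        counts = np.asarray(counts, dtype=np.int32).reshape(-1, 5)
        mass = counts @ np.array([MONO_MASS[el] for el in ELEMENTS])
        order = np.lexsort((*counts.T[::-1], mass))
        self.counts = counts[order]
        self.mass = mass[order]
        self.limits = dict(limits)
        self.mz_max = float(mz_max)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def window(self, lo_mass: float, hi_mass: float, brute_force: bool = False) -> np.ndarray:
        """Indices of formulas with neutral mass in [lo_mass, hi_mass].

        Binary search over the sorted mass column by default; the linear-scan
        path exists as an oracle for equivalence testing.
        """
        if brute_force:
            return np.nonzero((self.mass >= lo_mass) & (self.mass <= hi_mass))[0]
        lo = int(np.searchsorted(self.mass, lo_mass, side="left"))
        hi = int(np.searchsorted(self.mass, hi_mass, side="right"))
        return np.arange(lo, hi)


def generate_cache(config: AssignmentConfig) -> FormulaCache:
    """Enumerate all in-limit formulas with [M+H]+ m/z <= mz_max."""
    lim = {el: config.cache_limits.get(el, 0) for el in ELEMENTS}
    budget = config.mz_max - ADDUCT_DELTA["H"]  # neutral-mass budget
    mH = MONO_MASS["H"]
    chunks = []
    h_lim = lim["H"]
    for c in range(lim["C"] + 1):
        m_c = c * MONO_MASS["C"]
        if m_c > budget:
            break
        for p in range(lim["P"] + 1):
            m_cp = m_c + p * MONO_MASS["P"]
            if m_cp > budget:
                break
            for n in range(lim["N"] + 1):
                m_cpn = m_cp + n * MONO_MASS["N"]
                if m_cpn > budget:
                    break
                for o in range(lim["O"] + 1):
                    base = m_cpn + o * MONO_MASS["O"]
                    if base > budget:
                        break
                    h_max = min(h_lim, int((budget - base) / mH))
                    h = np.arange(0, h_max + 1, dtype=np.int32)
                    if config.plausibility_filters:
                        rdbe_ok = c - h / 2.0 + n / 2.0 + 1.0 >= 0.0
                        hmax_ok = h <= 2 * c + n + 2
                        h = h[rdbe_ok & hmax_ok]
                    if h.size == 0:
                        continue
                    block = np.empty((h.size, 5), dtype=np.int32)
                    block[:, 0] = c
                    block[:, 1] = h
                    block[:, 2] = n
                    block[:, 3] = o
                    block[:, 4] = p
                    chunks.append(block)
    counts = np.concatenate(chunks) if chunks else np.empty((0, 5), dtype=np.int32)
    return FormulaCache(counts, lim, config.mz_max)


def save_cache(cache: FormulaCache, path: str | Path) -> None:
    header = (
        "limits "
        + " ".join(f"{el}={cache.limits[el]}" for el in ELEMENTS)
        + f" mz_max={cache.mz_max}\n"
        + "\t".join(ELEMENTS)
    )
    np.savetxt(path, cache.counts, fmt="%d", delimiter="\t", header=header)


def load_cache(path: str | Path, config: AssignmentConfig | None = None) -> FormulaCache:
    """Load a persisted cache, rejecting it if limits disagree with config."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# limits"):
        raise ValueError(f"{path}: not a formula cache (missing limits header)")
    fields = dict(tok.split("=") for tok in first.split()[2:])
    limits = {el: int(fields[el]) for el in ELEMENTS}
    mz_max = float(fields["mz_max"])
    if config is not None:
        want = {el: config.cache_limits.get(el, 0) for el in ELEMENTS}
        if limits != want or abs(mz_max - config.mz_max) > 1e-9:
            raise ValueError(
                f"{path}: stale cache (limits {limits}, mz_max {mz_max}) "
                f"does not match config (limits {want}, mz_max {config.mz_max})"
            )
    counts = np.loadtxt(path, dtype=np.int32, delimiter="\t", skiprows=2, ndmin=2)
    return FormulaCache(counts, limits, mz_max)
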