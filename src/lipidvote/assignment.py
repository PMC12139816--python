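"""Isotopologue-resolved elemental-formula assignment of consensus peaks.

Every consensus peak seeds candidate (formula, adduct) hypotheses from the
mass-sorted cache; each candidate is extended along the isotopologue series
its sample's labeling scheme allows (natural ¹³C everywhere; tracer ¹³C, ¹⁵N
or ²H in labeled samples) by looking for peaks at the expected mass spacings.
Candidates are scored with an e-value in [0, 1]:

    e = 1 − (∏_i exp(−z_i²/2))^(1/k) · α^m

where z_i is the ppm deviation of matched peak i divided by the calibration
width, k is the number of matched peaks (so the survival term is the geometric
mean and extra matched evidence never worsens the score), m counts
expected-but-unmatched isotopologues (natural relative intensity above the
detection floor), and α = 0.5 halves the survival term per missing peak.  A
perfect match scores e = 0.  Candidates with e ≤ 0.1 and monoisotopic m/z
within range are kept; formulas with any lipid or metabolite classification
get their (1 − e) score doubled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ADDUCT_DELTA, ADDUCTS, Formula, ISOTOPE_DELTA, formula_to_string
from .cache import AssignmentConfig, FormulaCache
from .consensus import SampleSpectrum
from .isotopes import TRACER_ISOTOPES, natural_envelope
from .library import LipidLibrary, NOT_CATEGORIZED, NOT_LIPID

HeavyKey = tuple[int, int, int]  # (n 13C, n 15N, n 2H)
MONO: HeavyKey = (0, 0, 0)

_ISO_INDEX = {"13C": 0, "15N": 1, "2H": 2}
_ISO_ELEMENT_INDEX = {"13C": 0, "15N": 2, "2H": 1}  # index into Formula


@dataclass
class MatchedPeak:
    peak_id: int
    mz: float
    intensity: float
    ppm_dev: float


@dataclass
class AssignmentCandidate:
    sample_id: str
    emf: Formula
    adduct: str
    mono_mz: float
    matched: dict[HeavyKey, MatchedPeak]
    n_missing: int
    evalue: float = math.nan
    score: float = math.nan
    categories: frozenset[str] = field(default_factory=frozenset)

    @property
    def formula(self) -> str:
        return formula_to_string(self.emf)

    @property
    def peak_ids(self) -> frozenset[int]:
        return frozenset(m.peak_id for m in self.matched.values())

    @property
    def classified(self) -> bool:
        # a NOT_LIPID hit is still a (metabolite) library classification
        return bool(self.categories - {NOT_CATEGORIZED})


def allowed_isotopes(labeling: str) -> tuple[str, ...]:
    """Isotopologue series searched under a labeling scheme.

    Natural ¹³C series are searched for every scheme; tracer isotopes add
    their own series.
    """
    isos = list(TRACER_ISOTOPES[labeling])
    if "13C" not in isos:
        isos.append("13C")
    return tuple(sorted(isos))


def score_assignment(
    candidate: AssignmentCandidate, config: AssignmentConfig
) -> tuple[float, float]:
    """(e-value, score) for a candidate; see the module docstring for the model."""
    if not candidate.matched:
        raise ValueError("candidate has no matched isotopologues")
    log_surv = 0.0
    for m in candidate.matched.values():
        z = m.ppm_dev / config.ppm_sigma0
        log_surv += -0.5 * z * z
    log_surv /= len(candidate.matched)
    surv = math.exp(log_surv) * config.missing_alpha**candidate.n_missing
    evalue = min(1.0, max(0.0, 1.0 - surv))
    weight = config.classified_weight if candidate.classified else 1.0
    return evalue, (1.0 - evalue) * weight


def classify_emf(emf: Formula, library: LipidLibrary) -> frozenset[str]:
    """Exact-formula category lookup (see :meth:`LipidLibrary.classify`)."""
    return library.classify(emf)


def _nearest_within(
    mz_sorted: np.ndarray, target: float, ppm_tol: float
) -> int | None:
    """Index of the peak closest to target within ppm_tol, or None."""
    i = int(np.searchsorted(mz_sorted, target))
    best, best_err = None, ppm_tol
    for j in (i - 1, i):
        if 0 <= j < mz_sorted.size:
            err = abs(mz_sorted[j] - target) / target * 1e6
            if err <= best_err:
                best, best_err = j, err
    return best


def search_sample(
    spectrum: SampleSpectrum,
    cache: FormulaCache,
    config: AssignmentConfig,
    library: LipidLibrary,
    brute_force: bool = False,
) -> list[AssignmentCandidate]:
    """Assign every consensus peak of one sample against the formula cache.

    ``brute_force=True`` replaces the binary search over the mass-sorted cache
    with a linear scan; results are identical and the flag exists so tests can
    assert that equivalence.
    """
    if len(spectrum) == 0:
        return []
    labeling = spectrum.meta.labeling
    isos = allowed_isotopes(labeling)
    peaks = spectrum.peaks
    mz_arr = np.array([p.mz for p in peaks])
    seen: set[tuple[Formula, str]] = set()
    out: list[AssignmentCandidate] = []

    for seed in peaks:
        if seed.mz > config.mz_max:
            continue
        half = seed.mz * config.ppm_tol * 1e-6
        for adduct in ADDUCTS:
            lo = seed.mz - half - ADDUCT_DELTA[adduct]
            hi = seed.mz + half - ADDUCT_DELTA[adduct]
            if hi <= 0:
                continue
            for idx in cache.window(lo, hi, brute_force=brute_force):
                emf: Formula = tuple(int(x) for x in cache.counts[idx])
                key = (emf, adduct)
                if key in seen:
                    continue
                seen.add(key)
                cand = _evaluate_candidate(
                    emf, float(cache.mass[idx]), adduct, peaks, mz_arr, isos, config
                )
                if cand is None:
                    continue
                cand.sample_id = spectrum.meta.sample_id
                cand.categories = classify_emf(emf, library)
                cand.evalue, cand.score = score_assignment(cand, config)
                if cand.evalue <= config.evalue_max:
                    out.append(cand)
    out.sort(key=lambda c: (c.mono_mz, c.adduct, c.emf))
    return out


def _evaluate_candidate(
    emf: Formula,
    neutral_mass: float,
    adduct: str,
    peaks: list,
    mz_arr: np.ndarray,
    isos: tuple[str, ...],
    config: AssignmentConfig,
) -> AssignmentCandidate | None:
    mono_mz = neutral_mass + ADDUCT_DELTA[adduct]
    if mono_mz > config.mz_max:
        return None
    mono_idx = _nearest_within(mz_arr, mono_mz, config.ppm_tol)
    if mono_idx is None:
        return None
    matched: dict[HeavyKey, MatchedPeak] = {}

    def add(heavy: HeavyKey, theo: float, j: int):
        p = peaks[j]
        matched[heavy] = MatchedPeak(
            p.peak_id, p.mz, p.intensity, (p.mz - theo) / theo * 1e6
        )

    add(MONO, mono_mz, mono_idx)
    # extend single-isotope chains by expected spacings
    for iso in isos:
        n_avail = emf[_ISO_ELEMENT_INDEX[iso]]
        for shift in range(1, min(n_avail, config.max_isotopologue_shift) + 1):
            theo = mono_mz + shift * ISOTOPE_DELTA[iso]
            j = _nearest_within(mz_arr, theo, config.ppm_tol)
            if j is None:
                continue
            heavy = [0, 0, 0]
            heavy[_ISO_INDEX[iso]] = shift
            add(tuple(heavy), theo, j)

    # expected-but-missing: natural envelope above the detection floor
    env = natural_envelope(emf, config.max_isotopologue_shift)
    n_missing = 0
    for shift in range(1, config.max_isotopologue_shift + 1):
        if env[0] > 0 and env[shift] / env[0] >= config.detection_floor:
            key = (shift, 0, 0)
            if key not in matched:
                n_missing += 1
    return AssignmentCandidate(
        sample_id="",
        emf=emf,
        adduct=adduct,
        mono_mz=mono_mz,
        matched=matched,
        n_missing=n_missing,
    )
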