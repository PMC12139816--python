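"""Isotopologue envelopes and natural-abundance correction.

The pipeline tracks three heavy isotopes — ¹³C, ¹⁵N and ²H — matching the
labeling schemes of stable-isotope-resolved lipidomics (¹³C-glucose,
¹³C-serine/¹⁵N-glutamine, ²H tracers, or unlabeled).  Natural abundance is
modeled for ¹³C and ¹⁵N by default; natural ²H and ¹⁸O are negligible at the
envelope depths used here and are off by default but can be switched on.

Atoms are treated as independent Bernoulli draws, so per-isotope envelopes are
binomial and multi-isotope envelopes are their convolution.  A traced element
in a labeled sample is modeled at the tracer enrichment (which replaces, not
adds to, its natural abundance); all other elements stay at natural abundance.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import nnls

from .chem import (
    ELEMENTS,
    Formula,
    ISOTOPE_ELEMENT,
    NATURAL_ABUNDANCE,
    formula_to_string,
)

LABELING_SCHEMES: tuple[str, ...] = ("unlabeled", "C13", "C13_N15", "H2")

#: heavy isotopes introduced by each labeling scheme
TRACER_ISOTOPES: dict[str, tuple[str, ...]] = {
    "unlabeled": (),
    "C13": ("13C",),
    "C13_N15": ("13C", "15N"),
    "H2": ("2H",),
}

DEFAULT_NATURAL_ISOTOPES: tuple[str, ...] = ("13C", "15N")


def _check_elements(elements: Formula) -> None:
    if any(n < 0 for n in elements):
        raise ValueError(f"negative element count in {elements}")


def _per_isotope_pmf(n_atoms: int, p: float, max_heavy: int) -> np.ndarray:
    """Binomial pmf over 0..max_heavy heavy substitutions (truncated, not renormalized)."""
    pmf = np.zeros(max_heavy + 1)
    if p < 1e-300 or n_atoms == 0:  # scipy's pmf overflows on subnormal p
        pmf[0] = 1.0
        return pmf
    k = np.arange(min(n_atoms, max_heavy) + 1)
    pmf[: k.size] = stats.binom.pmf(k, n_atoms, p)
    return pmf


def isotopologue_distribution(
    elements: Formula,
    labeling: str,
    enrichment: float = 0.0,
    max_heavy: int = 4,
    natural_isotopes: tuple[str, ...] = DEFAULT_NATURAL_ISOTOPES,
) -> dict[tuple[int, int, int], float]:
    """Joint distribution over (¹³C, ¹⁵N, ²H) substitution counts.

    Returns a dict mapping ``(n13C, n15N, n2H)`` to probability, truncated to a
    total of ``max_heavy`` substitutions and renormalized.  Only isotopes that
    are either traced under ``labeling`` or listed in ``natural_isotopes``
    can be non-zero.
    """
    _check_elements(elements)
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError(f"enrichment {enrichment} outside [0, 1]")
    if labeling not in LABELING_SCHEMES:
        raise ValueError(f"unknown labeling scheme {labeling!r}")
    traced = TRACER_ISOTOPES[labeling]
    pmfs = []
    for iso in ("13C", "15N", "2H"):
        n_atoms = elements[ELEMENTS.index(ISOTOPE_ELEMENT[iso])]
        if iso in traced:
            p = enrichment
        elif iso in natural_isotopes:
            p = NATURAL_ABUNDANCE[iso]
        else:
            p = 0.0
        pmfs.append(_per_isotope_pmf(n_atoms, p, max_heavy))
    joint: dict[tuple[int, int, int], float] = {}
    for c in range(max_heavy + 1):
        if pmfs[0][c] == 0.0 and c > 0:
            continue
        for n in range(max_heavy + 1 - c):
            if pmfs[1][n] == 0.0 and n > 0:
                continue
            for h in range(max_heavy + 1 - c - n):
                p = pmfs[0][c] * pmfs[1][n] * pmfs[2][h]
                if p > 0.0:
                    joint[(c, n, h)] = p
    total = sum(joint.values())
    if total <= 0.0:
        raise ValueError(f"degenerate envelope for {formula_to_string(elements)}")
    return {k: v / total for k, v in joint.items()}


def isotope_envelope(
    elements: Formula,
    labeling: str = "unlabeled",
    enrichment: float = 0.0,
    max_heavy: int = 4,
    natural_isotopes: tuple[str, ...] = DEFAULT_NATURAL_ISOTOPES,
) -> np.ndarray:
    """Probability of 0..max_heavy total heavy substitutions, summing to 1.

    Marginal of :func:`isotopologue_distribution` over the total substitution
    count (natural-abundance binomials convolved with the tracer binomial).
    """
    joint = isotopologue_distribution(
        elements, labeling, enrichment, max_heavy, natural_isotopes
    )
    env = np.zeros(max_heavy + 1)
    for (c, n, h), p in joint.items():
        env[c + n + h] += p
    return env


def natural_envelope(
    elements: Formula,
    max_shift: int,
    natural_isotopes: tuple[str, ...] = DEFAULT_NATURAL_ISOTOPES,
) -> np.ndarray:
    """Unlabeled envelope over shifts 0..max_shift, truncated (NOT renormalized).

    Entry i is the probability that a molecule carries exactly i natural heavy
    substitutions among the modeled isotopes.
    """
    _check_elements(elements)
    env = np.ones(1)
    for iso in natural_isotopes:
        n_atoms = elements[ELEMENTS.index(ISOTOPE_ELEMENT[iso])]
        pmf = _per_isotope_pmf(n_atoms, NATURAL_ABUNDANCE[iso], max_shift)
        env = np.convolve(env, pmf)[: max_shift + 1]
    out = np.zeros(max_shift + 1)
    out[: env.size] = env
    return out


def natural_abundance_correct(
    observed: np.ndarray,
    elements: Formula,
    labeling: str = "C13",
    natural_isotopes: tuple[str, ...] = DEFAULT_NATURAL_ISOTOPES,
) -> np.ndarray:
    """Remove natural-abundance signal from an observed isotopologue vector.

    ``observed[i]`` is the intensity at tracer shift i (0..k).  The correction
    builds the lower-triangular matrix whose column j is the truncated natural
    envelope of a species carrying j tracer substitutions (j traced atoms are
    tracer-derived and no longer draw from natural abundance), and solves for
    the tracer-only intensities by non-negative least squares.

    For the ``C13`` and ``C13_N15`` schemes the traced element is carbon; for
    ``H2`` it is hydrogen.  Unlabeled samples are corrected against a ¹³C
    tracer axis, which simply collapses a purely natural envelope onto shift 0.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.ndim != 1:
        raise ValueError("observed must be a 1-D intensity vector")
    if np.any(observed < 0):
        raise ValueError("observed intensities must be non-negative")
    k = observed.size - 1
    if k == 0:  # only the monoisotopic species observed: nothing to correct
        return observed.copy()
    traced_iso = "2H" if labeling == "H2" else "13C"
    traced_el = ISOTOPE_ELEMENT[traced_iso]
    n_traced = elements[ELEMENTS.index(traced_el)]
    if k > n_traced:
        raise ValueError(
            f"{k} tracer shifts exceed {traced_el} count {n_traced} "
            f"of {formula_to_string(elements)}"
        )
    mat = np.zeros((k + 1, k + 1))
    el_idx = ELEMENTS.index(traced_el)
    for j in range(k + 1):
        reduced = list(elements)
        reduced[el_idx] = n_traced - j
        env = natural_envelope(tuple(reduced), k - j, natural_isotopes)
        mat[j:, j] = env
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"ill-conditioned natural-abundance matrix for {formula_to_string(elements)}"
        )
    corrected, _ = nnls(mat, observed)
    return corrected


def labeled_fraction(corrected: np.ndarray) -> float:
    """Fraction of total signal in tracer shifts ≥ 1: labeled / total species.

    Returns NaN for an all-zero vector.
    """
    corrected = np.asarray(corrected, dtype=float)
    if np.any(corrected < 0):
        raise ValueError("corrected intensities must be non-negative")
    total = corrected.sum()
    if total <= 0:
        return float("nan")
    return float(corrected[1:].sum() / total)
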