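import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipidvote.assignment import AssignmentCandidate, MatchedPeak
from lipidvote.library import LipidLibrary, LipidLibraryEntry, default_library
from lipidvote.chem import formula_from_string

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library() -> LipidLibrary:
    return default_library()


def make_tiny_library() -> LipidLibrary:
    """Eight lipids + two decoys spanning all five categories."""
    rows = [
        ("palmitic acid", "C16H32O2", "FA"),
        ("oleic acid", "C18H34O2", "FA"),
        ("PC 34:1", "C42H82NO8P", "GP"),
        ("PE 34:1", "C39H76NO8P", "GP"),
        ("SM d18:1/16:0", "C39H79N2O6P", "SP"),
        ("Cer d18:1/16:0", "C34H67NO3", "SP"),
        ("squalene", "C30H50", "PR"),
        ("naringenin", "C15H12O5", "PK"),
        ("glucose", "C6H12O6", "NONLIPID"),
        ("glutamine", "C5H10N2O3", "NONLIPID"),
    ]
    return LipidLibrary(
        [
            LipidLibraryEntry(name=n, category=c, elements=formula_from_string(f))
            for n, f, c in rows
        ]
    )


@pytest.fixture(scope="session")
def tiny_library() -> LipidLibrary:
    return make_tiny_library()


def make_candidate(
    sample_id: str,
    formula: str,
    adduct: str = "H",
    peak_ids: tuple[int, ...] = (0,),
    score: float = 1.0,
    evalue: float = 0.0,
    categories: frozenset[str] = frozenset({"NOT_CATEGORIZED"}),
    mzs: tuple[float, ...] | None = None,
    intensities: tuple[float, ...] | None = None,
) -> AssignmentCandidate:
    """Hand-built candidate for voting tests: peak i maps to isotopologue
    (i, 0, 0), so peak_ids double as the isotopologue ladder."""
    from lipidvote.chem import formula_from_string as ffs

    mzs = mzs or tuple(500.0 + i * 1.0033548 for i in range(len(peak_ids)))
    intensities = intensities or tuple(1000.0 / (i + 1) for i in range(len(peak_ids)))
    matched = {
        (i, 0, 0): MatchedPeak(pid, mz, inten, 0.0)
        for i, (pid, mz, inten) in enumerate(zip(peak_ids, mzs, intensities))
    }
    return AssignmentCandidate(
        sample_id=sample_id,
        emf=ffs(formula),
        adduct=adduct,
        mono_mz=mzs[0],
        matched=matched,
        n_missing=0,
        evalue=evalue,
        score=score,
        categories=categories,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
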