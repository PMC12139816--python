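"""Synthetic DI-FTMS study generator.

Emulates a two-condition, three-block-group direct-infusion lipidomics study:
each library entry is spiked into every sample as an adduct-shifted
isotopologue series with multiplicative log-normal intensity noise, Gaussian
ppm-scale m/z error per scan, and Bernoulli peak dropout.  Case samples carry
category-level log2 abundance shifts on top of an entry-level baseline.  The
exact generated abundances are recorded in a truth table so downstream stages
can be scored against ground truth.

The default design is 30 samples = 2 conditions x 3 block groups x 5
replicates, with labeling assigned per block group (group 1 unlabeled, group 2
13C, group 3 13C+15N), mirroring a mixed-labeling infusion study after
outlier removal.  Everything is a pure function of (library, design, effects,
config) including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import imf_mz
from .isotopes import isotopologue_distribution
from .library import CATEGORIES, LipidLibrary
from .study import Sample, SampleMeta, Scan, Study

HEAVY_KEYS = ("13C", "15N", "2H")


@dataclass(frozen=True)
class EffectModel:
    """Case-vs-control effect structure on the log2 abundance scale."""

    category_log2_shift: dict[str, float] = field(default_factory=dict)
    emf_sd: float = 0.5
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0

    def __post_init__(self):
        if self.emf_sd <= 0 or self.baseline_log2_sd <= 0:
            raise ValueError("emf_sd and baseline_log2_sd must be > 0")

    def shift(self, category: str) -> float:
        return self.category_log2_shift.get(category, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument/measurement noise model for the generator.

    ppm_sigma is the per-scan Gaussian m/z error (ppm); dropout_prob the
    per-peak-per-scan Bernoulli dropout; intensity_cv the log-normal
    multiplicative intensity noise.  Labeled samples follow a two-pool model:
    a fraction ``tracer_pool_fraction`` of each species is newly synthesized
    with per-atom enrichment ``tracer_enrichment`` in the traced element(s)
    (its envelope rendered to full binomial depth), the remainder is
    pre-existing material with a natural-abundance envelope.  ``max_heavy``
    bounds only the natural-abundance envelope depth.
    """

    seed: int = 0
    ppm_sigma: float = 2.0
    dropout_prob: float = 0.1
    intensity_cv: float = 0.2
    adduct_weights: dict[str, float] = field(
        default_factory=lambda: {"H": 0.7, "Na": 0.15, "NH4": 0.1, "K": 0.05}
    )
    tracer_enrichment: float = 0.25
    tracer_pool_fraction: float = 0.3
    max_heavy: int = 3
    secondary_adduct_prob: float = 0.3
    secondary_adduct_fraction: float = 0.25
    min_envelope_prob: float = 0.01
    intensity_scale: float = 1.0

    def __post_init__(self):
        w = sum(self.adduct_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"adduct_weights sum to {w}, expected 1")
        for name, p in (
            ("dropout_prob", self.dropout_prob),
            ("tracer_enrichment", self.tracer_enrichment),
            ("tracer_pool_fraction", self.tracer_pool_fraction),
            ("secondary_adduct_prob", self.secondary_adduct_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ppm_sigma < 0 or self.intensity_cv < 0:
            raise ValueError("ppm_sigma and intensity_cv must be >= 0")


@dataclass
class TruthTable:
    """Ground truth: exact linear abundance per (sample, entry), plus the
    realized per-category mean log2 case-vs-control shift."""

    table: pd.DataFrame  # columns: sample_id, name, category, abundance
    realized_shift: dict[str, float]

    def abundances(self, category: str | None = None) -> pd.DataFrame:
        t = self.table
        return t if category is None else t[t.category == category]


def default_design(
    n_per_cell: int = 5,
    n_scans: int = 5,
    block_labeling: dict[int, str] | None = None,
) -> list[SampleMeta]:
    """2 conditions x 3 block groups x n_per_cell replicates (30 by default)."""
    block_labeling = block_labeling or {1: "unlabeled", 2: "C13", 3: "C13_N15"}
    design = []
    for condition in ("case", "control"):
        for group in (1, 2, 3):
            for r in range(1, n_per_cell + 1):
                design.append(
                    SampleMeta(
                        sample_id=f"{condition}_g{group}_r{r}",
                        condition=condition,
                        block_group=group,
                        labeling=block_labeling[group],
                        n_scans=n_scans,
                    )
                )
    return design


def simulate_study(
    library: LipidLibrary,
    design: list[SampleMeta],
    effects: EffectModel,
    config: SimulationConfig,
    study_id: str = "synthetic",
) -> tuple[Study, TruthTable]:
    """Generate scans and ground truth for a full study.

    Deterministic given (library, design, effects, config): reruns with the
    same arguments produce byte-identical peak lists.
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    conditions = {m.condition for m in design}
    if not {"case", "control"} <= conditions:
        raise ValueError("design needs at least one sample per condition")
    rng = np.random.default_rng(config.seed)
    entries = list(library)
    baselines = rng.normal(effects.baseline_log2_mean, effects.baseline_log2_sd, len(entries))

    # per-entry isotopologue templates are labeling-dependent; cache per scheme
    env_cache: dict[tuple[str, int], list[tuple[dict[str, int], float]]] = {}

    def envelope(entry_idx: int, labeling: str):
        key = (labeling, entry_idx)
        if key not in env_cache:
            elements = entries[entry_idx].elements
            natural = isotopologue_distribution(
                elements, "unlabeled", 0.0, config.max_heavy
            )
            if labeling == "unlabeled" or config.tracer_pool_fraction == 0.0:
                joint = dict(natural)
            else:
                # two-pool mixture: pre-existing natural + newly synthesized
                # enriched material at full binomial envelope depth
                depth = _tracer_depth(elements, labeling, config.tracer_enrichment)
                labeled = isotopologue_distribution(
                    elements, labeling, config.tracer_enrichment, depth
                )
                pool = config.tracer_pool_fraction
                joint = {k: (1.0 - pool) * p for k, p in natural.items()}
                for k, p in labeled.items():
                    joint[k] = joint.get(k, 0.0) + pool * p
            total = sum(p for p in joint.values() if p >= config.min_envelope_prob)
            comps = [
                ({"13C": c, "15N": n, "2H": h}, p / total)
                for (c, n, h), p in sorted(joint.items())
                if p >= config.min_envelope_prob
            ]
            env_cache[key] = comps
        return env_cache[key]

    adduct_names = sorted(config.adduct_weights)
    adduct_p = np.array([config.adduct_weights[a] for a in adduct_names])

    truth_rows = []
    samples = []
    for meta in design:
        truth_log2 = np.empty(len(entries))
        scan_peaks: list[list[tuple[float, float]]] = [[] for _ in range(meta.n_scans)]
        for ei, entry in enumerate(entries):
            shift = effects.shift(entry.category) if meta.condition == "case" else 0.0
            log2_ab = baselines[ei] + shift + rng.normal(0.0, effects.emf_sd)
            truth_log2[ei] = log2_ab
            abundance = 2.0**log2_ab * config.intensity_scale
            truth_rows.append((meta.sample_id, entry.name, entry.category, abundance))

            primary = rng.choice(len(adduct_names), p=adduct_p)
            forms = [(adduct_names[primary], 1.0)]
            if rng.random() < config.secondary_adduct_prob and len(adduct_names) > 1:
                others = [a for a in range(len(adduct_names)) if a != primary]
                w = adduct_p[others] / adduct_p[others].sum()
                secondary = others[rng.choice(len(others), p=w)]
                forms = [
                    (adduct_names[primary], 1.0 - config.secondary_adduct_fraction),
                    (adduct_names[secondary], config.secondary_adduct_fraction),
                ]
            comps = envelope(ei, meta.labeling)
            for adduct, frac in forms:
                for heavy, prob in comps:
                    theo = imf_mz(entry.elements, heavy, adduct)
                    base_intensity = abundance * frac * prob
                    for si in range(meta.n_scans):
                        if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
                            continue
                        mz = theo
                        if config.ppm_sigma > 0:
                            mz *= 1.0 + rng.normal(0.0, config.ppm_sigma * 1e-6)
                        inten = base_intensity
                        if config.intensity_cv > 0:
                            inten *= rng.lognormal(0.0, config.intensity_cv)
                        scan_peaks[si].append((mz, inten))
        scans = []
        for si, plist in enumerate(scan_peaks):
            plist.sort()
            mz = np.array([p[0] for p in plist])
            inten = np.array([p[1] for p in plist])
            scans.append(Scan(f"{meta.sample_id}_scan{si + 1}", mz, inten))
        samples.append(Sample(meta, scans))

    table = pd.DataFrame(truth_rows, columns=["sample_id", "name", "category", "abundance"])
    realized = _realized_shifts(table, design)
    return Study(study_id, samples), TruthTable(table, realized)


def _tracer_depth(elements, labeling: str, enrichment: float) -> int:
    """Envelope depth covering ~99.9% of the enriched-pool binomial mass."""
    from scipy import stats as _st

    from .chem import ELEMENTS as _ELS
    from .isotopes import TRACER_ISOTOPES
    from .chem import ISOTOPE_ELEMENT

    depth = 0
    for iso in TRACER_ISOTOPES[labeling]:
        n = elements[_ELS.index(ISOTOPE_ELEMENT[iso])]
        if n == 0 or enrichment == 0.0:
            continue
        depth += int(_st.binom.ppf(0.999, n, enrichment)) + 1
    return max(depth, 1)


def _realized_shifts(table: pd.DataFrame, design: list[SampleMeta]) -> dict[str, float]:
    cond = {m.sample_id: m.condition for m in design}
    t = table.assign(condition=table.sample_id.map(cond), log2=np.log2(table.abundance))
    out = {}
    for cat in CATEGORIES:
        sub = t[t.category == cat]
        if sub.empty:
            continue
        case = sub[sub.condition == "case"].log2.mean()
        ctrl = sub[sub.condition == "control"].log2.mean()
        out[cat] = float(case - ctrl)
    return out


def simulate_emf_table(
    library: LipidLibrary,
    design: list[SampleMeta],
    effects: EffectModel,
    seed: int = 0,
    observation_cv: float = 0.1,
):
    """Truth-level shortcut: an EMF x sample log2 intensity table without scan
    rendering.

    Generates the same abundance model as :func:`simulate_study` (entry
    baselines, category shifts, per-sample biological noise) plus log-normal
    measurement noise, and returns it in the quantified-table form the
    statistics stage consumes.  Useful for statistics-level studies where the
    spectral stages would only add runtime, not information.
    """
    from .stats import EMFIntensityTable
    import pandas as pd  # noqa: F811 - local to avoid cycle at import time

    if len(library) == 0 or not design:
        raise ValueError("library and design must be non-empty")
    rng = np.random.default_rng(seed)
    entries = list(library)
    sample_ids = [m.sample_id for m in design]
    baselines = rng.normal(effects.baseline_log2_mean, effects.baseline_log2_sd, len(entries))
    vals = np.empty((len(entries), len(design)))
    for j, meta in enumerate(design):
        for i, entry in enumerate(entries):
            shift = effects.shift(entry.category) if meta.condition == "case" else 0.0
            log2_ab = baselines[i] + shift + rng.normal(0.0, effects.emf_sd)
            if observation_cv > 0:
                log2_ab += np.log2(rng.lognormal(0.0, observation_cv))
            vals[i, j] = log2_ab
    names = [e.formula for e in entries]
    # duplicate formulas (rare) get suffixed so the index stays unique
    seen: dict[str, int] = {}
    for k, n in enumerate(names):
        if n in seen:
            names[k] = f"{n}#{k}"
        seen[n] = k
    values = pd.DataFrame(vals, index=names, columns=sample_ids)
    imputed = pd.DataFrame(False, index=names, columns=sample_ids)
    # decoy entries carry the table-level NOT_LIPID label so the category
    # statistics exclude them, mirroring the voted pipeline output
    cats = ["NOT_LIPID" if e.category == "NONLIPID" else e.category for e in entries]
    category = pd.Series(cats, index=names, name="category")
    emf_mz = pd.Series([e.neutral_mass + 1.00728 for e in entries], index=names, name="emf_mz")
    return EMFIntensityTable(values=values, imputed=imputed, category=category, emf_mz=emf_mz)


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path, design: list[SampleMeta]) -> TruthTable:
    table = pd.read_csv(path, sep="\t")
    return TruthTable(table, _realized_shifts(table, design))
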