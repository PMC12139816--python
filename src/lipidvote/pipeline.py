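"""End-to-end orchestration of the five pipeline stages.

Stages: ``simulate`` (synthetic study) -> ``peaks`` (consensus peak lists) ->
``assign`` (formula candidates) -> ``vote`` (sudo_EMFs) -> ``stats``
(differential, category, correlation tables and figures).  Each stage writes
self-describing artifacts carrying the tool version, a hash of the effective
configuration and the seed; chaining across mismatched config hashes is
refused unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import AssignmentCandidate, MatchedPeak, search_sample
from .cache import AssignmentConfig, FormulaCache, generate_cache
from .consensus import (
    SampleSpectrum,
    build_sample_spectrum,
    export_peak_characteristics,
    import_peak_characteristics,
)
from .library import LipidLibrary, default_library, read_library
from .stats import (
    StatsConfig,
    aggregate_emf_log2,
    category_binomial,
    compute_fold_change,
    fit_blocked_model,
    normalize_and_impute,
    quantify_sudo_emfs,
    weighted_pairwise_correlation,
)
from .study import Study, read_peaklists, write_peaklists
from .synthetic import (
    EffectModel,
    SimulationConfig,
    default_design,
    simulate_study,
    write_truth_table,
)
from .voting import (
    VotingConfig,
    build_group_emfs,
    determine_mz_cutoffs,
    merge_and_revote,
    vote_sudo_emfs,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "peaks", "assign", "vote", "stats")


class ConfigError(ValueError):
    """Unknown or invalid configuration key (CLI exit code 3)."""


class MissingInputError(FileNotFoundError):
    """A required input artifact is absent (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("lipidvote_out")
    library_path: str | None = None  # None -> bundled library
    n_per_cell: int = 5
    n_scans: int = 5
    min_intensity: float = 0.0
    consensus_ppm_tol: float = 5.0
    effects: EffectModel = field(default_factory=EffectModel)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    voting: VotingConfig = field(default_factory=VotingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    force: bool = False

    def library(self) -> LipidLibrary:
        if self.library_path is None:
            return default_library()
        p = Path(self.library_path)
        if not p.exists():
            raise MissingInputError(str(p))
        return read_library(p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        # the hash fingerprints the scientific configuration, not where the
        # artifacts happen to live
        d.pop("force", None)
        d.pop("out_dir", None)
        return hashlib.md5(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


_SECTION_TYPES = {
    "effects": EffectModel,
    "simulation": SimulationConfig,
    "assignment": AssignmentConfig,
    "voting": VotingConfig,
    "stats": StatsConfig,
}
_SCALAR_KEYS = {
    "seed",
    "out_dir",
    "library_path",
    "n_per_cell",
    "n_scans",
    "min_intensity",
    "consensus_ppm_tol",
    "force",
}


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build a PipelineConfig from a (YAML) mapping, rejecting unknown keys."""
    kwargs: dict = {}
    for key, val in (doc or {}).items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val) - valid
            if unknown:
                raise ConfigError(f"unknown keys {sorted(unknown)} in section {key!r}")
            kwargs[key] = cls(**val)
        elif key in _SCALAR_KEYS:
            kwargs[key] = Path(val) if key == "out_dir" else val
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    p = Path(path)
    if not p.exists():
        raise MissingInputError(str(p))
    return config_from_dict(yaml.safe_load(p.read_text()) or {})


def _header(cfg: PipelineConfig) -> str:
    return f"# lipidvote {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index)


def _check_hash(meta: dict, cfg: PipelineConfig, path: Path) -> None:
    h = meta.get("config_hash")
    if h is not None and h != cfg.config_hash() and not cfg.force:
        raise ConfigError(
            f"{path}: written under config hash {h}, current is {cfg.config_hash()}; "
            "rerun upstream stages or pass force"
        )


# ---------------------------------------------------------------- candidates IO


def _candidates_to_json(per_sample: dict[str, list[AssignmentCandidate]], cfg) -> dict:
    def enc(c: AssignmentCandidate) -> dict:
        return {
            "emf": list(c.emf),
            "adduct": c.adduct,
            "mono_mz": round(c.mono_mz, 6),
            "evalue": round(c.evalue, 8),
            "score": round(c.score, 8),
            "n_missing": c.n_missing,
            "categories": sorted(c.categories),
            "matched": [
                {"heavy": list(h), "peak_id": m.peak_id, "mz": round(m.mz, 6),
                 "intensity": round(m.intensity, 4), "ppm_dev": round(m.ppm_dev, 5)}
                for h, m in sorted(c.matched.items())
            ],
        }

    return {
        "_meta": {"version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed},
        "samples": {sid: [enc(c) for c in cands] for sid, cands in per_sample.items()},
    }


def _candidates_from_json(doc: dict) -> dict[str, list[AssignmentCandidate]]:
    out: dict[str, list[AssignmentCandidate]] = {}
    for sid, cands in doc["samples"].items():
        lst = []
        for c in cands:
            matched = {
                tuple(m["heavy"]): MatchedPeak(m["peak_id"], m["mz"], m["intensity"], m["ppm_dev"])
                for m in c["matched"]
            }
            lst.append(
                AssignmentCandidate(
                    sample_id=sid,
                    emf=tuple(c["emf"]),
                    adduct=c["adduct"],
                    mono_mz=c["mono_mz"],
                    matched=matched,
                    n_missing=c["n_missing"],
                    evalue=c["evalue"],
                    score=c["score"],
                    categories=frozenset(c["categories"]),
                )
            )
        out[sid] = lst
    return out


# ---------------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig) -> Study:
    library = cfg.library()
    design = default_design(cfg.n_per_cell, cfg.n_scans)
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    study, truth = simulate_study(library, design, cfg.effects, sim)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    write_peaklists(study, cfg.out_dir / "peaklists.json")
    write_truth_table(truth, cfg.out_dir / "truth_table.tsv")
    logger.info("simulate: %d samples, %d library entries", len(study.samples), len(library))
    return study


def stage_peaks(cfg: PipelineConfig, study: Study | None = None) -> dict[str, SampleSpectrum]:
    if study is None:
        src = cfg.out_dir / "peaklists.json"
        if not src.exists():
            raise MissingInputError(str(src))
        study = read_peaklists(src)
    peaks_dir = cfg.out_dir / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    spectra = {}
    for sample in study:
        spec = build_sample_spectrum(sample, cfg.min_intensity, cfg.consensus_ppm_tol)
        spectra[sample.meta.sample_id] = spec
        export_peak_characteristics(spec, peaks_dir / f"{sample.meta.sample_id}.json")
    logger.info(
        "peaks: %d samples, median %d consensus peaks",
        len(spectra),
        int(np.median([len(s) for s in spectra.values()])),
    )
    return spectra


def _load_spectra(cfg: PipelineConfig) -> dict[str, SampleSpectrum]:
    peaks_dir = cfg.out_dir / "peaks"
    if not peaks_dir.is_dir():
        raise MissingInputError(str(peaks_dir))
    spectra = {}
    for p in sorted(peaks_dir.glob("*.json")):
        spec = import_peak_characteristics(p)
        spectra[spec.meta.sample_id] = spec
    if not spectra:
        raise MissingInputError(f"{peaks_dir}: no per-sample peak files")
    return spectra


def stage_assign(
    cfg: PipelineConfig,
    spectra: dict[str, SampleSpectrum] | None = None,
    cache: FormulaCache | None = None,
) -> dict[str, list[AssignmentCandidate]]:
    if spectra is None:
        spectra = _load_spectra(cfg)
    if cache is None:
        cache = generate_cache(cfg.assignment)
    library = cfg.library()
    per_sample = {}
    for sid in sorted(spectra):
        per_sample[sid] = search_sample(spectra[sid], cache, cfg.assignment, library)
    (cfg.out_dir).mkdir(parents=True, exist_ok=True)
    with open(cfg.out_dir / "candidates.json", "w") as fh:
        json.dump(_candidates_to_json(per_sample, cfg), fh, separators=(",", ":"))
    rows = [
        {
            "sample_id": sid,
            "formula": c.formula,
            "adduct": c.adduct,
            "mono_mz": round(c.mono_mz, 6),
            "evalue": c.evalue,
            "score": c.score,
            "n_matched": len(c.matched),
            "categories": ";".join(sorted(c.categories)),
        }
        for sid in sorted(per_sample)
        for c in per_sample[sid]
    ]
    _write_tsv(pd.DataFrame(rows), cfg.out_dir / "candidates.tsv", cfg, index=False)
    logger.info("assign: %d candidates over %d samples (cache size %d)",
                sum(map(len, per_sample.values())), len(per_sample), len(cache))
    return per_sample


def stage_vote(
    cfg: PipelineConfig,
    per_sample: dict[str, list[AssignmentCandidate]] | None = None,
    study: Study | None = None,
):
    if per_sample is None:
        src = cfg.out_dir / "candidates.json"
        if not src.exists():
            raise MissingInputError(str(src))
        doc = json.loads(src.read_text())
        _check_hash(doc.get("_meta", {}), cfg, src)
        per_sample = _candidates_from_json(doc)
    metas = _metas(cfg, study)
    cutoffs = determine_mz_cutoffs(per_sample, metas, cfg.voting)
    groups = {sid: build_group_emfs(cands) for sid, cands in per_sample.items() if cands}
    sudos = vote_sudo_emfs(groups, cutoffs, cfg.voting)
    sudos = merge_and_revote(sudos, cutoffs, cfg.voting)
    rows = [
        {
            "emf": ";".join(s.retained_formulas()),
            "emf_mz": round(s.emf_mz, 6),
            "category": s.category,
            "n_samples": s.n_samples,
            "summed_score": max(s.emf_scores.values()),
            "peak_ids": ";".join(f"{sid}:{pid}" for sid, pid in sorted(s.peak_keys)),
        }
        for s in sudos
    ]
    _write_tsv(pd.DataFrame(rows), cfg.out_dir / "sudo_emfs.tsv", cfg, index=False)
    logger.info("vote: %d sudo_EMFs (cutoffs %s)", len(sudos),
                {k: round(v, 3) for k, v in cutoffs.items()})
    return sudos


def _metas(cfg: PipelineConfig, study: Study | None):
    if study is not None:
        return study.metas()
    src = cfg.out_dir / "peaklists.json"
    if src.exists():
        return read_peaklists(src).metas()
    return [s.meta for s in _load_spectra(cfg).values()]


def stage_stats(
    cfg: PipelineConfig,
    sudos=None,
    spectra: dict[str, SampleSpectrum] | None = None,
    study: Study | None = None,
) -> dict:
    if spectra is None:
        spectra = _load_spectra(cfg)
    if sudos is None:
        logger.info("stats: re-deriving sudo_EMFs from stored candidates")
        sudos = stage_vote(cfg, None, study)
    metas = _metas(cfg, study)
    raw = quantify_sudo_emfs(sudos, spectra)
    normalized, mask = normalize_and_impute(raw)
    table = aggregate_emf_log2(normalized, mask, sudos)
    diff = fit_blocked_model(table, metas, cfg.stats)
    fc = compute_fold_change(table, metas, cfg.stats)
    diff["log2_fc"] = fc.log2_fc
    cats = category_binomial(fc, cfg.stats)
    corr = weighted_pairwise_correlation(table)
    _write_tsv(diff, cfg.out_dir / "differential.tsv", cfg)
    _write_tsv(cats, cfg.out_dir / "category_tests.tsv", cfg)
    _write_tsv(corr, cfg.out_dir / "correlation_matrix.tsv", cfg)
    try:
        from .plots import plot_fc_vs_mz, plot_correlation_heatmap

        fig_dir = cfg.out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        plot_fc_vs_mz(fc, fig_dir / "log2fc_vs_mz.png")
        plot_correlation_heatmap(corr, fig_dir / "correlation_heatmap.png")
    except Exception as e:  # plotting must never sink the stats stage
        logger.warning("plotting failed: %s", e)
    logger.info("stats: %d EMFs, %d categories tested", len(diff), len(cats))
    return {"table": table, "differential": diff, "fold_change": fc,
            "categories": cats, "correlation": corr}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order, passing artifacts in memory where
    contiguous and through files otherwise."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    study = spectra = per_sample = sudos = results = None
    for st in ordered:
        if st == "simulate":
            study = stage_simulate(cfg)
        elif st == "peaks":
            spectra = stage_peaks(cfg, study)
        elif st == "assign":
            per_sample = stage_assign(cfg, spectra)
        elif st == "vote":
            sudos = stage_vote(cfg, per_sample, study)
        elif st == "stats":
            results = stage_stats(cfg, sudos, spectra, study)
    return {
        "study": study,
        "spectra": spectra,
        "candidates": per_sample,
        "sudo_emfs": sudos,
        "stats": results,
    }


def write_report(bundle: dict, path: str | Path, cfg: PipelineConfig) -> dict:
    """Human-readable run summary plus a machine-readable JSON twin."""
    path = Path(path)
    lines = [f"lipidvote {__version__} run report (seed {cfg.seed})", "=" * 40]
    rep: dict = {"version": __version__, "seed": cfg.seed,
                 "config_hash": cfg.config_hash(), "missing_stages": []}
    spectra = bundle.get("spectra")
    if spectra:
        n_peaks = int(sum(len(s) for s in spectra.values()))
        rep["n_samples"] = len(spectra)
        rep["n_consensus_peaks"] = n_peaks
        lines.append(f"samples: {len(spectra)}; consensus peaks: {n_peaks}")
    else:
        rep["missing_stages"].append("peaks")
        lines.append("[stage missing: peaks]")
    cands = bundle.get("candidates")
    if cands:
        rep["n_candidates"] = int(sum(len(v) for v in cands.values()))
        lines.append(f"assignment candidates: {rep['n_candidates']}")
    else:
        rep["missing_stages"].append("assign")
        lines.append("[stage missing: assign]")
    sudos = bundle.get("sudo_emfs")
    if sudos is not None:
        rep["n_sudo_emfs"] = len(sudos)
        lines.append(f"sudo_EMFs: {len(sudos)}")
    else:
        rep["missing_stages"].append("vote")
        lines.append("[stage missing: vote]")
    stats_res = bundle.get("stats")
    if stats_res is not None:
        cats = stats_res["categories"].reset_index()
        rep["categories"] = cats.to_dict(orient="records")
        for _, row in cats.iterrows():
            lines.append(
                f"  {row.category}: +{int(row.n_pos)}/-{int(row.n_neg)} "
                f"p_raw={row.p_raw:.3g} p_adj={row.p_adj:.3g}"
            )
        rep["n_significant_emfs"] = int(stats_res["differential"].significant.sum())
        lines.append(f"significant EMFs (raw p <= 0.1): {rep['n_significant_emfs']}")
    else:
        rep["missing_stages"].append("stats")
        lines.append("[stage missing: stats]")
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(".json").write_text(json.dumps(rep, indent=1))
    return rep
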