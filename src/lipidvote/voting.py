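"""Cross-sample EMF voting: group_EMFs, sudo_EMFs, retention and category votes.

Per sample, assignment candidates that touch a common set of peaks — plus any
candidate with the same base formula under a different adduct — are unioned
into a *group_EMF* (connected components).  Across samples, group_EMFs sharing
candidate formulas are iteratively intersected and unioned into *sudo_EMFs*:
the globally top-scoring formula seeds a sudo_EMF that unions every group_EMF
carrying it (at most one per sample), those group_EMFs leave the pool, and the
extraction repeats on the remainder — so each group_EMF belongs to exactly one
sudo_EMF and two features bridged by a shared decoy formula cannot annihilate
each other.  Within a sudo_EMF, per-formula scores are summed across member
samples and formulas within ``retain_fraction`` (default 90%) of the maximum
are retained.  Member samples left without a
retained formula are rescued only if their peaks agree with the cross-sample
consensus in both m/z (within the labeling-group cutoff) and relative
intensity ordering of the top isotopologues.  Isotopologues whose cross-sample
m/z standard deviation exceeds the cutoff lose their most deviant peaks, and
candidates that lose their monoisotopic peak are removed.  Finally sudo_EMFs
sharing at least ``merge_fraction`` of their peaks are merged and voting
repeated to a fixed point.

All merge loops process items in canonical (formula, sample) order, so the
result is invariant to input permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assignment import MONO, AssignmentCandidate, HeavyKey
from .chem import Formula, formula_to_string
from .library import NOT_CATEGORIZED, NOT_LIPID
from .study import SampleMeta

logger = logging.getLogger(__name__)

MULTIPLE = "multiple"

PeakKey = tuple[str, int]  # (sample_id, peak_id)


@dataclass(frozen=True)
class VotingConfig:
    retain_fraction: float = 0.9
    merge_fraction: float = 0.5
    mz_sd_percentile: float = 95.0
    mz_sd_floor_ppm: float = 0.5
    default_cutoff_ppm: float = 2.0
    rescue_top_k: int = 3

    def __post_init__(self):
        for name in ("retain_fraction", "merge_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class GroupEMF:
    """All candidates of one sample sharing a common peak set (or base formula)."""

    sample_id: str
    candidates: list[AssignmentCandidate]

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("GroupEMF needs at least one candidate")
        self.candidates.sort(key=lambda c: (c.formula, c.adduct))

    @property
    def peak_ids(self) -> frozenset[int]:
        return frozenset(pid for c in self.candidates for pid in c.peak_ids)

    @property
    def emfs(self) -> frozenset[Formula]:
        return frozenset(c.emf for c in self.candidates)

    @property
    def total_score(self) -> float:
        return sum(c.score for c in self.candidates)

    def best_score(self, emf: Formula) -> float:
        return max((c.score for c in self.candidates if c.emf == emf), default=0.0)

    def min_formula(self) -> str:
        return min(c.formula for c in self.candidates)


@dataclass
class SudoEMF:
    """Cross-sample consensus feature with voted formulas and category."""

    members: dict[str, GroupEMF]
    emf_scores: dict[Formula, float]
    retained_emfs: set[Formula]
    rescued: set[str] = field(default_factory=set)
    category: str = NOT_CATEGORIZED
    emf_mz: float = float("nan")

    @property
    def peak_keys(self) -> frozenset[PeakKey]:
        """Peaks matched by the retained formulas (bridging candidates that
        lost the vote do not define the feature's footprint)."""
        keys = {
            (sid, m.peak_id)
            for sid, g in self.members.items()
            for c in g.candidates
            if c.emf in self.retained_emfs
            for m in c.matched.values()
        }
        if not keys:  # rescued-only members: fall back to all member peaks
            keys = {
                (sid, pid) for sid, g in self.members.items() for pid in g.peak_ids
            }
        return frozenset(keys)

    @property
    def n_samples(self) -> int:
        return len(self.members)

    def retained_formulas(self) -> list[str]:
        return sorted(formula_to_string(e) for e in self.retained_emfs)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_group_emfs(candidates: list[AssignmentCandidate]) -> list[GroupEMF]:
    """Union candidates of one sample into group_EMFs.

    Two candidates join when they share any matched peak or when they carry
    the same base formula under different adducts.
    """
    if not candidates:
        return []
    sample_ids = {c.sample_id for c in candidates}
    if len(sample_ids) != 1:
        raise ValueError("build_group_emfs expects candidates from a single sample")
    cands = sorted(candidates, key=lambda c: (c.formula, c.adduct))
    uf = _UnionFind(len(cands))
    by_peak: dict[int, int] = {}
    by_emf: dict[Formula, int] = {}
    for i, c in enumerate(cands):
        for pid in c.peak_ids:
            if pid in by_peak:
                uf.union(i, by_peak[pid])
            else:
                by_peak[pid] = i
        if c.emf in by_emf:
            uf.union(i, by_emf[c.emf])
        else:
            by_emf[c.emf] = i
    comps: dict[int, list[AssignmentCandidate]] = {}
    for i, c in enumerate(cands):
        comps.setdefault(uf.find(i), []).append(c)
    groups = [GroupEMF(next(iter(sample_ids)), cs) for _, cs in sorted(comps.items())]
    groups.sort(key=lambda g: (g.min_formula(), min(g.peak_ids)))
    return groups


def determine_mz_cutoffs(
    candidates_by_sample: dict[str, list[AssignmentCandidate]],
    metas: list[SampleMeta],
    config: VotingConfig = VotingConfig(),
) -> dict[str, float]:
    """Per-labeling-group ppm cutoff on cross-sample isotopologue m/z spread.

    For every (formula, adduct, isotopologue) observed in >= 2 samples of a
    labeling group, the ppm standard deviation of its matched m/z values is
    computed; the group cutoff is the ``mz_sd_percentile`` of those SDs,
    floored at ``mz_sd_floor_ppm``.  A group with no repeated observations
    falls back to the config default with a warning.
    """
    labeling = {m.sample_id: m.labeling for m in metas}
    groups: dict[str, dict[tuple, list[float]]] = {}
    for sid, cands in candidates_by_sample.items():
        lab = labeling[sid]
        bucket = groups.setdefault(lab, {})
        for c in cands:
            for heavy, m in c.matched.items():
                bucket.setdefault((c.emf, c.adduct, heavy), []).append(m.mz)
    cutoffs: dict[str, float] = {}
    for lab in sorted({m.labeling for m in metas}):
        sds = [
            float(np.std(v, ddof=1) / np.mean(v) * 1e6)
            for v in groups.get(lab, {}).values()
            if len(v) >= 2
        ]
        if not sds:
            logger.warning(
                "labeling group %s has no repeated isotopologues; using default "
                "cutoff %.2f ppm", lab, config.default_cutoff_ppm,
            )
            cutoffs[lab] = config.default_cutoff_ppm
        else:
            cutoffs[lab] = max(
                config.mz_sd_floor_ppm, float(np.percentile(sds, config.mz_sd_percentile))
            )
    return cutoffs


def _ppm_sd(values: list[float]) -> float:
    return float(np.std(values, ddof=1) / np.mean(values) * 1e6)


def _score_and_retain(
    members: dict[str, GroupEMF], retain_fraction: float
) -> tuple[dict[Formula, float], set[Formula]]:
    emf_scores: dict[Formula, float] = {}
    for sid in sorted(members):
        g = members[sid]
        for emf in sorted(g.emfs, key=formula_to_string):
            emf_scores[emf] = emf_scores.get(emf, 0.0) + g.best_score(emf)
    if not emf_scores:
        return {}, set()
    max_score = max(emf_scores.values())
    retained = {e for e, s in emf_scores.items() if s >= retain_fraction * max_score}
    return emf_scores, retained


def _consensus_profile(
    members: dict[str, GroupEMF], retained: set[Formula]
) -> tuple[dict[tuple[str, HeavyKey], float], dict[str, list[HeavyKey]]]:
    """Cross-sample mean m/z per (adduct, isotopologue) and, per adduct, the
    descending-intensity isotopologue order, over retained-formula candidates.
    Adducts are never pooled: the same isotopologue under H+ and Na+ sits
    ~22 Da apart."""
    mzs: dict[tuple[str, HeavyKey], list[float]] = {}
    intens: dict[tuple[str, HeavyKey], list[float]] = {}
    for sid in sorted(members):
        for c in members[sid].candidates:
            if c.emf not in retained:
                continue
            for heavy, m in c.matched.items():
                key = (c.adduct, heavy)
                mzs.setdefault(key, []).append(m.mz)
                intens.setdefault(key, []).append(m.intensity)
    mean_mz = {k: float(np.mean(v)) for k, v in mzs.items()}
    order: dict[str, list[HeavyKey]] = {}
    for (adduct, heavy), v in intens.items():
        order.setdefault(adduct, [])
    for adduct in order:
        keys = [(k, float(np.mean(intens[(adduct, k)])))
                for (a, k) in intens if a == adduct]
        order[adduct] = [k for k, _ in sorted(keys, key=lambda t: (-t[1], t[0]))]
    return mean_mz, order


def _rescue_ok(
    g: GroupEMF,
    mean_mz: dict[tuple[str, HeavyKey], float],
    order: dict[str, list[HeavyKey]],
    cutoff_ppm: float,
    top_k: int,
) -> bool:
    """Peaks match the consensus of the candidate's own adduct by m/z and by
    relative intensity ordering of the top isotopologues."""
    best = max(g.candidates, key=lambda c: c.score)
    top = order.get(best.adduct, [])[:top_k]
    if not top:
        return False
    own = []
    for heavy in top:
        m = best.matched.get(heavy)
        if m is None:
            return False
        ref = mean_mz[(best.adduct, heavy)]
        if abs(m.mz - ref) / ref * 1e6 > cutoff_ppm:
            return False
        own.append((heavy, m.intensity))
    own_order = [h for h, _ in sorted(own, key=lambda t: (-t[1], t[0]))]
    return own_order == top


def _filter_mz_sd(
    members: dict[str, GroupEMF], retained: set[Formula], cutoff_ppm: float
) -> None:
    """Remove isotopologue observations whose cross-sample spread exceeds the
    cutoff; candidates losing their monoisotopic peak are dropped."""
    for emf in sorted(retained, key=formula_to_string):
        by_heavy: dict[tuple[str, HeavyKey], list[tuple[str, AssignmentCandidate]]] = {}
        for sid in sorted(members):
            for c in members[sid].candidates:
                if c.emf != emf:
                    continue
                for heavy in list(c.matched):
                    by_heavy.setdefault((c.adduct, heavy), []).append((sid, c))
        for adduct_heavy in sorted(by_heavy):
            heavy = adduct_heavy[1]
            obs = by_heavy[adduct_heavy]
            while len(obs) > 2:
                vals = [c.matched[heavy].mz for _, c in obs]
                if _ppm_sd(vals) <= cutoff_ppm:
                    break
                med = float(np.median(vals))
                worst = max(range(len(obs)), key=lambda i: abs(vals[i] - med))
                _, cand = obs.pop(worst)
                del cand.matched[heavy]
    for sid in sorted(members):
        g = members[sid]
        keep = [c for c in g.candidates if MONO in c.matched]
        g.candidates = keep


def vote_category(sudo: SudoEMF) -> str:
    """Plurality vote over the categories of the retained formulas.

    NOT_LIPID / NOT_CATEGORIZED votes are discarded first; a strict plurality
    wins, a tie reports "multiple"; with no lipid votes the result is
    NOT_LIPID if any decoy vote existed, else NOT_CATEGORIZED.
    """
    votes: list[str] = []
    had_not_lipid = False
    for emf in sudo.retained_emfs:
        cats = _categories_of(sudo, emf)
        if NOT_LIPID in cats:
            had_not_lipid = True
        votes.extend(c for c in cats if c not in (NOT_LIPID, NOT_CATEGORIZED))
    if not votes:
        return NOT_LIPID if had_not_lipid else NOT_CATEGORIZED
    counts: dict[str, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == best)
    return winners[0] if len(winners) == 1 else MULTIPLE


def _categories_of(sudo: SudoEMF, emf: Formula) -> frozenset[str]:
    for sid in sorted(sudo.members):
        for c in sudo.members[sid].candidates:
            if c.emf == emf:
                return c.categories
    return frozenset({NOT_CATEGORIZED})


def _finalize_sudo(
    members: dict[str, GroupEMF], cutoff_ppm: float, config: VotingConfig
) -> SudoEMF | None:
    """Score, retain, rescue, m/z-SD-filter and categorize one sudo_EMF."""
    emf_scores, retained = _score_and_retain(members, config.retain_fraction)
    if not retained:
        return None
    mean_mz, order = _consensus_profile(members, retained)
    kept: dict[str, GroupEMF] = {}
    rescued: set[str] = set()
    for sid in sorted(members):
        g = members[sid]
        if g.emfs & retained:
            kept[sid] = g
        elif _rescue_ok(g, mean_mz, order, cutoff_ppm, config.rescue_top_k):
            kept[sid] = g
            rescued.add(sid)
    if not kept:
        return None
    _filter_mz_sd(kept, retained, cutoff_ppm)
    surviving = {
        e
        for e in retained
        if any(c.emf == e for g in kept.values() for c in g.candidates)
    }
    kept = {sid: g for sid, g in kept.items() if g.candidates or sid in rescued}
    kept = {sid: g for sid, g in kept.items() if g.candidates}
    if not surviving or not kept:
        logger.info("sudo_EMF lost all retained formulas; dropped")
        return None
    sudo = SudoEMF(
        members=kept,
        emf_scores=emf_scores,
        retained_emfs=surviving,
        rescued=rescued & set(kept),
    )
    mzs = [
        m.mz
        for g in kept.values()
        for c in g.candidates
        if c.emf in surviving
        for m in c.matched.values()
    ]
    sudo.emf_mz = min(mzs) if mzs else float("nan")
    sudo.category = vote_category(sudo)
    return sudo


def _applied_cutoff(cutoffs: dict[str, float]) -> float:
    # the per-labeling-group cutoffs are applied to the whole study together;
    # a mixed-labeling consensus uses the most permissive one
    return max(cutoffs.values()) if cutoffs else 2.0


def vote_sudo_emfs(
    group_emfs_by_sample: dict[str, list[GroupEMF]],
    cutoffs: dict[str, float],
    config: VotingConfig = VotingConfig(),
) -> list[SudoEMF]:
    """Iteratively extract sudo_EMFs from the pooled candidates.

    Each extraction seeds on the formula with the highest cross-sample summed
    score among unconsumed candidates and takes, per sample, the seed's own
    candidates plus every unconsumed candidate sharing a peak with them (one
    hop), so a chain-extension artifact bridging two real features is consumed
    by whichever feature wins it without starving the other.  Samples without
    a member are rescued from the remaining pool when their peaks match the
    consensus by m/z and relative intensity ordering.
    """
    flat: list[AssignmentCandidate] = []
    for sid in sorted(group_emfs_by_sample):
        for g in group_emfs_by_sample[sid]:
            flat.extend(g.candidates)
    cutoff = _applied_cutoff(cutoffs)
    sudos = _extract_sudos(flat, cutoff, config, rescue=True)
    sudos.sort(key=lambda s: (min(map(formula_to_string, s.retained_emfs)), -s.n_samples))
    return sudos


def _extract_sudos(
    candidates: list[AssignmentCandidate],
    cutoff: float,
    config: VotingConfig,
    rescue: bool = False,
) -> list[SudoEMF]:
    import heapq

    pool = sorted(candidates, key=lambda c: (c.sample_id, c.formula, c.adduct))
    alive = [True] * len(pool)
    by_emf: dict[Formula, list[int]] = {}
    peak_map: dict[PeakKey, list[int]] = {}
    for i, c in enumerate(pool):
        by_emf.setdefault(c.emf, []).append(i)
        for pid in c.peak_ids:
            peak_map.setdefault((c.sample_id, pid), []).append(i)

    def current_sum(emf: Formula) -> float:
        best: dict[str, float] = {}
        for i in by_emf.get(emf, ()):
            if alive[i]:
                c = pool[i]
                best[c.sample_id] = max(best.get(c.sample_id, 0.0), c.score)
        return sum(best.values())

    def closure(seed_idx: list[int]) -> list[int]:
        # seed candidates plus unconsumed candidates sharing any of their peaks
        out = set(seed_idx)
        for i in seed_idx:
            c = pool[i]
            for pid in c.peak_ids:
                for j in peak_map.get((c.sample_id, pid), ()):
                    if alive[j]:
                        out.add(j)
        return sorted(out)

    mz_order = sorted(range(len(pool)), key=lambda i: pool[i].mono_mz)
    mz_sorted = np.array([pool[i].mono_mz for i in mz_order])

    def rescue_window(lo: float, hi: float) -> list[int]:
        a = int(np.searchsorted(mz_sorted, lo, side="left"))
        b = int(np.searchsorted(mz_sorted, hi, side="right"))
        return [mz_order[k] for k in range(a, b)]

    heap = [(-current_sum(e), formula_to_string(e), e) for e in by_emf]
    heapq.heapify(heap)
    sudos: list[SudoEMF] = []
    while heap:
        neg, _, seed = heapq.heappop(heap)
        cur = current_sum(seed)
        if cur <= 0.0:
            continue
        if -neg > cur + 1e-12:  # stale heap entry
            heapq.heappush(heap, (-cur, formula_to_string(seed), seed))
            continue
        seed_idx = [i for i in by_emf[seed] if alive[i]]
        taken = closure(seed_idx)
        per_sample: dict[str, list[AssignmentCandidate]] = {}
        for i in taken:
            alive[i] = False
            per_sample.setdefault(pool[i].sample_id, []).append(pool[i])
        members = {sid: GroupEMF(sid, cs) for sid, cs in per_sample.items()}
        if rescue:
            _rescue_from_pool(members, pool, alive, closure, rescue_window, cutoff, config)
        sudo = _finalize_sudo(members, cutoff, config)
        if sudo is not None:
            sudos.append(sudo)
    return sudos


def _rescue_from_pool(
    members: dict[str, GroupEMF],
    pool: list[AssignmentCandidate],
    alive: list[bool],
    closure,
    rescue_window,
    cutoff: float,
    config: VotingConfig,
) -> None:
    """Pull peak-profile-matching candidates of absent samples into the sudo."""
    _, retained = _score_and_retain(members, config.retain_fraction)
    if not retained:
        return
    mean_mz, order = _consensus_profile(members, retained)
    mono_by_adduct = {a: m for (a, h), m in mean_mz.items() if h == MONO}
    if not mono_by_adduct:
        return
    best_by_sample: dict[str, int] = {}
    for adduct in sorted(mono_by_adduct):
        mono_mz = mono_by_adduct[adduct]
        half = mono_mz * cutoff * 1e-6
        for i in rescue_window(mono_mz - half, mono_mz + half):
            c = pool[i]
            if not alive[i] or c.sample_id in members or c.adduct != adduct:
                continue
            prev = best_by_sample.get(c.sample_id)
            if prev is None or c.score > pool[prev].score:
                best_by_sample[c.sample_id] = i
    for sid in sorted(best_by_sample):
        i = best_by_sample[sid]
        g = GroupEMF(sid, [pool[i]])
        if _rescue_ok(g, mean_mz, order, cutoff, config.rescue_top_k):
            taken = closure([i])
            cs = [pool[j] for j in taken]
            for j in taken:
                alive[j] = False
            members[sid] = GroupEMF(sid, cs)

def _dedupe_members(
    items: list[tuple[str, GroupEMF]],
) -> tuple[dict[str, GroupEMF], list[tuple[str, GroupEMF]]]:
    members: dict[str, GroupEMF] = {}
    losers: list[tuple[str, GroupEMF]] = []
    for sid, g in sorted(items, key=lambda t: (t[0], t[1].min_formula())):
        if sid not in members:
            members[sid] = g
        elif g.total_score > members[sid].total_score:
            losers.append((sid, members[sid]))
            members[sid] = g
        else:
            losers.append((sid, g))
    return members, losers


def merge_and_revote(
    sudos: list[SudoEMF],
    cutoffs: dict[str, float],
    config: VotingConfig = VotingConfig(),
) -> list[SudoEMF]:
    """Merge sudo_EMFs sharing >= merge_fraction of their peaks; re-vote; repeat.

    The overlap fraction is |shared peaks| / size of the smaller peak set
    (peaks are (sample, peak) pairs).  Runs to a fixed point and is idempotent.
    """
    cutoff = _applied_cutoff(cutoffs)
    current = list(sudos)
    while True:
        current.sort(
            key=lambda s: (min(map(formula_to_string, s.retained_emfs)), -s.n_samples)
        )
        n = len(current)
        uf = _UnionFind(n)
        merged_any = False
        keysets = [s.peak_keys for s in current]
        for i in range(n):
            for j in range(i + 1, n):
                a, b = keysets[i], keysets[j]
                if not a or not b:
                    continue
                overlap = len(a & b) / min(len(a), len(b))
                if overlap >= config.merge_fraction and uf.find(i) != uf.find(j):
                    uf.union(i, j)
                    merged_any = True
        if not merged_any:
            return current
        comps: dict[int, list[SudoEMF]] = {}
        for i, s in enumerate(current):
            comps.setdefault(uf.find(i), []).append(s)
        nxt = []
        for _, group in sorted(comps.items()):
            items = [(sid, g) for s in group for sid, g in sorted(s.members.items())]
            members, losers = _dedupe_members(items)
            sudo = _finalize_sudo(members, cutoff, config)
            if sudo is not None:
                nxt.append(sudo)
        current = nxt
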