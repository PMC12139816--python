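"""Cross-sample EMF voting: grouping, cutoffs, retention, merging, category."""

import random

import numpy as np
import pytest

from lipidvote.chem import formula_from_string
from lipidvote.study import SampleMeta
from lipidvote.voting import (
    GroupEMF,
    SudoEMF,
    VotingConfig,
    build_group_emfs,
    determine_mz_cutoffs,
    merge_and_revote,
    vote_category,
    vote_sudo_emfs,
)

from conftest import make_candidate


def metas_for(sample_ids, labeling="unlabeled"):
    return [SampleMeta(s, "case", 1, labeling, 1) for s in sample_ids]


class TestBuildGroupEmfs:
    def test_shared_peaks_union(self):
        c1 = make_candidate("s1", "C10H20O2", peak_ids=(0, 1))
        c2 = make_candidate("s1", "C9H16N2O", peak_ids=(1, 2))
        groups = build_group_emfs([c1, c2])
        assert len(groups) == 1
        assert groups[0].emfs == {c1.emf, c2.emf}

    def test_same_formula_different_adducts_disjoint_peaks(self):
        c1 = make_candidate("s1", "C10H20O2", adduct="H", peak_ids=(0, 1))
        c2 = make_candidate("s1", "C10H20O2", adduct="Na", peak_ids=(5, 6))
        groups = build_group_emfs([c1, c2])
        assert len(groups) == 1

    def test_disjoint_candidates_stay_separate(self):
        c1 = make_candidate("s1", "C10H20O2", peak_ids=(0,))
        c2 = make_candidate("s1", "C9H16N2O", peak_ids=(5,))
        assert len(build_group_emfs([c1, c2])) == 2

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            build_group_emfs(
                [make_candidate("s1", "C10H20O2"), make_candidate("s2", "C10H20O2")]
            )


class TestMzCutoffs:
    def test_zero_spread_hits_floor(self):
        cands = {
            s: [make_candidate(s, "C10H20O2", mzs=(500.0, 501.0033548))]
            for s in ("s1", "s2", "s3")
        }
        cut = determine_mz_cutoffs(cands, metas_for(["s1", "s2", "s3"]))
        assert cut["unlabeled"] == 0.5  # floor

    def test_one_cutoff_per_labeling_group(self):
        metas = [
            SampleMeta("a", "case", 1, "unlabeled", 1),
            SampleMeta("b", "case", 2, "C13", 1),
            SampleMeta("c", "case", 3, "C13_N15", 1),
        ]
        cands = {m.sample_id: [make_candidate(m.sample_id, "C10H20O2")] for m in metas}
        cut = determine_mz_cutoffs(cands, metas)
        assert set(cut) == {"unlabeled", "C13", "C13_N15"}

    def test_empty_group_falls_back_with_warning(self, caplog):
        metas = [
            SampleMeta("a", "case", 1, "unlabeled", 1),
            SampleMeta("b", "case", 2, "C13", 1),
        ]
        cands = {"a": [make_candidate("a", "C10H20O2")], "b": []}
        cfg = VotingConfig(default_cutoff_ppm=3.0)
        with caplog.at_level("WARNING"):
            cut = determine_mz_cutoffs(cands, metas, cfg)
        assert cut["C13"] == 3.0

    def test_gaussian_spread_tracks_95th_percentile(self, rng):
        # simulation oracle: per-sample m/z jitter with known ppm sigma
        sigma = 1.0
        metas = metas_for([f"s{i}" for i in range(12)])
        cands = {}
        sds = []
        base = {f"f{k}": 400.0 + 37.0 * k for k in range(40)}
        jitters = {
            (m.sample_id, name): mz * (1 + rng.normal(0, sigma * 1e-6))
            for m in metas
            for name, mz in base.items()
        }
        for m in metas:
            cands[m.sample_id] = [
                make_candidate(m.sample_id, f"C{10 + k}H20O2",
                               mzs=(jitters[(m.sample_id, f"f{k}")],),
                               peak_ids=(k,))
                for k in range(40)
            ]
        for k, (name, mz) in enumerate(base.items()):
            v = [jitters[(m.sample_id, name)] for m in metas]
            sds.append(np.std(v, ddof=1) / np.mean(v) * 1e6)
        expected = np.percentile(sds, 95)
        cut = determine_mz_cutoffs(cands, metas)
        assert cut["unlabeled"] == pytest.approx(expected, rel=1e-9)


def vote(groups_by_sample, config=VotingConfig(), cutoff=2.0):
    return vote_sudo_emfs(groups_by_sample, {"unlabeled": cutoff}, config)


class TestVoting:
    def test_single_sample_groups_become_sudos(self):
        c1 = make_candidate("s1", "C10H20O2", peak_ids=(0, 1), score=1.0)
        c2 = make_candidate("s1", "C9H16N2O", peak_ids=(0, 1), score=0.5)
        c3 = make_candidate("s1", "C20H40O4", peak_ids=(9, 10), score=1.0)
        groups = {"s1": build_group_emfs([c1, c2, c3])}
        sudos = vote(groups)
        assert len(sudos) == 2
        retained = {frozenset(s.retained_formulas()) for s in sudos}
        # within the shared-peak group only the max-score formula is retained
        assert frozenset({"C10H20O2"}) in retained
        assert frozenset({"C20H40O4"}) in retained

    def test_ninety_percent_retention_rule(self):
        # A scores 0.9 in three samples (sum 2.7); B scores 0.9 once
        groups = {}
        for s in ("s1", "s2", "s3"):
            cands = [make_candidate(s, "C10H20O2", peak_ids=(0, 1), score=0.9)]
            if s == "s1":
                cands.append(
                    make_candidate(s, "C9H16N2O", peak_ids=(0, 1), score=0.9)
                )
            groups[s] = build_group_emfs(cands)
        sudos = vote(groups)
        assert len(sudos) == 1
        assert sudos[0].retained_formulas() == ["C10H20O2"]
        assert sudos[0].emf_scores[formula_from_string("C10H20O2")] == pytest.approx(2.7)
        assert sudos[0].emf_scores[formula_from_string("C9H16N2O")] == pytest.approx(0.9)

    def test_exact_ninety_percent_boundary_retained(self):
        groups = {
            "s1": build_group_emfs(
                [
                    make_candidate("s1", "C10H20O2", peak_ids=(0, 1), score=1.0),
                    make_candidate("s1", "C9H16N2O", peak_ids=(0, 1), score=0.9),
                ]
            )
        }
        sudos = vote(groups)
        assert sudos[0].retained_formulas() == ["C10H20O2", "C9H16N2O"] or set(
            sudos[0].retained_formulas()
        ) == {"C10H20O2", "C9H16N2O"}

    def test_rescue_by_mz_and_intensity_ordering(self):
        # s3 has no shared formula but identical peaks / ordering
        mzs = (500.0, 501.0033548, 502.0067096)
        intens = (1000.0, 400.0, 100.0)
        groups = {
            s: build_group_emfs(
                [make_candidate(s, "C10H20O2", peak_ids=(0, 1, 2), mzs=mzs,
                                intensities=intens, score=1.0)]
            )
            for s in ("s1", "s2")
        }
        groups["s3"] = build_group_emfs(
            [make_candidate("s3", "C9H16N2O", peak_ids=(0, 1, 2), mzs=mzs,
                            intensities=intens, score=0.2)]
        )
        sudos = vote(groups)
        top = max(sudos, key=lambda s: s.n_samples)
        assert "s3" in top.members and "s3" in top.rescued

    def test_rescue_rejected_on_wrong_ordering(self):
        mzs = (500.0, 501.0033548, 502.0067096)
        groups = {
            s: build_group_emfs(
                [make_candidate(s, "C10H20O2", peak_ids=(0, 1, 2), mzs=mzs,
                                intensities=(1000.0, 400.0, 100.0), score=1.0)]
            )
            for s in ("s1", "s2")
        }
        groups["s3"] = build_group_emfs(
            [make_candidate("s3", "C9H16N2O", peak_ids=(0, 1, 2), mzs=mzs,
                            intensities=(400.0, 1000.0, 100.0), score=0.2)]
        )
        sudos = vote(groups)
        top = max(sudos, key=lambda s: s.n_samples)
        assert "s3" not in top.members

    def test_permutation_invariance(self):
        base = {}
        for k, s in enumerate(("s1", "s2", "s3", "s4")):
            base[s] = [
                make_candidate(s, "C10H20O2", peak_ids=(0, 1), score=1.0),
                make_candidate(s, "C20H40O4", peak_ids=(7, 8), score=0.8),
                make_candidate(s, "C9H16N2O", peak_ids=(1, 2), score=0.3),
            ]
        ref = None
        rnd = random.Random(0)
        for _ in range(5):
            groups = {}
            order = list(base)
            rnd.shuffle(order)
            for s in order:
                cands = list(base[s])
                rnd.shuffle(cands)
                groups[s] = build_group_emfs(cands)
            sudos = vote(groups)
            sig = sorted(
                (tuple(s.retained_formulas()), tuple(sorted(s.members)))
                for s in sudos
            )
            if ref is None:
                ref = sig
            assert sig == ref

    def test_retained_scores_respect_fraction_invariant(self):
        groups = {}
        rnd = random.Random(1)
        formulas = ["C10H20O2", "C9H16N2O", "C20H40O4", "C8H14O3"]
        for s in ("s1", "s2", "s3"):
            cands = [
                make_candidate(s, f, peak_ids=(0, 1), score=rnd.uniform(0.1, 1.0))
                for f in formulas
            ]
            groups[s] = build_group_emfs(cands)
        for sudo in vote(groups):
            mx = max(sudo.emf_scores.values())
            for emf in sudo.retained_emfs:
                assert sudo.emf_scores[emf] >= 0.9 * mx - 1e-12


def make_sudo(sample_peaks: dict[str, tuple[int, ...]], formula: str, score=1.0):
    members = {}
    for sid, pids in sample_peaks.items():
        c = make_candidate(sid, formula, peak_ids=pids, score=score)
        members[sid] = GroupEMF(sid, [c])
    f = formula_from_string(formula)
    sudo = SudoEMF(
        members=members,
        emf_scores={f: score * len(members)},
        retained_emfs={f},
    )
    sudo.emf_mz = 500.0
    return sudo


class TestMergeAndRevote:
    def test_boundary_half_overlap_merges(self):
        a = make_sudo({"s1": (1, 2, 3, 4)}, "C10H20O2")
        b = make_sudo({"s1": (3, 4, 5, 6)}, "C9H16N2O")
        merged = merge_and_revote([a, b], {"unlabeled": 2.0})
        assert len(merged) == 1

    def test_below_half_overlap_does_not_merge(self):
        a = make_sudo({"s1": (1, 2, 3, 4)}, "C10H20O2")
        b = make_sudo({"s1": (4, 5, 6, 7)}, "C9H16N2O")
        merged = merge_and_revote([a, b], {"unlabeled": 2.0})
        assert len(merged) == 2

    def test_idempotent(self):
        sudos = [
            make_sudo({"s1": (1, 2, 3, 4), "s2": (1, 2, 3, 4)}, "C10H20O2"),
            make_sudo({"s1": (3, 4, 5, 6)}, "C9H16N2O"),
            make_sudo({"s2": (9, 10)}, "C20H40O4"),
        ]
        once = merge_and_revote(sudos, {"unlabeled": 2.0})
        twice = merge_and_revote(once, {"unlabeled": 2.0})
        assert [s.retained_formulas() for s in once] == [
            s.retained_formulas() for s in twice
        ]
        assert [sorted(s.members) for s in once] == [sorted(s.members) for s in twice]

    def test_post_merge_overlaps_below_threshold(self):
        sudos = [
            make_sudo({"s1": (1, 2, 3, 4)}, "C10H20O2"),
            make_sudo({"s1": (3, 4, 5, 6)}, "C9H16N2O"),
            make_sudo({"s1": (20, 21)}, "C20H40O4"),
        ]
        merged = merge_and_revote(sudos, {"unlabeled": 2.0})
        for i, a in enumerate(merged):
            for b in merged[i + 1:]:
                ka, kb = a.peak_keys, b.peak_keys
                if ka and kb:
                    assert len(ka & kb) / min(len(ka), len(kb)) < 0.5

    def test_one_member_per_sample_after_merge(self):
        a = make_sudo({"s1": (1, 2, 3, 4), "s2": (1, 2, 3, 4)}, "C10H20O2", score=1.0)
        b = make_sudo({"s1": (3, 4, 5, 6)}, "C9H16N2O", score=0.4)
        merged = merge_and_revote([a, b], {"unlabeled": 2.0})
        for s in merged:
            assert len(s.members) == len(set(s.members))


class TestCategoryVote:
    def make_with_categories(self, cat_sets):
        cands = [
            make_candidate("s1", f"C{10 + i}H20O2", peak_ids=(i,),
                           categories=frozenset(cats))
            for i, cats in enumerate(cat_sets)
        ]
        return SudoEMF(
            members={"s1": GroupEMF("s1", list(cands))},
            emf_scores={c.emf: 1.0 for c in cands},
            retained_emfs={c.emf for c in cands},
        )

    @pytest.mark.parametrize(
        "cat_sets, expected",
        [
            ([{"SP"}, {"SP"}, {"GP"}], "SP"),
            ([{"SP"}, {"GP"}], "multiple"),
            ([{"NOT_LIPID"}, {"SP"}], "SP"),
            ([{"NOT_LIPID"}, {"NOT_LIPID"}], "NOT_LIPID"),
            ([{"NOT_CATEGORIZED"}], "NOT_CATEGORIZED"),
            ([{"GP", "SP"}, {"SP"}], "SP"),
        ],
    )
    def test_vote_rules(self, cat_sets, expected):
        assert vote_category(self.make_with_categories(cat_sets)) == expected
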