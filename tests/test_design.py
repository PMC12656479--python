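"""Combinatorial split enumeration, selection constraints, study bookkeeping."""

from __future__ import annotations

from math import comb

import pytest

import medeeg
from medeeg import (LKM_SELF, NONMED, PipelineParams, StudyDesign,
                    count_tests, enumerate_splits, run_experiment, run_study,
                    select_experiment)
from medeeg import tests_per_experiment as splits_per_experiment
from medeeg import design as design_mod


class TestSplitEnumeration:
    @pytest.mark.parametrize("t,count", [(2, 30), (3, 20), (4, 5)])
    def test_split_counts(self, t, count):
        plan = enumerate_splits(t)
        assert len(plan.splits) == count == (t + 1) * comb(5, t + 1)
        assert len(set(plan.splits)) == count  # unique

    @pytest.mark.parametrize("t", [2, 3, 4])
    def test_test_pair_excluded_and_coverage(self, t):
        plan = enumerate_splits(t)
        test_counts = {i: 0 for i in range(5)}
        for train, test in plan.splits:
            assert test not in train
            assert len(train) == t
            test_counts[test] += 1
        # each pair is the test pair exactly C(4, t) times
        assert set(test_counts.values()) == {comb(4, t)}

    @pytest.mark.parametrize("t", [0, 1, 5])
    def test_invalid_train_size(self, t):
        with pytest.raises(ValueError):
            enumerate_splits(t)


class TestSelection:
    def test_constraints_hold(self, unit_cohort):
        sel = select_experiment(unit_cohort, LKM_SELF, seed=1)
        med_subj = [p.meditation.subject_id for p in sel.pairs]
        non_subj = [p.non_meditation.subject_id for p in sel.pairs]
        assert len(set(med_subj)) == 5 and len(set(non_subj)) == 5
        for p in sel.pairs:
            assert p.meditation.task == LKM_SELF
            assert p.non_meditation.task == NONMED

    def test_deterministic_given_seed(self, unit_cohort):
        a = select_experiment(unit_cohort, LKM_SELF, seed=4)
        b = select_experiment(unit_cohort, LKM_SELF, seed=4)
        assert [(p.meditation.key(), p.non_meditation.key()) for p in a.pairs] \
            == [(p.meditation.key(), p.non_meditation.key()) for p in b.pairs]

    def test_too_few_subjects_rejected(self):
        cfg = medeeg.SimConfig(n_subjects=4, n_sessions_per_task=1,
                               n_channels=4, duration=4.0, n_sources=2,
                               n_oscillators=1)
        cohort = medeeg.generate_cohort(cfg)
        with pytest.raises(ValueError, match="5 subjects"):
            select_experiment(cohort, LKM_SELF, seed=0)

    def test_non_meditation_task_rejected(self, unit_cohort):
        with pytest.raises(ValueError):
            select_experiment(unit_cohort, NONMED, seed=0)


class TestBookkeeping:
    def test_full_design_counts(self):
        counts = count_tests(StudyDesign())
        for cell, want in {2: 900, 3: 600, 4: 150}.items():
            for task in ("LKM_SELF", "LKM_OTHER"):
                assert counts["cells"][(task, cell)]["per_pipeline"] == want
                assert counts["cells"][(task, cell)]["total"] == want * 3
        assert counts["cells"][("LKM_SELF", 2)]["total"] == 2700
        assert counts["per_task"] == {"LKM_SELF": 4950, "LKM_OTHER": 4950}
        assert counts["total"] == 9900

    def test_reduced_design_scales_linearly(self):
        counts = count_tests(StudyDesign(n_experiments=2))
        assert counts["total"] == 9900 * 2 // 30
        assert counts["cells"][("LKM_OTHER", 3)]["per_pipeline"] == 40

    @pytest.mark.parametrize("t,count", [(2, 30), (3, 20), (4, 5)])
    def test_tests_per_experiment(self, t, count):
        assert splits_per_experiment(t) == count


class TestRunExperiment:
    def test_result_count_and_fields(self, unit_cohort):
        sel = select_experiment(unit_cohort, LKM_SELF, seed=2)
        plan = enumerate_splits(4)
        params = PipelineParams(n_csp_pairs=2, stft_groups=2)
        res = run_experiment(sel, plan, "CSP", params, experiment_id=7)
        assert len(res) == 5
        assert {r.test_pair for r in res} == set(range(5))
        assert all(0 <= r.accuracy <= 100 for r in res)
        assert all(r.experiment_id == 7 and r.pipeline == "CSP" for r in res)

    def test_unknown_pipeline_rejected(self, unit_cohort):
        sel = select_experiment(unit_cohort, LKM_SELF, seed=2)
        with pytest.raises(ValueError, match="pipeline"):
            run_experiment(sel, enumerate_splits(4), "PCA")

    def test_no_leakage_between_train_and_test(self, unit_cohort, monkeypatch):
        """The held-out pair's sessions never reach training in any split."""
        seen = []
        orig = design_mod.run_split

        def spy(pair_epochs, split, pipeline, params, seed):
            train_idx, test_idx = split
            train_src = {s for i in train_idx for s in pair_epochs[i].source}
            test_src = set(pair_epochs[test_idx].source)
            seen.append((train_src, test_src))
            return 50.0

        monkeypatch.setattr(design_mod, "run_split", spy)
        sel = select_experiment(unit_cohort, LKM_SELF, seed=3)
        run_experiment(sel, enumerate_splits(2), "CSP_STFT")
        assert len(seen) == 30
        for train_src, test_src in seen:
            assert not (train_src & test_src)

    def test_determinism_same_selection_and_seed(self, unit_cohort):
        sel = select_experiment(unit_cohort, LKM_SELF, seed=2)
        plan = enumerate_splits(4)
        params = PipelineParams(n_csp_pairs=2, stft_groups=2)
        a = run_experiment(sel, plan, "STFT", params)
        b = run_experiment(sel, plan, "STFT", params)
        assert [r.accuracy for r in a] == [r.accuracy for r in b]


class TestRunStudy:
    def test_small_study_shape_and_determinism(self, unit_cohort):
        design = StudyDesign(n_experiments=1, train_sizes=(4,),
                             meditation_tasks=(LKM_SELF,),
                             pipelines=("CSP",), master_seed=5)
        params = PipelineParams(n_csp_pairs=2, stft_groups=2)
        res1 = run_study(unit_cohort, design, params)
        res2 = run_study(unit_cohort, design, params)
        assert len(res1) == count_tests(design)["total"] == 5
        assert [r.accuracy for r in res1] == [r.accuracy for r in res2]
        assert [r.seed for r in res1] == [r.seed for r in res2]

    def test_infeasible_cohort_fails_before_compute(self, unit_cohort):
        partial = [r for r in unit_cohort if r.task != NONMED]
        with pytest.raises(ValueError, match="NONMED"):
            run_study(partial, StudyDesign(n_experiments=1))
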