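"""The combinatorial session-pair evaluation design.

One *experiment* draws 5 meditation and 5 non-meditation sessions from the
cohort pool under the distinct-participant constraint (at most one session
per subject per task; the two task draws are independent, so a subject may
appear in both) and pairs them randomly.  For a training size t in {2, 3, 4}
every (t+1)-subset of the 5 pairs is enumerated and rotated over its members
as the held-out test pair, giving (t+1) * C(5, t+1) = 30 / 20 / 5 splits.
A full study runs 30 experiments per cell over 2 meditation tasks x 3
training sizes x 3 pipelines: 900/600/150 tests per pipeline per cell and
9900 tests in total.

Within a split, CSP filters, the STFT fusion ranking and the classifier's
standardization are fitted on the pooled training epochs only and applied
unchanged to the held-out pair, so no test information leaks into training.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import classify, features, preprocess
from .containers import (EEGRecording, EpochArray, FeatureTable,
                         MEDITATION_TASKS, NONMED, TASKS, concatenate_epochs)

PIPELINES = ("CSP", "STFT", "CSP_STFT")
TRAIN_SIZES = (2, 3, 4)
N_PAIRS_PER_EXPERIMENT = 5


@dataclass
class SessionPair:
    meditation: EEGRecording
    non_meditation: EEGRecording

    def __post_init__(self) -> None:
        if self.meditation.task not in MEDITATION_TASKS:
            raise ValueError("meditation member has a non-meditation task")
        if self.non_meditation.task != NONMED:
            raise ValueError("non_meditation member must be the NONMED task")


@dataclass
class ExperimentSelection:
    pairs: list[SessionPair]
    meditation_task: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.pairs) != N_PAIRS_PER_EXPERIMENT:
            raise ValueError("an experiment uses exactly 5 session pairs")
        med_subjects = {p.meditation.subject_id for p in self.pairs}
        non_subjects = {p.non_meditation.subject_id for p in self.pairs}
        if len(med_subjects) != 5 or len(non_subjects) != 5:
            raise ValueError("each task's 5 sessions must come from 5 distinct subjects")


@dataclass(frozen=True)
class SplitPlan:
    train_size: int
    splits: tuple[tuple[tuple[int, ...], int], ...]


@dataclass
class TestResult:
    accuracy: float
    pipeline: str
    train_size: int
    meditation_task: str
    experiment_id: int
    split_id: int
    test_pair: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must lie in [0, 100]")


@dataclass
class PipelineParams:
    """Everything a single train/test split needs besides the data."""

    band: tuple[float, float] = preprocess.DEFAULT_BAND
    epoching: preprocess.EpochingParams = field(
        default_factory=preprocess.EpochingParams)
    n_csp_pairs: int = 3
    stft_bands: tuple[tuple[float, float], ...] = features.DEFAULT_BANDS
    stft_window: float = 1.0
    stft_overlap: float = 0.5
    stft_groups: int = 4
    cap: int = features.FEATURE_CAP
    mlp: classify.MLPSpec = field(default_factory=classify.MLPSpec)


def select_experiment(cohort: list[EEGRecording], meditation_task: str,
                      seed: int | np.random.SeedSequence) -> ExperimentSelection:
    """Draw 5 session pairs under the distinct-participant constraint.

    Per task: 5 subjects (without replacement) from those with at least one
    session of that task, then one of each subject's sessions uniformly.
    The two task draws are independent; pairing is a random permutation.
    """
    if meditation_task not in MEDITATION_TASKS:
        raise ValueError(f"{meditation_task!r} is not a meditation task")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seed_int = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss)

    def draw(task: str) -> list[EEGRecording]:
        by_subject: dict[str, list[EEGRecording]] = {}
        for rec in cohort:
            if rec.task == task:
                by_subject.setdefault(rec.subject_id, []).append(rec)
        if len(by_subject) < 5:
            raise ValueError(
                f"need >= 5 subjects with {task} sessions, found {len(by_subject)}"
            )
        subjects = rng.choice(sorted(by_subject), size=5, replace=False)
        return [by_subject[s][rng.integers(len(by_subject[s]))] for s in subjects]

    med = draw(meditation_task)
    non = draw(NONMED)
    order = rng.permutation(5)
    pairs = [SessionPair(meditation=med[i], non_meditation=non[order[i]])
             for i in range(5)]
    return ExperimentSelection(pairs=pairs, meditation_task=meditation_task,
                               seed=seed_int)


def enumerate_splits(train_size: int) -> SplitPlan:
    """All (train_size+1)-subsets of the 5 pairs, each member held out once."""
    if train_size not in TRAIN_SIZES:
        raise ValueError(f"train_size must be one of {TRAIN_SIZES}")
    splits = []
    for subset in itertools.combinations(range(N_PAIRS_PER_EXPERIMENT),
                                         train_size + 1):
        for test in subset:
            train = tuple(i for i in subset if i != test)
            splits.append((train, test))
    return SplitPlan(train_size=train_size, splits=tuple(splits))


def _pair_epochs(pair: SessionPair, params: PipelineParams) -> EpochArray:
    return concatenate_epochs([
        preprocess.filter_and_epoch(pair.meditation, params.band, params.epoching),
        preprocess.filter_and_epoch(pair.non_meditation, params.band, params.epoching),
    ])


def extract_features(train: EpochArray, test: EpochArray, pipeline: str,
                     params: PipelineParams) -> tuple[FeatureTable, FeatureTable]:
    """Fit feature extractors on training epochs; apply to both sets."""
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}; expected one of {PIPELINES}")
    stft_kw = dict(bands=params.stft_bands, window_length=params.stft_window,
                   window_overlap=params.stft_overlap, n_groups=params.stft_groups)
    if pipeline == "STFT":
        return (features.stft_band_power(train, **stft_kw),
                features.stft_band_power(test, **stft_kw))
    bank = features.fit_csp(train, n_pairs=params.n_csp_pairs)
    csp_tr = features.csp_features(train, bank)
    csp_te = features.csp_features(test, bank)
    if pipeline == "CSP":
        return csp_tr, csp_te
    stft_tr = features.stft_band_power(train, **stft_kw)
    stft_te = features.stft_band_power(test, **stft_kw)
    order = features.stft_order_by_variance(stft_tr)
    return (features.fuse(csp_tr, stft_tr, params.cap, stft_order=order),
            features.fuse(csp_te, stft_te, params.cap, stft_order=order))


def run_split(pair_epochs: list[EpochArray], split: tuple[tuple[int, ...], int],
              pipeline: str, params: PipelineParams, seed: int) -> float:
    """One train/test split: features -> fresh MLP -> epoch-level accuracy."""
    train_idx, test_idx = split
    train = concatenate_epochs([pair_epochs[i] for i in train_idx])
    test = pair_epochs[test_idx]
    ft_train, ft_test = extract_features(train, test, pipeline, params)
    spec = classify.MLPSpec(
        hidden_layers=params.mlp.hidden_layers,
        max_epochs=params.mlp.max_epochs,
        learning_rate=params.mlp.learning_rate,
        seed=seed,
        early_stopping=params.mlp.early_stopping,
        validation_fraction=params.mlp.validation_fraction,
        patience=params.mlp.patience,
    )
    model = classify.train(ft_train, spec)
    return classify.accuracy(model, ft_test)


def run_experiment(selection: ExperimentSelection, plan: SplitPlan,
                   pipeline: str,
                   params: PipelineParams | None = None,
                   experiment_id: int = 0,
                   seed: int | np.random.SeedSequence | None = None
                   ) -> list[TestResult]:
    """Run every split of one experiment; one TestResult per split."""
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}; expected one of {PIPELINES}")
    params = params or PipelineParams()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(selection.seed if seed is None else seed))
    split_seeds = [int(s % (2**31))
                   for s in ss.generate_state(len(plan.splits), dtype=np.uint64)]
    pair_epochs = [_pair_epochs(p, params) for p in selection.pairs]
    results = []
    for split_id, split in enumerate(plan.splits):
        acc = run_split(pair_epochs, split, pipeline, params, split_seeds[split_id])
        results.append(TestResult(
            accuracy=acc, pipeline=pipeline, train_size=plan.train_size,
            meditation_task=selection.meditation_task,
            experiment_id=experiment_id, split_id=split_id,
            test_pair=split[1], seed=split_seeds[split_id],
        ))
    return results


@dataclass
class StudyDesign:
    """The full-study grid; defaults are the complete 9900-test design."""

    n_experiments: int = 30
    train_sizes: tuple[int, ...] = TRAIN_SIZES
    meditation_tasks: tuple[str, ...] = MEDITATION_TASKS
    pipelines: tuple[str, ...] = PIPELINES
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        bad = set(self.pipelines) - set(PIPELINES)
        if bad:
            raise ValueError(f"unknown pipelines: {sorted(bad)}")
        bad_t = set(self.train_sizes) - set(TRAIN_SIZES)
        if bad_t:
            raise ValueError(f"unsupported train sizes: {sorted(bad_t)}")


def tests_per_experiment(train_size: int) -> int:
    return len(enumerate_splits(train_size).splits)


def count_tests(design: StudyDesign) -> dict:
    """Dry-run bookkeeping: test counts per cell and in total, no classifier.

    A *cell* is (meditation task, train size); within a cell each pipeline
    contributes n_experiments x splits(train_size) tests.
    """
    cells = {}
    total = 0
    for task in design.meditation_tasks:
        for t in design.train_sizes:
            per_pipeline = design.n_experiments * tests_per_experiment(t)
            cell_total = per_pipeline * len(design.pipelines)
            cells[(task, t)] = {"per_pipeline": per_pipeline, "total": cell_total}
            total += cell_total
    per_task = {
        task: sum(v["total"] for (tk, _), v in cells.items() if tk == task)
        for task in design.meditation_tasks
    }
    return {"cells": cells, "per_task": per_task, "total": total}


def _experiment_seed(design: StudyDesign, task: str, train_size: int,
                     exp: int) -> np.random.SeedSequence:
    """Documented seed derivation: master seed + cell coordinates + index.

    The same sequence is reused across pipelines within a cell so the three
    pipelines see identical session selections (per-experiment comparability
    across pipeline columns).
    """
    return np.random.SeedSequence(
        [design.master_seed, TASKS.index(task), train_size, exp])


def run_study(cohort: list[EEGRecording], design: StudyDesign = StudyDesign(),
              params: PipelineParams | None = None,
              progress: bool = False) -> list[TestResult]:
    """Execute the full design; deterministic given ``design.master_seed``."""
    params = params or PipelineParams()
    for task in design.meditation_tasks:
        # fail fast before any computation if the draw is infeasible
        for t in (task, NONMED):
            if len({r.subject_id for r in cohort if r.task == t}) < 5:
                raise ValueError(f"cohort has < 5 subjects with {t} sessions")
    results: list[TestResult] = []
    for task in design.meditation_tasks:
        for train_size in design.train_sizes:
            plan = enumerate_splits(train_size)
            for exp in range(design.n_experiments):
                exp_ss = _experiment_seed(design, task, train_size, exp)
                selection = select_experiment(cohort, task, exp_ss.spawn(1)[0])
                for pi, pipeline in enumerate(design.pipelines):
                    # per-(cell, experiment, pipeline) seed stream for the
                    # per-split MLP seeds, disjoint from the selection stream
                    pipe_ss = np.random.SeedSequence(
                        list(exp_ss.entropy) + [1 + pi])
                    res = run_experiment(selection, plan, pipeline, params,
                                         experiment_id=exp, seed=pipe_ss)
                    results.extend(res)
                if progress:  # pragma: no cover - logging only
                    print(f"[{task} t={train_size}] experiment {exp + 1}"
                          f"/{design.n_experiments} done")
    return results
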