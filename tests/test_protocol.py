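"""Training protocol: selection rule, cascade bookkeeping, reproducibility."""

import logging

import numpy as np
import pytest

from tstn_bci import (
    EpochSet,
    PreprocConfig,
    TrainConfig,
    assemble_epochs,
    preprocess,
)
from tstn_bci.io import DataError
from tstn_bci.model import TSTNClassifier
from tstn_bci.protocol import (
    ContinualState,
    STAGES,
    continual_step,
    cross_validate,
    evaluate,
    fit,
    initial_state,
    replay_online,
    run_cascade,
    select_correct,
)
from tstn_bci.synth import ErdModel, SessionSpec, generate_session

FAST = dict(max_epochs=3, early_stop_patience=3, folds=2)


def _separable_epochs(rng, n_per=12, n_ch=6, n_s=500):
    """Classes marked by an order-of-magnitude louder oscillation on one
    channel each; trivially separable by any variance-reading classifier."""
    t = np.arange(n_s) / 250.0
    data, labels = [], []
    for cls in (0, 1, 2):
        for _ in range(n_per):
            x = rng.normal(scale=0.5, size=(n_ch, n_s))
            phase = rng.uniform(0, 2 * np.pi)
            x[cls] += 20.0 * np.sin(2 * np.pi * 10.0 * t + phase)
            data.append(x)
            labels.append(cls)
    return EpochSet(
        data=np.array(data), labels=np.array(labels),
        sampling_rate=250.0, epoch_window=(0.0, 2.0),
    )


@pytest.fixture(scope="module")
def separable():
    return _separable_epochs(np.random.default_rng(5))


@pytest.fixture(scope="module")
def fitted_separable(separable):
    cfg = TrainConfig(max_epochs=25, early_stop_patience=25, folds=2, seed=0)
    model, _ = fit(separable, cfg, run_cv=False)
    return model


class TestSelectCorrect:
    def test_all_correct_returns_all_indices(self):
        idx = select_correct([0, 1, 2, 1], [0, 1, 2, 1])
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])

    def test_no_match_returns_empty_and_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            idx = select_correct([0, 0], [1, 1])
        assert idx.size == 0
        assert any("no correctly classified" in r.message for r in caplog.records)

    def test_mixed_example(self):
        labels = [0, 1, 2, 0]
        preds = [0, 2, 2, 0]
        np.testing.assert_array_equal(select_correct(preds, labels), [0, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            select_correct([0, 1], [0])


class TestFitAndEvaluate:
    def test_separable_fixture_reaches_perfect_training_accuracy(
        self, separable, fitted_separable
    ):
        pred, report = evaluate(fitted_separable, separable)
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(pred, separable.labels)

    def test_fit_is_seed_deterministic(self, separable):
        cfg = TrainConfig(seed=11, **FAST)
        m1, _ = fit(separable, cfg, run_cv=False)
        m2, _ = fit(separable, cfg, run_cv=False)
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k], m2.params_[k])
        np.testing.assert_array_equal(m1.bank_.Z_, m2.bank_.Z_)

    def test_missing_class_rejected(self, separable):
        two_class = separable.subset(np.flatnonzero(separable.labels != 2))
        with pytest.raises(DataError):
            fit(two_class, TrainConfig(seed=0, **FAST), run_cv=False)

    def test_cross_validate_returns_fold_reports(self, separable):
        cfg = TrainConfig(seed=0, **FAST)
        reports = cross_validate(separable, cfg)
        assert len(reports) == cfg.folds
        assert all(0.0 <= r.accuracy <= 1.0 for r in reports)

    def test_cv_requires_enough_trials_per_class(self, separable):
        tiny = separable.subset([0, 1, 12, 13, 24, 25])
        with pytest.raises(DataError):
            cross_validate(tiny, TrainConfig(seed=0, folds=10))

    def test_evaluate_empty_epochs(self, fitted_separable):
        empty = EpochSet(
            data=np.empty((0, 6, 500)), labels=np.empty(0, dtype=int),
            sampling_rate=250.0, epoch_window=(0.0, 2.0),
        )
        pred, report = evaluate(fitted_separable, empty)
        assert pred.size == 0
        assert report is None

    def test_model_save_load_round_trip(self, tmp_path, separable,
                                        fitted_separable):
        path = tmp_path / "model.tstn.npz"
        fitted_separable.save(path)
        back = TSTNClassifier.load(path)
        np.testing.assert_array_equal(
            back.predict(separable.data), fitted_separable.predict(separable.data)
        )
        probs1 = back.predict_proba(separable.data[:3])
        probs2 = fitted_separable.predict_proba(separable.data[:3])
        np.testing.assert_allclose(probs1, probs2, atol=1e-7)


class TestContinualStep:
    def test_pool_grows_by_number_of_correct_trials(self, separable,
                                                    fitted_separable, rng):
        cfg = TrainConfig(seed=0, **FAST)
        new = _separable_epochs(rng, n_per=4)
        pred, _ = evaluate(fitted_separable, new)
        n_correct = int(np.sum(pred == new.labels))
        state = initial_state(fitted_separable, separable)
        state2 = continual_step(state, new, cfg)
        assert len(state2.training_pool) == len(separable) + n_correct
        assert state2.stage == STAGES[1]
        assert state2.history[-1]["n_selected"] == n_correct

    def test_zero_selected_leaves_model_unchanged(self, separable,
                                                  fitted_separable, rng):
        cfg = TrainConfig(seed=0, **FAST)
        new = _separable_epochs(rng, n_per=3)
        pred, _ = evaluate(fitted_separable, new)
        wrong = new.subset(np.arange(len(new)))
        wrong.labels = (pred + 1) % 3  # force every prediction wrong
        state = initial_state(fitted_separable, separable)
        state2 = continual_step(state, wrong, cfg)
        assert state2.model is fitted_separable
        assert len(state2.training_pool) == len(separable)
        assert state2.stage == STAGES[1]

    def test_metrics_recorded_before_update(self, separable,
                                            fitted_separable, rng):
        cfg = TrainConfig(seed=0, **FAST)
        new = _separable_epochs(rng, n_per=4)
        pred, report = evaluate(fitted_separable, new)
        state2 = continual_step(initial_state(fitted_separable, separable),
                                new, cfg)
        assert state2.history[-1]["metrics"]["accuracy"] == report.accuracy

    def test_cascade_exhaustion_rejected(self, separable, fitted_separable):
        state = ContinualState(stage=STAGES[-1], model=fitted_separable,
                               training_pool=separable)
        with pytest.raises(DataError):
            continual_step(state, separable, TrainConfig(seed=0, **FAST))


@pytest.fixture(scope="module")
def tiny_sessions():
    pcfg = PreprocConfig()
    erd = ErdModel(erd_depth=0.5)
    spec = SessionSpec(session_kind="ao_mi", n_trials=12,
                       sampling_rate=250.0, seed=21)
    raw, tl, _ = generate_session(spec, erd)
    asm = assemble_epochs(preprocess(raw, pcfg), tl, pcfg)
    tests = [asm.mi]
    for s in range(3):
        spec_fb = SessionSpec(session_kind="mi_fb", n_trials=9,
                              sampling_rate=250.0, seed=100 + s)
        raw_fb, tl_fb, _ = generate_session(spec_fb, erd)
        tests.append(assemble_epochs(preprocess(raw_fb, pcfg), tl_fb, pcfg).train)
    return asm.train, tests


@pytest.fixture(scope="module")
def fb_session():
    spec = SessionSpec(session_kind="mi_fb", n_trials=9,
                       sampling_rate=250.0, seed=31)
    return generate_session(spec, ErdModel(erd_depth=0.5))


@pytest.fixture(scope="module")
def fb_model(fb_session):
    raw, tl, _ = fb_session
    pcfg = PreprocConfig()
    ep = assemble_epochs(preprocess(raw, pcfg), tl, pcfg).train
    cfg = TrainConfig(seed=0, **FAST)
    model, _ = fit(ep, cfg, run_cv=False)
    return model, ep


class TestCascade:
    def test_full_cascade_logs_four_stage_metric_records(self, tiny_sessions):
        train, tests = tiny_sessions
        cfg = TrainConfig(seed=2, **FAST)
        state, _ = run_cascade(train, tests, cfg)
        metric_records = [h for h in state.history if h.get("metrics")]
        assert len(metric_records) == 4
        assert state.stage == STAGES[-1]

    def test_cascade_is_bit_reproducible(self, tiny_sessions):
        train, tests = tiny_sessions
        cfg = TrainConfig(seed=2, **FAST)
        s1, _ = run_cascade(train, tests, cfg)
        s2, _ = run_cascade(train, tests, cfg)
        for k in s1.model.params_:
            np.testing.assert_array_equal(s1.model.params_[k],
                                          s2.model.params_[k])
        accs1 = [h["metrics"]["accuracy"] for h in s1.history if h.get("metrics")]
        accs2 = [h["metrics"]["accuracy"] for h in s2.history if h.get("metrics")]
        assert accs1 == accs2

    def test_selection_soundness(self, tiny_sessions):
        """Every trial added to the pool was correctly classified by the
        then-current model (replayable from the history records)."""
        train, tests = tiny_sessions
        cfg = TrainConfig(seed=2, **FAST)
        state, _ = run_cascade(train, tests, cfg)
        expected = len(train)
        for h in state.history[:-1]:
            expected += h["n_selected"]
        assert len(state.training_pool) == expected


class TestReplay:
    def test_replay_matches_batch_evaluation(self, fb_session, fb_model):
        raw, tl, _ = fb_session
        model, ep = fb_model
        decisions = replay_online(model, raw, tl)
        batch_pred, _ = evaluate(model, ep)
        assert [d["decision"] for d in decisions] == list(batch_pred)
        assert [d["label"] for d in decisions] == list(ep.labels)
        correct_rate = np.mean([d["correct"] for d in decisions])
        assert correct_rate == np.mean(batch_pred == ep.labels)

    def test_replay_is_deterministic(self, fb_session, fb_model):
        raw, tl, _ = fb_session
        model, _ = fb_model
        assert replay_online(model, raw, tl) == replay_online(model, raw, tl)

    def test_non_feedback_session_rejected(self, small_aomi, fb_model):
        raw, tl, _ = small_aomi
        model, _ = fb_model
        with pytest.raises(DataError):
            replay_online(model, raw, tl)
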