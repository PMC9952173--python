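"""Training protocol: cross-validated initial fit and the continual-learning cascade.

The cascade mirrors the four-stage training/testing procedure of the study
design: an initial classifier is fit on the AO+MI training epochs, tested on
the feedback-free MI epochs of the same session, and then refined across the
three MI-FB sessions.  At each step the *current* model is evaluated on the
incoming dataset (this pre-update accuracy is the reported per-stage test
metric), the correctly classified trials are appended to the cumulative
training pool, and the network is fine-tuned warm-start on the grown pool
with the CSP bank refit.  Warm-start fine-tuning on the cumulative pool
(rather than retraining from scratch on the new trials only) prevents
catastrophic forgetting while still adapting to between-session change.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import DataError, EpochSet, concat_epochs
from .metrics import MetricsReport, compute_metrics
from .model import TSTNClassifier
from .preprocess import PreprocConfig, assemble_epochs, preprocess
from .synth import MI_FB, TrialTimeline

logger = logging.getLogger(__name__)

STAGES = ("ao_mi", "mi", "mi_fb_1", "mi_fb_2", "mi_fb_3")


@dataclasses.dataclass
class TrainConfig:
    """Optimization and cross-validation settings (Adam throughout)."""

    learning_rate: float = 2e-4
    batch_size: int = 50
    dropout_spatial: float = 0.3
    dropout_temporal: float = 0.5
    folds: int = 10
    max_epochs: int = 100
    early_stop_patience: int = 20
    min_delta: float = 0.0
    validation_fraction: float = 0.1
    attention_lr_scale: float = 0.02
    embed_lr_scale: float = 2.0
    head_lr_scale: float = 10.0
    conv_activation: str = "elu"
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 <= self.dropout_spatial < 1 and 0 <= self.dropout_temporal < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def make_classifier(self, seed_offset: int = 0,
                        warm_start: bool = False) -> TSTNClassifier:
        return TSTNClassifier(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            min_delta=self.min_delta,
            validation_fraction=self.validation_fraction,
            dropout_spatial=self.dropout_spatial,
            dropout_temporal=self.dropout_temporal,
            attention_lr_scale=self.attention_lr_scale,
            embed_lr_scale=self.embed_lr_scale,
            head_lr_scale=self.head_lr_scale,
            conv_activation=self.conv_activation,
            dtype=self.dtype,
            warm_start=warm_start,
            random_state=self.seed + seed_offset,
        )


def cross_validate(epochs: EpochSet, cfg: TrainConfig) -> list[MetricsReport]:
    """Stratified k-fold cross validation; one metrics report per fold.

    Each fold fits the full stack (CSP bank included) on the 90% training
    split only and evaluates on the held-out 10%.
    """
    y = epochs.labels
    counts = np.bincount(y, minlength=3)
    if (counts < cfg.folds).any():
        raise DataError(
            f"need at least {cfg.folds} trials per class for {cfg.folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(epochs.data, y)):
        clf = cfg.make_classifier(seed_offset=1000 + fold)
        clf.fit(epochs.data[tr], y[tr])
        pred = clf.predict(epochs.data[te])
        reports.append(compute_metrics(y[te], pred))
    return reports


def fit(epochs: EpochSet, cfg: TrainConfig,
        run_cv: bool = True) -> tuple[TSTNClassifier, list[MetricsReport]]:
    """Fit the initial model.

    Runs stratified k-fold cross validation for fold-wise validation
    metrics (optional), then refits on all epochs with an internal
    hold-out controlling early stopping.  Fully seeded.
    """
    present = set(np.unique(epochs.labels).tolist())
    if present != {0, 1, 2}:
        raise DataError("training data must contain all three classes")
    cv_reports = cross_validate(epochs, cfg) if run_cv else []
    clf = cfg.make_classifier()
    clf.fit(epochs.data, epochs.labels)
    clf.lineage_ = STAGES[0]
    return clf, cv_reports


def evaluate(model: TSTNClassifier, epochs: EpochSet):
    """Evaluation-mode predictions and a metrics report.

    Empty epoch sets return empty predictions and ``None`` metrics.
    """
    if len(epochs) == 0:
        return np.empty(0, dtype=np.int64), None
    pred = model.predict(epochs.data)
    return pred, compute_metrics(epochs.labels, pred)


def select_correct(predictions, labels) -> np.ndarray:
    """Indices of correctly classified trials, order preserved."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise DataError("predictions and labels must have equal length")
    idx = np.flatnonzero(predictions == labels)
    if predictions.size and idx.size == 0:
        logger.warning("no correctly classified trials to select")
    return idx


@dataclasses.dataclass
class ContinualState:
    """Rolling state of the continual-learning cascade."""

    stage: str
    model: TSTNClassifier
    training_pool: EpochSet
    history: list[dict] = dataclasses.field(default_factory=list)


def initial_state(model: TSTNClassifier, training_pool: EpochSet) -> ContinualState:
    return ContinualState(stage=STAGES[0], model=model, training_pool=training_pool)


def continual_step(state: ContinualState, new_epochs: EpochSet,
                   cfg: TrainConfig) -> ContinualState:
    """One refinement step of the cascade.

    Evaluates the current model on ``new_epochs`` (metrics recorded BEFORE
    any update — this is the reported per-stage test accuracy), appends the
    correctly classified trials to the pool, and fine-tunes warm-start on
    the grown pool with the CSP bank refit.  If no trial is selected the
    model is left unchanged and the stage still advances.
    """
    stage_idx = STAGES.index(state.stage)
    if stage_idx + 1 >= len(STAGES):
        raise DataError("cascade already completed all stages")
    next_stage = STAGES[stage_idx + 1]

    pred, report = evaluate(state.model, new_epochs)
    selected = select_correct(pred, new_epochs.labels)
    record = {
        "stage": next_stage,
        "tested_on": next_stage,
        "n_test": len(new_epochs),
        "n_selected": int(selected.size),
        "metrics": report.to_dict() if report else None,
    }

    if selected.size == 0:
        logger.warning("stage %s selected zero trials; model unchanged", next_stage)
        model = state.model
        pool = state.training_pool
    else:
        pool = concat_epochs([state.training_pool, new_epochs.subset(selected)])
        model = cfg.make_classifier(
            seed_offset=100 * (stage_idx + 1), warm_start=True
        )
        model.params_ = {k: v.copy() for k, v in state.model.params_.items()}
        model.net_config_ = state.model.net_config_
        model.fit(pool.data, pool.labels)
        model.lineage_ = next_stage

    return ContinualState(
        stage=next_stage,
        model=model,
        training_pool=pool,
        history=state.history + [record],
    )


def replay_online(model: TSTNClassifier, raw, timeline: TrialTimeline,
                  cfg: PreprocConfig | None = None):
    """Offline replay of an MI-FB session: chronological frozen-model decisions.

    Each task block is preprocessed and classified with the model frozen (no
    within-session updates).  Returns per-trial dicts with onset, decision,
    true label, and correctness; equivalent to batch evaluation.
    """
    cfg = cfg or PreprocConfig()
    if raw.meta.get("session_kind") != MI_FB:
        raise DataError("replay_online expects an MI-FB session")
    prep = preprocess(raw, cfg)
    epochs = assemble_epochs(prep, timeline, cfg).train
    decisions = []
    for i in range(len(epochs)):
        pred = int(model.predict(epochs.data[i][None])[0])
        true = int(epochs.labels[i])
        decisions.append(
            {
                "trial": i,
                "decision": pred,
                "label": true,
                "correct": pred == true,
            }
        )
    return decisions


def run_cascade(initial_train: EpochSet, test_sets: list[EpochSet],
                cfg: TrainConfig, run_cv: bool = False):
    """Fit the initial model and run the full cascade over ``test_sets``.

    ``test_sets`` is the ordered list [MI, MI-FB 1, MI-FB 2, MI-FB 3]; the
    last set is evaluated only (there is no later stage to train for).
    Returns the final state; ``state.history`` has one record per stage.
    """
    model, cv_reports = fit(initial_train, cfg, run_cv=run_cv)
    state = initial_state(model, initial_train)
    for new_epochs in test_sets[:-1]:
        state = continual_step(state, new_epochs, cfg)
    if test_sets:
        final_stage = STAGES[min(len(test_sets), len(STAGES) - 1)]
        _, report = evaluate(state.model, test_sets[-1])
        state.history.append(
            {
                "stage": final_stage,
                "tested_on": "final",
                "n_test": len(test_sets[-1]),
                "metrics": report.to_dict() if report else None,
            }
        )
        state.stage = final_stage
    return state, cv_reports
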