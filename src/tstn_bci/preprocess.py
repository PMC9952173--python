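"""Band-pass filtering, downsampling, and epoch assembly.

The continuous recording is band-pass filtered to 4-40 Hz with a 3rd-order
Butterworth IIR filter applied forward-backward (zero phase, so epochs stay
aligned to their cue onsets), decimated to 250 Hz, and cut into 2-s epochs:

* AO+MI sessions yield a training set (one epoch per AO+MI block, labeled
  left/right, plus one rest epoch per trial taken from the final 2 s of the
  trial's first rest period) and a separate motor-imagery test set (the MI
  block of every trial) used as the feedback-free evaluation data.
* MI-FB sessions yield one epoch per task block, labeled left/right/rest.

Task blocks shorter than the epoch length are skipped with a warning.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ConfigurationError, DataError, EpochSet, RawRecording, REST
from .synth import (
    BLOCK_AO_MI,
    BLOCK_MI,
    BLOCK_MI_FB_TASK,
    BLOCK_REST,
    TASK_BLOCK_KINDS,
    TrialTimeline,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PreprocConfig:
    band: tuple[float, float] = (4.0, 40.0)
    filter_order: int = 3
    target_rate: float = 250.0
    epoch_len_s: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < self.target_rate / 2):
            raise ConfigurationError(
                f"band {self.band} must lie inside (0, {self.target_rate / 2}) Hz"
            )
        n = self.epoch_len_s * self.target_rate
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("epoch_len_s x target_rate must be an integer")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_len_s * self.target_rate))


def bandpass(raw: RawRecording, cfg: PreprocConfig | None = None) -> RawRecording:
    """Zero-phase 3rd-order Butterworth band-pass; shape and rate preserved."""
    cfg = cfg or PreprocConfig()
    lo, hi = cfg.band
    if raw.sampling_rate <= 2 * hi:
        raise ConfigurationError(
            f"band edge {hi} Hz outside Nyquist for {raw.sampling_rate} Hz input"
        )
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass",
                     fs=raw.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.signal, axis=1)
    return RawRecording(
        signal=filtered,
        sampling_rate=raw.sampling_rate,
        channel_labels=raw.channel_labels,
        meta={**raw.meta, "band": cfg.band},
    )


def downsample(raw: RawRecording, cfg: PreprocConfig | None = None) -> RawRecording:
    """Anti-aliased decimation to ``cfg.target_rate`` (integer ratio only)."""
    cfg = cfg or PreprocConfig()
    ratio = raw.sampling_rate / cfg.target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            f"sampling rate {raw.sampling_rate} is not an integer multiple "
            f"of target rate {cfg.target_rate}"
        )
    q = int(round(ratio))
    if q == 1:
        out = raw.signal.copy()
    else:
        out = sps.decimate(raw.signal, q, axis=1, ftype="fir", zero_phase=True)
    return RawRecording(
        signal=out,
        sampling_rate=cfg.target_rate,
        channel_labels=raw.channel_labels,
        meta=dict(raw.meta),
    )


def preprocess(raw: RawRecording, cfg: PreprocConfig | None = None) -> RawRecording:
    """Band-pass then decimate."""
    cfg = cfg or PreprocConfig()
    return downsample(bandpass(raw, cfg), cfg)


@dataclasses.dataclass
class EpochAssembly:
    """``train`` plus, for AO+MI sessions, the feedback-free MI test set."""

    train: EpochSet
    mi: EpochSet | None = None


def _cut(raw: RawRecording, start_s: float, n_samples: int) -> np.ndarray | None:
    i0 = int(round(start_s * raw.sampling_rate))
    i1 = i0 + n_samples
    if i0 < 0 or i1 > raw.n_samples:
        return None
    return raw.signal[:, i0:i1]


def _make_set(chunks, labels, kinds, raw, cfg, window) -> EpochSet:
    data = (
        np.stack(chunks)
        if chunks
        else np.empty((0, raw.n_channels, cfg.epoch_samples))
    )
    session_id = str(raw.meta.get("session_kind", ""))
    return EpochSet(
        data=data,
        labels=np.asarray(labels, dtype=np.int64),
        sampling_rate=raw.sampling_rate,
        epoch_window=window,
        provenance=pd.DataFrame(
            {
                "session_id": [session_id] * len(chunks),
                "block_kind": kinds,
                "trial_index": np.arange(len(chunks)),
            }
        ),
    )


def assemble_epochs(raw: RawRecording, timeline: TrialTimeline,
                    cfg: PreprocConfig | None = None) -> EpochAssembly:
    """Cut a preprocessed recording into labeled epochs per the session design.

    ``raw`` must already be at ``cfg.target_rate``.  Epoch windows are
    half-open ``[onset, onset + epoch_len_s)``.  Rest-class training epochs
    for AO+MI sessions are the final ``epoch_len_s`` of each trial's first
    rest period, maximizing temporal distance from task activity.
    """
    cfg = cfg or PreprocConfig()
    if abs(raw.sampling_rate - cfg.target_rate) > 1e-9:
        raise ConfigurationError(
            f"assemble_epochs expects a recording at {cfg.target_rate} Hz"
        )
    n_ep = cfg.epoch_samples
    win = (0.0, cfg.epoch_len_s)

    kinds_present = {b.kind for b in timeline.blocks}
    is_ao_mi = BLOCK_AO_MI in kinds_present or BLOCK_MI in kinds_present

    train_chunks, train_labels, train_kinds = [], [], []
    mi_chunks, mi_labels, mi_kinds = [], [], []

    if is_ao_mi:
        # Walk trials: blocks come in (rest, ao)(rest, ao)(rest, mi) groups.
        blocks = timeline.blocks
        i = 0
        while i < len(blocks):
            group = blocks[i : i + 6]
            i += 6
            if len(group) < 6:
                break
            rest0 = group[0]
            task_ok = True
            for b in group[1::2]:
                if b.duration + 1e-9 < cfg.epoch_len_s:
                    logger.warning(
                        "skipping trial at %.1f s: task block shorter than "
                        "%.1f s epoch", b.onset, cfg.epoch_len_s,
                    )
                    task_ok = False
            if not task_ok:
                continue
            for b in group[1::2]:
                chunk = _cut(raw, b.onset, n_ep)
                if chunk is None:
                    continue
                if b.kind == BLOCK_AO_MI:
                    train_chunks.append(chunk)
                    train_labels.append(b.class_label)
                    train_kinds.append(b.kind)
                else:  # the trial's MI block -> feedback-free test set
                    mi_chunks.append(chunk)
                    mi_labels.append(b.class_label)
                    mi_kinds.append(b.kind)
            rest_chunk = _cut(
                raw, rest0.onset + rest0.duration - cfg.epoch_len_s, n_ep
            )
            if rest_chunk is not None and rest0.duration + 1e-9 >= cfg.epoch_len_s:
                train_chunks.append(rest_chunk)
                train_labels.append(REST)
                train_kinds.append(BLOCK_REST)
    else:
        for b in timeline.task_blocks():
            if b.duration + 1e-9 < cfg.epoch_len_s:
                logger.warning(
                    "skipping trial at %.1f s: task block shorter than "
                    "%.1f s epoch", b.onset, cfg.epoch_len_s,
                )
                continue
            chunk = _cut(raw, b.onset, n_ep)
            if chunk is None:
                continue
            train_chunks.append(chunk)
            train_labels.append(b.class_label)
            train_kinds.append(b.kind)

    train = _make_set(train_chunks, train_labels, train_kinds, raw, cfg, win)
    if is_ao_mi:
        mi = _make_set(mi_chunks, mi_labels, mi_kinds, raw, cfg, win)
        return EpochAssembly(train=train, mi=mi)
    return EpochAssembly(train=train, mi=None)


def extract_task_epochs(raw: RawRecording, timeline: TrialTimeline,
                        window: tuple[float, float] = (-2.0, 2.0),
                        kinds: tuple[str, ...] = TASK_BLOCK_KINDS) -> EpochSet:
    """Cut task-locked epochs with pre-onset context (for ERD analysis).

    ``window`` is (start_s, end_s) relative to task-block onset; the default
    covers the 2-s pre-cue reference period plus the first 2 s of the task.
    Blocks whose window falls outside the recording are dropped.
    """
    lo, hi = window
    if hi <= lo:
        raise ConfigurationError("empty epoch window")
    n = int(round((hi - lo) * raw.sampling_rate))
    chunks, labels, block_kinds = [], [], []
    for b in timeline.task_blocks():
        if b.kind not in kinds:
            continue
        chunk = _cut(raw, b.onset + lo, n)
        if chunk is None:
            continue
        chunks.append(chunk)
        labels.append(b.class_label)
        block_kinds.append(b.kind)
    if not chunks:
        raise DataError("no task block provides the requested window")
    return EpochSet(
        data=np.stack(chunks),
        labels=np.asarray(labels, dtype=np.int64),
        sampling_rate=raw.sampling_rate,
        epoch_window=window,
        provenance=pd.DataFrame(
            {
                "session_id": [str(raw.meta.get("session_kind", ""))] * len(chunks),
                "block_kind": block_kinds,
                "trial_index": np.arange(len(chunks)),
            }
        ),
    )
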