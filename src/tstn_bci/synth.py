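"""Seeded synthetic motor-imagery EEG sessions with a controllable mu-rhythm ERD.

The generator emulates an 8-channel, 1 kHz dry-electrode recording during two
session designs:

* an action-observation + motor-imagery (AO+MI) calibration session: 300
  trials (150 left / 150 right), each trial the concatenation of two AO+MI
  time blocks and one MI time block, every task block (2 s) preceded by a
  5-7 s rest period;
* a motor-imagery feedback (MI-FB) session: 150 trials (50 left / 50 right /
  50 rest), each a 5-7 s preparation period followed by a 3 s imagery block.

The signal model is deliberately minimal: per channel, a constant-amplitude
10 Hz mu-rhythm sinusoid with a slowly wandering instantaneous frequency
(which leaves the phase at any cue onset random and the channels mutually
incoherent, as in real EEG) rides on 1/f background noise plus a white
noise floor.  During a task block the mu *power* on the
channels named in that class's ERD profile is attenuated by the programmed
``erd_depth`` (amplitude scaled by sqrt(1-depth)), with a short raised-cosine
ramp around block edges.  Event-related desynchronization is thus the only
class-discriminative feature, with a known ground-truth magnitude.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import (
    CLASS_NAMES,
    ConfigurationError,
    LEFT,
    REST,
    RIGHT,
    RawRecording,
)

#: Seven electrodes named by the montage plus one configurable extra lead.
DEFAULT_MONTAGE = ("FC1", "FC2", "C3", "Cz", "C4", "P1", "P2", "EX8")

AO_MI = "ao_mi"
MI_FB = "mi_fb"

# Block kinds appearing in timelines.
BLOCK_REST = "rest"
BLOCK_AO_MI = "ao_mi"
BLOCK_MI = "mi"
BLOCK_MI_FB_TASK = "mi_fb_task"

TASK_BLOCK_KINDS = (BLOCK_AO_MI, BLOCK_MI, BLOCK_MI_FB_TASK)


@dataclasses.dataclass(frozen=True)
class Block:
    kind: str
    onset: float
    duration: float
    class_label: int | None = None  # LEFT / RIGHT / REST or None for rest blocks


@dataclasses.dataclass
class TrialTimeline:
    """Ordered, non-overlapping blocks with monotonically increasing onsets."""

    blocks: list[Block]

    def __post_init__(self) -> None:
        t = -1e-9
        for b in self.blocks:
            if b.duration <= 0:
                raise ConfigurationError("block durations must be positive")
            if b.onset < t - 1e-9:
                raise ConfigurationError("blocks overlap or are out of order")
            t = b.onset + b.duration

    def task_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.kind in TASK_BLOCK_KINDS]

    def n_trials(self) -> int:
        kinds = {b.kind for b in self.blocks}
        per_trial = 3 if BLOCK_AO_MI in kinds else 1
        return len(self.task_blocks()) // per_trial

    @property
    def duration(self) -> float:
        last = self.blocks[-1]
        return last.onset + last.duration


@dataclasses.dataclass
class SessionSpec:
    """Parameters of one recording session.

    ``class_mix`` maps class code to trial count and must sum to
    ``n_trials``; AO+MI sessions have no rest-class trials, MI-FB sessions
    have all three classes.  ``rest_range`` is the uniform range the rest /
    preparation duration is drawn from, in seconds.
    """

    session_kind: str = AO_MI
    n_trials: int = 300
    class_mix: dict[int, int] | None = None
    rest_range: tuple[float, float] = (5.0, 7.0)
    task_s: float | None = None  # 2 s AO+MI / MI; 3 s MI-FB task block
    sampling_rate: float = 1000.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_kind not in (AO_MI, MI_FB):
            raise ConfigurationError(f"unknown session kind {self.session_kind!r}")
        if self.task_s is None:
            self.task_s = 2.0 if self.session_kind == AO_MI else 3.0
        if self.class_mix is None:
            if self.session_kind == AO_MI:
                half = self.n_trials // 2
                self.class_mix = {LEFT: half, RIGHT: self.n_trials - half}
            else:
                third = self.n_trials // 3
                self.class_mix = {
                    LEFT: third,
                    RIGHT: third,
                    REST: self.n_trials - 2 * third,
                }
        if sum(self.class_mix.values()) != self.n_trials:
            raise ConfigurationError("class_mix must sum to n_trials")
        if self.session_kind == AO_MI and REST in self.class_mix:
            raise ConfigurationError("AO+MI sessions have no rest-class trials")
        if self.session_kind == MI_FB and set(self.class_mix) != {LEFT, RIGHT, REST}:
            raise ConfigurationError("MI-FB sessions need left, right and rest trials")
        lo, hi = self.rest_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid rest-duration range")
        if self.task_s <= 0:
            raise ConfigurationError("task duration must be positive")
        if self.sampling_rate <= 2 * 40:
            raise ConfigurationError("sampling rate below twice the synthesized band")


def _default_profiles(montage) -> dict[int, dict[str, float]]:
    """Class -> channel -> fractional weight on erd_depth.

    Contralateral sensorimotor suppression with a shared midline component:
    left-hand imagery desynchronizes C4 (plus Cz), right-hand C3 (plus Cz).
    Lateralization is configurable; rest trials carry no ERD.
    """
    prof = {
        LEFT: {"C4": 1.0, "Cz": 0.5},
        RIGHT: {"C3": 1.0, "Cz": 0.5},
        REST: {},
    }
    return {
        cls: {ch: w for ch, w in chans.items() if ch in montage}
        for cls, chans in prof.items()
    }


@dataclasses.dataclass
class ErdModel:
    """Ground-truth signal model for the synthetic mu rhythm.

    ``erd_depth`` is the fractional band-power decrease during imagery
    (0..1); ``class_profiles`` scales it per class and channel.
    ``baseline_mu_amp`` maps channel label to resting mu amplitude in uV;
    unlisted channels get ``default_mu_amp``.
    """

    mu_freq: float = 10.0
    mu_band: tuple[float, float] = (8.0, 13.0)
    erd_depth: float = 0.4
    baseline_mu_amp: dict[str, float] | None = None
    default_mu_amp: float = 2.0
    class_profiles: dict[int, dict[str, float]] | None = None
    pink_sigma: float = 2.0  # uV RMS of the 1/f background (4-40 Hz band)
    pink_exponent: float = 1.0
    white_sigma: float = 1.0  # uV RMS of the broadband floor
    ramp_s: float = 0.1
    freq_drift_sd: float = 0.75   # Hz, sd of the wandering instantaneous frequency
    freq_drift_tau: float = 0.2   # s, correlation time of the frequency drift

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError("erd_depth must lie in [0, 1]")
        if self.baseline_mu_amp is None:
            # Mu dominates the sensorimotor leads so that band power is
            # mu-driven there and the programmed depth is recoverable.
            self.baseline_mu_amp = {"C3": 6.0, "Cz": 6.0, "C4": 6.0}
        for amp in self.baseline_mu_amp.values():
            if amp < 0:
                raise ConfigurationError("amplitudes must be nonnegative")
        if min(self.default_mu_amp, self.pink_sigma, self.white_sigma) < 0:
            raise ConfigurationError("amplitudes must be nonnegative")

    def mu_amp(self, channel: str) -> float:
        return self.baseline_mu_amp.get(channel, self.default_mu_amp)

    def depth(self, cls: int, channel: str, montage) -> float:
        profiles = self.class_profiles or _default_profiles(montage)
        return self.erd_depth * profiles.get(cls, {}).get(channel, 0.0)


def simulate_session_drift(base: ErdModel, step: int, rate: float = 0.15,
                           cap: float = 0.9) -> ErdModel:
    """Between-session change: imagery practice deepens ERD multiplicatively.

    ``step`` 0 returns ``base`` unchanged; each later step scales
    ``erd_depth`` by ``(1 + rate)`` up to ``cap``.  Deterministic.
    """
    if step < 0:
        raise ConfigurationError("step must be >= 0")
    if step == 0:
        return base
    new = dataclasses.replace(base)
    new.erd_depth = min(base.erd_depth * (1.0 + rate) ** step, cap)
    return new


def _build_timeline(spec: SessionSpec, rng: np.random.Generator):
    """Draw the trial order and rest durations; return (timeline, labels)."""
    labels = np.concatenate(
        [np.full(n, cls, dtype=np.int64) for cls, n in sorted(spec.class_mix.items())]
    )
    rng.shuffle(labels)
    blocks: list[Block] = []
    t = 0.0
    lo, hi = spec.rest_range
    for cls in labels:
        if spec.session_kind == AO_MI:
            trial_kinds = (BLOCK_AO_MI, BLOCK_AO_MI, BLOCK_MI)
        else:
            trial_kinds = (BLOCK_MI_FB_TASK,)
        for kind in trial_kinds:
            rest = float(rng.uniform(lo, hi))
            blocks.append(Block(BLOCK_REST, t, rest, None))
            t += rest
            blocks.append(Block(kind, t, spec.task_s, int(cls)))
            t += spec.task_s
    return TrialTimeline(blocks=blocks), labels


def _pink_noise(n: int, fs: float, sigma: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, scaled to ``sigma`` RMS within 4-40 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    band = (freqs >= 4.0) & (freqs <= 40.0)
    band_rms = np.sqrt(np.sum(np.abs(spec[band] * shaping[band]) ** 2) / n**2 * 2)
    if band_rms > 0:
        x *= sigma / band_rms
    return x


def _erd_envelope(n: int, fs: float, timeline: TrialTimeline, channel: str,
                  erd: ErdModel, montage) -> np.ndarray:
    """Multiplicative mu-amplitude envelope implementing per-block ERD."""
    env = np.ones(n)
    half = erd.ramp_s / 2.0
    t = np.arange(n) / fs
    for b in timeline.task_blocks():
        d = erd.depth(b.class_label, channel, montage)
        if d <= 0:
            continue
        gain = np.sqrt(1.0 - d)
        i0 = np.searchsorted(t, b.onset - half)
        i1 = np.searchsorted(t, b.onset + half)
        i2 = np.searchsorted(t, b.onset + b.duration - half)
        i3 = np.searchsorted(t, b.onset + b.duration + half)
        env[i1:i2] = gain
        if i1 > i0:  # raised-cosine ramps centred on the block edges
            phase = np.linspace(0, np.pi, i1 - i0, endpoint=False)
            env[i0:i1] = 1.0 + (gain - 1.0) * (1 - np.cos(phase)) / 2.0
        if i3 > i2:
            phase = np.linspace(0, np.pi, i3 - i2, endpoint=False)
            env[i2:i3] = gain + (1.0 - gain) * (1 - np.cos(phase)) / 2.0
    return env


def generate_session(spec: SessionSpec, erd: ErdModel | None = None):
    """Synthesize one session.

    Returns ``(raw, timeline, labels)`` where ``labels`` is the per-trial
    class sequence.  Identical ``(spec, erd)`` (including ``spec.seed``)
    produce bit-identical output.
    """
    erd = erd if erd is not None else ErdModel()
    rng = np.random.default_rng(spec.seed)
    timeline, labels = _build_timeline(spec, rng)
    fs = spec.sampling_rate
    n = int(np.ceil(timeline.duration * fs))

    signal = np.empty((len(spec.montage), n))
    for c, ch in enumerate(spec.montage):
        mu = erd.mu_amp(ch) * _mu_oscillation(n, fs, erd, rng)
        mu *= _erd_envelope(n, fs, timeline, ch, erd, spec.montage)
        pink = _pink_noise(n, fs, erd.pink_sigma, erd.pink_exponent, rng)
        white = erd.white_sigma * rng.standard_normal(n)
        signal[c] = mu + pink + white

    raw = RawRecording(
        signal=signal,
        sampling_rate=fs,
        channel_labels=spec.montage,
        meta={
            "session_kind": spec.session_kind,
            "seed": spec.seed,
            "n_trials": spec.n_trials,
            "erd_depth": erd.erd_depth,
        },
    )
    return raw, timeline, labels


def _mu_oscillation(n: int, fs: float, erd: ErdModel,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude mu rhythm: a sinusoid whose instantaneous frequency
    wanders slowly around ``mu_freq``.

    The frequency drift (sd ``freq_drift_sd`` Hz, correlation time
    ``freq_drift_tau`` s) decorrelates the phase across channels and trials,
    so no phase-locked feature exists and spatial projections do not
    interfere coherently, while the constant amplitude keeps single-trial
    band power essentially deterministic.
    """
    from scipy.ndimage import gaussian_filter1d

    phi0 = rng.uniform(0, 2 * np.pi)
    if erd.freq_drift_sd > 0:
        drift = gaussian_filter1d(
            rng.standard_normal(n), sigma=erd.freq_drift_tau * fs, mode="wrap"
        )
        sd = drift.std()
        if sd > 0:
            drift *= erd.freq_drift_sd / sd
    else:
        drift = np.zeros(n)
    theta = phi0 + 2 * np.pi * np.cumsum(erd.mu_freq + drift) / fs
    return np.sin(theta)


def class_label_names(labels) -> list[str]:
    return [CLASS_NAMES[int(v)] for v in labels]
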