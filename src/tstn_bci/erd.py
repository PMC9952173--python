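"""Event-related desynchronization / synchronization (ERD/ERS) analysis.

Relative power follows the classical Pfurtscheller formulation

    RP (%) = (A - R) / R * 100

where ``A`` is the band power in the analysis (task) window and ``R`` the
band power in the pre-cue reference window (default -2..0 s relative to
task onset), computed in the alpha/mu band (8-13 Hz by default).  Band
power is estimated by zero-phase band-pass filtering, squaring, averaging
over trials, and binning in time; the ratio cancels the estimator's scale,
so RP is invariant to global amplitude scaling of the recording.  When
analyzing model outputs, a trial mask restricts the average to (for
example) the correctly classified trials.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ConfigurationError, DataError, EpochSet


@dataclasses.dataclass
class RpConfig:
    band: tuple[float, float] = (8.0, 13.0)
    reference_window: tuple[float, float] = (-2.0, 0.0)
    analysis_window: tuple[float, float] = (0.0, 2.0)
    filter_order: int = 3
    time_resolution: float = 0.1  # seconds per RP bin

    def __post_init__(self) -> None:
        if self.reference_window[1] > self.analysis_window[0] + 1e-9:
            raise ConfigurationError("reference window must precede analysis window")
        if self.time_resolution <= 0:
            raise ConfigurationError("time_resolution must be positive")


@dataclasses.dataclass
class RPMap:
    """Time x channel relative-power values in percent."""

    values: np.ndarray              # (n_bins, n_channels)
    time_bins: np.ndarray           # bin start times, s relative to onset
    channels: tuple[str, ...] | None
    band: tuple[float, float]
    reference_window: tuple[float, float]
    n_trials: int

    def task_mean(self, window: tuple[float, float], channel: int) -> float:
        """Mean RP over bins whose start lies in ``window`` for one channel."""
        sel = (self.time_bins >= window[0]) & (self.time_bins < window[1])
        return float(self.values[sel, channel].mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, t in enumerate(self.time_bins):
            for ci in range(self.values.shape[1]):
                name = self.channels[ci] if self.channels else str(ci)
                rows.append(
                    {"time_bin_s": float(t), "channel": name,
                     "rp_percent": float(self.values[bi, ci])}
                )
        return pd.DataFrame(rows)


def relative_power(A, R):
    """Relative power change in percent, ``(A - R) / R * 100``."""
    A = np.asarray(A, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise DataError("reference power must be strictly positive")
    return (A - R) / R * 100.0


def erd_map(epochs: EpochSet, cfg: RpConfig | None = None,
            trial_mask=None, channels: tuple[str, ...] | None = None) -> RPMap:
    """Trial-averaged RP map from task-locked epochs with pre-onset context.

    ``epochs.epoch_window`` must start at or before the reference window and
    extend through the analysis window.  ``trial_mask`` is a boolean mask or
    index array selecting the trials to average (e.g. correctly classified
    ones); selecting zero trials is an error.
    """
    cfg = cfg or RpConfig()
    lo, hi = epochs.epoch_window
    if lo > cfg.reference_window[0] + 1e-9 or hi < cfg.analysis_window[1] - 1e-9:
        raise DataError(
            f"epochs cover {epochs.epoch_window}, need at least "
            f"{cfg.reference_window[0]}..{cfg.analysis_window[1]} around onset"
        )
    if trial_mask is None:
        idx = np.arange(len(epochs))
    else:
        trial_mask = np.asarray(trial_mask)
        if trial_mask.dtype == bool:
            if trial_mask.shape != (len(epochs),):
                raise DataError("mask length must equal trial count")
            idx = np.flatnonzero(trial_mask)
        else:
            idx = trial_mask
    if len(idx) == 0:
        raise DataError("trial mask selects zero trials")

    fs = epochs.sampling_rate
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass",
                     fs=fs, output="sos")
    narrow = sps.sosfiltfilt(sos, epochs.data[idx], axis=2)
    power = np.mean(narrow**2, axis=0)          # (channels, samples)

    bin_len = int(round(cfg.time_resolution * fs))
    n_samples = power.shape[1]
    n_bins = n_samples // bin_len
    binned = power[:, : n_bins * bin_len].reshape(
        power.shape[0], n_bins, bin_len
    ).mean(axis=2)                               # (channels, bins)
    t_bins = lo + np.arange(n_bins) * cfg.time_resolution

    ref_sel = (t_bins >= cfg.reference_window[0] - 1e-9) & (
        t_bins < cfg.reference_window[1] - 1e-9
    )
    if not ref_sel.any():
        raise DataError("no time bins fall inside the reference window")
    R = binned[:, ref_sel].mean(axis=1)          # per-channel reference power
    values = relative_power(binned.T, R[None, :])
    return RPMap(
        values=values,
        time_bins=t_bins,
        channels=channels,
        band=cfg.band,
        reference_window=cfg.reference_window,
        n_trials=len(idx),
    )


def render_map(rpmap: RPMap, path) -> None:
    """Save a time x channel RP heat map (blue = ERD, red = ERS)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    lim = np.nanmax(np.abs(rpmap.values)) or 1.0
    im = ax.imshow(
        rpmap.values.T, aspect="auto", origin="lower", cmap="RdBu_r",
        vmin=-lim, vmax=lim,
        extent=[rpmap.time_bins[0], rpmap.time_bins[-1],
                -0.5, rpmap.values.shape[1] - 0.5],
    )
    ax.set_xlabel("time relative to task onset (s)")
    ax.set_ylabel("channel")
    if rpmap.channels:
        ax.set_yticks(range(len(rpmap.channels)), rpmap.channels)
    fig.colorbar(im, ax=ax, label="relative power (%)")
    ax.set_title(
        f"{rpmap.band[0]:g}-{rpmap.band[1]:g} Hz relative power "
        f"(n={rpmap.n_trials})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
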