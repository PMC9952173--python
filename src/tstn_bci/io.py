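"""Containers and on-disk formats for continuous recordings and epoch sets.

Three formats are supported:

* EDF (European Data Format, 16-bit) for continuous multichannel EEG.
  Reading goes through :func:`mne.io.read_raw_edf`; writing uses a minimal
  EDF writer implemented here.  EDF stores an integer number of 1-second
  data records, so the final partial second of a recording is zero-padded
  on write and a read-back signal may be up to one second longer than the
  source.  Trial structure lives in the event table, which is unaffected.
* A tab-separated event table (columns ``onset_s``, ``duration_s``,
  ``block_kind``, ``class_label``) describing the trial timeline.
  Timestamps are seconds, 0-based from recording start.
* A single-file HDF5 epoch archive holding ``data`` (trials x channels x
  samples), integer class ``labels``, per-trial provenance, and metadata
  attributes including a format version.  Round trips are lossless.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Integer class codes used throughout the package (fixed order).
LEFT, RIGHT, REST = 0, 1, 2
CLASS_NAMES = ("left", "right", "rest")

EPOCH_ARCHIVE_VERSION = 1


class FormatError(RuntimeError):
    """A file does not conform to its declared format."""


class ConfigurationError(ValueError):
    """Inconsistent or invalid configuration."""


class DataError(ValueError):
    """Input data violate an operation's preconditions."""


@dataclasses.dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    ``signal`` is channels x samples; ``meta`` is free-form provenance
    (subject id, session kind, generator seed, ...).
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise DataError("signal must be channels x samples")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            raise DataError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclasses.dataclass
class EpochSet:
    """Labeled trials x channels x samples array with provenance.

    ``epoch_window`` is (start_s, end_s) relative to block onset, half-open
    ``[start, end)``.  ``provenance`` is a DataFrame with one row per trial
    (columns ``session_id``, ``block_kind``, ``trial_index``).
    """

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    epoch_window: tuple[float, float]
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise DataError("data must be trials x channels x samples")
        if self.labels.shape != (self.data.shape[0],):
            raise DataError("labels length must equal trial count")
        lo, hi = self.epoch_window
        n_expected = int(round((hi - lo) * self.sampling_rate))
        if self.data.shape[0] and n_expected != self.data.shape[2]:
            raise ConfigurationError(
                f"epoch_window {self.epoch_window} at {self.sampling_rate} Hz "
                f"implies {n_expected} samples, data has {self.data.shape[2]}"
            )
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                {
                    "session_id": [""] * len(self),
                    "block_kind": [""] * len(self),
                    "trial_index": np.arange(len(self)),
                }
            )
        if len(self.provenance) != len(self):
            raise DataError("provenance row count must equal trial count")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            sampling_rate=self.sampling_rate,
            epoch_window=self.epoch_window,
            provenance=self.provenance.iloc[idx].reset_index(drop=True),
        )

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == code))
            for code, name in enumerate(CLASS_NAMES)
        }


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets sharing rate, window, and channel count."""
    if not sets:
        raise DataError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.sampling_rate != first.sampling_rate:
            raise ConfigurationError("sampling rates differ")
        if s.epoch_window != first.epoch_window:
            raise ConfigurationError("epoch windows differ")
        if s.n_channels != first.n_channels:
            raise ConfigurationError("channel counts differ")
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        sampling_rate=first.sampling_rate,
        epoch_window=first.epoch_window,
        provenance=pd.concat(
            [s.provenance for s in sets], ignore_index=True
        ),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(raw: RawRecording, path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    Physical units are microvolts.  The last partial record, if any, is
    zero-padded.  Sampling rate must be a positive integer (EDF stores an
    integer sample count per record).
    """
    fs = raw.sampling_rate
    if fs != int(fs) or fs <= 0:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch = raw.n_channels
    n_rec = int(np.ceil(raw.n_samples / fs)) if raw.n_samples else 0

    sig = np.zeros((n_ch, n_rec * fs))
    sig[:, : raw.n_samples] = raw.signal

    # Per-channel symmetric physical range with headroom; digital +/-32767.
    phys_max = np.maximum(np.abs(sig).max(axis=1), 1e-6) * 1.000001
    scale = 32767.0 / phys_max
    digital = np.rint(sig * scale[:, None]).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad(str(raw.meta.get("subject_id", "X")), 80),
            pad(str(raw.meta.get("session_kind", "synthetic")), 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, list(raw.channel_labels)),
        (80, ["EEG"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, ["-32767"] * n_ch),
        (8, ["32767"] * n_ch),
        (80, [""] * n_ch),
        (8, [str(fs)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path, verbose=False) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (signal in microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_edf_integrity(path)
    try:
        mraw = mne.io.read_raw_edf(path, preload=True, verbose=verbose)
    except Exception as exc:  # malformed beyond the structural checks
        raise FormatError(f"cannot parse EDF {path}: {exc}") from exc
    data = mraw.get_data() * 1e6  # mne loads Volts
    return RawRecording(
        signal=data,
        sampling_rate=float(mraw.info["sfreq"]),
        channel_labels=tuple(mraw.ch_names),
        meta={"source": str(path)},
    )


def _check_edf_integrity(path: Path) -> None:
    """Structural sanity check: header complete and data area full length."""
    size = path.stat().st_size
    if size < 256:
        raise FormatError(f"{path}: truncated EDF header at byte {size}")
    with open(path, "rb") as fh:
        head = fh.read(256)
        try:
            header_bytes = int(head[184:192].decode().strip())
            n_rec = int(head[236:244].decode().strip())
            n_ch = int(head[252:256].decode().strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable EDF header") from exc
        if size < header_bytes:
            raise FormatError(
                f"{path}: truncated EDF at byte {size}, header declares "
                f"{header_bytes} header bytes"
            )
        # samples-per-record fields sit after label/transducer/unit/range blocks
        fh.seek(256 + n_ch * (16 + 80 + 8 * 5 + 80))
        spr_raw = fh.read(8 * n_ch)
        try:
            samples_per_rec = sum(
                int(spr_raw[i * 8 : (i + 1) * 8].decode().strip())
                for i in range(n_ch)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad samples-per-record field") from exc
    expected = header_bytes + 2 * samples_per_rec * n_rec
    if size < expected:
        raise FormatError(
            f"{path}: truncated EDF at byte {size}, expected {expected}"
        )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def write_event_table(timeline, path) -> None:
    """Write a trial timeline as a TSV event table."""
    rows = [
        {
            "onset_s": b.onset,
            "duration_s": b.duration,
            "block_kind": b.kind,
            "class_label": "" if b.class_label is None
            else CLASS_NAMES[b.class_label],
        }
        for b in timeline.blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_event_table(path):
    """Read a TSV event table back into a :class:`~tstn_bci.synth.TrialTimeline`."""
    from .synth import Block, TrialTimeline

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"onset_s", "duration_s", "block_kind", "class_label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    name_to_code = {n: i for i, n in enumerate(CLASS_NAMES)}
    blocks = [
        Block(
            kind=row.block_kind,
            onset=float(row.onset_s),
            duration=float(row.duration_s),
            class_label=name_to_code.get(str(row.class_label)) if row.class_label else None,
        )
        for row in df.itertuples()
    ]
    return TrialTimeline(blocks=blocks)


# ---------------------------------------------------------------------------
# Epoch archive (HDF5)
# ---------------------------------------------------------------------------

def write_epoch_archive(epochs: EpochSet, path) -> None:
    """Write an epoch set to a single HDF5 archive (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = EPOCH_ARCHIVE_VERSION
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["epoch_window"] = list(epochs.epoch_window)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        prov = epochs.provenance
        str_t = h5py.string_dtype()
        f.create_dataset(
            "provenance/session_id", shape=(len(prov),), dtype=str_t,
            data=prov["session_id"].astype(str).to_numpy(dtype=object),
        )
        f.create_dataset(
            "provenance/block_kind", shape=(len(prov),), dtype=str_t,
            data=prov["block_kind"].astype(str).to_numpy(dtype=object),
        )
        f.create_dataset(
            "provenance/trial_index", data=prov["trial_index"].to_numpy(np.int64)
        )


def read_epoch_archive(path) -> EpochSet:
    """Read an epoch archive written by :func:`write_epoch_archive`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != EPOCH_ARCHIVE_VERSION:
            raise FormatError(
                f"{path}: archive format version {version}, "
                f"this build reads version {EPOCH_ARCHIVE_VERSION}"
            )
        prov = pd.DataFrame(
            {
                "session_id": [s.decode() if isinstance(s, bytes) else s
                               for s in f["provenance/session_id"][()]],
                "block_kind": [s.decode() if isinstance(s, bytes) else s
                               for s in f["provenance/block_kind"][()]],
                "trial_index": f["provenance/trial_index"][()],
            }
        )
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            epoch_window=tuple(f.attrs["epoch_window"]),
            provenance=prov,
        )
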