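"""Loading continuous multichannel recordings, epoching, and artifact IO.

Supported input formats:

* **EDF** — read through :func:`mne.io.read_raw_edf`; channel labels come
  from the EDF header in order, amplitudes are converted to microvolts.
* **delimited** — a plain text matrix (CSV/TSV/whitespace), channels as rows
  by default, with the sampling rate supplied by the caller.
* **binary** — a raw little-endian float array with a JSON sidecar
  (``<path>.json``) holding ``sfreq``, ``n_channels``, ``dtype`` and
  optionally ``channel_names``.

Inputs are assumed pre-cleaned (re-referencing, band-pass/notch filtering and
ICA artifact removal happen upstream); this module only epochs and moves data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._partition import SegmentPartition

__all__ = [
    "ContinuousRecording",
    "EpochedRecording",
    "load_recording",
    "epoch_signal",
    "write_partition",
    "read_partition",
    "write_manifest",
]


@dataclass
class ContinuousRecording:
    """A channels x samples block with its sampling rate and channel labels."""

    signal: np.ndarray  # (n_channels, n_samples), microvolts
    sfreq: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.sfreq <= 0:
            raise ValueError(f"sfreq must be positive, got {self.sfreq}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.isfinite(self.signal).all():
            bad = np.argwhere(~np.isfinite(self.signal))[0]
            raise ValueError(
                f"non-finite sample at channel {bad[0]} "
                f"({self.channel_names[bad[0]]}), sample {bad[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochedRecording:
    """Fixed-length non-overlapping epochs cut from a continuous recording.

    ``epoch_index`` carries the original 0-based position of each retained
    epoch in the continuous record; after artifact rejection all downstream
    indices refer to positions in the retained sequence and ``epoch_index``
    is reporting-only.
    """

    data: np.ndarray  # (n_epochs, n_channels, samples_per_epoch)
    epoch_len_s: float
    sfreq: float
    channel_names: list[str]
    epoch_index: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.epoch_index = np.asarray(self.epoch_index, dtype=np.int64)
        expected = round(self.epoch_len_s * self.sfreq)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"samples_per_epoch {self.data.shape[2]} != "
                f"round(epoch_len_s * sfreq) = {expected}"
            )
        if np.any(np.diff(self.epoch_index) <= 0):
            raise ValueError("epoch_index must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select_epochs(self, keep: np.ndarray) -> "EpochedRecording":
        """Subset epochs (boolean mask or index array), keeping provenance."""
        return EpochedRecording(
            self.data[keep],
            self.epoch_len_s,
            self.sfreq,
            list(self.channel_names),
            self.epoch_index[keep],
        )


def _load_edf(path: Path) -> ContinuousRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return ContinuousRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _load_delimited(
    path: Path,
    sfreq: float | None,
    channel_names: list[str] | None,
    orientation: str,
    delimiter: str | None,
) -> ContinuousRecording:
    if sfreq is None:
        raise ValueError("delimited input requires an explicit sampling rate")
    df = pd.read_csv(path, header=None, delimiter=delimiter, engine="python")
    mat = df.to_numpy(dtype=np.float64)
    if np.isnan(mat).any():
        r, c = np.argwhere(np.isnan(mat))[0]
        raise ValueError(f"NaN value in {path} at row {r}, column {c}")
    if orientation == "channels_columns":
        mat = mat.T
    elif orientation != "channels_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    names = channel_names or [f"ch{i}" for i in range(mat.shape[0])]
    return ContinuousRecording(mat, float(sfreq), names)


def _load_binary(path: Path) -> ContinuousRecording:
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise ValueError(f"binary input requires a sidecar file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("sfreq", "n_channels", "dtype"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required key {key!r}")
    flat = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    n_ch = int(meta["n_channels"])
    if flat.size % n_ch:
        raise ValueError(f"{flat.size} samples not divisible by {n_ch} channels")
    mat = flat.reshape(n_ch, -1).astype(np.float64)
    names = meta.get("channel_names") or [f"ch{i}" for i in range(n_ch)]
    return ContinuousRecording(mat, float(meta["sfreq"]), names)


def load_recording(
    path,
    format: str = "auto",
    *,
    sfreq: float | None = None,
    channel_names: list[str] | None = None,
    orientation: str = "channels_rows",
    delimiter: str | None = None,
) -> ContinuousRecording:
    """Load a continuous recording from EDF, delimited text or raw binary.

    ``format="auto"`` dispatches on the file suffix (``.edf``, ``.bin``/
    ``.raw``, anything else is treated as delimited text).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {"edf": "edf", ".edf": "edf", ".bin": "binary", ".raw": "binary"}.get(
            suffix, "delimited"
        )
    if format == "edf":
        return _load_edf(path)
    if format == "delimited":
        return _load_delimited(path, sfreq, channel_names, orientation, delimiter)
    if format in ("binary", "binary-matrix"):
        return _load_binary(path)
    raise ValueError(f"unknown format {format!r}")


def epoch_signal(rec: ContinuousRecording, epoch_len_s: float = 1.0) -> EpochedRecording:
    """Cut a continuous recording into non-overlapping fixed-length epochs.

    A trailing partial epoch is discarded, not padded, so every epoch feeds
    identically-shaped spectral estimators.
    """
    samples = epoch_len_s * rec.sfreq
    if abs(samples - round(samples)) > 1e-9 or round(samples) <= 0:
        raise ValueError(
            f"epoch_len_s * sfreq = {samples} is not a positive integer sample count"
        )
    spe = int(round(samples))
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.signal[:, : n_epochs * spe].reshape(rec.n_channels, n_epochs, spe)
    return EpochedRecording(
        data.transpose(1, 0, 2),
        epoch_len_s,
        rec.sfreq,
        list(rec.channel_names),
        np.arange(n_epochs),
    )


def write_partition(partition: SegmentPartition, path, epoch_len_s: float = 1.0) -> None:
    """Write a partition as a CSV of (state_id, start_epoch, end_epoch, duration_s)."""
    rows = [
        {
            "state_id": i + 1,
            "start_epoch": lo,
            "end_epoch": hi,
            "duration_s": (hi - lo) * epoch_len_s,
        }
        for i, (lo, hi) in enumerate(partition.segments)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_partition(path) -> SegmentPartition:
    """Read a partition CSV written by :func:`write_partition`."""
    df = pd.read_csv(path)
    required = {"state_id", "start_epoch", "end_epoch"}
    if not required.issubset(df.columns):
        raise ValueError(f"partition file {path} missing columns {required - set(df.columns)}")
    df = df.sort_values("start_epoch")
    starts = df["start_epoch"].to_numpy(dtype=np.int64)
    ends = df["end_epoch"].to_numpy(dtype=np.int64)
    if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
        raise ValueError(f"segments in {path} do not tile the epoch range")
    return SegmentPartition(np.concatenate((starts, ends[-1:])))


def write_manifest(path, *, seed=None, **params) -> None:
    """Write a JSON run manifest (hyperparameters, seed, package versions)."""
    import sklearn

    import statedetect

    manifest = {
        "statedetect": statedetect.__version__,
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
        "seed": seed,
        "params": params,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
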