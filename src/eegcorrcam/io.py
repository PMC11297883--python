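"""Reading, validating and segmenting multi-channel EEG recordings.

Recordings are channels x samples arrays in microvolts with an explicit
montage (ordered channel labels).  The only preprocessing applied here is
segmentation into fixed-length non-overlapping epochs; no filtering,
re-referencing or artifact rejection is performed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: The 12-channel clinical montage used as the package default.
DEFAULT_MONTAGE = (
    "Fp1", "Fp2", "F3", "F4", "P3", "P4", "O1", "O2", "F7", "F8", "T3", "T4",
)


class MontageError(ValueError):
    """A requested channel label is absent from the source file."""


class FormatError(ValueError):
    """The source file violates the expected container format."""


@dataclass
class Recording:
    """A labelled continuous multi-channel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered montage labels; one per row of ``data``.
    subject_id : str
        Opaque subject identifier.
    label : str or None
        Class tag (e.g. ``"ADHD"``, ``"ADHD+CD"``, ``"CD"``).
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length non-overlapping segment of a recording."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    source_subject: str = ""
    index: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_recording(
    path: str | Path,
    format: str | None = None,
    montage: Sequence[str] = DEFAULT_MONTAGE,
    fs: float | None = None,
    subject_id: str | None = None,
    label: str | None = None,
) -> Recording:
    """Read a multi-channel EEG recording from EDF or CSV.

    Channels are re-ordered to match ``montage`` exactly; channels in the
    file that are not in the montage are dropped.

    Parameters
    ----------
    path : path
        Source file.
    format : {"edf", "csv"}, optional
        Inferred from the suffix when omitted.
    montage : sequence of str
        Ordered channel labels to extract.
    fs : float, optional
        Sampling rate; required for CSV (the format carries no metadata)
        and ignored for EDF (taken from the header).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    montage = tuple(montage)
    if subject_id is None:
        subject_id = path.stem

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        missing = [ch for ch in montage if ch not in raw.ch_names]
        if missing:
            raise MontageError(f"channel(s) {missing} not present in {path.name}")
        data = raw.get_data(picks=list(montage)) * 1e6  # volts -> microvolts
        return Recording(data, float(raw.info["sfreq"]), montage, subject_id, label)

    if format == "csv":
        if fs is None:
            raise FormatError("CSV input requires an explicit sampling rate")
        frame = pd.read_csv(path)
        missing = [ch for ch in montage if ch not in frame.columns]
        if missing:
            raise MontageError(f"channel(s) {missing} not present in {path.name}")
        data = frame.loc[:, list(montage)].to_numpy(dtype=float).T
        return Recording(data, float(fs), montage, subject_id, label)

    raise FormatError(f"unsupported format {format!r} (expected 'edf' or 'csv')")


def segment(recording: Recording, epoch_seconds: float) -> list[Epoch]:
    """Cut a recording into non-overlapping fixed-length epochs.

    Windows start at sample 0; the trailing remainder shorter than one
    epoch is discarded, so a recording shorter than one epoch yields an
    empty list.  Epoch length is ``floor(epoch_seconds * fs)`` samples.
    """
    if not epoch_seconds > 0:
        raise ValueError("epoch_seconds must be positive")
    length = int(np.floor(epoch_seconds * recording.fs))
    n_epochs = recording.n_samples // length
    return [
        Epoch(
            data=recording.data[:, i * length : (i + 1) * length].copy(),
            fs=recording.fs,
            channel_names=recording.channel_names,
            source_subject=recording.subject_id,
            index=i,
            label=recording.label,
        )
        for i in range(n_epochs)
    ]


# ---------------------------------------------------------------------------
# HDF5 epoch container

def save_epochs(path: str | Path, epochs: Sequence[Epoch],
                label_names: Sequence[str] | None = None,
                folds: Sequence[int] | None = None) -> None:
    """Write epochs to an HDF5 container.

    Layout: ``/epochs`` (N x C x L float32), ``/labels`` (int, indexing the
    ``label_names`` attribute), ``/subjects`` (strings), ``/epoch_index``,
    optional ``/folds``; sampling rate and montage stored as root attributes.
    """
    if not epochs:
        raise ValueError("no epochs to save")
    if label_names is None:
        label_names = sorted({e.label for e in epochs if e.label is not None})
    label_to_idx = {l: i for i, l in enumerate(label_names)}
    data = np.stack([e.data for e in epochs]).astype(np.float32)
    labels = np.array([label_to_idx.get(e.label, -1) for e in epochs], dtype=np.int64)
    subjects = np.array([e.source_subject for e in epochs], dtype=h5py.string_dtype())
    indices = np.array([e.index for e in epochs], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=data)
        f.create_dataset("labels", data=labels)
        f.create_dataset("subjects", data=subjects)
        f.create_dataset("epoch_index", data=indices)
        if folds is not None:
            f.create_dataset("folds", data=np.asarray(folds, dtype=np.int64))
        f.attrs["fs"] = epochs[0].fs
        f.attrs["montage"] = list(epochs[0].channel_names)
        f.attrs["label_names"] = list(label_names)


def load_epochs(path: str | Path) -> list[Epoch]:
    """Read epochs back from the HDF5 container written by :func:`save_epochs`."""
    out: list[Epoch] = []
    with h5py.File(path, "r") as f:
        data = f["epochs"][...]
        labels = f["labels"][...]
        subjects = [s.decode() if isinstance(s, bytes) else s for s in f["subjects"][...]]
        indices = f["epoch_index"][...]
        fs = float(f.attrs["fs"])
        montage = tuple(str(c) for c in f.attrs["montage"])
        label_names = [str(l) for l in f.attrs["label_names"]]
    for i in range(data.shape[0]):
        lab = label_names[labels[i]] if labels[i] >= 0 else None
        out.append(Epoch(data[i], fs, montage, subjects[i], int(indices[i]), lab))
    return out


# ---------------------------------------------------------------------------
# Minimal EDF export (for round-trip tests of the reader)

def write_edf(path: str | Path, recording: Recording) -> None:
    """Write a recording as a minimal EDF file.

    One data record per second; each signal is quantised to 16-bit integers
    over its physical range, so the round trip is accurate to roughly
    ``(max - min) / 2**16`` in microvolts.  Intended for small exports and
    reader round-trip tests, not clinical archiving.
    """
    rec = recording
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    n_sig = rec.n_channels
    data = rec.data[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max - phys_min < 1e-12, 1.0, phys_max - phys_min)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / span
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(rec.subject_id or "X", 80),
        pad("Startdate X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * n_sig), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_sig), 4),
    ])
    fields = [
        (16, list(rec.channel_names)),
        (80, ["EEG"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, [str(dig_min)] * n_sig),
        (8, [str(dig_max)] * n_sig),
        (80, [""] * n_sig),
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(struct.pack(f"<{n_sig * spr}h", *block.ravel()))
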