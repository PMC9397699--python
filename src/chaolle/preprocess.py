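"""Segmentation, band-pass filtering and channel selection for motor-imagery EEG.

Continuous multichannel recordings are cut into fixed-length epochs around
cue markers (200 ms before to 2500 ms after the cue by default), band-pass
filtered with a zero-phase Butterworth filter in the mu/low-beta range
(8-15 Hz), and reduced to the sensorimotor channels of interest
(C3 and CP5 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as _signal

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "segment_trials",
    "bandpass_filter",
    "select_channels",
    "read_delimited_recording",
    "read_edf_recording",
]

#: canonical binary labels: 0 = open hand, 1 = fist
LABELS = {"open": 0, "fist": 1}


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with cue markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    markers : list of (int, str)
        ``(sample_index, label)`` pairs; labels are ``"open"`` or ``"fist"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        n = self.data.shape[1]
        for idx, label in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker at sample {idx} outside record of length {n}")
            if label not in LABELS:
                raise ValueError(f"unknown marker label {label!r}; expected one of {sorted(LABELS)}")


@dataclass
class EpochSet:
    """Labeled fixed-length multichannel epochs.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
    labels : ndarray of int, shape (n_epochs,)
        0 = open hand, 1 = fist.
    fs : float
    channel_names : list of str
    window : (float, float)
        ``(pre_ms, post_ms)`` relative to the cue.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    window: tuple[float, float] = (200.0, 2500.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match epoch count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        if self.data.size and not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        extra = set(np.unique(self.labels)) - {0, 1}
        if extra:
            raise ValueError(f"labels must be binary (0/1); found {sorted(extra)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n_epochs

    def subset(self, idx) -> "EpochSet":
        """Return a new EpochSet restricted to the epochs in ``idx``."""
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], labels=self.labels[idx])


def epoch_length(pre_ms: float, post_ms: float, fs: float) -> int:
    """Number of samples in one epoch window."""
    return int(round((pre_ms + post_ms) * fs / 1000.0))


def segment_trials(rec: ContinuousRecording, pre_ms: float = 200.0,
                   post_ms: float = 2500.0) -> EpochSet:
    """Cut one epoch per marker, spanning [cue - pre_ms, cue + post_ms).

    Windows use 0-based, half-open sample indexing: a marker at sample ``m``
    with fs=1000 and the default window yields samples ``[m-200, m+2500)``.
    """
    n_pre = int(round(pre_ms * rec.fs / 1000.0))
    length = epoch_length(pre_ms, post_ms, rec.fs)
    n = rec.data.shape[1]

    bad = [(m, lab) for m, lab in rec.markers
           if m - n_pre < 0 or m - n_pre + length > n]
    if bad:
        raise ValueError(
            "markers too close to the record edge for the requested window: "
            + ", ".join(f"{lab}@{m}" for m, lab in bad)
        )

    epochs = np.empty((len(rec.markers), rec.data.shape[0], length))
    labels = np.empty(len(rec.markers), dtype=int)
    for k, (m, lab) in enumerate(rec.markers):
        start = m - n_pre
        epochs[k] = rec.data[:, start:start + length]
        labels[k] = LABELS[lab]
    if not rec.markers:
        epochs = np.empty((0, rec.data.shape[0], length))
        labels = np.empty(0, dtype=int)
    return EpochSet(epochs, labels, rec.fs, list(rec.channel_names),
                    window=(pre_ms, post_ms))


def bandpass_filter(epochs: EpochSet, low: float = 8.0, high: float = 15.0,
                    order: int = 6) -> EpochSet:
    """Zero-phase Butterworth band-pass, applied per channel and epoch.

    The filter is designed as second-order sections and run forward-backward
    (``sosfiltfilt``), so the effective attenuation is that of a filter of
    twice the nominal order and the pass band keeps zero phase shift —
    event-related power changes are not delayed by the filter.
    """
    if epochs.fs <= 2 * high:
        raise ValueError(f"fs={epochs.fs} must exceed twice the upper edge {high} Hz")
    sos = _signal.butter(order, [low, high], btype="bandpass", fs=epochs.fs,
                         output="sos")
    if epochs.n_epochs == 0:
        return replace(epochs)
    filtered = _signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=filtered)


def select_channels(epochs: EpochSet, names: list[str] = ("C3", "CP5")) -> EpochSet:
    """Subset channels, honoring the requested order."""
    names = list(names)
    missing = [c for c in names if c not in epochs.channel_names]
    if missing:
        raise KeyError(
            f"channels {missing} not found; available: {epochs.channel_names}"
        )
    idx = [epochs.channel_names.index(c) for c in names]
    return replace(epochs, data=epochs.data[:, idx, :], channel_names=names)


# ---------------------------------------------------------------------------
# readers

def read_delimited_recording(matrix_path: str | Path,
                             sidecar_path: str | Path | None = None,
                             delimiter: str = ",") -> ContinuousRecording:
    """Read a channels-x-samples text matrix plus a JSON sidecar.

    The sidecar holds ``{"fs": ..., "channel_names": [...],
    "markers": [[sample, label], ...]}`` and defaults to
    ``<matrix>.json`` next to the matrix file.
    """
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(matrix_path.suffix + ".json")
    meta = json.loads(Path(sidecar_path).read_text())
    data = np.loadtxt(matrix_path, delimiter=delimiter, ndmin=2)
    markers = [(int(m), str(lab)) for m, lab in meta.get("markers", [])]
    return ContinuousRecording(data, float(meta["fs"]),
                               list(meta["channel_names"]), markers)


def read_edf_recording(path: str | Path,
                       marker_map: dict[str, str] | None = None) -> ContinuousRecording:
    """Read an EDF file into a ContinuousRecording (requires ``mne``).

    ``marker_map`` maps annotation descriptions onto the two class labels;
    annotations with no mapping are ignored.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    markers: list[tuple[int, str]] = []
    marker_map = marker_map or {}
    for ann in raw.annotations:
        label = marker_map.get(ann["description"])
        if label in LABELS:
            markers.append((int(round(ann["onset"] * fs)), label))
    return ContinuousRecording(data, fs, list(raw.ch_names), markers)
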