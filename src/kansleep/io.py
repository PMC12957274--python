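"""Recording I/O, filtering, epoching and per-epoch normalization.

A :class:`Recording` holds a multichannel polysomnography signal matrix in
microvolts together with its sampling rate.  Recordings are read either from
EDF files (through :mod:`mne`, optional) or from the package's plain-text
fixture format, which is what the test-suite and the synthetic generator use
so that no download is ever required.

Fixture format (one file per recording)::

    # kansleep-recording v1
    # subject_id: <string>
    # session_id: <string>
    # fs: <float Hz>
    # channels: <tab-separated channel labels>
    <tab-separated sample rows, one row per time point, one column per channel>

Hypnograms are a separate plain-text file with one stage token
(``W``/``N1``/``N2``/``N3``/``REM``) per line, one line per 30-s epoch,
0-based epoch indexing; epoch ``i`` covers the half-open sample window
``[i*30*fs, (i+1)*30*fs)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from scipy import signal as sps

from .stages import stages_from_tokens, tokens_from_stages

EPOCH_SECONDS = 30
#: Reference sampling rate; recordings at other rates are resampled to this
#: before epoching so convolution kernel sizes keep one temporal meaning.
TARGET_FS = 100.0

FIXTURE_MAGIC = "# kansleep-recording v1"


@dataclass
class Recording:
    """Multichannel signal matrix ``[n_channels x n_samples]`` in microvolts."""

    signals: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D [n_channels x n_samples]")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochedDataset:
    """Contiguous 30-s epochs: tensor ``[L x N x Ts]`` plus stage labels."""

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    epoch_seconds: int = EPOCH_SECONDS
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [L x N x Ts]")
        ts = int(round(self.fs * self.epoch_seconds))
        if self.epochs.shape[2] != ts:
            raise ValueError(f"Ts must equal fs*{self.epoch_seconds} = {ts}")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("label count must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def ts(self) -> int:
        return self.epochs.shape[2]


@dataclass
class NormalizedEpoch:
    """Per-channel z-scored 30-s epoch with the removed statistics kept."""

    values: np.ndarray
    source_mean: np.ndarray
    source_std: np.ndarray
    constant_channels: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


# ---------------------------------------------------------------------------
# reading / writing


def write_fixture(path, recording: Recording) -> None:
    """Write a recording in the plain-text fixture format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(FIXTURE_MAGIC + "\n")
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write(f"# session_id: {recording.session_id}\n")
        fh.write(f"# fs: {recording.fs!r}\n")
        fh.write("# channels: " + "\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.signals.T, fmt="%.6g", delimiter="\t")


def _read_fixture(path: Path) -> Recording:
    with path.open() as fh:
        magic = fh.readline().strip()
        if magic != FIXTURE_MAGIC:
            raise ValueError(f"{path} is not a kansleep fixture recording")
        header: dict[str, str] = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    labels = header["channels"].split("\t")
    return Recording(
        signals=data.T,
        fs=float(header["fs"]),
        channel_labels=labels,
        subject_id=header.get("subject_id", ""),
        session_id=header.get("session_id", ""),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    # MNE returns volts for EEG-like channels; express in microvolts.
    return Recording(
        signals=raw.get_data() * 1e6,
        fs=fs,
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def read_recording(path, channel_selection: list[str] | None = None) -> Recording:
    """Read a recording from a fixture file or an EDF file.

    ``channel_selection`` restricts and reorders the channels; an unknown
    label raises ``KeyError`` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        rec = _read_fixture(path)
    if channel_selection is not None:
        idx = []
        for label in channel_selection:
            if label not in rec.channel_labels:
                raise KeyError(f"channel label {label!r} not present in {path}")
            idx.append(rec.channel_labels.index(label))
        rec = Recording(
            signals=rec.signals[idx],
            fs=rec.fs,
            channel_labels=list(channel_selection),
            subject_id=rec.subject_id,
            session_id=rec.session_id,
        )
    return rec


def read_hypnogram(path) -> np.ndarray:
    """Read a one-token-per-line stage file into integer codes."""
    tokens = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return stages_from_tokens(tokens)


def write_hypnogram(path, labels) -> None:
    Path(path).write_text("\n".join(tokens_from_stages(labels)) + "\n")


# ---------------------------------------------------------------------------
# filtering and denoising


def filter_signal(x, fs: float, kind: str = "bandpass", band=(0.3, 35.0), order: int = 4):
    """Zero-phase Butterworth band-pass or notch filter.

    ``band`` is a ``(low, high)`` Hz pair for ``bandpass`` or a center
    frequency for ``notch``.  Filtering is forward-backward (``sosfiltfilt``
    / ``filtfilt``) so the output is phase-neutral and has the input length.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input signal")
    nyq = fs / 2.0
    if kind == "bandpass":
        lo, hi = band
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band edges {band} must satisfy 0 < lo < hi < fs/2 = {nyq}")
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x)
    if kind == "notch":
        f0 = float(band[0]) if np.ndim(band) else float(band)
        if not (0 < f0 < nyq):
            raise ValueError(f"notch frequency {f0} must be below fs/2 = {nyq}")
        b, a = sps.iirnotch(f0, Q=30.0, fs=fs)
        return sps.filtfilt(b, a, x)
    raise ValueError(f"unknown filter kind {kind!r}")


def wavelet_denoise(x, wavelet: str = "db4", level: int = 4):
    """Wavelet shrinkage denoising of a 1-D signal.

    4-level decomposition with an orthogonal Daubechies wavelet; detail
    coefficients are soft-thresholded with the universal threshold
    ``sigma * sqrt(2 ln n)`` where ``sigma`` is estimated from the median
    absolute deviation of the finest detail level.  Output length equals
    input length.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input signal")
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    if max_level < 1:
        raise ValueError("signal shorter than one wavelet decomposition support")
    level = min(level, max_level)
    coeffs = pywt.wavedec(x, w, level=level, mode="periodization")
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if len(coeffs[-1]) else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    if thr == 0.0:
        return x.copy()
    den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(den, w, mode="periodization")[: len(x)]


def resample_recording(recording: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Resample all channels to ``target_fs`` (polyphase, fs ratios rational)."""
    if abs(recording.fs - target_fs) < 1e-9:
        return recording
    from fractions import Fraction

    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    out = sps.resample_poly(recording.signals, frac.numerator, frac.denominator, axis=1)
    return Recording(
        signals=out,
        fs=target_fs,
        channel_labels=list(recording.channel_labels),
        subject_id=recording.subject_id,
        session_id=recording.session_id,
    )


# ---------------------------------------------------------------------------
# epoching and normalization


def segment_epochs(recording: Recording, labels) -> EpochedDataset:
    """Cut a recording into contiguous 30-s epochs aligned with its labels.

    ``L = floor(n_samples / (30*fs))``; a trailing partial epoch is
    discarded.  The label sequence may be one epoch longer or shorter than
    the signal supports (a common off-by-one between hypnogram and signal
    files); any larger mismatch raises.
    """
    labels = np.asarray(labels, dtype=np.int64)
    ts = int(round(recording.fs * EPOCH_SECONDS))
    n_sig = recording.n_samples // ts
    if n_sig < 1:
        raise ValueError("recording shorter than one 30-s epoch")
    if abs(len(labels) - n_sig) > 1:
        raise ValueError(
            f"label count {len(labels)} inconsistent with signal epochs {n_sig}"
        )
    n = min(n_sig, len(labels))
    epochs = recording.signals[:, : n * ts].reshape(recording.n_channels, n, ts)
    epochs = np.transpose(epochs, (1, 0, 2))
    rid = recording.subject_id + ("/" + recording.session_id if recording.session_id else "")
    return EpochedDataset(epochs=epochs, labels=labels[:n], fs=recording.fs, recording_id=rid)


def zscore_epoch(epoch) -> NormalizedEpoch:
    """Per-epoch, per-channel z-score: ``(X - mu) / sigma``.

    ``mu`` and ``sigma`` are the mean and population standard deviation of
    this epoch's channel.  Channels whose sigma is below 1e-12 (flat or
    disconnected leads) are mapped to zeros and flagged, with a warning,
    rather than aborting the run.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim == 1:
        epoch = epoch[None, :]
    if epoch.shape[1] < 2:
        raise ValueError("epoch must contain at least 2 samples")
    if not np.all(np.isfinite(epoch)):
        raise ValueError("non-finite values in epoch")
    mu = epoch.mean(axis=1)
    sigma = epoch.std(axis=1)  # population form (divide by Ts)
    constant = sigma < 1e-12
    safe = np.where(constant, 1.0, sigma)
    values = (epoch - mu[:, None]) / safe[:, None]
    if constant.any():
        values[constant] = 0.0
        warnings.warn(
            f"{int(constant.sum())} constant channel(s) in epoch mapped to zeros",
            stacklevel=2,
        )
    return NormalizedEpoch(values=values, source_mean=mu, source_std=sigma,
                           constant_channels=constant)


def normalize_dataset(ds: EpochedDataset) -> EpochedDataset:
    """Apply :func:`zscore_epoch` to every epoch of a dataset."""
    out = np.empty_like(ds.epochs)
    mu = ds.epochs.mean(axis=2, keepdims=True)
    sigma = ds.epochs.std(axis=2, keepdims=True)
    constant = sigma < 1e-12
    np.divide(ds.epochs - mu, np.where(constant, 1.0, sigma), out=out)
    out[np.broadcast_to(constant, out.shape)] = 0.0
    return EpochedDataset(epochs=out, labels=ds.labels.copy(), fs=ds.fs,
                          recording_id=ds.recording_id)


def preprocess_recording(
    recording: Recording,
    labels,
    eeg_band=(0.3, 35.0),
    emg_band=(10.0, 70.0),
    notch_hz: float | None = 50.0,
    denoise: bool = False,
    target_fs: float = TARGET_FS,
) -> EpochedDataset:
    """Filter, resample, epoch and z-score a labelled recording.

    EEG/EOG channels get the 0.3-35 Hz band-pass, EMG channels the 10-70 Hz
    band-pass (clipped below Nyquist), everything an optional 50 Hz notch,
    optional wavelet denoising, resampling to ``target_fs``, epoching and
    per-epoch z-scoring.  Channel modality is inferred from the label prefix
    (``EMG`` -> EMG band, otherwise the EEG band).
    """
    sigs = np.array(recording.signals, dtype=np.float64)
    nyq = recording.fs / 2.0
    for ci, label in enumerate(recording.channel_labels):
        band = emg_band if label.upper().startswith("EMG") else eeg_band
        hi = min(band[1], nyq * 0.95)
        if notch_hz is not None and notch_hz < nyq:
            sigs[ci] = filter_signal(sigs[ci], recording.fs, "notch", notch_hz)
        sigs[ci] = filter_signal(sigs[ci], recording.fs, "bandpass", (band[0], hi))
        if denoise:
            sigs[ci] = wavelet_denoise(sigs[ci])
    rec = Recording(sigs, recording.fs, list(recording.channel_labels),
                    recording.subject_id, recording.session_id)
    rec = resample_recording(rec, target_fs)
    return normalize_dataset(segment_epochs(rec, labels))
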