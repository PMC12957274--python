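"""Dual-stream 1-D convolutional feature extractor.

Each z-scored 30-s epoch channel is passed through two convolutional
branches and the results are concatenated:

- a *temporal* branch with small filters (kernel 50 at stride 6, then 8-8-8)
  that captures fine-grained time-domain detail, and
- a *frequency* branch with large filters (kernel 400 at stride 50, then
  6-6-6) whose first layer spans 4 s of signal and acts as a learned
  filter bank.

Both branches use the layer order conv-pool-conv-conv-conv-pool with a
rectifier after every convolution and dropout (rate 0.5) after each pool.
Convolutions are zero-padded "same" (output ``ceil(L/stride)``); pools are
valid and non-overlapping.  At the reference epoch length Ts = 3000 the
temporal branch yields 64 x 3 = 192 features and the frequency branch
64 x 1 = 64, i.e. 256 features per input channel, so an N-channel epoch maps
to an N x 256 vector — the input width of the downstream KAN.

One extractor is shared across input channels by default (a channel-wise
learned front-end); hand-crafted alternatives (differential entropy, STFT
band log-power, summary statistics) are provided for comparison runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .io import NormalizedEpoch, filter_signal
from .nn.ops import Conv1d, Dropout, MaxPool1d, ReLU, conv_same_out_len, pool_out_len

#: delta, theta, alpha, sigma, beta — the default band plan for DE/STFT modes
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (11.0, 16.0), (16.0, 30.0)
)


@dataclass
class ConvBranchSpec:
    channel_sizes: list[int]
    kernel_sizes: list[int]
    stride_sizes: list[int]
    pool_kernels: list[int]
    pool_strides: list[int]
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if not (len(self.channel_sizes) == len(self.kernel_sizes)
                == len(self.stride_sizes) == 4):
            raise ValueError("branch spec requires 4 conv layers")
        if not (len(self.pool_kernels) == len(self.pool_strides) == 2):
            raise ValueError("branch spec requires 2 pool layers")
        if any(s < 1 for s in self.stride_sizes + self.pool_strides):
            raise ValueError("strides must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")

    def output_length(self, ts: int) -> int:
        """Closed-form temporal length after conv1-pool1-conv2..4-pool2."""
        n = conv_same_out_len(ts, self.stride_sizes[0])
        n = pool_out_len(n, self.pool_kernels[0], self.pool_strides[0])
        for s in self.stride_sizes[1:]:
            n = conv_same_out_len(n, s)
        n = pool_out_len(n, self.pool_kernels[1], self.pool_strides[1])
        return n

    def output_features(self, ts: int) -> int:
        return self.channel_sizes[-1] * self.output_length(ts)


def temporal_branch_spec() -> ConvBranchSpec:
    """Small-filter branch: channels 32-64-64-64, kernels 50-8-8-8,
    strides 6-1-1-1, pools 16/16 and 8/8."""
    return ConvBranchSpec([32, 64, 64, 64], [50, 8, 8, 8], [6, 1, 1, 1],
                          [16, 8], [16, 8])


def frequency_branch_spec() -> ConvBranchSpec:
    """Large-filter branch: channels 64-64-64-64, kernels 400-6-6-6,
    strides 50-1-1-1, pools 8/8 and 4/4."""
    return ConvBranchSpec([64, 64, 64, 64], [400, 6, 6, 6], [50, 1, 1, 1],
                          [8, 4], [8, 4])


class ConvBranch:
    """One branch: conv1 -> pool1 -> conv2 -> conv3 -> conv4 -> pool2."""

    def __init__(self, spec: ConvBranchSpec, rng: np.random.Generator):
        self.spec = spec
        ch = spec.channel_sizes
        self.layers = [
            Conv1d(1, ch[0], spec.kernel_sizes[0], spec.stride_sizes[0], rng),
            ReLU(),
            MaxPool1d(spec.pool_kernels[0], spec.pool_strides[0]),
            Dropout(spec.dropout_rate, rng),
            Conv1d(ch[0], ch[1], spec.kernel_sizes[1], spec.stride_sizes[1], rng),
            ReLU(),
            Conv1d(ch[1], ch[2], spec.kernel_sizes[2], spec.stride_sizes[2], rng),
            ReLU(),
            Conv1d(ch[2], ch[3], spec.kernel_sizes[3], spec.stride_sizes[3], rng),
            ReLU(),
            MaxPool1d(spec.pool_kernels[1], spec.pool_strides[1]),
            Dropout(spec.dropout_rate, rng),
        ]

    def params(self):
        out = []
        for li, layer in enumerate(self.layers):
            out.extend((f"l{li}.{n}", p, g) for n, p, g in layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """``x``: (B, 1, Ts) -> flat features (B, C_last * out_len)."""
        length = x.shape[2]
        for layer in self.layers:
            nxt = layer.out_len(length) if hasattr(layer, "out_len") else length
            if nxt < 1:
                raise ValueError("branch spec empties the signal at some layer")
            x = layer.forward(x, training)
            length = x.shape[2]
        self._out_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dflat: np.ndarray) -> np.ndarray:
        dy = dflat.reshape(self._out_shape).astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def branch_forward(epoch_channel, branch: ConvBranch, training: bool = False):
    """Apply one branch to a single epoch channel (1-D, length Ts)."""
    x = np.asarray(epoch_channel, dtype=np.float32)[None, None, :]
    return branch.forward(x, training)[0]


class ExtractorParams:
    """Both branches plus the channel-sharing policy.

    With ``share_across_channels`` (default) a single pair of branches is
    applied to every input channel; otherwise each channel would need its
    own instance (not provided — sharing is the package's design choice).
    """

    def __init__(self, temporal: ConvBranchSpec | None = None,
                 frequency: ConvBranchSpec | None = None,
                 seed: int = 0, share_across_channels: bool = True):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.temporal_spec = temporal or temporal_branch_spec()
        self.frequency_spec = frequency or frequency_branch_spec()
        self.temporal = ConvBranch(self.temporal_spec, rng)
        self.frequency = ConvBranch(self.frequency_spec, rng)
        self.share_across_channels = share_across_channels

    def params(self):
        return ([(f"temporal.{n}", p, g) for n, p, g in self.temporal.params()]
                + [(f"frequency.{n}", p, g) for n, p, g in self.frequency.params()])

    def zero_grad(self):
        for _, __, g in self.params():
            g[...] = 0.0

    def features_per_channel(self, ts: int) -> int:
        return (self.temporal_spec.output_features(ts)
                + self.frequency_spec.output_features(ts))

    def forward_batch(self, epochs: np.ndarray, training: bool = False) -> np.ndarray:
        """``epochs``: (B, N, Ts) -> (B, N * features_per_channel).

        Channels are flattened into the batch, run through the shared
        branches, and re-assembled in input channel order (temporal block
        then frequency block per channel).
        """
        b, n, ts = epochs.shape
        flat = epochs.reshape(b * n, 1, ts).astype(np.float32)
        ft = self.temporal.forward(flat, training)
        ff = self.frequency.forward(flat, training)
        feats = np.concatenate([ft, ff], axis=1)  # (B*N, 256)
        self._bn = (b, n, ft.shape[1], ff.shape[1])
        return feats.reshape(b, n * feats.shape[1])

    def backward_batch(self, dfeat: np.ndarray) -> None:
        b, n, nt, nf = self._bn
        d = dfeat.reshape(b * n, nt + nf).astype(np.float32)
        self.temporal.backward(d[:, :nt])
        self.frequency.backward(d[:, nt:])


def extract_features(epoch: NormalizedEpoch | np.ndarray, params: ExtractorParams,
                     training: bool = False) -> np.ndarray:
    """Feature vector of one epoch: per channel, temporal-branch output
    concatenated with frequency-branch output; channels in input order."""
    values = epoch.values if isinstance(epoch, NormalizedEpoch) else np.asarray(epoch)
    if values.ndim != 2:
        raise ValueError("epoch must be [N x Ts]")
    return params.forward_batch(values[None], training)[0]


# ---------------------------------------------------------------------------
# hand-crafted alternatives

def alt_features(epoch, mode: str, band_plan=DEFAULT_BANDS, fs: float = 100.0,
                 ) -> np.ndarray:
    """Hand-crafted per-epoch features: ``DE``, ``STFT`` or ``statistic``.

    - ``DE``: differential entropy ``0.5 ln(2 pi e sigma_b^2)`` of each
      band-filtered channel (band covering the whole spectrum = unfiltered).
    - ``STFT``: log mean power per band from a 2-s Hann-window transform.
    - ``statistic``: mean, variance, skewness, kurtosis, min, max.

    Ordering is channel-major: all values for channel 0, then channel 1, ...
    """
    values = epoch.values if isinstance(epoch, NormalizedEpoch) else np.asarray(epoch)
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if mode == "statistic":
        feats = [
            np.array([x.mean(), x.var(), spstats.skew(x), spstats.kurtosis(x),
                      x.min(), x.max()])
            for x in values
        ]
        return np.concatenate(feats)
    band_plan = list(band_plan)
    if not band_plan:
        raise ValueError(f"{mode} mode requires a non-empty band plan")
    nyq = fs / 2.0
    out: list[float] = []
    if mode == "DE":
        for x in values:
            for lo, hi in band_plan:
                if lo <= 0 and hi >= nyq:
                    xb = x  # all-pass band
                else:
                    xb = filter_signal(x, fs, "bandpass",
                                       (max(lo, 1e-3), min(hi, nyq * 0.99)))
                var = max(xb.var(), 1e-300)
                out.append(0.5 * np.log(2.0 * np.pi * np.e * var))
        return np.asarray(out)
    if mode == "STFT":
        nper = int(round(2 * fs))
        for x in values:
            freqs, _, z = sps.stft(x, fs=fs, nperseg=min(nper, len(x)))
            power = (np.abs(z) ** 2).mean(axis=1)
            for lo, hi in band_plan:
                sel = (freqs >= lo) & (freqs < hi)
                out.append(np.log(max(power[sel].mean() if sel.any() else 0.0,
                                      1e-300)))
        return np.asarray(out)
    raise ValueError(f"unknown feature mode {mode!r}")


# ---------------------------------------------------------------------------
# feature persistence (one row per epoch, tab-separated, documented header)

def save_features(path, features: np.ndarray, labels: np.ndarray) -> None:
    """Write a feature matrix to a columnar TSV: ``label f0 f1 ...``."""
    features = np.asarray(features)
    labels = np.asarray(labels, dtype=np.int64)
    with Path(path).open("w") as fh:
        fh.write("# kansleep-features v1\n")
        fh.write("label\t" + "\t".join(f"f{i}" for i in range(features.shape[1])) + "\n")
        for lab, row in zip(labels, features):
            fh.write(str(int(lab)) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def load_features(path):
    data = np.loadtxt(path, skiprows=2, ndmin=2)
    return data[:, 1:], data[:, 0].astype(np.int64)
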