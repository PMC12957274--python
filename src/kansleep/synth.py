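"""Synthetic polysomnography generator.

Produces labelled multichannel recordings whose per-stage spectral structure
follows the canonical AASM signatures — alpha-dominant wake, low-amplitude
theta in N1, theta plus 13 Hz spindle bursts in N2, high-amplitude delta in
N3, and REM with mixed theta, large slow EOG deflections and minimal chin
EMG tone.  Stage sequences follow a first-order Markov chain with strong
self-transitions (sleep-bout persistence), optionally book-ended by forced
wake blocks that emulate the long lights-on segments at recording edges.

The point of the generator is testability, not physiological realism: the
band-power orderings it guarantees are what the feature extractor and
classifier are exercised against, so the whole pipeline runs with no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EPOCH_SECONDS, Recording
from .stages import N_STAGES, Stage

MODALITIES = ("EEG", "EOG", "EMG", "ECG")


@dataclass
class BandComponent:
    """One band-limited oscillation: center frequency, bandwidth, amplitude (uV)."""

    center_hz: float
    bandwidth_hz: float
    amplitude_uv: float


@dataclass
class BurstSpec:
    """Transient oscillatory burst (e.g. a sleep spindle)."""

    center_hz: float
    amplitude_uv: float
    duration_s: float
    probability: float  # per epoch


@dataclass
class StageTemplate:
    """Per-modality signal recipe for one sleep stage."""

    bands: dict[str, list[BandComponent]]
    noise_uv: dict[str, float]
    bursts: dict[str, BurstSpec] = field(default_factory=dict)


def default_templates() -> dict[int, StageTemplate]:
    """Canonical easy-to-separate stage signatures.

    W: 10 Hz alpha EEG + high tonic EMG; N1: low-amplitude 5 Hz theta;
    N2: theta + 13 Hz 1-s spindle bursts (p=0.8/epoch); N3: high-amplitude
    1.5 Hz delta; REM: mixed theta, large slow EOG deflections, minimal EMG.
    ECG is a 1.1 Hz periodic spike train in every stage.
    """
    ecg = [BandComponent(1.1, 0.1, 30.0)]
    return {
        int(Stage.W): StageTemplate(
            bands={"EEG": [BandComponent(10.0, 1.5, 30.0)],
                   "EOG": [BandComponent(1.0, 0.5, 20.0)],
                   "EMG": [BandComponent(30.0, 20.0, 40.0)],
                   "ECG": ecg},
            noise_uv={"EEG": 8.0, "EOG": 8.0, "EMG": 10.0, "ECG": 3.0},
        ),
        int(Stage.N1): StageTemplate(
            bands={"EEG": [BandComponent(5.0, 1.5, 20.0)],
                   "EOG": [BandComponent(0.5, 0.3, 15.0)],
                   "EMG": [BandComponent(30.0, 20.0, 15.0)],
                   "ECG": ecg},
            noise_uv={"EEG": 8.0, "EOG": 6.0, "EMG": 6.0, "ECG": 3.0},
        ),
        int(Stage.N2): StageTemplate(
            bands={"EEG": [BandComponent(5.0, 1.5, 25.0)],
                   "EOG": [BandComponent(0.5, 0.3, 10.0)],
                   "EMG": [BandComponent(30.0, 20.0, 10.0)],
                   "ECG": ecg},
            noise_uv={"EEG": 8.0, "EOG": 5.0, "EMG": 5.0, "ECG": 3.0},
            bursts={"EEG": BurstSpec(13.0, 40.0, 1.0, 0.8)},
        ),
        int(Stage.N3): StageTemplate(
            bands={"EEG": [BandComponent(1.5, 1.0, 80.0)],
                   "EOG": [BandComponent(0.5, 0.3, 10.0)],
                   "EMG": [BandComponent(30.0, 20.0, 8.0)],
                   "ECG": ecg},
            noise_uv={"EEG": 10.0, "EOG": 5.0, "EMG": 4.0, "ECG": 3.0},
        ),
        int(Stage.REM): StageTemplate(
            bands={"EEG": [BandComponent(5.0, 2.0, 22.0)],
                   "EOG": [BandComponent(0.3, 0.2, 60.0)],
                   "EMG": [BandComponent(30.0, 20.0, 3.0)],
                   "ECG": ecg},
            noise_uv={"EEG": 8.0, "EOG": 8.0, "EMG": 2.0, "ECG": 3.0},
        ),
    }


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic stage transition matrix with 0.85 self-transitions."""
    m = np.full((N_STAGES, N_STAGES), 0.15 / (N_STAGES - 1))
    np.fill_diagonal(m, 0.85)
    return m


@dataclass
class GeneratorConfig:
    fs: float = 100.0
    n_epochs: int = 100
    channel_plan: list[tuple[str, str]] = field(
        default_factory=lambda: [("EEG_C3", "EEG"), ("EMG_chin", "EMG")]
    )
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    initial_stage: int = int(Stage.W)
    edge_wake_epochs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        if self.transition_matrix.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition matrix must be 5x5")
        rows = self.transition_matrix.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9) or np.any(self.transition_matrix < 0):
            raise ValueError("transition matrix must be row-stochastic")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        for label, modality in self.channel_plan:
            if modality not in MODALITIES:
                raise ValueError(f"unknown modality {modality!r} for channel {label!r}")


def generate_hypnogram(config: GeneratorConfig) -> np.ndarray:
    """Sample a stage sequence from the Markov chain, with forced wake edges.

    Length is ``n_epochs + 2*edge_wake_epochs``; the first and last
    ``edge_wake_epochs`` entries are W.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    stages = np.empty(config.n_epochs, dtype=np.int64)
    s = int(config.initial_stage)
    cum = np.cumsum(config.transition_matrix, axis=1)
    for i in range(config.n_epochs):
        stages[i] = s
        s = int(np.searchsorted(cum[s], rng.random(), side="right"))
        s = min(s, N_STAGES - 1)
    if config.edge_wake_epochs:
        pad = np.full(config.edge_wake_epochs, int(Stage.W), dtype=np.int64)
        stages = np.concatenate([pad, stages, pad])
    return stages


def _epoch_rng(seed: int, epoch_index: int, channel_index: int) -> np.random.Generator:
    # one independent sub-stream per (epoch, channel), reproducible
    return np.random.default_rng(np.random.SeedSequence([seed, epoch_index, channel_index]))


def generate_epoch(
    stage: int,
    modality: str,
    template: StageTemplate,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One 30-s epoch: band oscillations + optional burst + 1/f noise."""
    if modality not in template.bands:
        raise KeyError(f"template has no recipe for modality {modality!r}")
    n = int(round(fs * EPOCH_SECONDS))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for comp in template.bands[modality]:
        # slow random frequency drift inside the band + random phase
        f_inst = comp.center_hz + comp.bandwidth_hz * (rng.random() - 0.5)
        phase = rng.uniform(0, 2 * np.pi)
        x += comp.amplitude_uv * np.sin(2 * np.pi * f_inst * t + phase)
    burst = template.bursts.get(modality)
    if burst is not None and rng.random() < burst.probability:
        dur = int(round(burst.duration_s * fs))
        start = rng.integers(0, max(n - dur, 1))
        tb = np.arange(dur) / fs
        env = np.hanning(dur)
        x[start:start + dur] += burst.amplitude_uv * env * np.sin(
            2 * np.pi * burst.center_hz * tb + rng.uniform(0, 2 * np.pi)
        )
    noise_amp = template.noise_uv.get(modality, 0.0)
    if noise_amp > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        shaping = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))  # 1/f amplitude
        pink = np.fft.irfft(spec * shaping, n)
        pink *= 1.0 / max(pink.std(), 1e-12)
        x += noise_amp * pink
    return x


def generate_recording(
    config: GeneratorConfig,
    templates: dict[int, StageTemplate] | None = None,
    subject_id: str = "synthetic",
    session_id: str = "1",
) -> tuple[Recording, np.ndarray]:
    """Generate a full labelled recording according to ``config``.

    Returns the recording and the aligned hypnogram; label ``i`` describes
    the half-open sample window ``[i*30*fs, (i+1)*30*fs)``.
    """
    if templates is None:
        templates = default_templates()
    labels = generate_hypnogram(config)
    n_epoch_samples = int(round(config.fs * EPOCH_SECONDS))
    n_ch = len(config.channel_plan)
    signals = np.empty((n_ch, len(labels) * n_epoch_samples))
    for ei, stage in enumerate(labels):
        tpl = templates[int(stage)]
        for ci, (_, modality) in enumerate(config.channel_plan):
            rng = _epoch_rng(config.seed, ei, ci)
            signals[ci, ei * n_epoch_samples:(ei + 1) * n_epoch_samples] = generate_epoch(
                int(stage), modality, tpl, config.fs, rng
            )
    rec = Recording(
        signals=signals,
        fs=config.fs,
        channel_labels=[label for label, _ in config.channel_plan],
        subject_id=subject_id,
        session_id=session_id,
    )
    return rec, labels


def generate_cohort(
    n_recordings: int,
    epochs_per_recording: int,
    seed: int,
    channel_plan=None,
    edge_wake_epochs: int = 0,
    templates: dict[int, StageTemplate] | None = None,
    fs: float = 100.0,
) -> list[tuple[Recording, np.ndarray]]:
    """Generate several independent recordings (one synthetic subject each)."""
    plan = channel_plan or [("EEG_C3", "EEG"), ("EMG_chin", "EMG")]
    out = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_recordings)
    for i in range(n_recordings):
        cfg = GeneratorConfig(
            fs=fs,
            n_epochs=epochs_per_recording,
            channel_plan=list(plan),
            edge_wake_epochs=edge_wake_epochs,
            seed=int(child_seeds[i] % (2**31 - 1)),
            initial_stage=int(Stage.W),
        )
        out.append(generate_recording(cfg, templates, subject_id=f"synth{i:02d}"))
    return out
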