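"""Synthetic labeled polysomnography with stage-conditioned structure.

The generator emulates the statistical features the staging analysis
relies on, so the whole pipeline is testable without any real recordings:

* a first-order Markov hypnogram over ``{W, N1, N2, N3, N4, REM}`` whose
  default transition matrix is Wake/N2-dominant with rare N1/N3 (matching
  the imbalance of overnight recordings) and emits N4 with small
  probability so the N4->N3 merge rule is exercised;
* per-channel signal recipes built from four component types — sinusoids,
  band-limited noise, oscillatory bursts (e.g. sleep spindles) and slow
  deflections (eye movements) — each with stage-specific gains.  The
  default recipes give every stage a separable, physiologically motivated
  signature: alpha (8-12 Hz) in Wake, low theta in N1, theta plus 12-14 Hz
  spindle bursts in N2, high-amplitude delta in N3/N4, and mixed theta in
  REM.  On EEG, N1 and REM are deliberately identical, so that decision
  rests on the EOG pair: EOG channels carry attenuated in-phase EEG
  crosstalk, *anti-correlated* 1-3 Hz deflections in REM (conjugate eye
  movements, one shared waveform with opposite polarity), weaker in-phase
  0.5-1.5 Hz slow activity in N1, and independent intermittent
  low-frequency artifact epochs that mask the ocular cue on one channel
  at a time — resolving N1 vs REM therefore genuinely benefits from
  having both EOG channels;
* power-line interference (50 or 60 Hz) and slow drift (< 0.5 Hz) are
  always injected, so the notch and high-pass stages have something real
  to remove.

Determinism: every random stream is derived by hashing
``(seed, record_id, epoch_index, stream-name)``, so a record is a pure
function of its spec and record id, independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .preprocess import (ChannelSignal, PsgRecord, write_edf,
                         write_hypnogram_csv)
from .stages import STAGES_6

EPOCH_SECONDS = 30.0


@dataclass(frozen=True)
class Component:
    """One additive ingredient of a channel recipe.

    ``kind`` is one of ``sinusoid`` (fixed frequency), ``band_noise``
    (band-limited Gaussian noise), ``burst`` (windowed oscillation bursts,
    e.g. spindles) or ``slow_deflection`` (smooth low-frequency waveform).
    ``amplitude`` is the RMS amplitude in µV at gain 1 (peak amplitude for
    sinusoids); a negative amplitude flips polarity, which is how the two
    EOG channels share one anti-correlated eye-movement waveform.
    ``stream`` names the random stream: components on different channels
    with the same stream draw the *same* waveform.
    """

    kind: str
    amplitude: float
    stage_gains: Mapping[str, float]
    freq: float | None = None
    band: tuple[float, float] | None = None
    stream: str | None = None
    n_bursts: int = 3
    burst_duration: float = 2.0
    occurrence_prob: float = 1.0   # component present in a given epoch

    def gain(self, stage: str) -> float:
        return float(self.stage_gains.get(stage, 0.0))


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything that defines a synthetic PSG cohort."""

    transition_matrix: np.ndarray       # 6x6 row-stochastic over STAGES_6
    initial_distribution: np.ndarray    # length-6 probability vector
    channel_recipes: Mapping[str, tuple[Component, ...]]
    noise_sd: float = 10.0              # broadband sensor noise, µV
    line_freq: float = 50.0             # power-line interference, Hz
    line_amplitude: float = 8.0         # µV
    drift_amplitude: float = 20.0       # µV, slow (<0.5 Hz) drift
    drift_freq: float = 0.2             # Hz
    fs: float = 100.0
    n_epochs: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        pi0 = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "initial_distribution", pi0)
        if tm.shape != (6, 6):
            raise ValueError("transition_matrix must be 6x6")
        if np.any(tm < 0):
            raise ValueError("transition probabilities must be >= 0")
        rowsums = tm.sum(axis=1)
        bad = np.where(np.abs(rowsums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"transition_matrix row(s) {[STAGES_6[i] for i in bad]} "
                f"do not sum to 1 (sums {rowsums[bad]})")
        if pi0.shape != (6,) or np.any(pi0 < 0) or \
                abs(pi0.sum() - 1.0) > 1e-9:
            raise ValueError("initial_distribution must be a length-6 "
                             "probability vector")
        for name, recipe in self.channel_recipes.items():
            for comp in recipe:
                if comp.kind not in ("sinusoid", "band_noise", "burst",
                                     "slow_deflection"):
                    raise ValueError(
                        f"unknown component kind {comp.kind!r} on {name!r}")
        if self.noise_sd < 0 or self.line_amplitude < 0 or \
                self.drift_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.fs <= 0 or self.n_epochs < 1:
            raise ValueError("fs and n_epochs must be positive")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channel_recipes.keys())

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the stage Markov chain."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


# -- default study conditions ----------------------------------------------

#: Wake/N2-heavy transition matrix (stage order W, N1, N2, N3, N4, REM)
#: with persistent stage runs; N4 appears rarely, from N2/N3 only.
DEFAULT_TRANSITIONS = np.array([
    #  W     N1    N2     N3     N4    REM
    [0.93, 0.04, 0.020, 0.000, 0.000, 0.010],   # W
    [0.10, 0.75, 0.120, 0.000, 0.000, 0.030],   # N1
    [0.03, 0.03, 0.840, 0.050, 0.005, 0.045],   # N2
    [0.01, 0.00, 0.140, 0.800, 0.030, 0.020],   # N3
    [0.01, 0.00, 0.040, 0.150, 0.800, 0.000],   # N4
    [0.05, 0.04, 0.060, 0.000, 0.000, 0.850],   # REM
])

def _stationary(tm: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(tm.T)
    pi = np.abs(np.real(vecs[:, int(np.argmin(np.abs(vals - 1.0)))]))
    return pi / pi.sum()


#: Records start from the chain's stationary distribution, so even short
#: synthetic records exhibit every stage at its equilibrium frequency (a
#: full night would instead start awake; short records emulate a window
#: of a night in progress).
DEFAULT_INITIAL = _stationary(DEFAULT_TRANSITIONS)


def _eeg_components() -> tuple[Component, ...]:
    return (
        Component("band_noise", 30.0, {"W": 1.0, "N1": 0.2, "N2": 0.1,
                                       "N3": 0.05, "N4": 0.05, "REM": 0.2},
                  band=(8.0, 12.0), stream="alpha"),
        Component("band_noise", 25.0, {"W": 0.2, "N1": 1.0, "N2": 0.8,
                                       "N3": 0.3, "N4": 0.2, "REM": 1.0},
                  band=(4.0, 8.0), stream="theta"),
        Component("burst", 40.0, {"N2": 1.0}, band=(12.0, 14.0),
                  stream="spindle", n_bursts=3, burst_duration=2.0),
        Component("band_noise", 80.0, {"W": 0.05, "N1": 0.1, "N2": 0.3,
                                       "N3": 1.0, "N4": 1.4, "REM": 0.1},
                  band=(1.0, 4.0), stream="delta"),
    )


def _eog_components(polarity: float, side: str) -> tuple[Component, ...]:
    # Attenuated in-phase EEG crosstalk, stage-specific ocular activity, and
    # channel-local artifact bursts.  REM eye movements are conjugate: one
    # shared waveform with opposite polarity on the two channels.  N1 slow
    # activity is in-phase and weaker.  The artifact bursts (broadband,
    # independent per channel, present in about half the epochs) emulate the
    # interference a single EOG channel is susceptible to — with two EOG
    # channels, at least one usually carries the ocular cue cleanly.
    crosstalk = tuple(replace(c, amplitude=0.15 * c.amplitude)
                      for c in _eeg_components())
    all_stages = {s: 1.0 for s in STAGES_6}
    return crosstalk + (
        Component("slow_deflection", polarity * 60.0, {"REM": 1.0},
                  band=(1.0, 3.0), stream="rem-eye"),
        Component("slow_deflection", 40.0, {"N1": 1.0},
                  band=(0.5, 1.5), stream="n1-slow"),
        Component("slow_deflection", 70.0, all_stages, band=(0.5, 3.0),
                  occurrence_prob=0.45, stream=f"artifact-{side}"),
    )


def default_spec(n_epochs: int = 120, fs: float = 100.0,
                 line_freq: float = 50.0, seed: int = 0) -> GeneratorSpec:
    """The package's default synthetic cohort: one EEG derivation plus two
    EOG channels with REM-conjugate / N1-in-phase slow activity."""
    recipes = {
        "EEG": _eeg_components(),
        "EOG(L)": _eog_components(+1.0, "L"),
        "EOG(R)": _eog_components(-1.0, "R"),
    }
    return GeneratorSpec(DEFAULT_TRANSITIONS, DEFAULT_INITIAL, recipes,
                         fs=fs, line_freq=line_freq, n_epochs=n_epochs,
                         seed=seed)


# -- seeded stream derivation ----------------------------------------------

def _stream_rng(seed: int, record_id: str, epoch_index: int,
                name: str) -> np.random.Generator:
    ent = [int(seed) & 0x7FFFFFFF,
           zlib.crc32(record_id.encode()),
           int(epoch_index),
           zlib.crc32(name.encode())]
    return np.random.default_rng(np.random.SeedSequence(ent))


# -- operations -------------------------------------------------------------

def sample_hypnogram(spec: GeneratorSpec, record_id: str = "") -> list[str]:
    """Draw a stage sequence from the first-order Markov chain."""
    rng = _stream_rng(spec.seed, record_id, 0, "hypnogram")
    cum = np.cumsum(spec.transition_matrix, axis=1)
    stages = np.empty(spec.n_epochs, dtype=np.int64)
    stages[0] = np.searchsorted(np.cumsum(spec.initial_distribution),
                                rng.random(), side="right")
    u = rng.random(spec.n_epochs)
    for t in range(1, spec.n_epochs):
        stages[t] = np.searchsorted(cum[stages[t - 1]], u[t], side="right")
    return [STAGES_6[i] for i in stages]


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to a frequency band."""
    white = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _component_wave(comp: Component, rng: np.random.Generator, n: int,
                    fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    if comp.kind == "sinusoid":
        phase = rng.uniform(0.0, 2 * np.pi)
        return np.sin(2 * np.pi * comp.freq * t + phase)
    if comp.kind in ("band_noise", "slow_deflection"):
        return _band_noise(rng, n, fs, comp.band)
    if comp.kind == "burst":
        out = np.zeros(n)
        dur = int(round(comp.burst_duration * fs))
        for _ in range(comp.n_bursts):
            f = rng.uniform(*comp.band)
            start = rng.integers(0, max(n - dur, 1))
            tt = np.arange(dur) / fs
            out[start:start + dur] += (np.hanning(dur)
                                       * np.sin(2 * np.pi * f * tt
                                                + rng.uniform(0, 2 * np.pi)))
        rms = np.sqrt(np.mean(out ** 2))
        return out / rms if rms > 0 else out
    raise ValueError(f"unknown component kind {comp.kind!r}")


def synthesize_epoch(stage: str, channel_name: str, spec: GeneratorSpec,
                     epoch_index: int, record_id: str = "") -> np.ndarray:
    """One 30 s epoch of one channel, in µV (length fs x 30).

    Sum of the channel's recipe components scaled by the stage's gains,
    plus Gaussian sensor noise, power-line interference and slow drift.
    Deterministic given (spec.seed, record_id, epoch_index, channel_name).
    """
    if stage not in STAGES_6:
        raise ValueError(f"unknown stage {stage!r}")
    if channel_name not in spec.channel_recipes:
        raise KeyError(f"no recipe for channel {channel_name!r}")
    n = int(round(spec.fs * EPOCH_SECONDS))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    for i, comp in enumerate(spec.channel_recipes[channel_name]):
        g = comp.gain(stage)
        if g == 0.0:
            continue
        stream = comp.stream if comp.stream is not None \
            else f"{channel_name}/c{i}"
        rng = _stream_rng(spec.seed, record_id, epoch_index, stream)
        if comp.occurrence_prob < 1.0 and rng.random() >= comp.occurrence_prob:
            continue
        x += g * comp.amplitude * _component_wave(comp, rng, n, spec.fs)
    rng_ch = _stream_rng(spec.seed, record_id, epoch_index, channel_name)
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng_ch.standard_normal(n)
    if spec.line_amplitude > 0:
        x += spec.line_amplitude * np.sin(
            2 * np.pi * spec.line_freq * t + rng_ch.uniform(0, 2 * np.pi))
    if spec.drift_amplitude > 0:
        x += spec.drift_amplitude * np.sin(
            2 * np.pi * spec.drift_freq
            * (t + EPOCH_SECONDS * epoch_index)
            + rng_ch.uniform(0, 2 * np.pi))
    return x


def generate_record(spec: GeneratorSpec, record_id: str) -> PsgRecord:
    """A full synthetic subject-night: signals plus 30 s stage annotations."""
    stages = sample_hypnogram(spec, record_id)
    channels = []
    for name in spec.channel_names:
        epochs = [synthesize_epoch(stage, name, spec, i, record_id)
                  for i, stage in enumerate(stages)]
        channels.append(ChannelSignal(name, np.concatenate(epochs), spec.fs))
    annotations = [(i * EPOCH_SECONDS, EPOCH_SECONDS, s)
                   for i, s in enumerate(stages)]
    return PsgRecord(record_id, channels, annotations,
                     line_freq=spec.line_freq)


def write_psg(record: PsgRecord, signal_path, label_path) -> None:
    """Write a record as a 16-bit EDF plus the hypnogram CSV dialect."""
    write_edf(record.channels, signal_path)
    write_hypnogram_csv([s for _, _, s in record.annotations], label_path)


def generate_cohort(spec: GeneratorSpec, n_records: int,
                    id_prefix: str = "synthetic") -> list[PsgRecord]:
    """Generate ``n_records`` records with distinct per-record streams."""
    return [generate_record(spec, f"{id_prefix}-{i:03d}")
            for i in range(n_records)]
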