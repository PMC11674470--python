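"""PSG record I/O and the preprocessing chain.

A polysomnography record arrives as an EDF signal file plus per-epoch stage
labels (a CSV hypnogram or EDF+ annotations).  The chain applied before any
classifier sees the data is fixed:

    merge/truncate -> resample to 100 Hz -> notch (50/60 Hz) ->
    band-pass 1-40 Hz -> re-reference (if requested) -> 30 s epoching

Epoching merges R&K's N4 into N3, drops epochs whose label is not a sleep
stage (movement/unknown pages), drops any trailing partial epoch, and
reports per-stage epoch counts.  Filters are zero-phase: a 4th-order
Butterworth band-pass and a Q=30 IIR notch, both run forward-backward.
Resampling is polyphase with anti-aliasing, exact for rational rate ratios
such as 512->100 and 125->100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .stages import STAGES_5, STAGES_6, StageCountReport

logger = logging.getLogger("somnastage")

TARGET_FS = 100.0
EPOCH_SECONDS = 30.0
EPOCH_SAMPLES = int(TARGET_FS * EPOCH_SECONDS)

#: Annotation vocabularies differ between studies; this alias table maps the
#: common spellings onto the package's six-code alphabet.  Extend via the
#: ``stage_aliases`` argument of :func:`load_psg`.
DEFAULT_STAGE_ALIASES: dict[str, str] = {
    **{s: s for s in STAGES_6},
    "Sleep stage W": "W", "Sleep stage 1": "N1", "Sleep stage 2": "N2",
    "Sleep stage 3": "N3", "Sleep stage 4": "N4", "Sleep stage R": "REM",
    "Wake": "W", "Stage 1": "N1", "Stage 2": "N2", "Stage 3": "N3",
    "Stage 4": "N4", "R": "REM",
}


@dataclass
class ChannelSignal:
    """One named channel: samples in microvolts at a fixed sampling rate."""

    name: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.name!r} contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class PsgRecord:
    """One subject-night: channels + timed stage annotations + metadata."""

    record_id: str
    channels: list[ChannelSignal]
    annotations: list[tuple[float, float, str]]  # (onset_s, duration_s, stage)
    line_freq: float = 50.0

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        onsets = [a[0] for a in self.annotations]
        if onsets != sorted(onsets):
            raise ValueError("annotations must be time-ordered")
        for (o1, d1, _), (o2, _, _) in zip(self.annotations,
                                           self.annotations[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError("annotations overlap")

    def channel(self, name: str) -> ChannelSignal:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"record {self.record_id!r} has no channel {name!r} "
                       f"(available: {[c.name for c in self.channels]})")


@dataclass
class EpochSet:
    """Aligned 30 s multi-channel epochs at 100 Hz with 5-class labels."""

    data: np.ndarray          # [n_epochs, n_channels, 3000] float32, µV
    labels: np.ndarray        # per-epoch codes from STAGES_5
    record_ids: np.ndarray    # per-epoch provenance
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=object)
        self.record_ids = np.asarray(self.record_ids, dtype=object)
        if self.data.ndim != 3 or self.data.shape[2] != EPOCH_SAMPLES:
            raise ValueError(
                f"data must be [n, n_channels, {EPOCH_SAMPLES}]")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match data axis 1")
        if len(self.labels) != len(self.data) or \
                len(self.record_ids) != len(self.data):
            raise ValueError("labels/record_ids must have one entry per epoch")
        bad = set(self.labels) - set(STAGES_5)
        if bad:
            raise ValueError(f"labels outside the 5-class alphabet: {bad}")

    def __len__(self) -> int:
        return len(self.data)

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(self.data[:, idx, :], self.labels.copy(),
                        self.record_ids.copy(), tuple(names))

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[mask], self.labels[mask],
                        self.record_ids[mask], self.channel_names)

    def stage_counts(self) -> StageCountReport:
        return StageCountReport(
            {s: int(np.sum(self.labels == s)) for s in STAGES_5})

    def save(self, path) -> None:
        """Compressed array container plus a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data)
        sidecar = {
            "labels": [str(s) for s in self.labels],
            "record_ids": [str(r) for r in self.record_ids],
            "channel_names": list(self.channel_names),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "EpochSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            data = z["data"]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(data, np.array(sidecar["labels"], dtype=object),
                   np.array(sidecar["record_ids"], dtype=object),
                   tuple(sidecar["channel_names"]))


def concat_epoch_sets(sets: Sequence[EpochSet]) -> EpochSet:
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    names = sets[0].channel_names
    if any(s.channel_names != names for s in sets):
        raise ValueError("channel names differ between epoch sets")
    return EpochSet(np.concatenate([s.data for s in sets]),
                    np.concatenate([s.labels for s in sets]),
                    np.concatenate([s.record_ids for s in sets]), names)


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def write_edf(channels: Sequence[ChannelSignal], path,
              record_duration: float = 30.0) -> None:
    """Write channels to a 16-bit EDF file.

    Physical min/max per channel are taken from the signal range; samples
    are quantized to the full 16-bit digital range, so the round-trip error
    is bounded by (physical range)/2^16 per sample.
    """
    fs0 = channels[0].fs
    if any(c.fs != fs0 for c in channels):
        raise ValueError("write_edf requires a common sampling rate")
    spr = fs0 * record_duration
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record_duration * fs must be an integer")
    spr = int(round(spr))
    n_records = min(len(c.samples) for c in channels) // spr
    if n_records == 0:
        raise ValueError("signals shorter than one data record")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    ns = len(channels)
    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad(_fmt_num(record_duration), 8),
        pad(str(ns), 4),
    ])
    pmins, pmaxs, scales = [], [], []
    for c in channels:
        lo = float(np.min(c.samples[: n_records * spr]))
        hi = float(np.max(c.samples[: n_records * spr]))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        scales.append((hi - lo) / 65535.0)
    sig_header = b"".join([
        b"".join(pad(c.name, 16) for c in channels),
        b"".join(pad("", 80) for _ in channels),
        b"".join(pad("uV", 8) for _ in channels),
        b"".join(pad(_fmt_num(p), 8) for p in pmins),
        b"".join(pad(_fmt_num(p), 8) for p in pmaxs),
        b"".join(pad("-32768", 8) for _ in channels),
        b"".join(pad("32767", 8) for _ in channels),
        b"".join(pad("", 80) for _ in channels),
        b"".join(pad(str(spr), 8) for _ in channels),
        b"".join(pad("", 32) for _ in channels),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for c, lo, scale in zip(channels, pmins, scales):
                chunk = c.samples[r * spr:(r + 1) * spr]
                dig = np.round((chunk - lo) / scale) - 32768
                fh.write(np.clip(dig, -32768, 32767)
                         .astype("<i2").tobytes())


def _fmt_num(x: float) -> str:
    """Format a number into <= 8 ASCII chars as EDF requires."""
    for fmt in ("%g", "%.6g", "%.4g", "%.2f", "%.1f", "%.0f"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {x} into 8 chars")


def read_edf(path) -> list[ChannelSignal]:
    """Read an EDF file into channel signals in microvolts (via mne)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    fs = float(raw.info["sfreq"])
    return [ChannelSignal(name, data[i], fs)
            for i, name in enumerate(raw.ch_names)]


# ---------------------------------------------------------------------------
# hypnogram label files
# ---------------------------------------------------------------------------

def write_hypnogram_csv(stages: Sequence[str], path,
                        epoch_seconds: float = EPOCH_SECONDS) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index,onset_seconds,stage\n")
        for i, s in enumerate(stages):
            fh.write(f"{i},{i * epoch_seconds:g},{s}\n")


def read_hypnogram_csv(path) -> list[tuple[float, float, str]]:
    """Read the hypnogram CSV dialect into (onset, duration, stage) tuples."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"epoch_index", "onset_seconds", "stage"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram CSV must have columns {sorted(required)}")
    df = df.sort_values("epoch_index")
    return [(float(o), EPOCH_SECONDS, str(s))
            for o, s in zip(df["onset_seconds"], df["stage"])]


def read_labels(path, stage_aliases: Mapping[str, str] | None = None,
                ) -> list[tuple[float, float, str]]:
    """Read stage annotations from a hypnogram CSV or an EDF+ file.

    Stage vocabulary is normalized through the alias table; unknown stage
    text is kept verbatim (epoching drops it with the non-stage epochs).
    """
    aliases = dict(DEFAULT_STAGE_ALIASES)
    if stage_aliases:
        aliases.update(stage_aliases)
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        ann = mne.read_annotations(path)
        out = []
        for onset, dur, desc in zip(ann.onset, ann.duration, ann.description):
            stage = aliases.get(str(desc), str(desc))
            n_pages = int(round(dur / EPOCH_SECONDS)) if dur else 1
            for p in range(max(n_pages, 1)):
                out.append((float(onset) + p * EPOCH_SECONDS,
                            EPOCH_SECONDS, stage))
        return out
    raw = read_hypnogram_csv(path)
    return [(o, d, aliases.get(s, s)) for o, d, s in raw]


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def resample(sig: ChannelSignal, fs_out: float) -> ChannelSignal:
    """Polyphase rational resampling with anti-aliasing."""
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out == sig.fs:
        return ChannelSignal(sig.name, sig.samples.copy(), sig.fs)
    ratio = Fraction(str(fs_out)) / Fraction(str(sig.fs))
    out = sps.resample_poly(sig.samples, ratio.numerator, ratio.denominator)
    return ChannelSignal(sig.name, out, fs_out)


def notch_filter(sig: ChannelSignal, freq: float, q: float = 30.0,
                 ) -> ChannelSignal:
    """Zero-phase IIR notch at the power-line frequency."""
    if freq >= sig.fs / 2:
        raise ValueError(
            f"notch frequency {freq} Hz is at or above Nyquist "
            f"({sig.fs / 2} Hz)")
    b, a = sps.iirnotch(freq, q, fs=sig.fs)
    return ChannelSignal(sig.name, sps.filtfilt(b, a, sig.samples), sig.fs)


def bandpass_filter(sig: ChannelSignal, low: float = 1.0, high: float = 40.0,
                    order: int = 4) -> ChannelSignal:
    """Zero-phase Butterworth band-pass (default 1-40 Hz)."""
    if not 0 < low < high < sig.fs / 2:
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for fs={sig.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sig.fs,
                     output="sos")
    return ChannelSignal(sig.name, sps.sosfiltfilt(sos, sig.samples), sig.fs)


def rereference(sig: ChannelSignal, ref: ChannelSignal) -> ChannelSignal:
    """Pointwise difference of an active electrode and its reference."""
    if sig.fs != ref.fs:
        raise ValueError(f"fs mismatch: {sig.fs} vs {ref.fs}")
    if len(sig.samples) != len(ref.samples):
        raise ValueError(
            f"length mismatch: {len(sig.samples)} vs {len(ref.samples)}")
    return ChannelSignal(f"{sig.name}-{ref.name}", sig.samples - ref.samples,
                         sig.fs)


def load_psg(signal_path, label_path,
             channel_select: Sequence[str] | None = None,
             line_freq: float = 50.0,
             stage_aliases: Mapping[str, str] | None = None,
             record_id: str | None = None) -> PsgRecord:
    """Read an EDF record and its labels, truncated to their overlap.

    ``channel_select`` may name raw channels or derivations like
    ``"C3-M2"``; a derivation absent from the file is computed by
    re-referencing when both electrodes are present.  A missing channel
    raises; labels extending beyond the signal raise (signal loss); signal
    extending beyond the labels is truncated with a logged warning.
    """
    channels = read_edf(signal_path)
    by_name = {c.name: c for c in channels}
    if channel_select is not None:
        picked = []
        for name in channel_select:
            if name in by_name:
                picked.append(by_name[name])
            elif "-" in name:
                a, _, r = name.partition("-")
                if a in by_name and r in by_name:
                    picked.append(rereference(by_name[a], by_name[r]))
                else:
                    raise KeyError(
                        f"channel {name!r} missing and not derivable from "
                        f"{sorted(by_name)}")
            else:
                raise KeyError(f"missing channel {name!r} "
                               f"(available: {sorted(by_name)})")
        channels = picked
    annotations = read_labels(label_path, stage_aliases)

    sig_dur = min(c.duration for c in channels)
    lab_end = max(o + d for o, d, _ in annotations)
    if lab_end > sig_dur + 1e-6:
        raise ValueError(
            f"signal ({sig_dur:.0f} s) shorter than labels "
            f"({lab_end:.0f} s): signal loss")
    if sig_dur > lab_end:
        logger.warning("truncating %s: %.0f s of unlabeled signal dropped",
                       signal_path, sig_dur - lab_end)
        channels = [ChannelSignal(c.name,
                                  c.samples[: int(round(lab_end * c.fs))],
                                  c.fs) for c in channels]
    rid = record_id if record_id is not None else Path(signal_path).stem
    return PsgRecord(rid, channels, annotations, line_freq=line_freq)


def preprocess_record(record: PsgRecord, fs_out: float = TARGET_FS,
                      low: float = 1.0, high: float = 40.0) -> PsgRecord:
    """Resample to 100 Hz, notch at the record's line frequency, band-pass."""
    out = []
    for c in record.channels:
        c = resample(c, fs_out)
        if record.line_freq < c.fs / 2:
            c = notch_filter(c, record.line_freq)
        else:
            # e.g. 50 Hz line at 100 Hz: at/above Nyquist after
            # standardization; the 1-40 Hz band-pass removes it instead
            logger.info("skipping notch at %g Hz (>= Nyquist at %g Hz)",
                        record.line_freq, c.fs)
        c = bandpass_filter(c, low, high)
        out.append(c)
    return PsgRecord(record.record_id, out, list(record.annotations),
                     line_freq=record.line_freq)


def epoch_and_align(record: PsgRecord) -> tuple[EpochSet, StageCountReport]:
    """Cut a preprocessed record into labeled 30 s epochs.

    N4 merges into N3; epochs whose label is not a sleep stage are dropped;
    a trailing partial epoch is dropped.  The epoch grid starts at the
    first annotated onset; onsets must fall on the 30 s grid.
    """
    for c in record.channels:
        if c.fs != TARGET_FS:
            raise ValueError(
                f"epoching requires {TARGET_FS:g} Hz channels; "
                f"{c.name!r} is at {c.fs:g} Hz")
    if not record.annotations:
        raise ValueError(f"record {record.record_id!r} has no annotations")
    t0 = record.annotations[0][0]
    n_samples = min(len(c.samples) for c in record.channels)
    data, labels = [], []
    for onset, dur, stage in record.annotations:
        if abs(dur - EPOCH_SECONDS) > 1e-9:
            raise ValueError(
                f"annotation duration {dur} s is not one 30 s page")
        rel = onset - t0
        if abs(rel / EPOCH_SECONDS - round(rel / EPOCH_SECONDS)) > 1e-6:
            raise ValueError(
                f"annotation onset {onset} s off the 30 s epoch grid")
        stage = "N3" if stage == "N4" else stage
        if stage not in STAGES_5:
            continue  # movement / unknown pages are irrelevant to staging
        start = int(round(onset * TARGET_FS))
        stop = start + EPOCH_SAMPLES
        if stop > n_samples:
            break  # trailing partial epoch removed
        data.append(np.stack([c.samples[start:stop]
                              for c in record.channels]))
        labels.append(stage)
    if not data:
        raise ValueError(
            f"record {record.record_id!r} yields no valid epochs")
    epochs = EpochSet(np.stack(data), np.array(labels, dtype=object),
                      np.array([record.record_id] * len(data), dtype=object),
                      tuple(c.name for c in record.channels))
    return epochs, epochs.stage_counts()


def pipeline(signal_path, label_path,
             channel_select: Sequence[str] | None = None,
             line_freq: float = 50.0,
             stage_aliases: Mapping[str, str] | None = None,
             ) -> tuple[EpochSet, StageCountReport]:
    """Full chain: load -> resample -> notch -> band-pass -> epoch."""
    rec = load_psg(signal_path, label_path, channel_select, line_freq,
                   stage_aliases)
    return epoch_and_align(preprocess_record(rec))
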