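"""Seed-reproducible synthetic PSG recordings with known artifact truth.

The generator emulates the one statistical property the detector relies
on: during normal sleep the per-second power spectra of the six EEG
channels are highly correlated, because the channels observe a shared
underlying source.  Each EEG channel is

    gain_c * latent(t) + noise_c(t)

where the latent signal is a sum of band-limited Gaussian processes
(delta 0.5-4, theta 4-8, alpha 8-12, sigma 12-16, beta 16-30 Hz) whose
band amplitudes switch with the sleep stage of each 30 s epoch
(N3 delta-dominant, REM theta-rich, wake alpha/beta-raised), and
noise_c is independent white noise.  Mastoid references M1/M2 carry
only small-amplitude noise.

Artifact intervals overwrite the affected channel:

* ``flatline`` — constant signal (caught by the flat-epoch screen),
* ``pop_noise`` — independent broadband noise at normal amplitude (the
  lead-popping signature: survives preprocessing, kills correlation),
* ``movement_drift`` — slow excursions exceeding 500 μV,
* ``high_amplitude`` — the latent signal scaled past 500 μV.

Ground truth is defined at segment resolution with the same 4 s-window
convention as the spectral module: a segment is artifactual when its
window intersects an artifact interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .records import EEG_CHANNELS, EPOCH_LEN_S, MASTOIDS, ConfigurationError, RawPSGRecording

ARTIFACT_KINDS = ("flatline", "pop_noise", "movement_drift", "high_amplitude")

#: Frequency bands (Hz) of the latent source components.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}

#: Per-stage band standard deviations of the latent source, in μV.
STAGE_BAND_SD_UV: dict[str, dict[str, float]] = {
    "W":  {"delta": 8.0,  "theta": 6.0,  "alpha": 15.0, "sigma": 4.0,  "beta": 8.0},
    "N1": {"delta": 15.0, "theta": 12.0, "alpha": 8.0,  "sigma": 4.0,  "beta": 4.0},
    "N2": {"delta": 25.0, "theta": 10.0, "alpha": 6.0,  "sigma": 12.0, "beta": 4.0},
    "N3": {"delta": 40.0, "theta": 10.0, "alpha": 5.0,  "sigma": 6.0,  "beta": 3.0},
    "R":  {"delta": 12.0, "theta": 15.0, "alpha": 8.0,  "sigma": 4.0,  "beta": 6.0},
    "unknown": {"delta": 25.0, "theta": 10.0, "alpha": 6.0, "sigma": 12.0, "beta": 4.0},
}


@dataclass(frozen=True)
class ArtifactInterval:
    channel: str
    start_s: int
    end_s: int  # exclusive
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ConfigurationError(f"unknown artifact kind {self.kind!r}")
        if self.end_s <= self.start_s:
            raise ConfigurationError("artifact interval must have end_s > start_s")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic night."""

    duration_s: int = 7200
    fs: float = 256.0
    seed: int = 0
    stage_sequence: list[str] | None = None
    artifacts: list[ArtifactInterval] = field(default_factory=list)
    channel_noise_sd_uv: float = 3.0
    mastoid_noise_sd_uv: float = 2.0
    source_gain_per_channel: dict[str, float] | None = None
    window_s: int = 4  # ground-truth window convention, shared with spectral

    def __post_init__(self) -> None:
        for a in self.artifacts:
            if not (0 <= a.start_s < a.end_s <= self.duration_s):
                raise ConfigurationError(
                    f"artifact interval [{a.start_s}, {a.end_s}) outside record"
                )


@dataclass
class GroundTruth:
    """Per-channel per-segment artifact flags plus the source intervals."""

    flags: dict[str, np.ndarray]
    intervals: list[ArtifactInterval]
    duration_s: int
    fs: float


def default_stage_sequence(n_epochs: int) -> list[str]:
    """A plausible sleep-cycle pattern: N2 → N3 → N2 → REM, repeating."""
    cycle = ["N2"] * 20 + ["N3"] * 20 + ["N2"] * 10 + ["R"] * 10
    seq = (cycle * (n_epochs // len(cycle) + 1))[:n_epochs]
    return seq


def default_night(seed: int = 0) -> SyntheticSpec:
    """The reference fixture: 2 h at 256 Hz with a 15 min lead pop on C3."""
    duration = 7200
    return SyntheticSpec(
        duration_s=duration,
        seed=seed,
        stage_sequence=default_stage_sequence(duration // EPOCH_LEN_S),
        artifacts=[ArtifactInterval("C3", 4500, 5400, "pop_noise")],
    )


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _merge_intervals(artifacts: list[ArtifactInterval]) -> list[ArtifactInterval]:
    by_channel: dict[str, list[ArtifactInterval]] = {}
    for a in artifacts:
        by_channel.setdefault(a.channel, []).append(a)
    merged: list[ArtifactInterval] = []
    for ch, items in by_channel.items():
        items.sort(key=lambda a: a.start_s)
        cur = items[0]
        for nxt in items[1:]:
            if nxt.start_s < cur.end_s:
                warnings.warn(
                    f"overlapping artifact intervals on {ch} merged: "
                    f"[{cur.start_s},{cur.end_s}) + [{nxt.start_s},{nxt.end_s})"
                )
                cur = ArtifactInterval(ch, cur.start_s, max(cur.end_s, nxt.end_s), cur.kind)
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    return sorted(merged, key=lambda a: (a.channel, a.start_s))


def generate(spec: SyntheticSpec) -> tuple[RawPSGRecording, GroundTruth]:
    """Generate a recording and its segment-level ground truth."""
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    n_epochs = int(np.ceil(spec.duration_s / EPOCH_LEN_S))
    stages = spec.stage_sequence or default_stage_sequence(n_epochs)
    if len(stages) != n_epochs:
        raise ConfigurationError("stage_sequence length does not match duration")

    # latent source: stage-modulated band-limited components
    latent = np.zeros(n)
    spe = int(round(EPOCH_LEN_S * fs))
    for name, (lo, hi) in BANDS.items():
        comp = _bandlimited_noise(rng, n, fs, lo, hi)
        amp = np.empty(n)
        for e in range(n_epochs):
            sd = STAGE_BAND_SD_UV.get(stages[e], STAGE_BAND_SD_UV["unknown"])[name]
            amp[e * spe : min((e + 1) * spe, n)] = sd
        latent += amp * comp

    gains = dict(spec.source_gain_per_channel or {})
    for ch in EEG_CHANNELS:
        gains.setdefault(ch, float(rng.uniform(0.8, 1.2)))

    channels: dict[str, np.ndarray] = {}
    for ch in EEG_CHANNELS:
        channels[ch] = gains[ch] * latent + spec.channel_noise_sd_uv * rng.standard_normal(n)
    for m in MASTOIDS:
        channels[m] = spec.mastoid_noise_sd_uv * rng.standard_normal(n)

    intervals = _merge_intervals(spec.artifacts) if spec.artifacts else []
    for a in intervals:
        sl = slice(int(a.start_s * fs), int(a.end_s * fs))
        x = channels[a.channel]
        if a.kind == "flatline":
            x[sl] = x[sl.start] if sl.start < n else 0.0
        elif a.kind == "pop_noise":
            clean_sd = max(x[sl].std(), 1.0)
            x[sl] = clean_sd * _bandlimited_noise(rng, sl.stop - sl.start, fs, 0.5, 32.0)
        elif a.kind == "movement_drift":
            t = np.arange(sl.stop - sl.start) / fs
            f = rng.uniform(0.1, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            x[sl] = 700.0 * np.sin(2 * np.pi * f * t + phase) + x[sl]
        elif a.kind == "high_amplitude":
            peak = np.abs(x[sl]).max()
            if peak > 0:
                x[sl] = x[sl] * (650.0 / peak)

    recording = RawPSGRecording(
        channels=channels,
        sampling_rate=fs,
        duration_s=float(spec.duration_s),
        stage_labels=list(stages),
        subject_id=f"synthetic-{spec.seed}",
    )

    n_seg = spec.duration_s
    flags = {ch: np.zeros(n_seg, dtype=bool) for ch in EEG_CHANNELS}
    for a in intervals:
        # a segment's 4 s window [t, t+4) intersects [start, end)
        lo = max(0, a.start_s - (spec.window_s - 1))
        hi = min(n_seg, a.end_s)
        flags[a.channel][lo:hi] = True
    truth = GroundTruth(flags=flags, intervals=intervals,
                        duration_s=spec.duration_s, fs=fs)
    return recording, truth


# --------------------------------------------------------------------------
# EDF output
#
# Plain EDF: 256-byte fixed header, 256 bytes per signal header, then
# 1 s data records of little-endian int16 samples scaled between the
# declared physical and digital ranges.

def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawPSGRecording, path) -> None:
    """Write the recording as a plain 16-bit EDF file (1 s data records).

    The declared physical range covers the signal symmetrically; values
    outside it (or non-finite) are clipped to the range with a warning.
    """
    if not recording.channels:
        raise ConfigurationError("cannot write an EDF with no channels")
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    n_records = int(round(recording.duration_s))
    if abs(n_records - recording.duration_s) > 1e-9:
        raise ConfigurationError("EDF writer requires a whole-second duration")

    labels = list(recording.channels)
    data = {}
    phys = {}
    for ch in labels:
        x = np.asarray(recording.channels[ch], dtype=float)
        if not np.all(np.isfinite(x)):
            warnings.warn(f"channel {ch}: non-finite samples written as 0")
            x = np.where(np.isfinite(x), x, 0.0)
        pmax = float(np.ceil(max(np.abs(x).max(), 1.0)))
        phys[ch] = pmax
        # encode with the same affine map readers use:
        # physical = digital * cal + offset
        cal = 2.0 * pmax / 65535.0
        offset = -pmax - (-32768) * cal
        data[ch] = np.clip(np.round((x - offset) / cal), -32768, 32767).astype("<i2")

    ns = len(labels)
    header = b"".join([
        _field(0, 8),
        _field(recording.subject_id or "X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (ns + 1), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(ns, 4),
    ])
    sig_header = b"".join([
        b"".join(_field(ch, 16) for ch in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(-phys[ch], 8) for ch in labels),
        b"".join(_field(phys[ch], 8) for ch in labels),
        b"".join(_field(-32768, 8) for _ in labels),
        b"".join(_field(32767, 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(spr, 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for ch in labels:
                fh.write(data[ch][r * spr : (r + 1) * spr].tobytes())


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground-truth intervals as tab-separated text with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# duration_s={truth.duration_s}\tfs={truth.fs}\n")
        fh.write("channel\tstart_s\tend_s\tkind\n")
        for a in truth.intervals:
            fh.write(f"{a.channel}\t{a.start_s}\t{a.end_s}\t{a.kind}\n")


def read_ground_truth(path) -> GroundTruth:
    """Read the file written by :func:`write_ground_truth`."""
    duration = None
    fs = 256.0
    intervals: list[ArtifactInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("duration_s="):
                        duration = int(tok.split("=", 1)[1])
                    elif tok.startswith("fs="):
                        fs = float(tok.split("=", 1)[1])
                continue
            if line.startswith("channel\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ConfigurationError(f"malformed ground-truth line {i}: {line!r}")
            intervals.append(ArtifactInterval(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    if duration is None:
        raise ConfigurationError("ground-truth file lacks a duration_s header")
    n_seg = duration
    flags = {ch: np.zeros(n_seg, dtype=bool) for ch in EEG_CHANNELS}
    for a in intervals:
        lo = max(0, a.start_s - 3)
        hi = min(n_seg, a.end_s)
        flags.setdefault(a.channel, np.zeros(n_seg, dtype=bool))
        flags[a.channel][lo:hi] = True
    return GroundTruth(flags=flags, intervals=intervals, duration_s=duration, fs=fs)
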