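"""Preprocessing of raw PSG EEG potentials.

Each EEG channel is prepared independently for spectral analysis:

1. 30 s epochs containing non-finite samples are recoded wholly to NaN,
2. each channel is re-referenced to its contralateral mastoid
   (F3-M2, C3-M2, O1-M2, F4-M1, C4-M1, O2-M1),
3. a zero-phase notch filter removes power-line interference, then a
   zero-phase band-pass keeps 0.5-32.5 Hz,
4. 30 s epochs that are excessively flat (standard deviation below
   1 μV over the epoch, or below 0.2 μV within some 5 s sub-window)
   are removed,
5. 30 s epochs whose absolute amplitude exceeds 500 μV are removed.

Removed epochs are flagged in ``epoch_mask`` and their samples set to
NaN so that downstream spectral windows overlapping them are invalid.
The per-channel count of surviving seconds (``effective_length_s``)
is the denominator of the detector's 5% channel-exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .records import (
    EPOCH_LEN_S,
    REFERENCE_OF,
    ConfigurationError,
    RawPSGRecording,
)

EPOCH_KEPT = "kept"
EPOCH_REMOVED_INVALID = "removed_invalid"
EPOCH_REMOVED_FLAT = "removed_flat"
EPOCH_REMOVED_AMPLITUDE = "removed_amplitude"


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and epoch-screening parameters (defaults per the method).

    ``flat_sub_mode`` selects the reading of the 5 s flatness rule:
    ``"sd"`` (default) flags a 5 s sub-window whose standard deviation
    is below ``flat_sub_uv``; ``"amplitude"`` flags a sub-window whose
    peak absolute amplitude is below it.
    """

    notch_hz: float = 60.0
    notch_q: float = 30.0
    band_lo_hz: float = 0.5
    band_hi_hz: float = 32.5
    flat_sd_uv: float = 1.0
    flat_sub_uv: float = 0.2
    flat_sub_len_s: float = 5.0
    flat_sub_mode: str = "sd"
    max_amp_uv: float = 500.0
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ConfigurationError("need 0 < band_lo_hz < band_hi_hz")
        for name in ("flat_sd_uv", "flat_sub_uv", "flat_sub_len_s", "max_amp_uv"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.flat_sub_mode not in ("sd", "amplitude"):
            raise ConfigurationError("flat_sub_mode must be 'sd' or 'amplitude'")


@dataclass
class PreprocessedRecording:
    """Re-referenced, filtered EEG channels with per-epoch removal flags."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    duration_s: float
    epoch_mask: dict[str, list[str]]
    effective_length_s: dict[str, int]
    stage_labels: list[str] | None = None
    subject_id: str = ""

    def n_kept_epochs(self, channel: str) -> int:
        return sum(m == EPOCH_KEPT for m in self.epoch_mask[channel])


def _epoch_slices(n_samples: int, fs: float, epoch_len_s: int):
    spe = int(round(epoch_len_s * fs))
    n_epochs = int(np.ceil(n_samples / spe))
    for e in range(n_epochs):
        yield e, slice(e * spe, min((e + 1) * spe, n_samples))


def recode_invalid_epochs(recording: RawPSGRecording) -> RawPSGRecording:
    """Recode every 30 s epoch containing a non-finite sample wholly to NaN."""
    out = {}
    for label, series in recording.channels.items():
        series = np.asarray(series, dtype=float).copy()
        for _, sl in _epoch_slices(len(series), recording.sampling_rate, EPOCH_LEN_S):
            if not np.all(np.isfinite(series[sl])):
                series[sl] = np.nan
        out[label] = series
    return replace(recording, channels=out)


def rereference(recording: RawPSGRecording) -> dict[str, np.ndarray]:
    """Subtract the contralateral mastoid from each EEG channel."""
    eeg = recording.eeg_channels()
    needed = sorted({REFERENCE_OF[c] for c in eeg})
    recording.require_channels(needed)
    return {
        c: np.asarray(recording.channels[c], dtype=float)
        - np.asarray(recording.channels[REFERENCE_OF[c]], dtype=float)
        for c in eeg
    }


def apply_filters(series: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase notch then zero-phase band-pass.

    Non-finite spans are zero-filled for filtering only and re-masked
    afterwards, so NaN never contaminates neighbouring samples.
    """
    if fs <= 2 * cfg.band_hi_hz:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low for band edge {cfg.band_hi_hz} Hz"
        )
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    x = np.where(finite, series, 0.0)
    if cfg.notch_hz and cfg.notch_hz < fs / 2:
        b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=fs)
        x = signal.filtfilt(b, a, x)
    sos = signal.butter(
        4, [cfg.band_lo_hz, cfg.band_hi_hz], btype="bandpass", fs=fs, output="sos"
    )
    x = signal.sosfiltfilt(sos, x)
    x[~finite] = np.nan
    return x


def _subwindow_stat(epoch: np.ndarray, fs: float, cfg: PreprocessConfig) -> bool:
    """True when some 5 s sub-window (1 s stride) of the epoch is flat."""
    sub = int(round(cfg.flat_sub_len_s * fs))
    step = int(round(fs))
    if len(epoch) < sub:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(epoch, sub)[::step]
    if cfg.flat_sub_mode == "sd":
        stats = windows.std(axis=1)
    else:
        stats = np.abs(windows).max(axis=1)
    return bool(np.any(stats < cfg.flat_sub_uv))


def flag_flat_epochs(series: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Per-epoch flag for excessively flat signal.

    An epoch is flat when its sample standard deviation is below
    ``flat_sd_uv`` or some ``flat_sub_len_s`` sub-window falls below
    ``flat_sub_uv``.  All-NaN epochs are not flagged here (they are
    already removed as invalid).
    """
    series = np.asarray(series, dtype=float)
    flags = []
    for _, sl in _epoch_slices(len(series), fs, cfg.epoch_len_s):
        epoch = series[sl]
        finite = epoch[np.isfinite(epoch)]
        if finite.size == 0:
            flags.append(False)
            continue
        if finite.std() < cfg.flat_sd_uv:
            flags.append(True)
            continue
        flags.append(_subwindow_stat(finite, fs, cfg))
    return np.asarray(flags, dtype=bool)


def flag_high_amplitude_epochs(
    series: np.ndarray, fs: float, cfg: PreprocessConfig
) -> np.ndarray:
    """Per-epoch flag: max absolute amplitude strictly above ``max_amp_uv``."""
    series = np.asarray(series, dtype=float)
    flags = []
    for _, sl in _epoch_slices(len(series), fs, cfg.epoch_len_s):
        epoch = series[sl]
        finite = epoch[np.isfinite(epoch)]
        flags.append(bool(finite.size and np.abs(finite).max() > cfg.max_amp_uv))
    return np.asarray(flags, dtype=bool)


def preprocess(
    recording: RawPSGRecording, cfg: PreprocessConfig | None = None
) -> PreprocessedRecording:
    """Run the full preprocessing chain on every EEG channel."""
    cfg = cfg or PreprocessConfig()
    fs = recording.sampling_rate
    recording = recode_invalid_epochs(recording)
    referenced = rereference(recording)

    channels: dict[str, np.ndarray] = {}
    epoch_mask: dict[str, list[str]] = {}
    effective: dict[str, int] = {}
    for label, series in referenced.items():
        filtered = apply_filters(series, fs, cfg)
        mask = []
        flat = flag_flat_epochs(filtered, fs, cfg)
        high = flag_high_amplitude_epochs(filtered, fs, cfg)
        for e, sl in _epoch_slices(len(filtered), fs, cfg.epoch_len_s):
            if not np.any(np.isfinite(filtered[sl])):
                mask.append(EPOCH_REMOVED_INVALID)
            elif flat[e]:
                mask.append(EPOCH_REMOVED_FLAT)
                filtered[sl] = np.nan
            elif high[e]:
                mask.append(EPOCH_REMOVED_AMPLITUDE)
                filtered[sl] = np.nan
            else:
                mask.append(EPOCH_KEPT)
        channels[label] = filtered
        epoch_mask[label] = mask
        effective[label] = cfg.epoch_len_s * sum(m == EPOCH_KEPT for m in mask)

    if all(v == 0 for v in effective.values()):
        warnings.warn("preprocessing removed every epoch on every channel")
    return PreprocessedRecording(
        channels=channels,
        sampling_rate=fs,
        duration_s=recording.duration_s,
        epoch_mask=epoch_mask,
        effective_length_s=effective,
        stage_labels=recording.stage_labels,
        subject_id=recording.subject_id,
    )
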