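"""Multitaper spectrograms on a 1 s segment grid.

Each channel's preprocessed series is analysed in 4 s moving windows
with 3 s overlap, so one power spectrum is produced per elapsed second
("segment", indexed to the initial second of its window).  Within each
window the signal is tapered by seven discrete prolate spheroidal
(Slepian) sequences (time-half-bandwidth NW = 4, the standard choice
admitting 2*NW - 1 = 7 tapers), the per-taper periodograms are
averaged, and the one-sided power spectral density is read off on a
0.25 Hz grid covering [0.5, 32.5) Hz — 128 bands with centers
0.5, 0.75, ..., 32.25 Hz.

A record of T whole seconds yields T segments; the trailing seconds
whose 4 s window would run past the end of the record are emitted but
marked invalid, as are segments whose window overlaps any non-finite
(removed) sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .records import ConfigurationError, NoAnalyzableDataError


@dataclass(frozen=True)
class SpectralConfig:
    window_s: float = 4.0
    overlap_s: float = 3.0
    n_tapers: int = 7
    nw: float = 4.0
    band_lo_hz: float = 0.5
    band_hi_hz: float = 32.5
    band_width_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.overlap_s >= self.window_s:
            raise ConfigurationError("overlap_s must be < window_s")
        if self.n_tapers < 1:
            raise ConfigurationError("n_tapers must be >= 1")

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s

    def band_centers(self) -> np.ndarray:
        # half-open grid [band_lo, band_hi): 128 bands at the defaults
        n = int(round((self.band_hi_hz - self.band_lo_hz) / self.band_width_hz))
        return self.band_lo_hz + self.band_width_hz * np.arange(n)


@dataclass
class ChannelSpectrogram:
    """Per-segment absolute power (μV²/Hz) for one channel."""

    channel: str
    power: np.ndarray  # [n_segments, n_bands]
    band_centers: np.ndarray
    segment_times: np.ndarray  # integer seconds, unit step
    valid: np.ndarray  # [n_segments] bool

    @property
    def n_segments(self) -> int:
        return self.power.shape[0]


def multitaper_spectrogram(
    series: np.ndarray,
    fs: float,
    cfg: SpectralConfig | None = None,
    channel: str = "",
) -> ChannelSpectrogram:
    """Compute the multitaper spectrogram of one channel.

    Raises :class:`NoAnalyzableDataError` when the series is shorter
    than a single analysis window.
    """
    cfg = cfg or SpectralConfig()
    series = np.asarray(series, dtype=float)
    m = int(round(cfg.window_s * fs))
    hop = int(round(cfg.hop_s * fs))
    if len(series) < m:
        raise NoAnalyzableDataError(
            f"series of {len(series)} samples is shorter than one "
            f"{cfg.window_s} s window"
        )
    df = fs / m
    centers = cfg.band_centers()
    bin_idx = np.round(centers / df).astype(int)
    if not np.allclose(bin_idx * df, centers, atol=1e-9):
        raise ConfigurationError(
            "band grid is not commensurate with the window FFT resolution; "
            f"window of {m} samples at {fs} Hz gives {df} Hz bins"
        )

    n_segments = int(np.floor(len(series) / fs))
    n_windows = (len(series) - m) // hop + 1

    finite = np.isfinite(series)
    x = np.where(finite, series, 0.0)
    win_view = np.lib.stride_tricks.sliding_window_view(x, m)[::hop][:n_windows]
    bad_view = np.lib.stride_tricks.sliding_window_view(~finite, m)[::hop][:n_windows]
    window_ok = ~bad_view.any(axis=1)

    tapers = windows.dpss(m, cfg.nw, Kmax=cfg.n_tapers)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))

    psd = np.zeros((n_windows, len(bin_idx)))
    for taper in tapers:
        spec = np.fft.rfft(win_view * taper, axis=1)
        psd += np.abs(spec[:, bin_idx]) ** 2
    # one-sided density, averaged over tapers (interior bins only: the
    # band grid excludes DC and Nyquist)
    psd *= 2.0 / (fs * cfg.n_tapers)

    power = np.full((n_segments, len(bin_idx)), np.nan)
    valid = np.zeros(n_segments, dtype=bool)
    n_use = min(n_windows, n_segments)
    power[:n_use] = psd[:n_use]
    valid[:n_use] = window_ok[:n_use]
    power[~valid] = np.nan

    return ChannelSpectrogram(
        channel=channel,
        power=power,
        band_centers=centers,
        segment_times=np.arange(n_segments),
        valid=valid,
    )


def spectrograms_for(
    channels: dict[str, np.ndarray], fs: float, cfg: SpectralConfig | None = None
) -> dict[str, ChannelSpectrogram]:
    """Multitaper spectrogram for every channel in the mapping."""
    cfg = cfg or SpectralConfig()
    return {
        label: multitaper_spectrogram(series, fs, cfg, channel=label)
        for label, series in channels.items()
    }
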