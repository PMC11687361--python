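"""Segment-wise Spearman correlation between channel power spectra.

For every 1 s segment, the 128-band power vectors of two channels are
rank-correlated (Spearman with mid-ranks for ties), giving one
correlation time series per unordered channel pair — 15 series for six
channels.  Averaging the series that share an index channel, segment by
segment, yields that channel's average-correlation series; the set of
partner channels entering the average shrinks as channels are excluded
over detector iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

from .records import ConfigurationError
from .spectral import ChannelSpectrogram


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN when either vector is constant (undefined rank
    variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    nx = np.sqrt((rx**2).sum())
    ny = np.sqrt((ry**2).sum())
    if nx == 0 or ny == 0:
        return float("nan")
    return float((rx * ry).sum() / (nx * ny))


def _normalized_ranks(spec: ChannelSpectrogram) -> np.ndarray:
    """Per-segment mid-ranks of the power vector, centred and unit-norm.

    Invalid segments and zero-variance (constant) segments come out as
    all-NaN rows, which makes the pairwise product NaN (undefined).
    """
    power = spec.power
    out = np.full(power.shape, np.nan)
    rows = spec.valid & np.all(np.isfinite(power), axis=1)
    if rows.any():
        r = rankdata(power[rows], axis=1)
        r = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((r**2).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(norm > 0, r / norm, np.nan)
        out[rows] = r
    return out


@dataclass
class PairwiseCorrelationSeries:
    pair: tuple[str, str]  # sorted labels
    rho: np.ndarray  # [n_segments], NaN where undefined


@dataclass
class AverageCorrelationSeries:
    channel: str
    avg_rho: np.ndarray  # NaN where undefined
    active_partners: frozenset[str]
    n_pairs: np.ndarray  # per-segment count actually averaged


def pairwise_series(
    specs: Mapping[str, ChannelSpectrogram],
) -> dict[tuple[str, str], PairwiseCorrelationSeries]:
    """All unordered pairwise Spearman series (15 for six channels)."""
    labels = sorted(specs)
    if len(labels) < 2:
        raise ConfigurationError("need at least two channels")
    shapes = {specs[l].power.shape for l in labels}
    if len(shapes) != 1:
        raise ConfigurationError("spectrograms do not share a segment/band grid")
    ranks = {l: _normalized_ranks(specs[l]) for l in labels}
    out = {}
    for a, b in combinations(labels, 2):
        rho = np.sum(ranks[a] * ranks[b], axis=1)
        out[(a, b)] = PairwiseCorrelationSeries(pair=(a, b), rho=rho)
    return out


def average_series(
    pairs: Mapping[tuple[str, str], PairwiseCorrelationSeries],
    channel: str,
    active: Iterable[str],
) -> AverageCorrelationSeries:
    """Mean pairwise correlation of ``channel`` with the active partners.

    Undefined pair values are skipped; a segment with no defined pair is
    itself undefined (NaN, ``n_pairs == 0``).
    """
    partners = sorted(set(active) - {channel})
    if not partners:
        raise ConfigurationError(
            f"no active partner channels left for {channel}"
        )
    rows = []
    for p in partners:
        key = tuple(sorted((channel, p)))
        if key not in pairs:
            raise ConfigurationError(f"missing pairwise series for {key}")
        rows.append(pairs[key].rho)
    stack = np.vstack(rows)
    defined = np.isfinite(stack)
    n_pairs = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        total = np.where(defined, stack, 0.0).sum(axis=0)
        avg = np.where(n_pairs > 0, total / np.maximum(n_pairs, 1), np.nan)
    return AverageCorrelationSeries(
        channel=channel,
        avg_rho=avg,
        active_partners=frozenset(partners),
        n_pairs=n_pairs,
    )
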