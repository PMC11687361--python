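"""Adaptive-threshold artifact detection on average-correlation series.

Two thresholds classify each channel's segments:

* local ("bad") rule — within every 60 s moving window (1 s slide), a
  segment whose average correlation is less than half the window median
  is "bad"; a segment flagged in any covering window stays bad.
* global ("outlier") rule — bad segments are outliers outright; among
  the remaining "good" segments, any one below one fourth of the 75th
  percentile of the good pool is also an outlier.

Outliers closer than 300 s are then bridged: every segment between the
two becomes an outlier, producing contiguous artifact regions.  A
channel whose outliers exceed 5% of its post-preprocessing length is
dropped from the average-correlation calculation and the whole scan is
repeated on the surviving channels until no further channel is dropped.
Excluded channels are re-evaluated once against the surviving set so
they still receive artifact annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .correlation import AverageCorrelationSeries, average_series, pairwise_series
from .preprocessing import EPOCH_KEPT, PreprocessedRecording
from .records import (
    EPOCH_LEN_S,
    LABEL_GOOD,
    LABEL_INVALID,
    LABEL_OUTLIER,
    LABEL_REMOVED_PREPROC,
    NREM_STAGES,
    REM_STAGES,
    ArtifactRegion,
    ConfigurationError,
    DetectionResult,
    NoAnalyzableDataError,
    stage_of_segment,
)
from .spectral import ChannelSpectrogram

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the artifact scan.

    ``window_membership`` controls how the moving local window judges a
    segment: ``"any"`` flags a segment bad when any covering window
    flags it; ``"center"`` uses only the window centred on the segment.
    ``exclusion_mode`` is ``"one_at_a_time"`` (drop the worst channel
    per iteration) or ``"all_at_once"``.
    """

    local_window_s: int = 60
    local_slide_s: int = 1
    local_fraction: float = 0.5
    global_fraction: float = 0.25
    global_percentile: float = 75.0
    merge_gap_s: int = 300
    channel_exclude_fraction: float = 0.05
    stage_mode: str = "whole_record"
    window_membership: str = "any"
    exclusion_mode: str = "one_at_a_time"
    min_window_segments: int = 30

    def __post_init__(self) -> None:
        for name in ("local_fraction", "global_fraction", "channel_exclude_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if not (0 < self.global_percentile < 100):
            raise ConfigurationError("global_percentile must be in (0, 100)")
        if self.merge_gap_s < 1:
            raise ConfigurationError("merge_gap_s must be >= 1")
        if self.stage_mode not in ("whole_record", "nrem_rem_separate"):
            raise ConfigurationError("unknown stage_mode")
        if self.window_membership not in ("any", "center"):
            raise ConfigurationError("window_membership must be 'any' or 'center'")
        if self.exclusion_mode not in ("one_at_a_time", "all_at_once"):
            raise ConfigurationError("unknown exclusion_mode")


def local_bad_segments(
    series: AverageCorrelationSeries, cfg: DetectionConfig | None = None
) -> np.ndarray:
    """Apply the moving-window half-median rule.

    Windows are ``local_window_s`` long and slide by ``local_slide_s``;
    truncated windows at the record edges are evaluated when they hold
    at least ``min_window_segments`` defined segments.  The threshold is
    ``local_fraction`` times the window median of defined values,
    clamped below at zero so a negative median cannot invert the rule.
    Invalid (undefined) segments are never flagged.
    """
    cfg = cfg or DetectionConfig()
    rho = np.asarray(series.avg_rho, dtype=float)
    n = len(rho)
    defined = np.isfinite(rho)
    if not defined.any():
        raise NoAnalyzableDataError(
            f"channel {series.channel}: no defined segments"
        )
    w = cfg.local_window_s
    step = cfg.local_slide_s
    bad = np.zeros(n, dtype=bool)

    def judge(a: int, b: int, targets: slice | None = None) -> None:
        vals = rho[a:b][defined[a:b]]
        if vals.size < min(cfg.min_window_segments, n):
            return
        thr = cfg.local_fraction * max(float(np.median(vals)), 0.0)
        sl = slice(a, b) if targets is None else targets
        seg = np.arange(sl.start, sl.stop)
        mark = defined[sl] & (rho[sl] < thr)
        bad[seg[mark]] = True

    if cfg.window_membership == "center":
        half = w // 2
        for t in range(0, n, step):
            a, b = max(0, t - half), min(n, t - half + w)
            vals = rho[a:b][defined[a:b]]
            if vals.size < min(cfg.min_window_segments, n):
                continue
            thr = cfg.local_fraction * max(float(np.median(vals)), 0.0)
            if defined[t] and rho[t] < thr:
                bad[t] = True
        return bad

    # full windows, vectorised median; then truncated edge windows
    if n >= w:
        view = np.lib.stride_tricks.sliding_window_view(
            np.where(defined, rho, np.nan), w
        )[::step]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(view, axis=1)
        counts = np.lib.stride_tricks.sliding_window_view(
            defined.astype(int), w
        )[::step].sum(axis=1)
        for i, p in enumerate(range(0, n - w + 1, step)):
            if counts[i] < cfg.min_window_segments or not np.isfinite(med[i]):
                continue
            thr = cfg.local_fraction * max(float(med[i]), 0.0)
            sl = slice(p, p + w)
            idx = np.nonzero(defined[sl] & (rho[sl] < thr))[0]
            bad[idx + p] = True
        for k in range(cfg.min_window_segments, w, step):  # truncated edges
            judge(0, k)
            judge(n - k, n)
    else:
        judge(0, n)
    return bad


def global_outliers(
    series: AverageCorrelationSeries,
    bad: np.ndarray,
    cfg: DetectionConfig | None = None,
) -> np.ndarray:
    """Promote low-correlation "good" segments to outliers.

    The cutoff is ``global_fraction`` of the ``global_percentile``-th
    percentile (linear interpolation) of the good-segment pool; every
    bad segment is an outlier regardless of value.
    """
    cfg = cfg or DetectionConfig()
    rho = np.asarray(series.avg_rho, dtype=float)
    bad = np.asarray(bad, dtype=bool)
    defined = np.isfinite(rho)
    good = defined & ~bad
    if not good.any():
        warnings.warn(
            f"channel {series.channel}: empty good pool — "
            "marking every defined segment as an outlier"
        )
        return defined.copy()
    tau = global_cutoff(rho[good], cfg)
    return bad | (good & (rho < tau))


def global_cutoff(good_pool: np.ndarray, cfg: DetectionConfig | None = None) -> float:
    """The global outlier cutoff for a channel's good-segment pool.

    ``global_fraction`` times the ``global_percentile``-th percentile of
    the pool, with the percentile computed by linear interpolation
    between closest ranks.
    """
    cfg = cfg or DetectionConfig()
    return cfg.global_fraction * float(
        np.percentile(np.asarray(good_pool, dtype=float), cfg.global_percentile)
    )


def merge_outliers_into_regions(
    outliers: np.ndarray, cfg: DetectionConfig | None = None, channel: str = ""
) -> tuple[list[ArtifactRegion], np.ndarray]:
    """Bridge outliers closer than ``merge_gap_s`` and form regions.

    Consecutive outliers ``a < b`` with ``b - a < merge_gap_s`` have all
    intervening segments promoted to outliers.  Maximal runs of the
    resulting mask become regions; a region containing any promoted
    segment has source ``merged``, otherwise ``local``.  Returns the
    regions and the merged outlier mask.
    """
    cfg = cfg or DetectionConfig()
    outliers = np.asarray(outliers, dtype=bool)
    merged = outliers.copy()
    idx = np.nonzero(outliers)[0]
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a < cfg.merge_gap_s:
            merged[a : b + 1] = True
    promoted = merged & ~outliers

    regions: list[ArtifactRegion] = []
    if merged.any():
        m = np.nonzero(merged)[0]
        breaks = np.nonzero(np.diff(m) > 1)[0]
        starts = np.concatenate(([m[0]], m[breaks + 1]))
        ends = np.concatenate((m[breaks], [m[-1]]))
        for s, e in zip(starts, ends):
            source = "merged" if promoted[s : e + 1].any() else "local"
            regions.append(
                ArtifactRegion(channel=channel, start_s=int(s), end_s=int(e), source=source)
            )
    return regions, merged


def channel_outlier_fraction(
    outlier_mask: np.ndarray, analyzable_mask: np.ndarray
) -> float:
    """Outlier segments as a fraction of the analyzable segments.

    The denominator is the channel's length after preprocessing: all
    segments that are neither removed by preprocessing nor invalid.
    """
    analyzable = np.asarray(analyzable_mask, dtype=bool)
    denom = int(analyzable.sum())
    if denom == 0:
        raise NoAnalyzableDataError("no analyzable segments in channel")
    num = int((np.asarray(outlier_mask, dtype=bool) & analyzable).sum())
    return num / denom


def _segment_masks(
    preproc: PreprocessedRecording, spec: ChannelSpectrogram, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    """(removed_preproc, analyzable) per-segment masks for one channel."""
    n = spec.n_segments
    removed = np.zeros(n, dtype=bool)
    mask = preproc.epoch_mask[channel]
    for t in range(n):
        ep = t // EPOCH_LEN_S
        if ep < len(mask) and mask[ep] != EPOCH_KEPT:
            removed[t] = True
    analyzable = spec.valid & ~removed
    return removed, analyzable


def _classify_channel(
    series: AverageCorrelationSeries,
    cfg: DetectionConfig,
    stage_groups: Sequence[np.ndarray] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run local + global + merge on one average series.

    Returns (bad_mask, outlier_mask_pre_merge, merged_mask).  With
    stage-separate pooling the rules run independently within each
    stage group and the masks are unioned.
    """
    rho = series.avg_rho
    n = len(rho)
    if stage_groups is None:
        bad = local_bad_segments(series, cfg)
        out = global_outliers(series, bad, cfg)
        _, merged = merge_outliers_into_regions(out, cfg, series.channel)
        return bad, out, merged

    bad = np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    merged = np.zeros(n, dtype=bool)
    for group in stage_groups:
        if not group.any():
            continue
        sub = AverageCorrelationSeries(
            channel=series.channel,
            avg_rho=np.where(group, rho, np.nan),
            active_partners=series.active_partners,
            n_pairs=series.n_pairs,
        )
        if not np.isfinite(sub.avg_rho).any():
            continue
        b = local_bad_segments(sub, cfg)
        o = global_outliers(sub, b, cfg)
        _, m = merge_outliers_into_regions(o, cfg, series.channel)
        bad |= b
        out |= o
        merged |= m
    return bad, out, merged


def detect(
    preproc: PreprocessedRecording,
    specs: Mapping[str, ChannelSpectrogram],
    cfg: DetectionConfig | None = None,
) -> DetectionResult:
    """Iterative artifact detection over all channels.

    Each iteration recomputes every active channel's average-correlation
    series from pairwise correlations among active channels only,
    classifies segments, and drops channels whose outlier fraction
    strictly exceeds ``channel_exclude_fraction``.  Iteration stops when
    nothing is dropped or fewer than two channels would remain.
    """
    cfg = cfg or DetectionConfig()
    labels_all = sorted(specs)
    usable = [
        ch for ch in labels_all
        if preproc.effective_length_s.get(ch, 0) > 0 and specs[ch].valid.any()
    ]
    if len(usable) < 2:
        raise NoAnalyzableDataError(
            "fewer than two channels with analyzable data"
        )

    n_seg = specs[usable[0]].n_segments
    seg_masks = {ch: _segment_masks(preproc, specs[ch], ch) for ch in usable}

    stage_groups = None
    if cfg.stage_mode == "nrem_rem_separate":
        seg_stage = stage_of_segment(preproc.stage_labels, n_seg)
        nrem = np.array([s in NREM_STAGES for s in seg_stage])
        rem = np.array([s in REM_STAGES for s in seg_stage])
        stage_groups = [nrem, rem]

    pairs = pairwise_series({ch: specs[ch] for ch in usable})

    active = list(usable)
    excluded: list[tuple[int, str]] = []
    fractions: dict[str, float] = {}
    bad_masks: dict[str, np.ndarray] = {}
    outlier_masks: dict[str, np.ndarray] = {}
    iteration = 0

    while True:
        iteration += 1
        over: list[tuple[float, str]] = []
        for ch in active:
            series = average_series(pairs, ch, active)
            bad, out, merged = _classify_channel(series, cfg, stage_groups)
            bad_masks[ch] = bad
            outlier_masks[ch] = merged
            frac = channel_outlier_fraction(merged, seg_masks[ch][1])
            fractions[ch] = frac
            if frac > cfg.channel_exclude_fraction:
                over.append((frac, ch))
            logger.info(
                "iteration %d: channel %s outlier fraction %.4f%s",
                iteration, ch, frac,
                " (over threshold)" if frac > cfg.channel_exclude_fraction else "",
            )
        if not over or len(active) - (1 if cfg.exclusion_mode == "one_at_a_time" else len(over)) < 2:
            break
        over.sort(reverse=True)
        to_drop = [over[0][1]] if cfg.exclusion_mode == "one_at_a_time" else [c for _, c in over]
        for ch in to_drop:
            active.remove(ch)
            excluded.append((iteration, ch))
            logger.info("iteration %d: excluding channel %s", iteration, ch)

    # final pass: excluded channels re-evaluated against the survivors
    for _, ch in excluded:
        series = average_series(pairs, ch, set(active) | {ch})
        bad, out, merged = _classify_channel(series, cfg, stage_groups)
        bad_masks[ch] = bad
        outlier_masks[ch] = merged
        fractions[ch] = channel_outlier_fraction(merged, seg_masks[ch][1])

    regions: dict[str, list[ArtifactRegion]] = {}
    labels: dict[str, np.ndarray] = {}
    for ch in usable:
        merged = outlier_masks[ch]
        regs, _ = merge_outliers_into_regions(merged, cfg, ch)
        bad = bad_masks[ch]
        final_regs = []
        for r in regs:
            source = r.source
            if source == "local" and not bad[r.start_s : r.end_s + 1].any():
                source = "global"
            final_regs.append(
                ArtifactRegion(channel=ch, start_s=r.start_s, end_s=r.end_s, source=source)
            )
        regions[ch] = final_regs
        removed, analyzable = seg_masks[ch]
        lab = np.full(n_seg, LABEL_GOOD, dtype=object)
        lab[~specs[ch].valid & ~removed] = LABEL_INVALID
        lab[removed] = LABEL_REMOVED_PREPROC
        lab[analyzable & merged] = LABEL_OUTLIER
        labels[ch] = lab

    return DetectionResult(
        regions=regions,
        excluded_channels=excluded,
        n_iterations=iteration,
        per_channel_outlier_fraction=fractions,
        config=cfg,
        labels=labels,
        outlier_masks=outlier_masks,
    )
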