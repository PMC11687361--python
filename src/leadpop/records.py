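"""Shared domain types for polysomnography (PSG) EEG artifact detection.

The detector works on overnight six-channel sleep EEG (frontal F3/F4,
central C3/C4, occipital O1/O2) referenced to the contralateral mastoids
(M1/M2).  Time is carried in three resolutions throughout the package:

* samples — raw potentials at the recording rate (``sampling_rate``),
* segments — 1 s units, each indexed to the initial second of the 4 s
  spectral window that produced it,
* epochs — 30 s sleep-scoring units carrying stage labels (W, N1, N2,
  N3, R).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

EEG_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "O1", "O2")
MASTOIDS: tuple[str, str] = ("M1", "M2")

#: Contralateral mastoid used to re-reference each EEG channel
#: (left-hemisphere channels against M2, right-hemisphere against M1).
REFERENCE_OF: dict[str, str] = {
    "F3": "M2", "C3": "M2", "O1": "M2",
    "F4": "M1", "C4": "M1", "O2": "M1",
}

STAGE_CODES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R", "unknown")
NREM_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3"})
REM_STAGES: frozenset[str] = frozenset({"R"})

EPOCH_LEN_S = 30

# per-segment classification labels
LABEL_GOOD = "good"
LABEL_BAD = "bad"
LABEL_OUTLIER = "outlier"
LABEL_REMOVED_PREPROC = "removed_preproc"
LABEL_INVALID = "invalid"


class LeadpopError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(LeadpopError):
    """Invalid configuration or missing required channels."""


class NoAnalyzableDataError(LeadpopError):
    """All data were removed by preprocessing or the record is too short."""


class AnnotationParseError(LeadpopError):
    """A plain-text annotation file could not be parsed."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class RawPSGRecording:
    """A multichannel PSG recording held as per-channel μV series.

    All channels share one sampling rate and one length; stage labels,
    if present, cover the record in 30 s epochs.
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    duration_s: float
    stage_labels: list[str] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        n_expected = int(round(self.duration_s * self.sampling_rate))
        for label, series in self.channels.items():
            if len(series) != n_expected:
                raise ConfigurationError(
                    f"channel {label}: length {len(series)} != "
                    f"round(duration_s * sampling_rate) = {n_expected}"
                )
        if self.stage_labels is not None:
            n_epochs = ceil(self.duration_s / EPOCH_LEN_S)
            if len(self.stage_labels) != n_epochs:
                raise ConfigurationError(
                    f"stage_labels has {len(self.stage_labels)} entries, "
                    f"expected {n_epochs} (one per 30 s epoch)"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    @property
    def n_epochs(self) -> int:
        return ceil(self.duration_s / EPOCH_LEN_S)

    def eeg_channels(self) -> list[str]:
        return [c for c in EEG_CHANNELS if c in self.channels]

    def require_channels(self, labels: Sequence[str]) -> None:
        missing = [l for l in labels if l not in self.channels]
        if missing:
            raise ConfigurationError(
                f"required channel(s) absent: {', '.join(missing)}"
            )


@dataclass(frozen=True)
class ArtifactRegion:
    """A maximal run of outlier segments on one channel.

    Coordinates are 0-based seconds from the start of the recording and
    the interval is closed on both ends, so a single outlier segment is
    the region ``[t, t]`` with ``n_segments == 1``.
    """

    channel: str
    start_s: int
    end_s: int
    source: str = "local"

    SOURCES = ("local", "global", "merged", "channel_excluded")

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("end_s must be >= start_s")
        if self.source not in self.SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n_segments(self) -> int:
        return self.end_s - self.start_s + 1


@dataclass
class DetectionResult:
    """Outcome of the iterative artifact scan.

    ``regions`` holds, per channel, the artifact regions from the
    iteration in which that channel was last evaluated (excluded
    channels are re-evaluated once against the surviving active set).
    ``excluded_channels`` records the exclusion order as
    ``(iteration_index, channel)`` pairs (iterations are 1-based).
    """

    regions: dict[str, list[ArtifactRegion]]
    excluded_channels: list[tuple[int, str]]
    n_iterations: int
    per_channel_outlier_fraction: dict[str, float]
    config: "object"
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    outlier_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def excluded_set(self) -> set[str]:
        return {ch for _, ch in self.excluded_channels}


def stage_of_segment(stage_labels: Sequence[str] | None, n_segments: int) -> np.ndarray:
    """Expand per-epoch stage labels to per-segment labels.

    A segment takes the stage of the 30 s epoch containing its initial
    second.  Without stage labels every segment is ``unknown``.
    """
    out = np.full(n_segments, "unknown", dtype=object)
    if stage_labels is None:
        return out
    for t in range(n_segments):
        ep = t // EPOCH_LEN_S
        if ep < len(stage_labels):
            out[t] = stage_labels[ep]
    return out
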