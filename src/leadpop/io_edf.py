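"""EDF input and plain-text annotation I/O.

Reading goes through MNE's EDF reader; channels are relabelled to the
canonical montage names (F3, F4, C3, C4, O1, O2, M1, M2) via an
optional alias map, since real-world EDFs label channels
inconsistently ("EEG F3-Ref", "F3-A2", ...).  Mixed per-channel
sampling rates are resampled by the reader to a common rate before
analysis.

Sleep-stage annotations are accepted in two plain-text dialects: one
stage code per line (commas allowed), or ``start duration stage``
triples covering 30 s epochs.

The detector's output is written as a tab-separated ASCII file with an
explicit header, one artifact region per line, deterministically
ordered by channel label then start second.
"""

from __future__ import annotations

import logging
import os
import numpy as np

from .records import (
    EEG_CHANNELS,
    EPOCH_LEN_S,
    MASTOIDS,
    STAGE_CODES,
    AnnotationParseError,
    ArtifactRegion,
    ConfigurationError,
    DetectionResult,
    RawPSGRecording,
)

logger = logging.getLogger(__name__)

ANNOTATION_HEADER = "channel\tstart_s\tend_s\tn_segments\tsource"


def read_psg_edf(path, channel_map: dict[str, str] | None = None,
                 min_eeg_channels: int = 3) -> RawPSGRecording:
    """Read an EDF/EDF+ PSG recording into canonical μV series.

    ``channel_map`` maps labels as stored in the file to canonical
    names.  Both mastoids and at least ``min_eeg_channels`` EEG
    channels must be resolvable.
    """
    import mne

    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise IOError(f"could not read EDF file {path}: {exc}") from exc

    rename = {}
    for name in raw.ch_names:
        if channel_map and name in channel_map:
            rename[name] = channel_map[name]
        else:
            stripped = name.removeprefix("EEG ").strip()
            if stripped in EEG_CHANNELS or stripped in MASTOIDS:
                rename[name] = stripped
    if rename:
        raw.rename_channels(rename)

    present = set(raw.ch_names)
    missing_refs = [m for m in MASTOIDS if m not in present]
    if missing_refs:
        raise ConfigurationError(
            f"required mastoid channel(s) absent from EDF: {', '.join(missing_refs)}"
        )
    eeg_present = [c for c in EEG_CHANNELS if c in present]
    if len(eeg_present) < min_eeg_channels:
        missing = [c for c in EEG_CHANNELS if c not in present]
        raise ConfigurationError(
            f"need at least {min_eeg_channels} EEG channels; absent: "
            f"{', '.join(missing)}"
        )

    keep = eeg_present + list(MASTOIDS)
    raw.pick(keep)
    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data(units="uV")
    duration = raw.n_times / fs
    channels = {name: data_uv[i] for i, name in enumerate(raw.ch_names)}
    return RawPSGRecording(
        channels=channels,
        sampling_rate=fs,
        duration_s=duration,
        subject_id=os.path.basename(str(path)),
    )


def read_stage_annotations(path, epoch_len_s: int = EPOCH_LEN_S) -> list[str]:
    """Read per-epoch sleep stages from a plain-text file.

    Dialect A: one stage code per line (or comma-separated codes).
    Dialect B: ``start duration stage`` triples in seconds.
    Unrecognised codes map to ``unknown`` with a logged warning.
    """
    known = set(STAGE_CODES) - {"unknown"}
    tokens: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            tokens.append((i, parts))
    if not tokens:
        return []

    def is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    triple_dialect = all(
        len(p) == 3 and is_number(p[0]) and is_number(p[1]) for _, p in tokens
    )

    def normalize(code: str, line_no: int) -> str:
        c = code.upper().replace("STAGE", "").strip()
        aliases = {"NREM1": "N1", "NREM2": "N2", "NREM3": "N3", "REM": "R",
                   "WAKE": "W", "1": "N1", "2": "N2", "3": "N3", "4": "N3",
                   "0": "W", "5": "R"}
        c = aliases.get(c, c)
        if c not in known:
            logger.warning("line %d: unrecognized stage code %r mapped to unknown",
                           line_no, code)
            return "unknown"
        return c

    if triple_dialect:
        stages: list[str] = []
        for line_no, parts in tokens:
            start, dur, code = float(parts[0]), float(parts[1]), parts[2]
            if dur <= 0 or start < 0:
                raise AnnotationParseError(
                    f"invalid start/duration {parts[0]}/{parts[1]}", line_no
                )
            n_ep = int(round(dur / epoch_len_s))
            first = int(round(start / epoch_len_s))
            stage = normalize(code, line_no)
            while len(stages) < first + max(n_ep, 1):
                stages.append("unknown")
            for e in range(first, first + max(n_ep, 1)):
                stages[e] = stage
        return stages

    stages = []
    for line_no, parts in tokens:
        for code in parts:
            if is_number(code) and code not in ("0", "1", "2", "3", "4", "5"):
                raise AnnotationParseError(f"unexpected numeric token {code!r}", line_no)
            stages.append(normalize(code, line_no))
    return stages


def write_artifact_annotations(result: DetectionResult, path) -> None:
    """Write the artifact regions as tab-separated ASCII text."""
    rows = []
    for channel in sorted(result.regions):
        for r in sorted(result.regions[channel], key=lambda r: r.start_s):
            rows.append((r.channel, r.start_s, r.end_s, r.n_segments, r.source))
    with open(path, "w", encoding="ascii") as fh:
        fh.write(ANNOTATION_HEADER + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_artifact_annotations(path) -> dict[str, list[ArtifactRegion]]:
    """Read a file written by :func:`write_artifact_annotations`."""
    regions: dict[str, list[ArtifactRegion]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != ANNOTATION_HEADER:
            raise AnnotationParseError(f"unexpected header {header!r}", 1)
        for i, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise AnnotationParseError("expected 5 tab-separated fields", i)
            ch, start_s, end_s, n_seg, source = parts
            try:
                region = ArtifactRegion(ch, int(start_s), int(end_s), source)
            except ValueError as exc:
                raise AnnotationParseError(str(exc), i) from exc
            if region.n_segments != int(n_seg):
                raise AnnotationParseError(
                    f"n_segments {n_seg} inconsistent with span", i
                )
            regions.setdefault(ch, []).append(region)
    return regions


def regions_to_mask(regions: list[ArtifactRegion], n_segments: int) -> np.ndarray:
    """Expand closed-interval regions to a per-segment boolean mask."""
    mask = np.zeros(n_segments, dtype=bool)
    for r in regions:
        mask[r.start_s : min(r.end_s + 1, n_segments)] = True
    return mask
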