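"""End-to-end convenience wrapper: raw recording → detection result."""

from __future__ import annotations

from dataclasses import dataclass

from .detection import DetectionConfig, DetectionResult, detect
from .preprocessing import PreprocessConfig, PreprocessedRecording, preprocess
from .records import RawPSGRecording
from .spectral import ChannelSpectrogram, SpectralConfig, spectrograms_for


@dataclass
class PipelineOutput:
    preprocessed: PreprocessedRecording
    spectrograms: dict[str, ChannelSpectrogram]
    result: DetectionResult


def run_detection(
    recording: RawPSGRecording,
    preprocess_cfg: PreprocessConfig | None = None,
    spectral_cfg: SpectralConfig | None = None,
    detection_cfg: DetectionConfig | None = None,
) -> PipelineOutput:
    """Preprocess, compute spectrograms, and run the iterative detector."""
    pre = preprocess(recording, preprocess_cfg)
    specs = spectrograms_for(pre.channels, pre.sampling_rate, spectral_cfg)
    result = detect(pre, specs, detection_cfg)
    return PipelineOutput(preprocessed=pre, spectrograms=specs, result=result)
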