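"""End-to-end convenience: micrographs in, staged fish out."""

from __future__ import annotations

from typing import Sequence

from .config import ClassBounds, DetectionConfig
from .detection import Micrograph, detect_objects, filter_oocytes, merge_fish_detections
from .staging import UltrametricResult, stage_fish


def stage_micrographs(
    micrographs: Sequence[Micrograph],
    detection_config: DetectionConfig | None = None,
    bounds: ClassBounds | None = None,
    fish_id: str = "",
) -> UltrametricResult:
    """Detect, filter, pool and stage one fish's micrographs."""
    cfg = detection_config or DetectionConfig()
    per = [
        (m.id, filter_oocytes(detect_objects(m, cfg), cfg)) for m in micrographs
    ]
    diameters, flags = merge_fish_detections(per)
    return stage_fish(diameters, bounds, fish_id=fish_id, qc_flags=flags)
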