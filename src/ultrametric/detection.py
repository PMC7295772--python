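"""Oocyte detection and filtering in whole-mount micrographs.

Stained whole-mounts show oocytes as dark, near-elliptical objects on a light
background.  Detection is a global intensity threshold at the configured grey
cut-off on the dark phase, hole filling, 8-connected labelling, and removal of
border-touching components; each remaining component is measured through its
fitted ellipse (image second moments).  Touching oocytes are not split: merged
blobs fail the roundness/ellipticity criteria downstream, mirroring manual
cleaning practice in the original workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .config import DetectionConfig
from .errors import InputFormatError

REJECTION_REASONS = ("none", "size", "grey", "roundness", "ellipticity")

QC_LOW_COUNT = "low_count"
QC_FEW_MICROGRAPHS = "few_micrographs"

#: protocol QC: at least this many passed oocytes per fish ...
MIN_OOCYTES_PER_FISH = 200
#: ... photographed over at least this many micrographs.
MIN_MICROGRAPHS_PER_FISH = 3


@dataclass(frozen=True)
class Micrograph:
    """A single 8-bit grey-level whole-mount image with known resolution."""

    pixels: np.ndarray
    resolution_px_per_um: float = 0.1803
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InputFormatError("micrograph must be a non-empty 2-D raster")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise InputFormatError("micrograph must hold 8-bit integer grey levels")
            if px.min() < 0 or px.max() > 255:
                raise InputFormatError("grey levels must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.resolution_px_per_um <= 0:
            raise InputFormatError("resolution must be positive (px/um)")


@dataclass(frozen=True)
class OocyteRecord:
    """One detected object with size, shape and intensity descriptors.

    Lengths are in µm; ``centroid`` is (row, col) in 0-based pixel
    coordinates.  ``diameter_um = sqrt(major_um * minor_um)`` is the
    equal-area equivalent diameter of the fitted ellipse.
    """

    diameter_um: float
    major_um: float
    minor_um: float
    area_um2: float
    roundness: float
    ellipticity: float
    mean_grey: float
    centroid: tuple[float, float]
    passed_filter: bool = False
    rejection_reason: str = "none"


def detect_objects(
    micrograph: Micrograph, config: DetectionConfig | None = None
) -> list[OocyteRecord]:
    """Detect all candidate objects in a micrograph (no filtering applied).

    Returns one record per connected dark component that does not touch the
    image border, with all shape descriptors populated and
    ``passed_filter=False``; apply :func:`filter_oocytes` to select oocytes.
    A blank image yields an empty list.
    """
    config = config or DetectionConfig()
    px = micrograph.pixels
    res = micrograph.resolution_px_per_um

    mask = px < config.max_grey
    mask = ndi.binary_fill_holes(mask)
    mask = clear_border(mask)
    labels = label(mask, connectivity=2)

    records: list[OocyteRecord] = []
    for region in regionprops(labels, intensity_image=px):
        area_px = float(region.area)
        major_px = float(region.axis_major_length)
        minor_px = float(region.axis_minor_length)
        if major_px > 0:
            roundness = min(1.0, 4.0 * area_px / (np.pi * major_px**2))
        else:
            roundness = 0.0
        ellipse_area_px = np.pi * major_px * minor_px / 4.0
        if ellipse_area_px > 0:
            ellipticity = min(1.0, area_px / ellipse_area_px)
        else:
            ellipticity = 0.0
        major_um = major_px / res
        minor_um = minor_px / res
        records.append(
            OocyteRecord(
                diameter_um=float(np.sqrt(major_um * minor_um)),
                major_um=major_um,
                minor_um=minor_um,
                area_um2=area_px / res**2,
                roundness=roundness,
                ellipticity=ellipticity,
                mean_grey=float(region.intensity_mean),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    return records


def _rejection_reason(rec: OocyteRecord, config: DetectionConfig) -> str:
    """First failing criterion, in protocol order: size, grey, shape."""
    if not config.min_diameter_um <= rec.diameter_um <= config.max_diameter_um:
        return "size"
    if not rec.mean_grey < config.max_grey:  # strict: grey tone < cut-off
        return "grey"
    if not config.roundness_min <= rec.roundness <= config.roundness_max:
        return "roundness"
    if not rec.ellipticity >= config.ellipticity_min:
        return "ellipticity"
    return "none"


def filter_oocytes(
    records: Iterable[OocyteRecord], config: DetectionConfig | None = None
) -> list[OocyteRecord]:
    """Apply the oocyte selection thresholds to detected objects.

    Every record is returned (order preserved) with ``passed_filter`` set and,
    for rejected records, the first failing criterion as ``rejection_reason``.
    Size, roundness and ellipticity bounds are inclusive; the grey-tone
    criterion is strict (mean grey must be below the cut-off).
    """
    config = config or DetectionConfig()
    out = []
    for rec in records:
        reason = _rejection_reason(rec, config)
        out.append(replace(rec, passed_filter=reason == "none", rejection_reason=reason))
    return out


def merge_fish_detections(
    per_micrograph: Sequence[tuple[str, Sequence[OocyteRecord]]],
) -> tuple[list[float], list[str]]:
    """Pool passed oocyte diameters for one fish across its micrographs.

    Returns the concatenated diameters of records with ``passed_filter`` and
    QC flags: ``low_count`` if fewer than 200 oocytes passed in total,
    ``few_micrographs`` if fewer than 3 micrographs were supplied.
    """
    if len(per_micrograph) == 0:
        raise ValueError("at least one micrograph is required")
    diameters = [
        rec.diameter_um
        for _, recs in per_micrograph
        for rec in recs
        if rec.passed_filter
    ]
    flags = []
    if len(diameters) < MIN_OOCYTES_PER_FISH:
        flags.append(QC_LOW_COUNT)
    if len(per_micrograph) < MIN_MICROGRAPHS_PER_FISH:
        flags.append(QC_FEW_MICROGRAPHS)
    return diameters, flags
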