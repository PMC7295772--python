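"""Configuration dataclasses shared across pipeline stages.

Every numeric default that the staging protocol fixes (detection thresholds,
counting windows, category breaks, stereology constants) lives here so that
the generator, the detector and the classifier are guaranteed to agree.
All configs round-trip losslessly through YAML via :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for selecting valid oocytes among detected objects.

    Shape descriptors follow common image-analysis definitions (the original
    ObjectJ macro does not publish its formulas, so these are documented
    substitutes):

    * ``roundness = 4 * area / (pi * major_axis**2)`` — 1 for a circle,
      ``minor/major`` for an ellipse.
    * ``ellipticity = area / fitted_ellipse_area`` capped at 1 — how well the
      object is described by its fitted ellipse; debris and touching blobs
      score low.

    The equivalent diameter is the geometric mean of the fitted-ellipse axes,
    ``sqrt(major * minor)``, i.e. the diameter of the equal-area circle for an
    elliptical profile.
    """

    min_diameter_um: float = 100.0
    max_diameter_um: float = 1600.0
    max_grey: int = 111  # exclusive: object mean grey must be < max_grey
    roundness_min: float = 0.8
    roundness_max: float = 1.0
    ellipticity_min: float = 0.91
    resolution_px_per_um: float = 0.1803

    def __post_init__(self) -> None:
        if not 0 < self.min_diameter_um < self.max_diameter_um:
            raise ValueError("require 0 < min_diameter_um < max_diameter_um")
        if not 0 <= self.roundness_min <= self.roundness_max <= 1:
            raise ValueError("roundness bounds must satisfy 0 <= min <= max <= 1")
        if not 0 < self.ellipticity_min <= 1:
            raise ValueError("ellipticity_min must be in (0, 1]")
        if not 0 < self.max_grey <= 255:
            raise ValueError("max_grey must be in (0, 255]")
        if self.resolution_px_per_um <= 0:
            raise ValueError("resolution must be positive")


@dataclass(frozen=True)
class ClassBounds:
    """Counting windows and category breaks for the oocyte ratio (OR).

    PVOs are counted on the half-open window ``[pvo_min, dev_min)`` and
    developing oocytes (vitellogenic + final maturation) on the closed window
    ``[dev_min, dev_max]``; anything above ``dev_max`` is a hydrated/ovulated
    egg and is excluded from the ratio.  When a fish has no developing
    oocytes at all, the denominator is replaced by
    ``zero_denominator_substitute`` so a (large) OR can still be computed.

    ``orc_breaks`` split the OR scale into the four oocyte ratio categories:
    OR <= 1 -> 1, 1 < OR <= 3 -> 2, 3 < OR <= 15 -> 3, OR > 15 -> 4.

    A 200 µm lower split for the developing window was evaluated and rejected
    during method development; set ``dev_min=200`` to reproduce that variant.
    """

    pvo_min_um: float = 100.0
    dev_min_um: float = 250.0
    dev_max_um: float = 1200.0
    max_diameter_um: float = 1600.0
    orc_breaks: tuple[float, float, float] = (1.0, 3.0, 15.0)
    zero_denominator_substitute: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.pvo_min_um < self.dev_min_um < self.dev_max_um:
            raise ValueError("windows must satisfy 0 < pvo_min < dev_min < dev_max")
        if self.dev_max_um > self.max_diameter_um:
            raise ValueError("dev_max_um cannot exceed max_diameter_um")
        b = self.orc_breaks
        if not (len(b) == 3 and b[0] < b[1] < b[2]):
            raise ValueError("orc_breaks must be three strictly increasing values")
        if self.zero_denominator_substitute <= 0:
            raise ValueError("zero_denominator_substitute must be positive")


@dataclass(frozen=True)
class StereologyConfig:
    """Constants for Weibel point-count stereology of POFs.

    ``beta`` is the particle shape coefficient in the Weibel–Gomez number
    estimator ``Nv = (k / beta) * Na**1.5 / Vv**0.5``; 1.38 is the value for
    spheres (``2**1.5 / sqrt(4*pi/3)``).  ``k_size`` corrects for the spread
    of the particle size distribution (1.0 = monodisperse).  Ovary volume is
    obtained from ovary weight at the given specific gravity.
    """

    beta: float = 1.38
    k_size: float = 1.0
    specific_gravity_g_per_cm3: float = 1.0464

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.k_size <= 0 or self.specific_gravity_g_per_cm3 <= 0:
            raise ValueError("k_size and specific gravity must be positive")


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunables for OSFD smoothing, cohort detection and hiatus placement.

    The KDE bandwidth defaults to Silverman's rule clamped to
    ``[bandwidth_min_um, bandwidth_max_um]``, which resolves the PVO/VO
    structure of whole-mount distributions without over-smoothing.  The
    remaining fractions calibrate the qualitative phenotype flags (bimodal
    vitellogenic cohorts, long tails, ambiguous hiatus); the staging protocol
    defines these phenotypes visually, so the thresholds are calibrated
    defaults, all overridable.
    """

    bin_width_um: float = 20.0
    grid_step_um: float = 1.0
    bandwidth_min_um: float = 10.0
    bandwidth_max_um: float = 40.0
    dev_window_um: tuple[float, float] = (250.0, 1200.0)
    fom_onset_um: float = 875.0  # annotation only, never used in classification
    budding_window_um: tuple[float, float] = (850.0, 1200.0)
    peak_prominence_frac: float = 0.05
    valley_frac: float = 0.5
    tail_frac: float = 0.05
    gap_frac: float = 0.05
    gap_occupancy_frac: float = 0.10


@dataclass
class RunConfig:
    """Aggregate configuration for a full pipeline run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bounds: ClassBounds = field(default_factory=ClassBounds)
    stereology: StereologyConfig = field(default_factory=StereologyConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0
    out_dir: str = "ultrametric_out"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        # tuples -> lists for clean YAML; restored on load
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        def _tup(section: dict, key: str) -> None:
            if key in section and isinstance(section[key], list):
                section[key] = tuple(section[key])

        det = dict(d.get("detection", {}))
        bounds = dict(d.get("bounds", {}))
        _tup(bounds, "orc_breaks")
        stereo = dict(d.get("stereology", {}))
        ann = dict(d.get("annotation", {}))
        _tup(ann, "dev_window_um")
        _tup(ann, "budding_window_um")
        return cls(
            detection=DetectionConfig(**det),
            bounds=ClassBounds(**bounds),
            stereology=StereologyConfig(**stereo),
            annotation=AnnotationConfig(**ann),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "ultrametric_out")),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})
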