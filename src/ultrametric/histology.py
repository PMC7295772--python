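"""Histology-derived metrics: atresia and post-ovulatory follicles (POFs).

Atresia and POF identification is done by a human reader on stained sections;
this module consumes the resulting count/area tables.  POF number is
estimated by Weibel point-count stereology: a grid of (by default) 256 points
over 10 counting fields of 6 mm^2 gives the POF volume fraction Vv and the
profile count per area Na, combined by the Weibel-Gomez estimator

    Nv = (k / beta) * Na**(3/2) / Vv**(1/2)

into a number density per volume, scaled by ovary volume (ovary weight at a
specific gravity of 1.0464 g/cm^3) into total POF number F_POF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import StereologyConfig
from .errors import BiometryError, InconsistentCountsError, UltrametricError


@dataclass(frozen=True)
class AtresiaSample:
    """Human-scored alpha-atresia counts for one fish.

    ``n_alpha`` may be given directly or as the EA/LARC/LANC sub-stage
    breakdown (early alpha, late alpha residual chorion, late alpha no
    chorion), which must then sum to ``n_alpha``.
    """

    fish_id: str
    n_alpha: int
    n_normal: int
    n_ea: int | None = None
    n_larc: int | None = None
    n_lanc: int | None = None

    def __post_init__(self) -> None:
        if self.n_alpha < 0 or self.n_normal < 0:
            raise ValueError("counts must be non-negative")
        subs = (self.n_ea, self.n_larc, self.n_lanc)
        if any(s is not None for s in subs):
            total = sum(s or 0 for s in subs)
            if total != self.n_alpha:
                raise ValueError("EA + LARC + LANC must equal n_alpha")


@dataclass(frozen=True)
class PofSample:
    """Stereological counts and POF profile areas for one fish."""

    fish_id: str
    points_on_pof: tuple[int, ...]  # per counting field
    pof_profiles: tuple[int, ...]  # per counting field
    pof_areas_mm2: tuple[float, ...] = ()
    n_fields: int = 10
    field_area_mm2: float = 6.0
    grid_points: int = 256
    ow_g: float = 0.0
    bw_g: float = 0.0

    def __post_init__(self) -> None:
        if len(self.points_on_pof) != len(self.pof_profiles):
            raise ValueError("per-field point and profile counts must align")
        if any(p < 0 or p > self.grid_points for p in self.points_on_pof):
            raise ValueError("points per field must lie in [0, grid_points]")
        if any(c < 0 for c in self.pof_profiles):
            raise ValueError("profile counts must be non-negative")
        if any(a <= 0 for a in self.pof_areas_mm2):
            raise ValueError("POF areas must be positive")


@dataclass
class PofMetrics:
    """Derived POF quantities for one fish."""

    fish_id: str = ""
    vv: float = 0.0  # volume fraction, dimensionless
    na_per_mm2: float = 0.0
    nv_per_mm3: float = 0.0
    ovary_volume_cm3: float = 0.0
    f_pof: float = 0.0
    pof_xsa_mm2: float | None = None  # largest POF cross-sectional area
    rf_pof: float | None = None  # F_POF / BW  (g^-1)
    rf_o_pof: float | None = None  # F_POF / (BW - OW)
    recent_spawner_010: bool = False  # POF_XSA > 0.10 mm^2
    recent_spawner_011: bool = False  # POF_XSA > 0.11 mm^2


def atresia_prevalence(samples: Sequence[AtresiaSample]) -> float:
    """Fraction of fish with any alpha-atretic oocytes (0..1)."""
    if len(samples) == 0:
        raise UltrametricError("prevalence undefined for zero fish")
    return sum(s.n_alpha > 0 for s in samples) / len(samples)


def atresia_intensity(n_alpha: int, n_normal: int) -> float:
    """Relative intensity of alpha atresia, n_alpha / (n_alpha + n_normal)."""
    if n_alpha < 0 or n_normal < 0:
        raise ValueError("counts must be non-negative")
    total = n_alpha + n_normal
    if total == 0:
        raise UltrametricError("atresia intensity undefined with no oocytes scored")
    return n_alpha / total


def weibel_pof_number(
    sample: PofSample, config: StereologyConfig | None = None
) -> PofMetrics:
    """Estimate POF number density and total POF number stereologically.

    Fields are pooled before estimation: Vv = sum(points)/(fields*grid) and
    Na = sum(profiles)/(fields*field_area).  Zero hits with nonzero profile
    counts are contradictory and raise :class:`InconsistentCountsError`; zero
    everywhere legitimately means no POFs (F_POF = 0).
    """
    cfg = config or StereologyConfig()
    n_fields = len(sample.points_on_pof)
    if n_fields == 0:
        raise UltrametricError("at least one counting field is required")
    vv = sum(sample.points_on_pof) / (n_fields * sample.grid_points)
    na = sum(sample.pof_profiles) / (n_fields * sample.field_area_mm2)
    if vv == 0 and na > 0:
        raise InconsistentCountsError(
            "POF profiles counted but no grid points hit any POF"
        )
    nv = (cfg.k_size / cfg.beta) * na**1.5 / vv**0.5 if vv > 0 else 0.0
    volume_cm3 = sample.ow_g / cfg.specific_gravity_g_per_cm3 if sample.ow_g else 0.0
    f_pof = nv * volume_cm3 * 1e3  # cm^3 -> mm^3
    return PofMetrics(
        fish_id=sample.fish_id,
        vv=vv,
        na_per_mm2=na,
        nv_per_mm3=nv,
        ovary_volume_cm3=volume_cm3,
        f_pof=f_pof,
    )


def ovary_volume_cm3(ow_g: float, config: StereologyConfig | None = None) -> float:
    """Ovary volume from weight at the configured specific gravity."""
    cfg = config or StereologyConfig()
    if ow_g < 0:
        raise ValueError("ovary weight must be non-negative")
    return ow_g / cfg.specific_gravity_g_per_cm3


def pof_size_metrics(
    sample: PofSample,
    bw_g: float,
    ow_g: float,
    f_pof: float,
    metrics: PofMetrics | None = None,
) -> PofMetrics:
    """POF size and relative-fecundity metrics for one fish.

    ``pof_xsa`` is the cross-sectional area of the largest POF (assumed
    equatorially transected); the recent-spawner flags use strict >
    comparisons against the 0.10 / 0.11 mm^2 size thresholds.  Relative POF
    fecundities normalise F_POF by whole body weight (``rf_pof``) and by
    ovary-free body weight (``rf_o_pof``).
    """
    if bw_g <= ow_g:
        raise BiometryError(f"body weight {bw_g} g must exceed ovary weight {ow_g} g")
    if ow_g < 0:
        raise BiometryError("ovary weight must be non-negative")
    m = metrics or PofMetrics(fish_id=sample.fish_id)
    m.f_pof = f_pof
    if sample.pof_areas_mm2:
        m.pof_xsa_mm2 = max(sample.pof_areas_mm2)
        m.recent_spawner_010 = m.pof_xsa_mm2 > 0.10
        m.recent_spawner_011 = m.pof_xsa_mm2 > 0.11
    else:
        m.pof_xsa_mm2 = None
        m.recent_spawner_010 = False
        m.recent_spawner_011 = False
    m.rf_pof = f_pof / bw_g
    m.rf_o_pof = f_pof / (bw_g - ow_g)
    return m


def compute_pof_metrics(
    sample: PofSample, config: StereologyConfig | None = None
) -> PofMetrics:
    """Full per-fish POF workup: Weibel number estimate plus size metrics."""
    m = weibel_pof_number(sample, config)
    return pof_size_metrics(sample, sample.bw_g, sample.ow_g, m.f_pof, metrics=m)
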