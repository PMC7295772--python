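"""Oocyte ratio (OR) computation and spawning-stage classification (ORC).

In serial-spawning determinate species the previtellogenic (PVO) pool stays
roughly constant through the spawning season while the vitellogenic pool is
released batch by batch, so the ratio of PVOs to developing oocytes

    OR = n(PVO, <250 um) / n(VO+FOM, 250-1200 um)

increases monotonically as a female spawns out.  Oocytes above 1200 µm are
free hydrated/ovulated eggs whose sampled proportion is unreliable, so they
are excluded from the ratio.  OR is banded into four oocyte ratio categories
(ORC): pre/early (OR <= 1), mid (1 < OR <= 3), late (3 < OR <= 15) and very
late/post spawning (OR > 15).  A fish with no developing oocytes at all gets
denominator 1 so its (very large) OR is still defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ClassBounds
from .errors import CalibrationUnavailableError, NoCountableOocytesError

_DEFAULT_BOUNDS = ClassBounds()


@dataclass(frozen=True)
class UltrametricResult:
    """Counts, oocyte ratio and stage category for one fish."""

    fish_id: str
    n_pvo: int
    n_dev: int
    n_hydrated: int
    or_value: float
    orc: int | None = None
    zero_denominator_used: bool = False
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class PvoFecundity:
    """Estimated number of previtellogenic oocytes in the whole ovary.

    ``f_pvo = ow_g * or_value * opd_vo_per_g`` where ``opd_vo_per_g`` is the
    vitellogenic oocyte packing density (oocytes per gram of ovary).
    """

    ow_g: float
    or_value: float
    opd_vo_per_g: float
    f_pvo: float


def oocyte_ratio(
    diameters_um: Sequence[float],
    bounds: ClassBounds | None = None,
    fish_id: str = "",
    qc_flags: Sequence[str] = (),
) -> UltrametricResult:
    """Count oocytes into the staging windows and compute the oocyte ratio.

    Diameters must already have passed detection filtering (i.e. lie within
    the countable range).  Hydrated eggs (> upper developing limit) are
    tallied but excluded from the ratio.  Raises
    :class:`NoCountableOocytesError` when both counting windows are empty.
    """
    b = bounds or _DEFAULT_BOUNDS
    d = np.asarray(diameters_um, dtype=float)
    if d.size and (d.min() < b.pvo_min_um or d.max() > b.max_diameter_um):
        raise ValueError(
            f"diameters outside the countable range "
            f"[{b.pvo_min_um}, {b.max_diameter_um}] um; filter detections first"
        )
    n_pvo = int(np.count_nonzero((d >= b.pvo_min_um) & (d < b.dev_min_um)))
    n_dev = int(np.count_nonzero((d >= b.dev_min_um) & (d <= b.dev_max_um)))
    n_hyd = int(np.count_nonzero(d > b.dev_max_um))
    if n_pvo == 0 and n_dev == 0:
        raise NoCountableOocytesError(
            f"fish {fish_id!r}: no oocytes in either counting window"
        )
    zero_denom = n_dev == 0
    denom = b.zero_denominator_substitute if zero_denom else n_dev
    return UltrametricResult(
        fish_id=fish_id,
        n_pvo=n_pvo,
        n_dev=n_dev,
        n_hydrated=n_hyd,
        or_value=n_pvo / denom,
        zero_denominator_used=zero_denom,
        qc_flags=tuple(qc_flags),
    )


def classify_orc(or_value: float, bounds: ClassBounds | None = None) -> int:
    """Assign the oocyte ratio category (1-4) for an oocyte ratio.

    Category breaks are upper-inclusive: OR <= 1 -> 1, 1 < OR <= 3 -> 2,
    3 < OR <= 15 -> 3, OR > 15 -> 4.  Classification uses the unrounded OR.
    """
    b = bounds or _DEFAULT_BOUNDS
    if not np.isfinite(or_value) or or_value <= 0:
        raise ValueError(f"oocyte ratio must be positive and finite, got {or_value}")
    return 1 + sum(or_value > brk for brk in b.orc_breaks)


def stage_fish(
    diameters_um: Sequence[float],
    bounds: ClassBounds | None = None,
    fish_id: str = "",
    qc_flags: Sequence[str] = (),
) -> UltrametricResult:
    """Convenience: oocyte_ratio followed by ORC assignment."""
    res = oocyte_ratio(diameters_um, bounds, fish_id=fish_id, qc_flags=qc_flags)
    from dataclasses import replace

    return replace(res, orc=classify_orc(res.or_value, bounds))


def pvo_fecundity(
    or_value: float,
    ow_g: float,
    opd_vo_per_g: float | None = None,
    *,
    opd_alpha: float | None = None,
    opd_gamma: float | None = None,
    mean_vo_diameter_um: float | None = None,
) -> PvoFecundity:
    """Estimate total PVO number from ovary weight, OR and packing density.

    The packing density may be given directly (``opd_vo_per_g``, oocytes per
    gram) or through a user-supplied power-law calibration
    ``opd = opd_alpha * mean_vo_diameter_um ** opd_gamma``.  There is no
    built-in default: the calibration is stock- and method-specific, so a
    missing one raises :class:`CalibrationUnavailableError` rather than
    silently assuming a value.
    """
    if ow_g <= 0:
        raise ValueError("ovary weight must be positive")
    if or_value <= 0:
        raise ValueError("oocyte ratio must be positive")
    if opd_vo_per_g is None:
        if opd_alpha is None or opd_gamma is None or mean_vo_diameter_um is None:
            raise CalibrationUnavailableError(
                "no packing-density calibration: supply opd_vo_per_g or "
                "(opd_alpha, opd_gamma, mean_vo_diameter_um)"
            )
        opd_vo_per_g = opd_alpha * mean_vo_diameter_um**opd_gamma
    if opd_vo_per_g <= 0:
        raise ValueError("packing density must be positive")
    return PvoFecundity(
        ow_g=ow_g,
        or_value=or_value,
        opd_vo_per_g=opd_vo_per_g,
        f_pvo=ow_g * or_value * opd_vo_per_g,
    )
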