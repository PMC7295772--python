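"""Allometric length-weight fitting and condition/gonadosomatic indices.

Weight scales with length as W = a * TL**b.  The exponent is estimated by
ordinary least squares on log-transformed data; when it departs from 3, the
classical cube-law Fulton index K = 100 * BW / TL**3 confounds condition with
length, so the relative somatic condition C_SW = SW_obs / SW_exp (with
SW = BW - OW, the ovary-free somatic weight) is the preferred index during
spawning.  The gonadosomatic index is computed against length rather than the
(spawning-variable) body weight: GSI = OW / TL**b * 1e4.

The default somatic-weight calibration (a = e^-5.82, b = 3.23, R^2 = 0.91,
n = 72) is for prespawning-season Northeast Arctic cod females; the exponent
is stock-specific and should be refit for other stocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AllometricFit:
    """OLS fit of ln(weight) on ln(length)."""

    log_intercept: float  # ln a
    exponent: float  # b
    r2: float
    ci_half_width: float  # half-width of the 95% CI on the exponent
    n: int

    @property
    def exponent_ci(self) -> tuple[float, float]:
        return (self.exponent - self.ci_half_width, self.exponent + self.ci_half_width)


#: Somatic-weight calibration for Northeast Arctic cod females (n = 72).
DEFAULT_SOMATIC_FIT = AllometricFit(
    log_intercept=-5.82, exponent=3.23, r2=0.91, ci_half_width=0.22, n=72
)

#: Default length exponent for the gonadosomatic index (matches the somatic fit).
DEFAULT_GSI_EXPONENT = 3.23


@dataclass(frozen=True)
class FishRecord:
    """Biometry for one female: total length (cm), body and ovary weight (g)."""

    fish_id: str
    tl_cm: float
    bw_g: float
    ow_g: float

    def __post_init__(self) -> None:
        if self.tl_cm <= 0:
            raise ValueError("total length must be positive")
        if not self.bw_g > self.ow_g >= 0:
            raise ValueError("require body weight > ovary weight >= 0")

    @property
    def sw_g(self) -> float:
        """Somatic (ovary-free) weight."""
        return self.bw_g - self.ow_g


def fit_allometry(
    lengths_cm: Sequence[float], weights_g: Sequence[float]
) -> AllometricFit:
    """Fit W = a * TL**b by OLS on the log-log scale.

    The confidence half-width is ``t_{0.975, n-2} * SE(slope)``.
    """
    tl = np.asarray(lengths_cm, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if tl.size != w.size or tl.size < 3:
        raise ValueError("need at least 3 matched (length, weight) pairs")
    if np.any(tl <= 0) or np.any(w <= 0):
        raise ValueError("lengths and weights must be positive")
    res = sps.linregress(np.log(tl), np.log(w))
    n = tl.size
    tcrit = sps.t.ppf(0.975, n - 2)
    return AllometricFit(
        log_intercept=float(res.intercept),
        exponent=float(res.slope),
        r2=float(res.rvalue**2),
        ci_half_width=float(tcrit * res.stderr) if np.isfinite(res.stderr) else 0.0,
        n=int(n),
    )


def expected_sw(tl_cm: float, fit: AllometricFit | None = None) -> float:
    """Expected somatic weight (g) at a given total length, a * TL**b."""
    f = fit or DEFAULT_SOMATIC_FIT
    if tl_cm <= 0:
        raise ValueError("total length must be positive")
    return math.exp(f.log_intercept + f.exponent * math.log(tl_cm))


def condition_indices(
    record: FishRecord, fit: AllometricFit | None = None
) -> tuple[float, float, float]:
    """Relative somatic condition and Fulton-style indices.

    Returns ``(c_sw, k_fulton, k_sw)``:

    * ``c_sw = SW_observed / SW_expected`` (1 = exactly as expected);
    * ``k_fulton = 100 * BW / TL**3``;
    * ``k_sw = 100 * (BW - OW) / TL**3``.
    """
    c_sw = record.sw_g / expected_sw(record.tl_cm, fit)
    k_fulton = 100.0 * record.bw_g / record.tl_cm**3
    k_sw = 100.0 * record.sw_g / record.tl_cm**3
    return c_sw, k_fulton, k_sw


def gsi(ow_g: float, tl_cm: float, exponent: float = DEFAULT_GSI_EXPONENT) -> float:
    """Gonadosomatic index, OW / TL**exponent * 1e4.

    The exponent is stock-specific (default 3.23); reuse across stocks may
    require refitting the length-weight relation.
    """
    if ow_g < 0:
        raise ValueError("ovary weight must be non-negative")
    if tl_cm <= 0:
        raise ValueError("total length must be positive")
    return ow_g / tl_cm**exponent * 1e4


def annotate_fish(record: FishRecord, fit: AllometricFit | None = None) -> dict:
    """All derived per-fish metrics as a flat dict (for CSV reporting)."""
    c_sw, k, k_sw = condition_indices(record, fit)
    return {
        "fish_id": record.fish_id,
        "tl_cm": record.tl_cm,
        "bw_g": record.bw_g,
        "ow_g": record.ow_g,
        "sw_g": record.sw_g,
        "c_sw": c_sw,
        "k_fulton": k,
        "k_sw": k_sw,
        "gsi": gsi(record.ow_g, record.tl_cm),
    }
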