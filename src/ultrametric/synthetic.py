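"""Ground-truthed synthetic data: micrographs and simulated spawning cohorts.

Two generators make every pipeline stage testable without any real data:

* A cohort simulator drawing oocyte diameters from truncated-normal
  components — a stable previtellogenic (PVO) pool, vitellogenic/maturation
  components that deplete as spawning progresses, and an optional hydrated
  component above 1200 µm.  Ground truth (class labels, true oocyte ratio,
  intended category) is recorded alongside the draws.

* A micrograph renderer placing anti-aliased dark ellipses (axis ratio
  0.85-1.0) on a light background without overlap, optionally with concave
  debris, returning the image together with per-object ground truth.

``simulate_study`` composes both with biometry (capital-breeder energy
drawdown) and histology tables (POF accumulation, early-spawning atresia)
into a full multi-fish study bundle consumable by every other module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.draw import ellipse as draw_ellipse

from .biometry import DEFAULT_SOMATIC_FIT, expected_sw
from .config import ClassBounds
from .detection import Micrograph, OocyteRecord
from .histology import AtresiaSample, PofSample
from .staging import classify_orc, oocyte_ratio

_BOUNDS = ClassBounds()

#: Default cohort geometry (mean µm, SD µm, count) calibrated to spawning
#: whole-mount distributions: tight PVO mass, two developing modes, hydrated
#: eggs well above the 1200 µm exclusion limit.
DEFAULT_PVO = (160.0, 35.0, 300)
DEFAULT_DEV = ((500.0, 60.0, 300), (800.0, 70.0, 300))
DEFAULT_HYDRATED = (1300.0, 80.0, 0)


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one fish's oocyte population."""

    pvo: tuple[float, float, int] = DEFAULT_PVO
    dev_components: tuple[tuple[float, float, int], ...] = DEFAULT_DEV
    hydrated: tuple[float, float, int] = DEFAULT_HYDRATED
    depletion: float = 1.0  # 1 = undepleted, 0 = fully spawned out
    gap_contamination: float = 0.0  # fraction scattered in the hiatus region
    tail_fraction: float = 0.0  # fraction in a long tail above the top cohort
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.depletion <= 1:
            raise ValueError("depletion must lie in [0, 1]")
        means = [self.pvo[0], *(c[0] for c in self.dev_components), self.hydrated[0]]
        if any(a >= b for a, b in zip(means, means[1:])):
            raise ValueError("component means must increase: pvo < dev < hydrated")
        if any(c[2] < 0 for c in (self.pvo, *self.dev_components, self.hydrated)):
            raise ValueError("counts must be non-negative")


@dataclass
class CohortDraw:
    """Realized oocyte population with ground truth."""

    diameters_um: np.ndarray
    labels: np.ndarray  # 'pvo' | 'dev' | 'hydrated' per oocyte (component of origin)
    true_or: float
    intended_orc: int
    zero_denominator_used: bool


@dataclass(frozen=True)
class SceneSpec:
    """Rendering parameters for one synthetic whole-mount micrograph."""

    shape_px: tuple[int, int] = (1280, 1280)
    resolution_px_per_um: float = 0.1803
    background_grey: int = 230
    oocyte_grey_range: tuple[int, int] = (55, 100)  # all below the 111 cut-off
    noise_sd: float = 3.0
    debris_count: int = 0
    debris_axis_ratio: tuple[float, float] = (0.25, 0.55)  # concave/elongated
    axis_ratio_range: tuple[float, float] = (0.85, 1.0)
    allow_overlap: bool = False
    margin_px: int = 3
    placement_attempts: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oocyte_grey_range[1] >= self.background_grey:
            raise ValueError("oocytes must be darker than the background")
        if self.resolution_px_per_um <= 0:
            raise ValueError("resolution must be positive")


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, n: int,
    lo: float = 100.0, hi: float = 1600.0,
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    bounds: ClassBounds | None = None,
    multinomial_n: int | None = None,
) -> CohortDraw:
    """Draw one fish's oocyte diameters with ground-truth staging.

    Developing-component counts are scaled by ``depletion`` (1 = intact pool,
    0 = spawned out).  With ``multinomial_n`` set, a total of that many
    oocytes is drawn with class probabilities proportional to the (scaled)
    component counts — the sampling noise of photographing a fixed number of
    oocytes.  The true OR and intended category are computed from the
    realized diameters with the same windows the classifier uses.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    b = bounds or _BOUNDS
    # each component is truncated to its staging window, so the component of
    # origin and the counting window agree exactly (shared ClassBounds)
    windows = {
        "pvo": (b.pvo_min_um, b.dev_min_um),
        "dev": (b.dev_min_um, b.dev_max_um),
        "hydrated": (b.dev_max_um, b.max_diameter_um),
    }
    comps: list[tuple[float, float, float, str]] = [(*spec.pvo, "pvo")]
    for mean, sd, count in spec.dev_components:
        comps.append((mean, sd, count * spec.depletion, "dev"))
    comps.append((*spec.hydrated, "hydrated"))

    weights = np.array([c[2] for c in comps], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("spec yields zero oocytes")
    if multinomial_n is not None:
        counts = rng.multinomial(multinomial_n, weights / weights.sum())
    else:
        counts = np.round(weights).astype(int)

    parts, labels = [], []
    extra_parts = []
    for (mean, sd, _, lab), n in zip(comps, counts):
        if n == 0:
            continue
        n_main = n
        if lab == "pvo" and spec.gap_contamination > 0:
            n_gap = rng.binomial(n, spec.gap_contamination)
            n_main = n - n_gap
            if n_gap:
                lo_dev = spec.dev_components[0][0] if spec.dev_components else b.dev_max_um
                extra_parts.append(
                    (rng.uniform(b.dev_min_um, lo_dev, size=n_gap), "dev")
                )
        if lab == "dev" and spec.tail_fraction > 0:
            n_tail = rng.binomial(n_main, spec.tail_fraction)
            n_main = n_main - n_tail
            if n_tail:
                extra_parts.append(
                    (rng.uniform(mean + 2 * sd, b.dev_max_um, size=n_tail), "dev")
                )
        lo_w, hi_w = windows[lab]
        d = _truncnorm(rng, mean, sd, n_main, lo=lo_w, hi=hi_w)
        parts.append(d)
        labels.append(np.full(n_main, lab, dtype=object))
    for d, lab in extra_parts:
        parts.append(d)
        labels.append(np.full(d.size, lab, dtype=object))

    diameters = np.concatenate(parts)
    lab_arr = np.concatenate(labels)
    order = rng.permutation(diameters.size)
    diameters, lab_arr = diameters[order], lab_arr[order]

    res = oocyte_ratio(diameters, b)
    return CohortDraw(
        diameters_um=diameters,
        labels=lab_arr,
        true_or=res.or_value,
        intended_orc=classify_orc(res.or_value, b),
        zero_denominator_used=res.zero_denominator_used,
    )


def _place_objects(
    rng: np.random.Generator,
    radii_px: Sequence[float],
    shape: tuple[int, int],
    margin: int,
    attempts: int,
    allow_overlap: bool,
) -> list[tuple[float, float] | None]:
    """Dart-throwing placement; None where an object could not be placed."""
    placed: list[tuple[float, float, float]] = []
    centres: list[tuple[float, float] | None] = []
    for r in radii_px:
        ok = None
        lo_r, hi_r = r + margin, shape[0] - r - margin
        lo_c, hi_c = r + margin, shape[1] - r - margin
        if hi_r <= lo_r or hi_c <= lo_c:
            centres.append(None)  # object larger than the field
            continue
        for _ in range(attempts):
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            if allow_overlap or all(
                (cr - pr) ** 2 + (cc - pc) ** 2 > (r + p_rad + 2) ** 2
                for pr, pc, p_rad in placed
            ):
                ok = (cr, cc)
                placed.append((cr, cc, r))
                break
        centres.append(ok)
    return centres


def render_micrograph(
    diameters_um: Sequence[float],
    scene: SceneSpec | None = None,
    rng: np.random.Generator | None = None,
    micrograph_id: str = "m0",
) -> tuple[Micrograph, list[OocyteRecord], np.ndarray]:
    """Render one micrograph of dark elliptical oocytes on a light background.

    Oocytes are placed largest-first by dart throwing (capped attempts);
    diameters that do not fit are returned as leftovers to be carried to the
    next image.  Ground truth records hold the drawn continuous axes and
    positions.  Debris is rendered as strongly elongated dark objects whose
    roundness is below the oocyte acceptance window by construction.
    """
    scene = scene or SceneSpec()
    rng = rng if rng is not None else np.random.default_rng(scene.seed)
    res = scene.resolution_px_per_um
    d = np.asarray(diameters_um, dtype=float)
    order = np.argsort(d)[::-1]  # place big ones first

    # circumscribing radius in px for placement (major semi-axis + margin)
    ratios = rng.uniform(*scene.axis_ratio_range, size=d.size)
    majors_um = d / np.sqrt(ratios)
    minors_um = d * np.sqrt(ratios)
    radii_px = majors_um[order] * res / 2

    debris_sizes = rng.uniform(150, 500, size=scene.debris_count)
    debris_ratio = rng.uniform(*scene.debris_axis_ratio, size=scene.debris_count)
    debris_radii = (debris_sizes / np.sqrt(debris_ratio)) * res / 2

    centres = _place_objects(
        rng,
        list(radii_px) + list(debris_radii),
        scene.shape_px,
        scene.margin_px,
        scene.placement_attempts,
        scene.allow_overlap,
    )

    img = np.full(scene.shape_px, float(scene.background_grey))
    records: list[OocyteRecord] = []
    leftover = []
    for k, idx in enumerate(order):
        centre = centres[k]
        if centre is None:
            leftover.append(d[idx])
            continue
        grey = rng.integers(*scene.oocyte_grey_range)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(
            centre[0],
            centre[1],
            majors_um[idx] * res / 2,
            minors_um[idx] * res / 2,
            shape=scene.shape_px,
            rotation=rot,
        )
        img[rr, cc] = grey
        records.append(
            OocyteRecord(
                diameter_um=float(d[idx]),
                major_um=float(majors_um[idx]),
                minor_um=float(minors_um[idx]),
                area_um2=float(np.pi * majors_um[idx] * minors_um[idx] / 4),
                roundness=float(ratios[idx]),
                ellipticity=1.0,
                mean_grey=float(grey),
                centroid=centre,
            )
        )
    for k in range(scene.debris_count):
        centre = centres[len(order) + k]
        if centre is None:
            continue
        grey = rng.integers(*scene.oocyte_grey_range)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(
            centre[0],
            centre[1],
            (debris_sizes[k] / np.sqrt(debris_ratio[k])) * res / 2,
            (debris_sizes[k] * np.sqrt(debris_ratio[k])) * res / 2,
            shape=scene.shape_px,
            rotation=rot,
        )
        img[rr, cc] = grey

    if scene.noise_sd > 0:
        img = img + rng.normal(0, scene.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    micro = Micrograph(pixels=img, resolution_px_per_um=res, id=micrograph_id)
    return micro, records, np.asarray(leftover)


def render_fish(
    diameters_um: Sequence[float],
    scene: SceneSpec | None = None,
    rng: np.random.Generator | None = None,
    fish_id: str = "fish",
    max_micrographs: int = 10,
) -> list[tuple[Micrograph, list[OocyteRecord]]]:
    """Render a fish's oocytes across as many micrographs as needed."""
    scene = scene or SceneSpec()
    rng = rng if rng is not None else np.random.default_rng(scene.seed)
    remaining = np.asarray(diameters_um, dtype=float)
    out = []
    for i in range(max_micrographs):
        micro, truth, leftover = render_micrograph(
            remaining, scene, rng, micrograph_id=f"{fish_id}_m{i}"
        )
        out.append((micro, truth))
        if leftover.size == 0 or leftover.size == remaining.size:
            break
        remaining = leftover
    return out


# --- full-study simulation -------------------------------------------------

#: Per-category study conditions: target OR mid-values, hydrated-egg counts,
#: median GSI, median relative somatic condition, POF number density (mm^-3)
#: and POF section-area scale (mm^2) — chosen as realistic for a spawning
#: capital breeder: GSI and condition fall while POFs accumulate with stage.
STAGE_TARGET_OR = {1: 0.5, 2: 2.0, 3: 8.0, 4: 30.0}
STAGE_HYDRATED = {1: 0, 2: 15, 3: 10, 4: 5}
STAGE_GSI = {1: 8.0, 2: 5.0, 3: 3.0, 4: 1.5}
STAGE_CSW = {1: 1.05, 2: 0.98, 3: 0.94, 4: 0.91}
STAGE_POF_NV = {1: 0.05, 2: 0.4, 3: 0.8, 4: 1.0}
STAGE_ATRESIA_P = {1: 0.20, 2: 0.04, 3: 0.0, 4: 0.0}


@dataclass
class StudyFish:
    """One simulated fish: truth, oocytes, biometry and histology tables."""

    fish_id: str
    intended_orc: int
    depletion: float
    cohort: CohortDraw
    biometry: "pd.Series"
    atresia: AtresiaSample
    pof: PofSample


@dataclass
class StudyData:
    fish: list[StudyFish]

    @property
    def biometry_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.biometry for f in self.fish]).reset_index(drop=True)

    @property
    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": [f.fish_id for f in self.fish],
                "intended_orc": [f.intended_orc for f in self.fish],
                "true_or": [f.cohort.true_or for f in self.fish],
            }
        )


def _fish_cohort_spec(target_or: float, orc: int, seed: int) -> CohortSpec:
    """Scale the default cohort geometry to hit a target oocyte ratio."""
    pvo_n = DEFAULT_PVO[2]
    dev_total = pvo_n / target_or
    base_total = sum(c[2] for c in DEFAULT_DEV)
    depletion = min(1.0, dev_total / base_total)
    # late stages keep a single developing cohort
    dev = DEFAULT_DEV if orc <= 2 else (DEFAULT_DEV[1],)
    if orc > 2:
        depletion = min(1.0, dev_total / DEFAULT_DEV[1][2])
    hyd = (DEFAULT_HYDRATED[0], DEFAULT_HYDRATED[1], STAGE_HYDRATED[orc])
    return CohortSpec(
        pvo=DEFAULT_PVO, dev_components=dev, hydrated=hyd,
        depletion=depletion, seed=seed,
    )


def simulate_study(
    n_fish: int = 72,
    seed: int = 0,
    oocytes_per_fish: int = 400,
    stage_proportions: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> StudyData:
    """Simulate a full spawning-season study across the four categories.

    Fish are spread over the four intended categories; each fish gets a
    multinomial draw of ``oocytes_per_fish`` oocytes at a depletion level
    targeting its category's mid-interval OR (log-normal jitter keeps fish
    spread within categories), biometry following the somatic length-weight
    calibration with a stage-dependent condition multiplier and GSI, and
    histology tables with stage-dependent POF density and early-stage
    atresia.
    """
    rng = np.random.default_rng(seed)
    stages = np.repeat(
        np.arange(1, 5), np.round(np.asarray(stage_proportions) * n_fish).astype(int)
    )
    stages = stages[:n_fish]
    while stages.size < n_fish:
        stages = np.append(stages, 4)

    fish: list[StudyFish] = []
    for i, orc in enumerate(stages):
        fid = f"F{i + 1:03d}"
        target = STAGE_TARGET_OR[int(orc)] * math.exp(rng.normal(0, 0.15))
        spec = _fish_cohort_spec(target, int(orc), seed=i)
        cohort = simulate_cohort(spec, rng=rng, multinomial_n=oocytes_per_fish)

        tl = float(np.clip(rng.normal(96, 12), 63, 126))
        csw = STAGE_CSW[int(orc)] * math.exp(rng.normal(0, 0.03))
        sw = csw * expected_sw(tl, DEFAULT_SOMATIC_FIT)
        gsi_val = STAGE_GSI[int(orc)] * math.exp(rng.normal(0, 0.25))
        ow = gsi_val / 1e4 * tl**DEFAULT_SOMATIC_FIT.exponent
        bw = sw + ow
        biometry = pd.Series(
            {"fish_id": fid, "tl_cm": tl, "bw_g": bw, "ow_g": ow}
        )

        atretic = rng.random() < STAGE_ATRESIA_P[int(orc)]
        n_scored = int(rng.integers(40, 80))
        n_alpha = int(rng.integers(1, 5)) if atretic else 0
        atresia = AtresiaSample(
            fish_id=fid, n_alpha=n_alpha, n_normal=n_scored - n_alpha
        )

        nv = STAGE_POF_NV[int(orc)] * math.exp(rng.normal(0, 0.2))
        r_pof = 0.18  # POF radius, mm
        na = nv * 2 * r_pof
        vv = nv * 4 / 3 * np.pi * r_pof**3
        n_fields, field_area, grid = 10, 6.0, 256
        profiles = rng.poisson(na * field_area, size=n_fields)
        points = rng.binomial(grid, min(vv, 1.0), size=n_fields)
        n_areas = int(min(profiles.sum(), 15))
        areas = tuple(
            float(a)
            for a in rng.uniform(0.01, np.pi * r_pof**2, size=n_areas)
        )
        pof = PofSample(
            fish_id=fid,
            points_on_pof=tuple(int(p) for p in points),
            pof_profiles=tuple(int(p) for p in profiles),
            pof_areas_mm2=areas,
            n_fields=n_fields,
            field_area_mm2=field_area,
            grid_points=grid,
            ow_g=ow,
            bw_g=bw,
        )
        fish.append(
            StudyFish(
                fish_id=fid,
                intended_orc=int(orc),
                depletion=spec.depletion,
                cohort=cohort,
                biometry=biometry,
                atresia=atresia,
                pof=pof,
            )
        )
    return StudyData(fish=fish)
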