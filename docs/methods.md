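# Methods

This note documents the models and numerical choices behind the package, in
the order the pipeline runs them.

## Oocyte detection in whole-mount micrographs

Stained whole-mounts are high-contrast fields: oocytes are dark, rounded
objects on a light background. Detection is deliberately simple — a global
threshold at the grey-tone cut-off (mean grey < 111 on the 8-bit scale),
hole filling, 8-connected labelling, and removal of border-touching
components — because the grey-tone selection criterion itself implies that a
single intensity threshold separates objects from background. Touching
oocytes are *not* split by watershed in this version: a merged blob is
rejected by the shape filter, which mirrors the manual cleaning step of the
original bench workflow. The cost is a small loss of countable oocytes in
crowded previtellogenic fields; because the oocyte ratio is a ratio of large
counts in wide bands, staging is insensitive to this loss unless a fish sits
exactly on a category break.

Each component is measured through its image-moment fitted ellipse:

- `major, minor` — fitted-ellipse axes (µm, using the supplied px/µm
  resolution; default 0.1803 px/µm);
- `diameter = sqrt(major · minor)` — the equal-area equivalent diameter for
  an elliptical profile, stable for near-circles;
- `roundness = 4·area / (π·major²)` — 1 for a circle, `minor/major` for an
  ellipse;
- `ellipticity = area / (π·major·minor/4)`, capped at 1 — how completely the
  object fills its fitted ellipse; concave debris and fused blobs score low.

The selection filter keeps objects with diameter in [100, 1600] µm
(inclusive), mean grey < 111 (strict), roundness in [0.8, 1.0] and
ellipticity ≥ 0.91. The reference image-analysis macro does not publish its
exact shape formulas, so the two definitions above are documented
substitutes, not claimed identities. The 100 µm floor reflects sample
preparation: oocytes below ≈ 75 µm are lost through the washing mesh, and
100 µm is the conservative counting limit. Per-fish QC flags fire when fewer
than 200 oocytes passed in total or fewer than 3 micrographs were pooled.

Border-touching objects are discarded (their sizes are biased); whether the
original workflow counted them is unknown, and for staging purposes the
choice only removes a thin, size-unbiased margin of the field.

## Size frequency distributions and cohort annotation

The OSFD uses half-open 20 µm bins from the 100 µm floor. The smoothed
profile is a Gaussian KDE on a 1 µm grid over [100, 1600] µm, bandwidth by
Silverman's rule clamped to [10, 40] µm — free bandwidths over-smooth the
narrow PVO mass (SD ≈ 35 µm) when a broad vitellogenic cohort is present,
and under 10 µm the profile follows bin noise. The density is renormalised
to integrate to 1 on the grid.

Cohorts are local maxima of the smoothed density with prominence ≥ 5% of the
global maximum, counted inside the developing window [250, 1200] µm. The
qualitative phenotype flags have no published numeric criteria (they were
read off plots), so they are defined here by calibrated, configurable rules:

- **bimodal VO** — two adjacent developing modes whose connecting valley
  falls below 0.5 × the lower peak;
- **budding peak** — the upper of ≥ 2 developing modes lies in [850, 1200]
  µm, the window where oocytes leave the main cohort at hydration onset
  (≈ 875 µm — drawn on plots as a dashed marker, never used in
  classification);
- **long tail** — more than 5% of developing oocytes lie over two
  cohort-SDs above the largest mode (cohort SD from the peak's full width at
  half maximum);
- **hiatus** — walking up from the PVO mode, the lower gap limit is where
  density first falls below 5% of the PVO peak; the upper limit is the
  mirror-image crossing below the smallest developing mode. Placement is
  flagged *ambiguous* when the mean density inside the candidate gap exceeds
  10% of the PVO peak (or when no crossing exists at all): this reproduces
  the situation where oocytes occupying the gap make any manual limit
  subjective. In the simulator, scattering ~15% of the PVO count into the
  gap reproduces a minority-of-fish ambiguity rate of the magnitude seen in
  practice.

## Oocyte ratio and staging

Counting windows: PVO `[100, 250)` µm (half-open), developing `[250, 1200]`
µm (closed), hydrated `> 1200` µm excluded from the ratio because the
sampled proportion of free eggs is method-dependent. The 250 µm split is the
established primary-growth boundary for this stock; a 200 µm variant exists
as a config option (it separated stages less cleanly and is not the
default). Category breaks (1, 3, 15) are upper-inclusive and classification
always uses the unrounded OR; no hysteresis is applied near breaks. A fish
with an empty developing window gets denominator 1 (`zero_denominator_used`
is set), keeping OR defined and the fish in category 4 whenever it has a
normal PVO complement.

PVO fecundity is `F_PVO = OW × OR × OPD_VO` with the vitellogenic packing
density `OPD_VO` (oocytes g⁻¹) supplied by the user, either directly or as a
power law in mean VO diameter. There is deliberately no default calibration:
packing density is stock- and preparation-specific, and a silent default
would produce plausible-looking nonsense.

## Histology metrics

Atresia prevalence is the fraction of fish with any α-atretic oocytes;
intensity is `Iα = N_i / (N_i + N_j)` per fish. Both are consumed from
human-scored tables — automated atresia recognition is out of scope.

POF number uses Weibel point-count stereology with the Weibel–Gómez number
estimator: with a 256-point grid over ten 6 mm² fields (all pooled before
estimation), `Vv = Σpoints/(fields·grid)`, `Na = Σprofiles/(fields·area)`,
and `Nv = (k/β) · Na^{3/2} / Vv^{1/2}`. The shape coefficient β = 1.38 is
the spherical value (2^{3/2}/√(4π/3) ≈ 1.382), k = 1 assumes a narrow size
distribution; both are configurable since the exact variant used on any
given dataset may differ. Ovary volume is weight / 1.0464 g cm⁻³, and
`F_POF = Nv × volume`. The test suite validates the estimator against a
brute-force oracle that places Poisson spheres in 3-D and sections them with
a plane; with β at its spherical value the estimator is essentially unbiased
(single-sample scatter at the default grid is ± ~20%, dominated by the
profile count, so the recovery check averages 100 seeded samples).

POF size metrics: `POF_XSA` is the cross-sectional area of the largest POF
(assumed equatorially transected — a caveat, not a model), recent-spawner
flags use strict `>` against 0.10 and 0.11 mm²; `RF_POF = F_POF/BW` and
`RF-O_POF = F_POF/(BW−OW)` normalise by whole and ovary-free body weight.

## Biometry

Length–weight fits are OLS on `ln W ~ ln TL`; the 95% interval on the
exponent is reported as a half-width (`t_{0.975,n−2}·SE`), so a fit with
b = 3.42 and half-width 0.30 has lower limit 3.12. The default somatic
calibration `SW = e^{−5.82}·TL^{3.23}` (R² = 0.91, n = 72) is for Northeast
Arctic cod females and should be refit for other stocks. Condition is
reported three ways — `C_SW = SW_obs/SW_exp`, Fulton's `K = 100·BW/TL³`, and
`K_SW = 100·SW/TL³` — because the cube-law K confounds condition with length
when the true exponent is far from 3. GSI uses length rather than the
spawning-variable body weight: `GSI = OW/TL^{3.23} × 10⁴` (exponent
configurable, stock-specific).

## Group statistics

Kruskal–Wallis (tie-corrected, χ² approximation) as omnibus test; pairwise
two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg step-up adjustment
over the k(k−1)/2 family; compact significance letters are the maximal
cliques of the not-significantly-different graph at α = 0.05. The paired
signed-rank test discards zero differences and uses the exact null for ≤ 25
untied differences, a normal approximation otherwise; two-sided alternatives
are the default throughout (one-sided is available for the paired test).
Under a simulated 4-group global null (n = 18 per group) the full
KW-gate + BH procedure keeps the family-wise error near 3–4%, below the
nominal 5%.

## Synthetic data: what it emulates, and what it does not

The cohort simulator draws diameters from truncated-normal components, each
confined to its staging window so component-of-origin and counting window
agree exactly: PVO 160 ± 35 µm, developing modes 500 ± 60 and 800 ± 70 µm
(300 + 300 oocytes undepleted against 300 PVOs, so an intact fish has
OR ≈ 0.5), hydrated 1300 ± 80 µm. Spawning is modelled by a depletion factor
scaling the developing counts; late-stage fish keep a single developing
cohort. Optional knobs scatter oocytes into the hiatus (gap contamination)
or add a uniform long tail. Sampling a fixed number of photographed oocytes
is modelled as a multinomial draw (default 400 per fish — comfortably above
the 200-oocyte QC floor, as three micrographs typically are).

The renderer places anti-aliased dark ellipses (axis ratio 0.85–1.0, grey
55–100 on a 230 background, Gaussian pixel noise) by dart-throwing without
overlap (500 attempts, oversized/unplaced diameters carry to the next
image); debris is rendered as strongly elongated dark objects whose
roundness is below 0.8 by construction. The full-study generator assigns
fish evenly to the four categories at mid-interval OR targets
{0.5, 2, 8, 30} with log-normal jitter, biometry from the somatic
calibration with stage-declining condition (≈ 1.05 → 0.91) and GSI
(≈ 8 → 1.5), POF density rising with stage, and atresia concentrated in
early-stage fish at a realistic overall prevalence.

What the synthetic data does **not** emulate: staining texture and uneven
illumination, partially separated or overlapping oocyte clumps (the default
scene is non-overlapping), out-of-focus blur, and real biological covariance
between condition, fecundity and stage. Passing tests therefore demonstrate
that the measurement and classification chain is correct and unbiased under
controlled conditions — not that segmentation is robust to every real
micrograph. On real data the manual-cleaning/QC path (rejected records with
reasons, QC flags) is the guard rail.

## Problem sizes used in the test suite

Simulation-backed checks run at: 20 seeds × 4 fish × 400 oocytes for
end-to-end category recovery (≥ 95% required); 6 scenes × 150 oocytes with
5 debris objects for detection fidelity (recall/precision ≥ 0.95, mean
diameter error ≤ 2%); 100 seeded sphere-sectioning samples for the
stereology oracle (mean recovery within 15%); 2000 replicates for the
family-wise error bound (≤ 0.07); 200 replicates for category recovery from
multinomial noise. These sizes were chosen so each property is measured well
inside its tolerance while the whole suite stays quick to run.

## Known limitations

- No watershed splitting: heavily crowded PVO fields undercount; the ratio
  is robust but extreme crowding can bias OR downward.
- Phenotype flags (bimodality, tail, hiatus ambiguity) are calibrated to the
  simulator's geometry; on a new stock the fractions deserve re-inspection.
- The Weibel β/k defaults assume near-spherical, narrowly distributed POFs.
- The GSI/condition defaults embed one stock's allometry; reuse across
  stocks without refitting will mis-scale expected weights.
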