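# ultrametric

Whole-mount oocyte analysis and spawning staging for serial-spawning,
determinate fish (developed on Northeast Arctic cod, *Gadus morhua*).

Assessing how far a female has progressed through the spawning season from a
single ovarian sample is hard: hiatus-based readings are subjective for many
fish, and mean/SD/skewness tracking of the vitellogenic cohort breaks down
once oocytes start hydrating. The *ultrametric* approach sidesteps both
problems by counting ultra-small oocytes too. After ultrasonication and
staining, whole-mount micrographs are measured automatically and each fish is
summarised by the **oocyte ratio**

```
OR = Σ PVO / Σ (VO + FOM)
```

the number of previtellogenic oocytes (< 250 µm) divided by the number of
developing oocytes (250–1200 µm; free hydrated eggs > 1200 µm are excluded).
Because the PVO pool is stable while the vitellogenic pool is spawned out
batch by batch, OR increases through the season and maps onto four **oocyte
ratio categories**:

| ORC | OR range      | stage                      |
|-----|---------------|----------------------------|
| 1   | OR ≤ 1        | pre-/early-spawning        |
| 2   | 1 < OR ≤ 3    | mid-spawning               |
| 3   | 3 < OR ≤ 15   | late-spawning              |
| 4   | OR > 15       | very late-/post-spawning   |

A fish with no developing oocytes at all gets denominator 1 so its (very
large) OR is still defined.

The package covers the full workflow:

- **detection** — threshold segmentation of dark oocytes in 8-bit
  whole-mounts, fitted-ellipse measurement, and the selection filter
  (size 100–1600 µm, grey tone < 111, roundness 0.8–1.0, ellipticity ≥ 0.91)
  with per-fish QC (≥ 200 oocytes over ≥ 3 micrographs);
- **osfd** — oocyte size frequency distributions: 20 µm binning, Gaussian-KDE
  smoothing, cohort/mode detection, bimodality, long-tail and hiatus
  annotation;
- **staging** — OR, ORC and PVO-fecundity (`F_PVO = OW × OR × OPD_VO`);
- **histology** — atresia prevalence/intensity (`Iα = N_i / (N_i + N_j)`) and
  Weibel point-count stereology for post-ovulatory follicle numbers
  (`Nv = (k/β) · Na^{3/2} / Vv^{1/2}`), sizes and relative fecundities;
- **biometry** — log–log allometric fits, expected somatic weight
  `SW = a·TL^b`, condition indices (C_SW, Fulton's K, K_SW) and
  `GSI = OW/TL^3.23 × 10⁴`;
- **stats** — Kruskal–Wallis plus BH-adjusted pairwise rank-sum tests with
  compact significance letters, and the exact paired signed-rank test;
- **synthetic** — ground-truthed synthetic micrographs and simulated
  spawning cohorts/studies, so every stage is testable without data
  downloads.

## Worked example

Simulate a mid-spawning fish (vitellogenic pool depleted to 25%), render its
oocytes into whole-mount micrographs, and run the full pipeline:

```python
import numpy as np
from ultrametric import (CohortSpec, SceneSpec, simulate_cohort, render_fish,
                         stage_micrographs)

rng = np.random.default_rng(7)
draw = simulate_cohort(CohortSpec(depletion=0.25), rng=rng, multinomial_n=400)
pages = render_fish(draw.diameters_um, SceneSpec(), rng, fish_id="demo")
res = stage_micrographs([m for m, _ in pages], fish_id="demo")
print(f"true OR = {draw.true_or:.3f} (intended ORC {draw.intended_orc})")
print(f"detected: n_pvo={res.n_pvo}, n_dev={res.n_dev}")
print(f"OR = {res.or_value:.3f} -> ORC {res.orc}, QC flags: {list(res.qc_flags)}")
```

prints

```
true OR = 1.941 (intended ORC 2)
detected: n_pvo=264, n_dev=136
OR = 1.941 -> ORC 2, QC flags: ['few_micrographs']
```

All 400 simulated oocytes fitted into two rendered micrographs and were
recovered by detection: 264 previtellogenic and 136 developing oocytes give
an oocyte ratio of 1.94, i.e. a mid-spawning fish (ORC 2), exactly matching
the generator's ground truth. The `few_micrographs` flag notes that fewer
than the protocol's three micrographs were used.

The same stages are available from the shell:

```sh
ultrametric simulate --n-fish 72 --seed 1 --out fixtures/
ultrametric report fixtures/ --out report/
ultrametric stats report/fish_metrics.csv --metric gsi
```

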