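# pulsechase

Analysis of in-vivo 6,6-²H₂-glucose pulse-chase labeling of human
eosinophils and basophils, as used in placebo-controlled anti-IL-5
(mepolizumab) trials in eosinophilic asthma.

Patients drink deuterated glucose (12 half-hourly doses, 1 g/kg in total);
cells dividing while labeled glucose is available build ²H into their DNA.
Sorting eosinophils and basophils from blood and induced sputum on later
days and measuring the labeled fraction of DNA by GC-MS turns each cell
population into its own clock: when label first appears in blood gives the
postmitotic transit time, how fast it disappears gives the blood residence,
and how much lower and flatter the sputum curve is tells how long cells
persist in the airways. The package is for quantitative biologists and
trial statisticians who want to run, test or extend this analysis without
access to patient data.

It implements the full chain:

1. **`pulsechase.enrichment`** — raw GC-MS peak-area pairs (DNA adenosine
   m/z 435/437, plasma glucose m/z 328/330) → tracer-to-tracee ratio
   TTR = (m+2)/m → calibration against standards → subtraction of the
   subject's pre-label background → precursor–product normalization
   `net / (b · p̄)`, with `b = 0.65` the de novo/base-salvage fraction and
   `p̄` the subject's mean plasma glucose enrichment. The result estimates
   the fraction of cells whose DNA was synthesized during the labeling
   window.
2. **`pulsechase.conveyor`** — a deterministic first-in-first-out
   ("conveyor belt") forward model: production → shifted-exponential
   postmitotic transit (shift δ₀, tail mean θ) → exponential blood
   residence (half-life t½) → well-mixed airway pool diluted by resident
   unlabeled cells; plus detection-day analysis and bounded least-squares
   parameter fitting.
3. **`pulsechase.synthesis`** — a synthetic two-arm (n = 10 + 10),
   two-phase (label at day 0 and day 84, dosing at days 4/32/60/88) trial
   generator with staggered per-subject sampling, measurement noise, and a
   truth sidecar that the analysis never reads.
4. **`pulsechase.stats`** — the trial statistics: simple linear regressions
   over the uplabeling (day 0–7) and downlabeling (day 8–22) windows
   compared between groups by classical two-line ANCOVA (slope equality,
   then elevation under a common slope), exact Mann-Whitney and Wilcoxon
   signed-rank tests, and day-7-referenced dilution ratios.
5. **`pulsechase.pipeline` / CLI** — `pulsechase simulate | enrich |
   analyze | report`, seed-deterministic, config-driven.

## Worked example

```python
import numpy as np
from pulsechase import (
    EOSINOPHIL_DEFAULTS, LabelAvailability, SimulationGrid,
    simulate_blood_curve, simulate_airway_curve, detection_days,
    normalize_enrichment,
)

grid = SimulationGrid(dt=0.1, horizon=60.0)
label = LabelAvailability(amplitude=0.05)          # p_bar = 5% plasma enrichment
blood = simulate_blood_curve(EOSINOPHIL_DEFAULTS, label, grid)
sputum = simulate_airway_curve(EOSINOPHIL_DEFAULTS, blood, grid)

days = list(range(1, 61))
print("blood  first/last detection:", detection_days(blood, 0.0005, days))
print("sputum first/last detection:", detection_days(sputum, 0.0005, days))
peak = blood.time_grid[np.argmax(blood.enrichment)]
print(f"blood peak: {blood.enrichment.max():.4f} at day {peak:.1f}")
print(f"fraction of cells labeled, day-7 sample, net enrichment 0.013: "
      f"{normalize_enrichment(0.013, 0.04):.3f}")
```

prints

```
blood  first/last detection: (4, 28)
sputum first/last detection: (5, 33)
blood peak: 0.0468 at day 7.1
fraction of cells labeled, day-7 sample, net enrichment 0.013: 0.500
```

Read: with the default eosinophil parameters (transit shift 3.6 d, tail
3.0 d, blood half-life 2.5 d) the first labeled eosinophils reach blood on
day 4 and the label falls below the 0.05% detection threshold after day 28;
at the peak (day ~7) about 4.7% of circulating eosinophils were made during
the labeling window. The airway curve peaks later and roughly five-fold
lower — resident unlabeled sputum cells dilute the arriving labeled ones —
and stays detectable longer than in blood. The last line is the
normalization step itself: a net DNA enrichment of 1.3% with 4% plasma
precursor availability corresponds to 50% newly made cells.

A full synthetic trial runs from the shell:

```sh
pulsechase simulate --seed 3 --out run
pulsechase enrich   --out run
pulsechase analyze  --out run
pulsechase report   --out run       # writes run/report.md
```

`run/results.tsv` then holds the group comparisons (ANCOVA slope and
elevation F/p per phase and window, per-day Mann-Whitney count tests,
paired blood-vs-sputum signed-rank tests); under the default treatment
scenario the phase-1 downlabeling of the mepolizumab arm is visibly
shallower while phase-2 kinetics match placebo.

## Layout

```
src/pulsechase/     enrichment, conveyor, synthesis, stats, pipeline, cli
src/pulsechase/data/default_params.yaml   packaged kinetic parameter sets
tests/              unit, property and acceptance suites
docs/methods.md     model description, assumptions, limitations
```
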