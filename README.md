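# mamsleep

Quantification pipelines for the cell-biological signature of sleep
loss: contact sites between the endoplasmic reticulum (ER) and
mitochondria in electron-microscopy segmentations, Drosophila sleep
architecture from activity-monitor counts, and differential expression
of organelle gene sets — each with a seeded synthetic-data generator
carrying planted ground truth, so every estimator can be validated by
parameter recovery.

## Who this is for

Sleep loss stresses neurons: the ER expands, ER–mitochondria contact
sites (mitochondria-associated membranes, MAMs) multiply, and organelle
gene programs shift. Measuring those changes means scoring thousands of
membrane appositions in 2-D EM sections, thousands of fly-nights of
1-min activity bins, and array-scale expression contrasts. This package
implements those measurements as tested, reusable library code plus
narrative analysis drivers.

## The measurements

**Contact sites.** Two membranes form a contact where a stretch of one
boundary lies strictly closer than 20 nm to the other. The reference
boundary is resampled at 2-nm arc steps, apposed runs are merged across
gaps < 30 nm and reported with their arc length and min/mean separation.
Kinds: MAM (ER vs mitochondrion), PAM (ER vs plasma membrane),
mito–plasma-membrane, and mito–mito (per touching pair). Per-cell
morphometry adds ER density (count per cytoplasmic area, nucleus
excluded), ER area fraction, compactness (perimeter/area, nm⁻¹),
mitochondrial density and size.

**Sleep.** Sleep is ≥ 5 consecutive minutes with zero activity counts.
Per fly and day: totals and bout structure for 24 h and the light/dark
halves, stability (max wake bout − max sleep bout), latency from
lights-off, 4-day baseline averages, dead-fly filtering, and the rebound
in total sleep after a 12-h enforced-wake night.

**Expression.** Welch's t per probe on log2 values, Benjamini–Hochberg
FDR across probes, probe→gene collapse by minimum raw p, linear fold
change from the log2 group means; genes with |FC| > 30 % at adjusted
p < 0.01 are called up/down and intersected with ER and mitochondrial
gene lists. Western-blot densitometry is normalized by the
total-protein rule (lane factor = lane Ponceau / max Ponceau).

## Worked example

```python
from dataclasses import replace
from mamsleep.synthetic import CellGenParams, synth_cells
from mamsleep.morphometry import cell_record, records_to_frame
from mamsleep.stats import percent_change

base = CellGenParams(n_cells=50, group="S", seed=7)           # sleep-like
sd = replace(base, group="SD", effect_mam=1.478)              # planted +47.8 %
recs = {}
for p in (base, sd):
    cells, truth = synth_cells(p)                             # geometry + truth
    recs[p.group] = records_to_frame([cell_record(c) for c in cells])

pc, se = percent_change(recs["S"].mam_per_mito, recs["SD"].mam_per_mito, seed=0)
print(f"MAM/mitochondrion: {pc:+.1f} % (bootstrap SE {se:.1f})")
```

prints

```
MAM/mitochondrion: +62.3 % (bootstrap SE 12.9)
```

— at 50 cells per group the planted +47.8 % is recovered within the
sampling noise the bootstrap SE reports; at the full study sizes
(139 vs 132 cells, `analysis/02_em_morphometry.py`) the same estimate
lands within ~2 points of the planted value.

The numbered scripts under `analysis/` run each stage at the study
cohort sizes and write their tables under `results/` (bulky per-cell and
per-gene tables go to `scratch/`):

```
python analysis/01_simulate_cohorts.py      # persist example synthetic datasets
python analysis/02_em_morphometry.py        # 139 vs 132 cells, EM contrasts
python analysis/03_sleep_architecture.py    # 181/118 flies, episode + rebound
python analysis/04_expression_intersection.py
python analysis/05_blot_normalization.py
```

A thin CLI wraps the same library for shell use:
`mamsleep synth cells|dam|expr`, `mamsleep morpho run`,
`mamsleep sleep run`, `mamsleep de run` (see `--help`).

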