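#!/usr/bin/env python
"""Generate the synthetic study cohorts and persist them with their truth.

Writes, under scratch/synthetic/ (bulky, regenerable at any time):
  * GeoJSON cell segmentations for a sleep (S) and a sleep-deprived-like
    (SD) EM group (20 cells per group on disk; the analysis scripts
    regenerate the full cohorts in memory),
  * one DAM monitor file per genotype plus channel maps,
  * the planted ground truth beside every dataset.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from mamsleep import dam_sleep, geometry
from mamsleep.synthetic import CellGenParams, FlyGenParams, synth_cells, synth_dam
from mamsleep.workflows import (
    BOUT_CONTRAST_PCT,
    ER_DENSITY_CONTRAST_PCT,
    MAM_CONTRAST_PCT,
    MITO_PAIR_CONTRAST_PCT,
    de_intersection_study,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    base = CellGenParams(n_cells=20, group="S", seed=SEED)
    sd = replace(base, group="SD",
                 effect_mam=1 + MAM_CONTRAST_PCT / 100,
                 effect_er=1 + ER_DENSITY_CONTRAST_PCT / 100,
                 effect_mito_pair=1 + MITO_PAIR_CONTRAST_PCT / 100)
    for params in (base, sd):
        cells, truth = synth_cells(params)
        d = OUT / f"cells_{params.group}"
        d.mkdir(exist_ok=True)
        for cell in cells:
            geometry.write_geometry(cell, d / f"{cell.cell_id}.geojson")
        truth.to_json(d / "truth.json")
        print(f"wrote {len(cells)} {params.group} cells -> {d}")

    for genotype, n in (("control", 16), ("mutant", 16)):
        params = FlyGenParams(n_flies=n, genotype=genotype, n_days=6, sd_night=4,
                              fragmentation=1.05 if genotype == "mutant" else 1.0,
                              sleep_offset=0.66 if genotype == "mutant" else 1.0,
                              seed=SEED)
        traces, truth = synth_dam(params)
        d = OUT / f"dam_{genotype}"
        d.mkdir(exist_ok=True)
        dam_sleep.write_dam(d / "monitor.txt", traces)
        pd.DataFrame({
            "channel": range(1, n + 1),
            "fly_id": [t.fly_id for t in traces],
            "genotype": [t.genotype for t in traces],
        }).to_csv(d / "channel_map.csv", index=False)
        truth.to_json(d / "truth.json")
        print(f"wrote {n} {genotype} traces -> {d}")

    study = de_intersection_study(seed=SEED, n_genes=4000)
    print("expression study planted intersections:", study["planted"])
    print("recovered on this draw:", study["counts"])


if __name__ == "__main__":
    main()
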