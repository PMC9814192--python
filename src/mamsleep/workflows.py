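"""Full study-condition runs: generate the synthetic cohorts at the study
group sizes, execute the measurement pipeline, and estimate the group
contrasts.

The planted effects are the study's reported group differences, so each
workflow is a parameter-recovery experiment: the generator plants a known
contrast and the pipeline must re-estimate it from raw synthetic data.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .dam_sleep import baseline_average, rebound_analysis, records_to_frame, sleep_architecture
from .de_intersect import GeneSets, classify_de, differential_expression, venn_intersect
from .morphometry import cell_record, records_to_frame as morpho_frame
from .stats import normalize_blot, percent_change
from .synthetic import (
    CellGenParams,
    FlyGenParams,
    calibrate_fragmentation,
    calibrate_rebound,
    calibrate_sleep_offset,
    synth_blot,
    synth_cells,
    synth_dam,
    synth_expr,
)

# Planted sleep-deprivation effects on the EM morphometry (percent):
# MAM rate per mitochondrion, ER cisterna density, mito-mito contact rate.
MAM_CONTRAST_PCT = 47.8
ER_DENSITY_CONTRAST_PCT = 13.1
MITO_PAIR_CONTRAST_PCT = 36.4
# Study group sizes: EM cells, fly cohorts, arrays, blot lanes.
N_CELLS_S, N_CELLS_SD = 139, 132
N_FLIES_MUTANT, N_FLIES_CONTROL = 181, 118
N_FLIES_SD_MUTANT = 139
N_ARRAYS = 6
N_LANES = 5
# Planted fly-sleep effects (percent): 24-h episode number (mutant vs
# control), 24-h total sleep (mutant vs control), post-SD rebound.
BOUT_CONTRAST_PCT = 22.6
TOTAL_SLEEP_CONTRAST_PCT = -11.5
REBOUND_CONTRAST_PCT = 11.4
# Planted blot effects (percent): VDAC1 and STIM2 after sleep deprivation.
BLOT_CONTRASTS_PCT = {"VDAC1": 24.7, "STIM2": 24.1}
# Organelle gene-set intersection design: list sizes and planted DE counts.
ER_LIST_SIZE, MITO_LIST_SIZE = 1899, 829
PLANTED_COUNTS = {"ER-SDup": 99, "ER-SDdown": 71, "Mito-SDup": 29, "Mito-SDdown": 18}


def em_group_records(
    n_s: int = N_CELLS_S,
    n_sd: int = N_CELLS_SD,
    seed: int = 0,
    outlier_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list, list]:
    """Generate both EM groups and run the morphometry pipeline on them.

    The two groups share per-cell base randomness (common random numbers);
    the sleep-deprived group carries the planted multipliers."""
    base = CellGenParams(n_cells=n_s, group="S", seed=seed)
    sd = replace(
        base,
        n_cells=n_sd,
        group="SD",
        effect_mam=1 + MAM_CONTRAST_PCT / 100,
        effect_er=1 + ER_DENSITY_CONTRAST_PCT / 100,
        effect_mito_pair=1 + MITO_PAIR_CONTRAST_PCT / 100,
        outlier_fraction=outlier_fraction,
    )
    cells_s, _ = synth_cells(base)
    cells_sd, _ = synth_cells(sd)
    rec_s = morpho_frame([cell_record(c) for c in cells_s])
    rec_sd = morpho_frame([cell_record(c) for c in cells_sd])
    return rec_s, rec_sd, cells_s, cells_sd


def em_contrasts(
    rec_s: pd.DataFrame,
    rec_sd: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Recovered percent changes (with bootstrap SE) for the three planted
    EM metrics."""
    out = {}
    for key, metric, planted in (
        ("mam_per_mito", "mam_per_mito", MAM_CONTRAST_PCT),
        ("er_density", "er_density_per_um2", ER_DENSITY_CONTRAST_PCT),
        ("mito_mito", "mito_mito_contacts", MITO_PAIR_CONTRAST_PCT),
    ):
        pc, se = percent_change(rec_s[metric], rec_sd[metric], n_boot=n_boot, seed=seed)
        out[key] = {"percent_change": pc, "se": se, "planted": planted,
                    "n": len(rec_s) + len(rec_sd)}
    return out


def fly_baseline_contrast(
    n_mutant: int = N_FLIES_MUTANT,
    n_control: int = N_FLIES_CONTROL,
    seed: int = 0,
    n_boot: int = 10_000,
) -> dict[str, float]:
    """Recovered percent change in 24-h sleep-episode number between a
    fragmented (mutant-like) and a control genotype.

    The mutant's dwell multipliers are calibrated (seeded bisection on an
    independent calibration cohort) so the planted conditions realize the
    target episode-number contrast at the matched total-sleep offset."""
    control = FlyGenParams(n_flies=n_control, genotype="control", n_days=4, seed=seed)
    offset = calibrate_sleep_offset(TOTAL_SLEEP_CONTRAST_PCT, control)
    frag = calibrate_fragmentation(BOUT_CONTRAST_PCT, control, sleep_offset=offset)
    mutant = replace(control, n_flies=n_mutant, genotype="mutant",
                     fragmentation=frag, sleep_offset=offset)
    traces_c, _ = synth_dam(control)
    traces_m, _ = synth_dam(mutant)

    def mean_bouts(traces):
        return [
            float(np.mean([sleep_architecture(t, d).n_bouts for d in range(4)]))
            for t in traces
        ]

    bouts_c, bouts_m = mean_bouts(traces_c), mean_bouts(traces_m)
    pc, se = percent_change(bouts_c, bouts_m, n_boot=n_boot, seed=seed)
    return {"percent_change": pc, "se": se, "planted": BOUT_CONTRAST_PCT,
            "fragmentation": frag, "sleep_offset": offset,
            "n": n_mutant + n_control}


def fly_rebound_contrast(
    n_flies: int = N_FLIES_SD_MUTANT,
    seed: int = 0,
    fragmentation: float = 1.0,
    sleep_offset: float = 1.0,
) -> dict[str, float]:
    """Recovered percent change of post-SD total sleep over the 4-day
    baseline mean within one (mutant-like) genotype.

    Night 5 (dark phase of day 4) is enforced wake; the rebound multiplier
    on next-day sleep pressure is calibrated to the target contrast."""
    base = FlyGenParams(
        n_flies=n_flies, genotype="mutant", n_days=6, sd_night=4, seed=seed,
        fragmentation=fragmentation, sleep_offset=sleep_offset,
    )
    rho = calibrate_rebound(REBOUND_CONTRAST_PCT, base)
    traces, _ = synth_dam(replace(base, rebound=rho))
    baseline, post, genotypes = {}, {}, {}
    for tr in traces:
        recs = [sleep_architecture(tr, d) for d in range(4)]
        baseline[tr.fly_id] = baseline_average(recs)
        post[tr.fly_id] = sleep_architecture(tr, 5)
        genotypes[tr.fly_id] = tr.genotype
    df, _ = rebound_analysis(baseline, post, genotypes, n_boot=0)
    pct = df["delta_pct"].to_numpy()
    return {
        "percent_change": float(pct.mean()),
        "se": float(pct.std(ddof=1) / np.sqrt(pct.size)),
        "planted": REBOUND_CONTRAST_PCT,
        "rebound_multiplier": rho,
        "n": n_flies,
    }


def blot_recovery(seed: int = 0, n_boot: int = 10_000) -> dict[str, dict[str, float]]:
    """Recovered normalized percent changes for the two planted blot
    targets (loading-confounded lanes, Ponceau normalization)."""
    out = {}
    for i, (target, planted) in enumerate(BLOT_CONTRASTS_PCT.items()):
        lanes, _ = synth_blot(effect_pct=planted, n_per_group=N_LANES,
                              seed=seed * 17 + i)
        norm = normalize_blot(lanes)
        s = norm[norm.group == "S"]["normalized_signal"]
        sd = norm[norm.group == "SD"]["normalized_signal"]
        pc, se = percent_change(s, sd, n_boot=n_boot, seed=seed)
        out[target] = {"percent_change": pc, "se": se, "planted": planted,
                       "n": 2 * N_LANES}
    return out


def de_intersection_study(
    seed: int = 0,
    n_genes: int = 12_000,
    noise_sd_log2: float = 0.05,
) -> dict:
    """Planted organelle gene-set study mirroring the intersection design:
    ER/Mito lists of the study sizes with the four planted DE subsets."""
    rng = np.random.default_rng(seed + 7)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    shuffled = list(rng.permutation(genes))
    er_list = shuffled[:ER_LIST_SIZE]
    mito_list = shuffled[ER_LIST_SIZE:ER_LIST_SIZE + MITO_LIST_SIZE]
    planted = {
        "ER-SDup": (er_list[:99], 50.0),
        "ER-SDdown": (er_list[99:170], -45.0),
        "Mito-SDup": (mito_list[:29], 50.0),
        "Mito-SDdown": (mito_list[29:47], -45.0),
    }
    study, truth = synth_expr(n_genes, N_ARRAYS, planted=planted,
                              noise_sd_log2=noise_sd_log2, seed=seed)
    res = differential_expression(study)
    up, down, _ = classify_de(res)
    sets = GeneSets.from_lists(ER=er_list, Mito=mito_list)
    counts, members = venn_intersect(up, down, sets, res)
    recovered = {
        f"{s}-{d}": int(c)
        for s, d, c in zip(counts["set"], counts["direction"], counts["count"])
    }
    return {"counts": recovered, "planted": PLANTED_COUNTS,
            "results": res, "members": members}
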