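"""Differential expression with a signed fold-change filter and
intersection with organelle gene lists.

Per probe: Welch's two-sided t-test between the sleep (S) and
sleep-deprived (SD) groups on log2 expression, Benjamini-Hochberg
adjustment across all tested probes, then collapse to unique gene symbols
by minimum raw p (adjustment first, so adjusted values stay coherent with
the tested family).  Fold change is computed on the linear scale from the
log2 group means:

    FC% = (2^mean_SD - 2^mean_S) / 2^mean_S * 100

A gene is *up* iff FC% > +30 and adjusted p < 0.01, *down* iff
FC% < -30 and adjusted p < 0.01 ("fold change below 30 %" is read as a
decrease exceeding 30 %), otherwise *ns*.  The raw-p variant of the filter
is available via ``use_raw_p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

FC_THRESH_PCT = 30.0
P_THRESH = 0.01


@dataclass
class ExpressionStudy:
    """Log2 expression matrix (rows = probes, columns = samples) with a
    sample->group sheet and an optional probe->gene-symbol map."""

    matrix: pd.DataFrame
    sample_groups: dict[str, str]
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.matrix.columns if c not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        if not np.isfinite(self.matrix.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.matrix.to_numpy()))
            cells = [(self.matrix.index[i], self.matrix.columns[j]) for i, j in bad[:5]]
            raise ValueError(f"non-finite expression values, e.g. {cells}")
        for grp in ("S", "SD"):
            n = sum(1 for g in self.sample_groups.values() if g == grp)
            if n < 2:
                raise ValueError(f"group {grp!r} has {n} samples; need >= 2")

    def samples_of(self, group: str) -> list[str]:
        return [c for c in self.matrix.columns if self.sample_groups[c] == group]


@dataclass
class GeneSets:
    """Named organelle gene lists with uppercase-normalized unique symbols."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_lists(cls, **lists) -> "GeneSets":
        return cls({name: frozenset(s.strip().upper() for s in symbols if s.strip())
                    for name, symbols in lists.items()})

    @classmethod
    def from_files(cls, **paths) -> "GeneSets":
        lists = {}
        for name, path in paths.items():
            with open(path) as fh:
                lists[name] = [line.strip() for line in fh if line.strip()]
        return cls.from_lists(**lists)


def differential_expression(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene Welch statistics, BH-adjusted p, and linear fold change.

    Returns a frame indexed by gene symbol with columns ``mean_S``,
    ``mean_SD``, ``fold_change_pct``, ``t``, ``p_raw``, ``p_adj``,
    ``probe`` (the probe that carried the minimum raw p for the gene).
    """
    s_cols = study.samples_of("S")
    sd_cols = study.samples_of("SD")
    a = study.matrix[s_cols].to_numpy()
    b = study.matrix[sd_cols].to_numpy()
    t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    # probes constant and identical across both groups: no evidence of change
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    mean_s = a.mean(axis=1)
    mean_sd = b.mean(axis=1)
    fc = (np.exp2(mean_sd) - np.exp2(mean_s)) / np.exp2(mean_s) * 100.0
    probes = study.matrix.index.astype(str)
    gene_map = study.probe_to_gene or {}
    genes = [str(gene_map.get(pr, pr)).upper() for pr in probes]
    df = pd.DataFrame({
        "gene": genes, "probe": probes,
        "mean_S": mean_s, "mean_SD": mean_sd,
        "fold_change_pct": fc, "t": t, "p_raw": p, "p_adj": p_adj,
    })
    # collapse probes -> genes keeping the minimum-raw-p probe's statistics
    df = df.sort_values(["p_raw", "probe"], kind="stable").drop_duplicates("gene")
    return df.set_index("gene").sort_index()


def classify_de(
    results: pd.DataFrame,
    fc_thresh_pct: float = FC_THRESH_PCT,
    p_thresh: float = P_THRESH,
    use_raw_p: bool = False,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition the gene universe into (up, down, ns) sets by the signed
    fold-change and adjusted-p thresholds."""
    p = results["p_raw"] if use_raw_p else results["p_adj"]
    fc = results["fold_change_pct"]
    up = frozenset(results.index[(fc > fc_thresh_pct) & (p < p_thresh)])
    down = frozenset(results.index[(fc < -fc_thresh_pct) & (p < p_thresh)])
    ns = frozenset(results.index) - up - down
    return up, down, ns


def venn_intersect(
    up: frozenset[str],
    down: frozenset[str],
    gene_sets: GeneSets,
    results: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intersect the up/down sets with each organelle gene list.

    Returns a count table (one row per list x direction, e.g. ``ER-SDup``)
    and the member lists, sorted by adjusted p when ``results`` is given
    (alphabetically otherwise).  Empty gene lists yield zero counts.
    """
    rows = []
    members: dict[str, list[str]] = {}
    for name, symbols in gene_sets.sets.items():
        for direction, de_set in (("SDup", up), ("SDdown", down)):
            inter = symbols & de_set
            key = f"{name}-{direction}"
            if results is not None:
                ordered = sorted(inter, key=lambda g: (results.loc[g, "p_adj"], g))
            else:
                ordered = sorted(inter)
            members[key] = ordered
            rows.append({"set": name, "direction": direction,
                         "list_size": len(symbols), "count": len(inter)})
    return pd.DataFrame(rows), members
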