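"""The four-procedure synthetic-lethality screen over driver x druggable pairs.

A candidate pair (driver D, partner P) must satisfy, simultaneously:

1. differential expression — P is up-regulated in D-mutant tumors
   (two-sided Wilcoxon rank-sum, BH-adjusted p < 0.05 per driver, and
   log2 fold change > 0 on the log2(TPM+1) scale);
2. co-expression — D and P correlate in normal tissue
   (Spearman rho > 0.1, BH-adjusted p < 0.05);
3. functional similarity — FSS > 0.45 (undefined FSS fails);
4. mutual exclusivity — D and P are co-mutated less than the
   margin-preserving null expects (BH-adjusted lower-tail p < 0.15).

The flags are computed independently and conjoined; the run manifest records
every threshold and drop count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import gosim, mutex
from .cohort import CohortBundle

__all__ = [
    "ScreenConfig",
    "diff_expression",
    "coexpression",
    "similarity_filter",
    "run_screen",
]


@dataclass(frozen=True)
class ScreenConfig:
    de_padj: float = 0.05
    coexpr_rho: float = 0.1
    coexpr_padj: float = 0.05
    fss_threshold: float = 0.45
    mutex_padj: float = 0.15  # 0.1 is the documented alternative
    min_group_size: int = 5
    min_normals: int = 5
    low_expr_detect_frac: float = 0.2


def diff_expression(
    bundle: CohortBundle,
    driver: str,
    candidates: list[str],
    padj_cut: float = 0.05,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Wilcoxon rank-sum mutant-vs-WT comparison for each candidate partner.

    Fold change is the difference of group means of log2(TPM+1).  BH is
    applied across this driver's candidates.  Pass requires padj < cut AND
    up-regulation in the mutated samples.
    """
    expr = bundle.expr_tumor.values
    status = bundle.mut.loc[driver].reindex(expr.columns)
    mut_cols = status.index[status == 1]
    wt_cols = status.index[status == 0]
    if len(mut_cols) < min_group_size or len(wt_cols) < min_group_size:
        raise ValueError(
            f"driver {driver!r}: group sizes {len(mut_cols)}/{len(wt_cols)} "
            f"below minimum {min_group_size}"
        )
    a = expr.loc[candidates, mut_cols].to_numpy()
    b = expr.loc[candidates, wt_cols].to_numpy()
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=1)
    pvals = np.atleast_1d(res.pvalue)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "de_p": pvals,
            "de_padj": padj,
            "log2fc": lfc,
            "pass_de": (padj < padj_cut) & (lfc > 0),
        },
        index=pd.Index(candidates, name="partner"),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho at tiny n (<= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def coexpression(
    bundle: CohortBundle,
    pairs: list[tuple[str, str]],
    rho_cut: float = 0.1,
    padj_cut: float = 0.05,
    min_normals: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of each pair in normal tissue, BH over all pairs.

    The t-approximation p-value is used except at n <= 9 where the exact
    permutation distribution is enumerated.  A constant expression vector
    makes rho undefined: the pair fails with a warning.
    """
    if bundle.expr_normal is None:
        raise ValueError("bundle has no normal-tissue expression")
    xn = bundle.expr_normal.values
    n = xn.shape[1]
    if n < min_normals:
        raise ValueError(f"only {n} normal samples (< {min_normals})")
    rhos, pvals = [], []
    for d, p in pairs:
        x = xn.loc[d].to_numpy()
        y = xn.loc[p].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"constant expression in pair ({d}, {p}); correlation undefined",
                stacklevel=2,
            )
            rhos.append(np.nan)
            pvals.append(1.0)
            continue
        rho, pv = stats.spearmanr(x, y)
        if n <= 9:
            pv = _exact_spearman_p(x, y)
        rhos.append(float(rho))
        pvals.append(float(pv))
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    rho_arr = np.array(rhos)
    return pd.DataFrame(
        {
            "driver": [d for d, _ in pairs],
            "partner": [p for _, p in pairs],
            "rho": rho_arr,
            "coexpr_p": pvals,
            "coexpr_padj": padj,
            "pass_coexpr": (~np.isnan(rho_arr))
            & (rho_arr > rho_cut)
            & (padj < padj_cut),
        }
    )


def similarity_filter(
    pairs: list[tuple[str, str]],
    graph,
    ann: dict,
    threshold: float = 0.45,
) -> pd.DataFrame:
    """FSS per pair; pass iff defined and strictly above ``threshold``."""
    rows = []
    for d, p in pairs:
        rec = gosim.fss(d, p, graph, ann)
        rows.append(
            {
                "driver": d,
                "partner": p,
                "ss_mf": rec.ss_mf,
                "ss_cc": rec.ss_cc,
                "fss": rec.fss,
                "pass_fss": rec.fss is not None and rec.fss > threshold,
            }
        )
    return pd.DataFrame(rows)


def _filter_low_expression(
    bundle: CohortBundle, genes: list[str], detect_frac: float
) -> tuple[list[str], int]:
    """Drop genes with zero variance or detected (> 0) in < detect_frac of tumors."""
    expr = bundle.expr_tumor.values
    kept = []
    for g in genes:
        if g not in expr.index:
            continue
        v = expr.loc[g].to_numpy()
        if np.ptp(v) > 0 and (v > 0).mean() >= detect_frac:
            kept.append(g)
    return kept, len(genes) - len(kept)


def run_screen(
    bundle: CohortBundle,
    drivers: list[str],
    druggable_genes: list[str],
    go_graph,
    annotations: dict,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Run all four procedures over every (driver, druggable gene) pair.

    Returns the candidate table (one row per pair, all statistics and flags,
    ``pass_all`` = conjunction) and a manifest of thresholds and drop counts.
    """
    if not drivers or not druggable_genes:
        raise ValueError("driver and druggable-gene lists must be non-empty")
    missing_drivers = [d for d in drivers if d not in bundle.mut.index]
    if missing_drivers:
        raise ValueError(f"drivers absent from mutation matrix: {missing_drivers}")
    dgs, n_dropped_low = _filter_low_expression(
        bundle, druggable_genes, config.low_expr_detect_frac
    )

    # procedure 1: per-driver differential expression
    de_frames = []
    skipped_drivers = []
    for d in drivers:
        cands = [g for g in dgs if g != d]
        try:
            de = diff_expression(
                bundle, d, cands, config.de_padj, config.min_group_size
            )
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
            skipped_drivers.append(d)
            continue
        de = de.reset_index()
        de.insert(0, "driver", d)
        de_frames.append(de)
    if not de_frames:
        raise ValueError("no driver had large enough mutant/WT groups")
    table = pd.concat(de_frames, ignore_index=True)
    pairs = list(zip(table["driver"], table["partner"]))

    # procedure 2: co-expression in normals (BH across all pairs)
    co = coexpression(
        bundle, pairs, config.coexpr_rho, config.coexpr_padj, config.min_normals
    )
    table = table.merge(co, on=["driver", "partner"])

    # procedure 3: functional similarity
    fs = similarity_filter(pairs, go_graph, annotations, config.fss_threshold)
    table = table.merge(fs, on=["driver", "partner"])

    # procedure 4: mutual exclusivity (BH across all pairs)
    rates = mutex.estimate_background(bundle.mut)
    results = []
    testable = []
    for d, p in pairs:
        if d in rates.p.index and p in rates.p.index:
            results.append(mutex.exclusivity_test(d, p, bundle.mut, rates))
            testable.append(True)
        else:
            testable.append(False)
    mutex.adjust_and_flag(results, config.mutex_padj)
    by_pair = {(r.gene_a, r.gene_b): r for r in results}
    table["n_co"] = [
        by_pair[(d, p)].n_co if (d, p) in by_pair else np.nan for d, p in pairs
    ]
    table["expected_co"] = [
        by_pair[(d, p)].expected_co if (d, p) in by_pair else np.nan for d, p in pairs
    ]
    table["mutex_p"] = [
        by_pair[(d, p)].p_value if (d, p) in by_pair else np.nan for d, p in pairs
    ]
    table["mutex_padj"] = [
        by_pair[(d, p)].p_adjust if (d, p) in by_pair else np.nan for d, p in pairs
    ]
    table["pass_mutex"] = [
        bool(by_pair[(d, p)].passed) if (d, p) in by_pair else False for d, p in pairs
    ]

    table["pass_all"] = (
        table["pass_de"] & table["pass_coexpr"] & table["pass_fss"] & table["pass_mutex"]
    )
    manifest = {
        "thresholds": {
            "de_padj": config.de_padj,
            "coexpr_rho": config.coexpr_rho,
            "coexpr_padj": config.coexpr_padj,
            "fss": config.fss_threshold,
            "mutex_padj": config.mutex_padj,
        },
        "bh_families": {
            "de": "per driver across candidates",
            "coexpression": "all pairs",
            "mutex": "all pairs",
        },
        "n_pairs_tested": len(table),
        "n_pass_all": int(table["pass_all"].sum()),
        "n_druggable_dropped_low_expression": n_dropped_low,
        "drivers_skipped_small_groups": skipped_drivers,
        "n_pairs_untestable_mutex": int(len(testable) - sum(testable)),
    }
    return table, manifest
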