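"""Driver-target-drug network assembly and survival validation of SL pairs.

Screened SL pairs are joined with the drug catalog and the differential
drug-response flags into a tripartite network: ``sl`` edges (driver ->
target, carrying RAS and procedure statistics), ``targets`` edges (drug ->
target) and ``effective`` edges (driver -> drug) present only when the
compound passed the response filter against that driver.  Every effective
edge is structurally supported by a driver -> target -> drug path.

Survival validation splits driver-mutant patients at the median partner
expression (ties to the inactive group) and compares the groups by log-rank
test and univariate Cox regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .cohort import CohortBundle
from .io_formats import DrugCatalog, write_network_json, write_results_tsv

__all__ = [
    "SurvivalValidation",
    "build_network",
    "validate_network",
    "survival_validate",
    "export",
]


@dataclass
class SurvivalValidation:
    driver: str
    partner: str
    n_active: int
    n_inactive: int
    logrank_p: float
    cox_hr: float
    hr_ci_low: float
    hr_ci_high: float


def build_network(
    sl_pairs: pd.DataFrame,
    catalog: DrugCatalog,
    drug_flags: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Join SL pairs, drug-target rows and response flags into one graph.

    ``sl_pairs`` needs columns driver/partner (plus optional statistics
    copied onto sl edges); ``drug_flags`` needs driver/compound/sl_flag
    (plus optional logfc, p_value).  Drugs targeting no SL partner are left
    out entirely — no orphan drug nodes.
    """
    g = nx.DiGraph()
    partners = set(sl_pairs["partner"])
    stat_cols = [
        c for c in ("ras", "stuart_p", "log2fc", "rho", "fss", "mutex_padj")
        if c in sl_pairs.columns
    ]
    for _, row in sl_pairs.iterrows():
        d, p = row["driver"], row["partner"]
        g.add_node(d, kind="driver")
        g.add_node(p, kind="target")
        attrs = {c: row[c] for c in stat_cols if pd.notna(row[c])}
        g.add_edge(d, p, etype="sl", **attrs)

    for _, row in catalog.records.iterrows():
        if row["target_gene"] in partners:
            g.add_node(row["drug_id"], kind="drug", name=row["drug_name"])
            g.add_edge(row["drug_id"], row["target_gene"], etype="targets")

    if drug_flags is not None:
        flagged = drug_flags[drug_flags["sl_flag"]]
        for _, row in flagged.iterrows():
            drug, driver = row["compound"], row["driver"]
            if drug not in g or driver not in g:
                continue
            # an effective edge needs a supporting sl + targets path
            supported = any(
                g.has_edge(driver, tgt)
                and g.edges[driver, tgt].get("etype") == "sl"
                for _, tgt in g.out_edges(drug)
            )
            if supported:
                g.add_edge(
                    driver,
                    drug,
                    etype="effective",
                    logfc=float(row.get("logfc", np.nan)),
                    p_value=float(row.get("p_value", np.nan)),
                )
    validate_network(g)
    return g


def validate_network(g: nx.DiGraph) -> None:
    """Structural invariants: path support for effective edges, no orphan drugs."""
    for u, v, data in g.edges(data=True):
        if data.get("etype") == "effective":
            ok = any(
                g.has_edge(u, t) and g.edges[u, t].get("etype") == "sl"
                for _, t in g.out_edges(v)
                if g.edges[v, t].get("etype") == "targets"
            )
            if not ok:
                raise ValueError(f"effective edge {u}->{v} lacks a supporting path")
    for n, data in g.nodes(data=True):
        if data.get("kind") == "drug" and g.out_degree(n) == 0:
            raise ValueError(f"orphan drug node {n!r}")


def survival_validate(
    bundle: CohortBundle,
    pair: tuple[str, str],
    min_mutant: int = 10,
) -> SurvivalValidation:
    """Median-split survival comparison within driver-mutant patients.

    Patients with partner expression strictly above the median form the
    active group; ties go to the inactive group.  Reports the log-rank p and
    the univariate Cox hazard ratio (active vs inactive) with 95% CI.
    """
    driver, partner = pair
    if bundle.clinical is None:
        raise ValueError("bundle has no clinical table")
    mut_samples = [
        s for s in bundle.mutant_samples(driver) if s in set(bundle.clinical["sample"])
    ]
    mut_samples = [s for s in mut_samples if s in bundle.expr_tumor.values.columns]
    if len(mut_samples) < min_mutant:
        raise ValueError(
            f"only {len(mut_samples)} driver-mutant samples with survival data "
            f"(< {min_mutant})"
        )
    expr = bundle.expr_tumor.values.loc[partner, mut_samples]
    med = float(expr.median())
    active = expr.index[expr > med]
    inactive = expr.index[expr <= med]
    if len(active) == 0 or len(inactive) == 0:
        raise ValueError(f"constant expression of {partner!r} in mutant samples")

    clin = bundle.clinical.set_index("sample")
    t_a, e_a = clin.loc[active, "time"], clin.loc[active, "event"]
    t_i, e_i = clin.loc[inactive, "time"], clin.loc[inactive, "event"]
    lr = logrank_test(t_a, t_i, event_observed_A=e_a, event_observed_B=e_i)

    df = pd.DataFrame(
        {
            "time": clin.loc[mut_samples, "time"],
            "event": clin.loc[mut_samples, "event"],
            "active": [1 if s in set(active) else 0 for s in mut_samples],
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["active"]))
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.loc["active"].iloc[0]))
    hi = float(np.exp(ci.loc["active"].iloc[1]))
    return SurvivalValidation(
        driver=driver,
        partner=partner,
        n_active=len(active),
        n_inactive=len(inactive),
        logrank_p=float(lr.p_value),
        cox_hr=hr,
        hr_ci_low=lo,
        hr_ci_high=hi,
    )


def export(
    network: nx.DiGraph,
    ranked_table: pd.DataFrame,
    validations: list[SurvivalValidation],
    outdir: str | Path,
    manifest: dict | None = None,
) -> None:
    """Write network JSON, ranked-pair TSV, validation TSV and run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_network(network)
    write_network_json(network, outdir / "network.json")
    write_results_tsv(ranked_table.reset_index(), outdir / "ranked_pairs.tsv")
    cols = [
        "driver",
        "partner",
        "n_active",
        "n_inactive",
        "logrank_p",
        "cox_hr",
        "hr_ci_low",
        "hr_ci_high",
    ]
    vdf = pd.DataFrame([vars(v) for v in validations], columns=cols)
    write_results_tsv(vdf, outdir / "survival_validation.tsv")
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest or {}, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
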