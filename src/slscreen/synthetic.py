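"""Synthetic cohorts, ontologies, drug catalogs and cell-line panels.

Every downstream stage of the screen is exercised on data generated here,
with planted ground truth.  A planted synthetic-lethal pair (driver D,
partner P) carries the four signals the screen looks for:

* partner up-regulation by ``de_shift`` log2-units in driver-mutant tumors
  (compensatory activation),
* driver-partner co-expression in normal tissue via a shared Gaussian
  latent factor calibrated to a target Spearman correlation,
* mutual exclusivity: the co-mutation probability is ``excl_factor`` times
  the independence product,
* shared GO neighborhood: both genes annotated to the same / sibling terms
  in MF and CC, while decoy genes live in distant branches.

Expression is modelled as Gaussian on the log2(TPM+1) scale with
gene-specific baselines — downstream tests are rank-based, so only the
ordering structure matters.  Mutations follow a per-gene rate x per-sample
burden product model, matching the background model the exclusivity test
fits.  All identifiers are synthetic ("G0001", "T0001"); no real gene
symbols appear.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortBundle
from .io_formats import (
    DrugCatalog,
    ExpressionMatrix,
    MutationTable,
    write_drug_catalog,
    write_expression,
    write_maf_subset,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_go",
    "generate_drug_catalog",
    "generate_ccl_panel",
    "generate_labeled_studies",
    "simulate_survival",
    "write_fixture_set",
]

FUNCTIONAL_CLASS_POOL = ("Frame_Shift_Del", "Frame_Shift_Ins", "Nonsense_Mutation")

# AUC linear response model: AUC = AUC_BASE - AUC_SLOPE * expr + noise
AUC_BASE = 10.0
AUC_SLOPE = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults define the benchmark conditions."""

    n_tumor: int = 300
    n_normal: int = 60
    n_drivers: int = 15
    n_druggable: int = 100
    n_planted_pairs: int = 15
    de_shift: float = 2.0  # log2-units partner up-regulation in mutants
    coexpr_rho: float = 0.6  # target Spearman correlation in normals
    excl_factor: float = 0.1  # co-mutation prob = excl_factor * independent
    base_mut_rate_range: tuple[float, float] = (0.1, 0.3)
    go_depth: int = 5
    go_branching: int = 3
    auc_noise_sd: float = 0.3
    na_rate: float = 0.05
    seed: int = 0
    # secondary knobs
    n_ccl: int = 200
    n_extra_drugs: int = 30
    heme_fraction: float = 0.1  # CCLs labeled haematopoietic/lymphoid
    expr_sd: float = 1.0  # per-gene log2 noise sd
    n_batches: int = 2

    def __post_init__(self) -> None:
        counts = (
            self.n_tumor,
            self.n_normal,
            self.n_drivers,
            self.n_druggable,
            self.n_planted_pairs,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_planted_pairs > self.n_drivers * self.n_druggable:
            raise ValueError("more planted pairs than driver x druggable combinations")
        if not 0 <= self.excl_factor < 1:
            raise ValueError("excl_factor must lie in [0, 1)")
        if not 0 <= self.na_rate < 1:
            raise ValueError("na_rate must lie in [0, 1)")
        if not 0 < self.coexpr_rho < 1:
            raise ValueError("coexpr_rho must lie in (0, 1)")
        lo, hi = self.base_mut_rate_range
        if not 0 < lo <= hi < 1:
            raise ValueError("base_mut_rate_range must satisfy 0 < lo <= hi < 1")
        if self.go_depth < 2:
            raise ValueError("go_depth must be >= 2")


@dataclass
class GroundTruth:
    """What was planted: SL pairs, responsive drugs, true mutation labels."""

    planted_pairs: list[tuple[str, str]]
    mutant_label: pd.DataFrame  # drivers x tumor samples, 0/1
    planted_drug_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def planted_partners(self) -> list[str]:
        return [p for _, p in self.planted_pairs]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def driver_genes(config: SimConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, config.n_drivers + 1)]


def druggable_genes(config: SimConfig) -> list[str]:
    start = config.n_drivers + 1
    return [f"G{i:04d}" for i in range(start, start + config.n_druggable)]


def planted_pairs_for(config: SimConfig) -> list[tuple[str, str]]:
    """Deterministic planted-pair selection shared by all generators.

    Partners are distinct druggable genes; drivers cycle if there are more
    pairs than drivers.
    """
    rng = _rng(config, 101)
    drivers = driver_genes(config)
    dgs = druggable_genes(config)
    partners = list(rng.choice(dgs, size=min(config.n_planted_pairs, len(dgs)), replace=False))
    pairs = []
    for k in range(config.n_planted_pairs):
        pairs.append((drivers[k % len(drivers)], partners[k % len(partners)]))
    return list(dict.fromkeys(pairs))  # dedupe while preserving order


def _gene_baselines(config: SimConfig) -> pd.Series:
    genes = driver_genes(config) + druggable_genes(config)
    rng = _rng(config, 102)
    return pd.Series(rng.uniform(3.0, 8.0, size=len(genes)), index=genes)


def generate_cohort(config: SimConfig) -> tuple[CohortBundle, GroundTruth]:
    """Simulate an analysis-ready cohort with planted SL structure."""
    if config.n_normal < 3:
        raise ValueError("n_normal must be >= 3 for co-expression to be defined")
    genes = driver_genes(config) + druggable_genes(config)
    tumors = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)]
    normals = [f"N{i:04d}" for i in range(1, config.n_normal + 1)]
    pairs = planted_pairs_for(config)
    mu = _gene_baselines(config)
    sd = config.expr_sd

    # --- mutations: per-gene rate x per-sample burden product model
    rng_mut = _rng(config, 103)
    lo, hi = config.base_mut_rate_range
    rate = pd.Series(rng_mut.uniform(lo, hi, size=len(genes)), index=genes)
    burden = rng_mut.lognormal(mean=0.0, sigma=0.25, size=config.n_tumor)
    p = np.clip(rate.to_numpy()[:, None] * burden[None, :], 1e-4, 0.95)
    mut = (rng_mut.random(p.shape) < p).astype(int)
    mut = pd.DataFrame(mut, index=genes, columns=tumors)

    # planted pairs: joint resampling with deflated co-mutation probability
    for d, part in pairs:
        pd_, pp_ = p[genes.index(d)], p[genes.index(part)]
        p_both = config.excl_factor * pd_ * pp_
        u = rng_mut.random(config.n_tumor)
        both = u < p_both
        d_only = (u >= p_both) & (u < pd_)
        p_only = (u >= pd_) & (u < pd_ + pp_ - p_both)
        mut.loc[d] = (both | d_only).astype(int)
        mut.loc[part] = (both | p_only).astype(int)

    # --- tumor expression: baseline + shift in driver-mutant samples
    rng_t = _rng(config, 104)
    xt = mu.to_numpy()[:, None] + sd * rng_t.standard_normal((len(genes), config.n_tumor))
    xt = pd.DataFrame(xt, index=genes, columns=tumors)
    for d, part in pairs:
        mask = mut.loc[d].to_numpy() == 1
        xt.loc[part, mask] += config.de_shift

    # --- normal expression: shared latent factor per driver
    # Pearson r giving the target Spearman: rho_S = (6/pi) asin(r/2)
    r = 2.0 * math.sin(math.pi * config.coexpr_rho / 6.0)
    lam = math.sqrt(r)
    rng_n = _rng(config, 105)
    xn = mu.to_numpy()[:, None] + sd * rng_n.standard_normal((len(genes), config.n_normal))
    xn = pd.DataFrame(xn, index=genes, columns=normals)
    latent: dict[str, np.ndarray] = {}
    resid = math.sqrt(1.0 - lam * lam)
    for d, part in pairs:
        if d not in latent:
            latent[d] = rng_n.standard_normal(config.n_normal)
            xn.loc[d] = mu[d] + sd * (
                lam * latent[d] + resid * rng_n.standard_normal(config.n_normal)
            )
        xn.loc[part] = mu[part] + sd * (
            lam * latent[d] + resid * rng_n.standard_normal(config.n_normal)
        )

    # keep the log2(TPM+1) scale strictly positive (TPM > 0)
    xt = xt.clip(lower=0.01)
    xn = xn.clip(lower=0.01)

    # --- clinical & batches
    rng_c = _rng(config, 106)
    t_event = rng_c.exponential(scale=5.0 / math.log(2.0), size=config.n_tumor)
    t_cens = rng_c.uniform(1.0, 10.0, size=config.n_tumor)
    clinical = pd.DataFrame(
        {
            "sample": tumors,
            "time": np.minimum(t_event, t_cens).round(4),
            "event": (t_event <= t_cens).astype(int),
        }
    )
    batch = pd.Series(
        [f"STUDY{1 + i % config.n_batches}" for i in range(config.n_tumor)],
        index=tumors,
        name="batch",
    )

    meta_t = pd.DataFrame({"tissue": "tumor", "batch": batch})
    meta_n = pd.DataFrame({"tissue": "normal", "batch": "STUDY1"}, index=normals)
    bundle = CohortBundle(
        expr_tumor=ExpressionMatrix(xt, "log2tpm", meta_t),
        expr_normal=ExpressionMatrix(xn, "log2tpm", meta_n),
        mut=mut,
        clinical=clinical,
        batch=batch,
        report={"generator": "synthetic", "n_planted": len(pairs)},
    )
    truth = GroundTruth(
        planted_pairs=pairs,
        mutant_label=mut.loc[driver_genes(config)].copy(),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# ontology


def _build_namespace_tree(
    ns: str, ns_digit: int, depth: int, branching: int
) -> tuple[nx.DiGraph, list[list[str]]]:
    """Complete ``branching``-ary tree with ``depth`` levels below one root.

    Returns the child->parent DAG and the node ids per level.  Every fifth
    edge is typed part_of, the rest is_a.
    """
    g = nx.DiGraph()
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{ns_digit}{counter:06d}"

    root = new_id()
    g.add_node(root, namespace=ns, name=f"{ns} root")
    levels = [[root]]
    edge_i = 0
    for _ in range(depth):
        nxt = []
        for parent in levels[-1]:
            for _ in range(branching):
                node = new_id()
                etype = "part_of" if edge_i % 5 == 4 else "is_a"
                g.add_node(node, namespace=ns, name=node)
                g.add_edge(node, parent, etype=etype)
                nxt.append(node)
                edge_i += 1
        levels.append(nxt)
    return g, levels


def generate_go(config: SimConfig) -> tuple[nx.DiGraph, dict]:
    """Generate MF/CC/BP trees and gene annotations with planted proximity.

    Each planted pair is assigned its own anchor node three levels below the
    root (or the deepest internal level on shallow test trees): the driver is
    annotated to one leaf child-chain of the anchor, the partner to that same
    leaf plus a sibling.  Decoy genes are annotated to leaves under anchors
    not used by any planted pair, so decoy-driver similarity stays low.
    """
    pairs = planted_pairs_for(config)
    drivers = driver_genes(config)
    dgs = druggable_genes(config)
    partners = {p for _, p in pairs}
    planted_drivers = {d for d, _ in pairs}
    rng = _rng(config, 107)

    graph = nx.DiGraph()
    ann: dict[str, dict[str, set]] = {
        g: {"MF": set(), "CC": set(), "BP": set()} for g in drivers + dgs
    }
    for ns, digit in (("MF", 1), ("CC", 2)):
        sub, levels = _build_namespace_tree(ns, digit, config.go_depth, config.go_branching)
        graph = nx.compose(graph, sub)
        anchor_level = min(3, config.go_depth - 1)
        anchors = levels[anchor_level]
        leaves = levels[-1]

        def leaves_under(anchor: str) -> list[str]:
            per_anchor = len(leaves) // len(anchors)
            i = anchors.index(anchor)
            return leaves[i * per_anchor : (i + 1) * per_anchor]

        n_anchor_planted = min(len(pairs), max(1, len(anchors) - 1))
        for k, (d, part) in enumerate(pairs):
            anchor = anchors[k % n_anchor_planted]
            lv = leaves_under(anchor)
            leaf = lv[k % len(lv)]
            sibling = lv[(k + 1) % len(lv)] if len(lv) > 1 else leaf
            ann[d][ns].add(leaf)
            ann[part][ns].update({leaf, sibling})
        decoy_anchors = anchors[n_anchor_planted:] or anchors[-1:]
        decoy_leaves = [l for a in decoy_anchors for l in leaves_under(a)]
        for g in drivers + dgs:
            if g in partners or g in planted_drivers:
                continue
            k_terms = int(rng.integers(1, 3))
            for leaf in rng.choice(decoy_leaves, size=k_terms, replace=False):
                ann[g][ns].add(str(leaf))

    # small BP tree: parsed and stored but unused by the FSS screen
    bp, bp_levels = _build_namespace_tree("BP", 3, 2, 2)
    graph = nx.compose(graph, bp)
    bp_leaves = bp_levels[-1]
    for g in drivers + dgs:
        ann[g]["BP"].add(str(rng.choice(bp_leaves)))
    return graph, ann


# ---------------------------------------------------------------------------
# drugs & cell lines


def generate_drug_catalog(
    truth: GroundTruth,
    config: SimConfig,
    n_extra_drugs: int | None = None,
) -> DrugCatalog:
    """One responsive compound per planted partner plus decoy compounds.

    Decoy compounds target random non-partner genes.  ``truth.planted_drug_map``
    is filled with the responsive compounds.
    """
    n_extra = config.n_extra_drugs if n_extra_drugs is None else n_extra_drugs
    rng = _rng(config, 108)
    rows = []
    truth.planted_drug_map = {}
    i = 0
    for partner in truth.planted_partners:
        i += 1
        did = f"CP{i:04d}"
        rows.append({"drug_id": did, "drug_name": f"compound-{i}", "target_gene": partner})
        truth.planted_drug_map.setdefault(partner, []).append(did)
    non_partners = [g for g in druggable_genes(config) if g not in set(truth.planted_partners)]
    for _ in range(n_extra):
        i += 1
        target = str(rng.choice(non_partners)) if non_partners else str(
            rng.choice(druggable_genes(config))
        )
        rows.append(
            {"drug_id": f"CP{i:04d}", "drug_name": f"compound-{i}", "target_gene": target}
        )
    return DrugCatalog(pd.DataFrame(rows))


def generate_ccl_panel(
    config: SimConfig, truth: GroundTruth, catalog: DrugCatalog
):
    """Cell-line panel whose AUCs respond linearly to target-gene expression.

    Responsive compounds (those in ``truth.planted_drug_map``) follow
    AUC = 10 - 0.5 * expr(target) + N(0, auc_noise_sd); decoy compounds are
    expression-independent noise around the same AUC range.  Missing values
    are injected completely at random at ``na_rate``, and ``heme_fraction``
    of the lines are labeled haematopoietic/lymphoid for the lineage filter.
    """
    from .drugs import DrugPanel  # local import to avoid a cycle

    genes = driver_genes(config) + druggable_genes(config)
    mu = _gene_baselines(config)
    ccls = [f"CL{i:04d}" for i in range(1, config.n_ccl + 1)]
    rng = _rng(config, 109)
    expr = mu.to_numpy()[:, None] + config.expr_sd * rng.standard_normal(
        (len(genes), config.n_ccl)
    )
    expr = pd.DataFrame(expr, index=genes, columns=ccls).clip(lower=0.01)

    responsive = {d for drugs in truth.planted_drug_map.values() for d in drugs}
    drug_ids = list(dict.fromkeys(catalog.records["drug_id"]))
    auc = pd.DataFrame(index=ccls, columns=drug_ids, dtype=float)
    for did in drug_ids:
        noise = rng.normal(0.0, config.auc_noise_sd, size=config.n_ccl)
        if did in responsive:
            target = catalog.targets_of(did)[0]
            auc[did] = AUC_BASE - AUC_SLOPE * expr.loc[target].to_numpy() + noise
        else:
            auc[did] = AUC_BASE - AUC_SLOPE * mu.mean() + noise
    if config.na_rate > 0:
        mask = rng.random(auc.shape) < config.na_rate
        auc = auc.mask(mask)

    n_heme = int(round(config.heme_fraction * config.n_ccl))
    tissues = ["haematopoietic_and_lymphoid_tissue"] * n_heme + ["kidney"] * (
        config.n_ccl - n_heme
    )
    order = rng.permutation(config.n_ccl)
    meta = pd.Series([tissues[i] for i in order], index=ccls, name="tissue")
    return DrugPanel(
        ccl_expr=ExpressionMatrix(expr, "log2tpm"),
        auc=auc,
        ccl_meta=meta,
    )


# ---------------------------------------------------------------------------
# auxiliary simulators


def generate_labeled_studies(
    n_per_study: int = 100,
    n_genes: int = 300,
    n_signature: int = 20,
    shift: float = 3.0,
    n_studies: int = 2,
    mut_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Multi-study expression with a planted mutation-status signature.

    Returns (expression genes x samples on log2 scale, binary labels,
    study labels, signature gene list).  Signature genes shift by ``shift``
    log2-units in labeled samples; used for classifier validation.
    """
    rng = np.random.default_rng([seed, 201])
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    signature = list(rng.choice(genes, size=n_signature, replace=False))
    cols, labels, studies = [], [], []
    blocks = []
    for s in range(n_studies):
        names = [f"S{s+1}{i:03d}" for i in range(1, n_per_study + 1)]
        lab = (rng.random(n_per_study) < mut_fraction).astype(int)
        mu = rng.uniform(3.0, 8.0, size=n_genes)
        x = mu[:, None] + rng.standard_normal((n_genes, n_per_study))
        xdf = pd.DataFrame(x, index=genes, columns=names)
        for g in signature:
            xdf.loc[g, lab == 1] += shift
        blocks.append(xdf)
        cols += names
        labels += list(lab)
        studies += [f"STUDY{s+1}"] * n_per_study
    expr = pd.concat(blocks, axis=1).clip(lower=0.01)
    return (
        expr,
        pd.Series(labels, index=cols, name="label"),
        pd.Series(studies, index=cols, name="study"),
        signature,
    )


def simulate_survival(
    expression: pd.Series,
    beta: float,
    seed: int = 0,
    median_years: float = 5.0,
    censor_range: tuple[float, float] = (1.0, 10.0),
) -> pd.DataFrame:
    """Survival times with hazard tied to a gene's (z-scored) expression.

    hazard_i = log(2)/median * exp(beta * z_i); censoring uniform over
    ``censor_range``.  beta > 0 means high expression is harmful.
    """
    rng = np.random.default_rng([seed, 202])
    z = (expression - expression.mean()) / max(expression.std(ddof=0), 1e-12)
    haz = math.log(2.0) / median_years * np.exp(beta * z.to_numpy())
    t_event = rng.exponential(1.0 / haz)
    t_cens = rng.uniform(*censor_range, size=len(expression))
    return pd.DataFrame(
        {
            "sample": expression.index,
            "time": np.minimum(t_event, t_cens).round(4),
            "event": (t_event <= t_cens).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# fixture export


def _maf_from_matrix(
    mut: pd.DataFrame, config: SimConfig, n_silent_mean: float = 3.0
) -> MutationTable:
    """Long MAF-style records consistent with the binary matrix.

    Each 1-cell becomes one functional record; Silent records are sprinkled
    on top so the parsing/filtering path sees non-functional classes.
    """
    rng = _rng(config, 110)
    rows = []
    genes = list(mut.index)
    for s in mut.columns:
        hit = mut.index[mut[s] == 1]
        for g in hit:
            rows.append(
                {
                    "sample": s,
                    "gene": g,
                    "variant_classification": str(rng.choice(FUNCTIONAL_CLASS_POOL)),
                }
            )
        for _ in range(rng.poisson(n_silent_mean)):
            rows.append(
                {
                    "sample": s,
                    "gene": str(rng.choice(genes)),
                    "variant_classification": "Silent",
                }
            )
    return MutationTable(pd.DataFrame(rows))


def _write_obo(graph: nx.DiGraph, path: Path) -> None:
    ns_long = {"MF": "molecular_function", "CC": "cellular_component", "BP": "biological_process"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for node in sorted(graph.nodes):
            data = graph.nodes[node]
            fh.write(f"\n[Term]\nid: {node}\nname: {data.get('name', node)}\n")
            fh.write(f"namespace: {ns_long[data['namespace']]}\n")
            for _, parent, ed in sorted(graph.out_edges(node, data=True)):
                if ed["etype"] == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def _write_gaf(ann: dict, path: Path) -> None:
    aspect = {"MF": "F", "CC": "C", "BP": "P"}
    rows = []
    for gene in sorted(ann):
        for ns, terms in sorted(ann[gene].items()):
            rows.extend(
                {"gene": gene, "term": t, "aspect": aspect[ns]} for t in sorted(terms)
            )
    pd.DataFrame(rows, columns=["gene", "term", "aspect"]).to_csv(
        path, sep="\t", index=False
    )


def write_fixture_set(config: SimConfig, outdir: str | Path) -> dict:
    """Write the complete synthetic input set as standard files.

    Returns a manifest of what was written; byte-identical for identical
    (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_cohort(config)
    graph, ann = generate_go(config)
    catalog = generate_drug_catalog(truth, config)
    panel = generate_ccl_panel(config, truth, catalog)

    write_expression(bundle.expr_tumor, outdir / "expr_tumor.tsv")
    write_expression(bundle.expr_normal, outdir / "expr_normal.tsv")
    write_maf_subset(_maf_from_matrix(bundle.mut, config), outdir / "mutations.maf.tsv")
    bundle.mut.to_csv(outdir / "mutation_matrix.tsv", sep="\t", index_label="gene")
    bundle.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    bundle.batch.rename("batch").to_csv(outdir / "batch.tsv", sep="\t", index_label="sample")
    _write_obo(graph, outdir / "ontology.obo")
    _write_gaf(ann, outdir / "annotations.gaf.tsv")
    write_drug_catalog(catalog, outdir / "drug_catalog.tsv")
    write_expression(panel.ccl_expr, outdir / "ccl_expr.tsv")
    panel.auc.to_csv(outdir / "ccl_auc.tsv", sep="\t", index_label="ccl")
    panel.ccl_meta.to_csv(outdir / "ccl_meta.tsv", sep="\t", index_label="ccl")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "planted_pairs": [list(p) for p in truth.planted_pairs],
                "planted_drug_map": truth.planted_drug_map,
                "mutant_label": {
                    d: truth.mutant_label.loc[d].to_dict()
                    for d in truth.mutant_label.index
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    manifest = {"config": asdict(config), "files": sorted(p.name for p in outdir.iterdir())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
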