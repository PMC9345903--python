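"""Cohort construction: TPM conversion, functional-mutation filtering, alignment.

A :class:`CohortBundle` is the analysis-ready unit downstream screens run on:
log2(TPM+1) tumor and normal expression, a binary functional-mutation matrix,
a clinical table and batch (pseudo-study) labels over a common sample set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, MutationTable

__all__ = [
    "DEFAULT_FUNCTIONAL_CLASSES",
    "CohortBundle",
    "counts_to_tpm",
    "filter_functional_mutations",
    "align_cohorts",
    "center_by_batch",
]

#: Variant classes treated as function-disrupting: frameshift and nonsense.
#: Splice-site / missense inclusion is a configuration choice.
DEFAULT_FUNCTIONAL_CLASSES = frozenset(
    {"Frame_Shift_Del", "Frame_Shift_Ins", "Nonsense_Mutation"}
)


@dataclass
class CohortBundle:
    """Aligned expression, binary mutations, clinical and batch labels."""

    expr_tumor: ExpressionMatrix  # log2(TPM+1)
    expr_normal: ExpressionMatrix | None
    mut: pd.DataFrame  # genes x tumor samples, 0/1
    clinical: pd.DataFrame | None  # sample, time (years), event (0/1)
    batch: pd.Series | None  # sample -> study label
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mut.isin([0, 1]).all().all():
            raise ValueError("mutation matrix entries must be 0/1")
        if self.clinical is not None and (self.clinical["time"] <= 0).any():
            raise ValueError("clinical times must be positive")

    @property
    def tumor_samples(self) -> list[str]:
        return self.expr_tumor.samples

    def mutant_samples(self, gene: str) -> list[str]:
        row = self.mut.loc[gene]
        return list(row.index[row == 1])


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw read counts (genes x samples) to TPM.

    TPM_gs = 1e6 * (counts_gs / length_g) / sum_g'(counts_g's / length_g');
    every sample column sums to one million.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return ExpressionMatrix(rate.div(denom, axis=1) * 1e6, scale_tag="tpm")


def filter_functional_mutations(
    mtab: MutationTable,
    min_mutations: int = 10,
    functional_classes: frozenset[str] = DEFAULT_FUNCTIONAL_CLASSES,
    burden_before_class_filter: bool = True,
) -> pd.DataFrame:
    """Binary functional-mutation matrix after the outlier-sample filter.

    Samples carrying fewer than ``min_mutations`` recorded mutations are
    dropped as outliers, as are samples with no functional mutation at all.
    The burden is counted over all records before the class filter by
    default (``burden_before_class_filter=False`` counts functional records
    only).  Silent and other non-functional classes are then excluded, and
    repeated mutations of one gene in one sample collapse to a single 1.
    """
    rec = mtab.records
    if "Silent" in functional_classes:
        raise ValueError("functional class set must exclude 'Silent'")
    burden_rec = rec if burden_before_class_filter else rec[
        rec["variant_classification"].isin(functional_classes)
    ]
    burden = burden_rec.groupby("sample").size()
    keep_burden = set(burden.index[burden >= min_mutations])

    func = rec[rec["variant_classification"].isin(functional_classes)]
    keep = keep_burden & set(func["sample"])
    func = func[func["sample"].isin(keep)]
    if func.empty:
        raise ValueError(
            f"no samples survive the burden filter (min_mutations={min_mutations})"
        )
    mat = (
        func.assign(v=1)
        .pivot_table(index="gene", columns="sample", values="v", aggfunc="max", fill_value=0)
        .astype(int)
    )
    mat.index.name = None
    mat.columns.name = None
    return mat.sort_index().sort_index(axis=1)


def align_cohorts(
    expr_tumor: ExpressionMatrix,
    mut: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    batch: pd.Series | None = None,
    expr_normal: ExpressionMatrix | None = None,
) -> CohortBundle:
    """Intersect sample sets and assemble an analysis-ready bundle.

    Expression is converted to log2(TPM+1).  The report records how many
    samples each source lost to the intersection.
    """
    sources = {"expression": set(expr_tumor.samples), "mutation": set(mut.columns)}
    if clinical is not None:
        sources["clinical"] = set(clinical["sample"])
    if batch is not None:
        sources["batch"] = set(batch.index)
    common = set.intersection(*sources.values())
    if not common:
        raise ValueError("no samples shared by all sources")
    order = [s for s in expr_tumor.samples if s in common]
    report = {
        f"dropped_{name}": len(have - common) for name, have in sources.items()
    }
    report["n_aligned"] = len(order)

    et = expr_tumor.to_log2()
    et = ExpressionMatrix(et.values[order], "log2tpm", et.sample_meta)
    mut_a = mut[order]
    clin = (
        clinical[clinical["sample"].isin(common)].reset_index(drop=True)
        if clinical is not None
        else None
    )
    batch_a = batch.loc[order] if batch is not None else None
    en = expr_normal.to_log2() if expr_normal is not None else None
    return CohortBundle(et, en, mut_a, clin, batch_a, report)


def center_by_batch(em: ExpressionMatrix, batch: pd.Series) -> ExpressionMatrix:
    """Optional per-batch, per-gene median centering (off by default upstream).

    A deliberately light-weight harmonization step; inputs are otherwise
    assumed already comparable across studies.
    """
    vals = em.values.copy()
    for label in batch.unique():
        cols = [s for s in vals.columns if batch.get(s) == label]
        sub = vals[cols]
        vals[cols] = sub.sub(sub.median(axis=1), axis=0)
    return ExpressionMatrix(vals, "log2tpm", em.sample_meta)
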