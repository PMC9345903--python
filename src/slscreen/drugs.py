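"""Drug-response imputation: cell-line-trained ridge models applied to tumors.

A pharmacogenomic panel (cell-line expression + dose-response AUC matrix,
lower AUC = more sensitive) is cleaned (lineage exclusion, missingness
filter, KNN imputation), then one ridge regression per compound maps
expression to AUC with the penalty chosen by ten-fold cross-validation.
Applied to tumor expression, the estimated AUCs are compared between
driver-mutant and wild-type samples; compounds with significantly lower
estimated AUC in mutants (logFC < 0, Wilcoxon p < 0.05) are flagged
SL-associated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .io_formats import ExpressionMatrix

__all__ = [
    "DrugPanel",
    "RidgeModel",
    "DrugResponseEstimate",
    "prep_panel",
    "train_ridge",
    "filter_predictive",
    "predict_auc",
    "differential_response",
]

EXCLUDED_LINEAGES = frozenset({"haematopoietic_and_lymphoid_tissue"})
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 13))


@dataclass
class DrugPanel:
    """Cell-line expression, AUC matrix (CCL x compound) and lineage labels."""

    ccl_expr: ExpressionMatrix
    auc: pd.DataFrame
    ccl_meta: pd.Series  # CCL -> tissue lineage
    prep_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shared = set(self.ccl_expr.samples) & set(self.auc.index)
        if not shared:
            raise ValueError("expression and AUC matrices share no cell lines")


@dataclass
class RidgeModel:
    """Per-compound expression->AUC model with its standardization state."""

    compound: str
    genes: list[str]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    lam: float
    cv_mse: float
    cv_r2: float

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        """Predict AUC for samples (columns of ``expr``, genes on rows).

        Model genes absent from ``expr`` are imputed at the training mean,
        i.e. contribute zero after standardization; at least half the model
        genes must be present.
        """
        present = [g for g in self.genes if g in expr.index]
        if len(present) < 0.5 * len(self.genes):
            raise ValueError(
                f"only {len(present)}/{len(self.genes)} model genes present in cohort"
            )
        x = np.zeros((expr.shape[1], len(self.genes)))
        idx = {g: i for i, g in enumerate(self.genes)}
        for g in present:
            i = idx[g]
            x[:, i] = (expr.loc[g].to_numpy() - self.center[i]) / self.scale[i]
        return pd.Series(x @ self.coef + self.intercept, index=expr.columns)


@dataclass
class DrugResponseEstimate:
    """Estimated AUC per sample x compound, with per-compound model metadata."""

    estimates: pd.DataFrame  # samples x compounds
    models: dict[str, RidgeModel]


def prep_panel(
    panel: DrugPanel, na_threshold: float = 0.2, knn_k: int = 10
) -> DrugPanel:
    """Lineage exclusion, missingness filter and KNN imputation.

    Haematopoietic/lymphoid cell lines are removed; compounds missing in
    more than ``na_threshold`` of the remaining lines are dropped; leftover
    missing cells are imputed by averaging the ``knn_k`` nearest compound
    profiles (Euclidean distance on co-observed AUCs).  Idempotent.
    """
    keep_ccl = [
        c
        for c in panel.auc.index
        if panel.ccl_meta.get(c) not in EXCLUDED_LINEAGES
        and c in set(panel.ccl_expr.samples)
    ]
    auc = panel.auc.loc[keep_ccl]
    na_frac = auc.isna().mean(axis=0)
    dropped = list(auc.columns[na_frac > na_threshold])
    auc = auc.drop(columns=dropped)
    if auc.isna().all().any():
        bad = auc.columns[auc.isna().all()][0]
        raise ValueError(f"compound {bad!r} has no observed AUC values")
    n_missing = int(auc.isna().sum().sum())
    if n_missing:
        k = min(knn_k, auc.shape[1] - 1)
        if k < knn_k:
            warnings.warn(f"knn_k reduced to {k} (only {auc.shape[1]} compounds)", stacklevel=2)
        # impute over compound profiles: compounds are rows for the imputer
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        auc = pd.DataFrame(
            imputer.fit_transform(auc.T.to_numpy()).T,
            index=auc.index,
            columns=auc.columns,
        )
    expr = ExpressionMatrix(
        panel.ccl_expr.values[keep_ccl], panel.ccl_expr.scale_tag, panel.ccl_expr.sample_meta
    )
    return DrugPanel(
        expr,
        auc,
        panel.ccl_meta.loc[keep_ccl],
        prep_report={
            "n_ccl": len(keep_ccl),
            "n_ccl_excluded_lineage": int(len(panel.auc.index) - len(keep_ccl)),
            "compounds_dropped_na": dropped,
            "n_imputed_cells": n_missing,
        },
    )


def train_ridge(
    panel: DrugPanel,
    compound: str,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    genes: list[str] | None = None,
) -> RidgeModel:
    """Fit an expression->AUC ridge model for one compound.

    Predictors are standardized on the training cell lines; the penalty is
    chosen from ``lambda_grid`` by ``cv_folds``-fold CV minimizing mean
    squared error.  ``genes`` restricts predictors (e.g. to the gene set
    shared with the target cohort).
    """
    if compound not in panel.auc.columns:
        raise KeyError(f"unknown compound {compound!r}")
    y_all = panel.auc[compound].dropna()
    ccls = [c for c in panel.ccl_expr.samples if c in y_all.index]
    if len(ccls) < 20:
        raise ValueError(f"only {len(ccls)} cell lines with AUC for {compound!r} (< 20)")
    if len(ccls) < cv_folds:
        raise ValueError("fewer cell lines than CV folds")
    use_genes = list(genes) if genes is not None else panel.ccl_expr.genes
    x = panel.ccl_expr.values.loc[use_genes, ccls].to_numpy().T
    y = y_all.loc[ccls].to_numpy()
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - center) / scale

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xs))
    cv_mse = []
    for lam in lambda_grid:
        errs = []
        for tr, te in splits:
            model = Ridge(alpha=lam).fit(xs[tr], y[tr])
            errs.append(float(np.mean((model.predict(xs[te]) - y[te]) ** 2)))
        cv_mse.append(float(np.mean(errs)))
    best = int(np.argmin(cv_mse))
    final = Ridge(alpha=lambda_grid[best]).fit(xs, y)
    return RidgeModel(
        compound=compound,
        genes=use_genes,
        center=center,
        scale=scale,
        coef=final.coef_,
        intercept=float(final.intercept_),
        lam=float(lambda_grid[best]),
        cv_mse=cv_mse[best],
        cv_r2=float(1.0 - cv_mse[best] / max(y.var(), 1e-12)),
    )


def filter_predictive(
    models: dict[str, RidgeModel], min_cv_r2: float = 0.05
) -> dict[str, RidgeModel]:
    """Keep only compounds whose model shows satisfactory CV accuracy.

    Expression carries no signal for many compounds; applying their models
    to tumors would compare structured noise between groups.  The gate is
    cross-validated R^2 > ``min_cv_r2`` (an uninformative model scores about
    zero or below).
    """
    return {name: m for name, m in models.items() if m.cv_r2 > min_cv_r2}


def predict_auc(
    models: dict[str, RidgeModel] | list[RidgeModel],
    clinical_expr: ExpressionMatrix,
) -> DrugResponseEstimate:
    """Estimate per-sample AUC for every compound model on a tumor cohort."""
    if isinstance(models, list):
        models = {m.compound: m for m in models}
    expr = clinical_expr.to_log2().values
    est = pd.DataFrame(
        {name: m.predict(expr) for name, m in models.items()}, index=expr.columns
    )
    if not np.isfinite(est.to_numpy()).all():
        raise ValueError("non-finite drug-response estimate")
    return DrugResponseEstimate(estimates=est, models=dict(models))


def differential_response(
    estimates: DrugResponseEstimate | pd.DataFrame,
    mutation_status: pd.Series,
    compounds: list[str] | None = None,
    alpha: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Mutant-vs-WT comparison of estimated AUC per compound.

    logFC = log2(mean AUC_mutant / mean AUC_WT) on the AUC scale; two-sided
    Wilcoxon rank-sum p.  ``sl_flag`` iff logFC < 0 (mutants more sensitive)
    and p < ``alpha``.
    """
    est = estimates.estimates if isinstance(estimates, DrugResponseEstimate) else estimates
    status = mutation_status.reindex(est.index).dropna()
    mut_samples = status.index[status == 1]
    wt_samples = status.index[status == 0]
    if len(mut_samples) < min_group or len(wt_samples) < min_group:
        raise ValueError(
            f"need >= {min_group} samples per group "
            f"(mutant {len(mut_samples)}, WT {len(wt_samples)})"
        )
    rows = []
    for comp in compounds if compounds is not None else est.columns:
        a = est.loc[mut_samples, comp].to_numpy()
        b = est.loc[wt_samples, comp].to_numpy()
        mean_a, mean_b = a.mean(), b.mean()
        if mean_a <= 0 or mean_b <= 0:
            warnings.warn(
                f"compound {comp!r} skipped: non-positive mean AUC", stacklevel=2
            )
            continue
        logfc = float(np.log2(mean_a / mean_b))
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "compound": comp,
                "logfc": logfc,
                "p_value": p,
                "sl_flag": bool(logfc < 0 and p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=["compound", "logfc", "p_value", "sl_flag"])
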