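"""Elastic-net transcriptome classifier of driver-mutation status.

For cohorts lacking mutation calls, mutation status is predicted from
expression: differentially expressed genes (|log2FC| > 1.5, BH-adjusted
Wilcoxon p < 0.05) feed a binomial elastic net with mixing parameter 0.9,
regularization strength chosen by cross-validated deviance.  Generalization
is measured by leave-one-study-out cross-validation with gene selection
redone inside each fold, so no information from the held-out study leaks
into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnModel",
    "select_de_genes",
    "train_en",
    "loso_cv",
    "roc_auc",
]

DEFAULT_C_GRID = tuple(np.logspace(-2, 2, 9))


@dataclass
class EnModel:
    genes: list[str]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    alpha: float  # elastic-net mixing (1 = lasso, 0 = ridge)
    c: float  # inverse regularization strength at the CV optimum
    seed: int
    cv_folds: int

    def _design(self, expr: pd.DataFrame) -> np.ndarray:
        x = expr.loc[self.genes].to_numpy().T
        return (x - self.center) / self.scale

    def predict_proba(self, expr: pd.DataFrame) -> pd.Series:
        """P(mutant) per sample (columns of ``expr``)."""
        z = self._design(expr) @ self.coef + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=expr.columns)

    def predict(self, expr: pd.DataFrame, cut: float = 0.5) -> pd.Series:
        return (self.predict_proba(expr) >= cut).astype(int)


def select_de_genes(
    expr: pd.DataFrame,
    labels: pd.Series,
    lfc_cut: float = 1.5,
    padj_cut: float = 0.05,
    min_class: int = 5,
) -> list[str]:
    """Genes with |log2FC| > ``lfc_cut`` and BH-adjusted Wilcoxon p < ``padj_cut``.

    Expression must be on the log2(TPM+1) scale; fold change is the
    difference of class means.  Returned in stable gene order.
    """
    lab = labels.reindex(expr.columns)
    pos = expr.columns[lab == 1]
    neg = expr.columns[lab == 0]
    if len(pos) < min_class or len(neg) < min_class:
        raise ValueError(
            f"both classes need >= {min_class} samples (got {len(pos)}/{len(neg)})"
        )
    a = expr[pos].to_numpy()
    b = expr[neg].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    pvals = stats.mannwhitneyu(a, b, alternative="two-sided", axis=1).pvalue
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    keep = (np.abs(lfc) > lfc_cut) & (padj < padj_cut)
    selected = [g for g, k in zip(expr.index, keep) if k]
    if not selected:
        raise ValueError(
            "no genes pass selection; consider relaxing lfc_cut/padj_cut"
        )
    return selected


def train_en(
    expr_selected: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.9,
    cv_folds: int = 10,
    seed: int = 0,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> EnModel:
    """Binomial elastic net at mixing ``alpha``; strength by CV deviance."""
    lab = labels.reindex(expr_selected.columns).to_numpy().astype(int)
    classes = np.unique(lab)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    x = expr_selected.to_numpy().T
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - center) / scale

    n_folds = min(cv_folds, int(np.bincount(lab).min()))
    best_c, best_dev = c_grid[0], np.inf
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(xs, lab))
        for c in c_grid:
            dev = 0.0
            for tr, te in splits:
                m = _fit_en(xs[tr], lab[tr], alpha, c, seed)
                p = _proba(m, xs[te])
                eps = 1e-12
                dev += -2.0 * float(
                    np.sum(lab[te] * np.log(p + eps) + (1 - lab[te]) * np.log(1 - p + eps))
                )
            if dev < best_dev:
                best_dev, best_c = dev, c
    final = _fit_en(xs, lab, alpha, best_c, seed)
    return EnModel(
        genes=list(expr_selected.index),
        center=center,
        scale=scale,
        coef=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        alpha=alpha,
        c=float(best_c),
        seed=seed,
        cv_folds=n_folds,
    )


def _fit_en(x: np.ndarray, y: np.ndarray, alpha: float, c: float, seed: int):
    return LogisticRegression(
        l1_ratio=alpha,
        C=c,
        solver="saga",
        max_iter=5000,
        tol=1e-6,
        random_state=seed,
    ).fit(x, y)


def _proba(model, x: np.ndarray) -> np.ndarray:
    return model.predict_proba(x)[:, 1]


def loso_cv(
    expr: pd.DataFrame,
    labels: pd.Series,
    studies: pd.Series,
    alpha: float = 0.9,
    lfc_cut: float = 1.5,
    padj_cut: float = 0.05,
    cv_folds: int = 10,
    seed: int = 0,
    prob_cut: float = 0.5,
) -> pd.DataFrame:
    """Leave-one-study-out validation with in-fold gene selection.

    For each held-out study the signature is re-selected and the elastic net
    re-trained on the remaining studies only.  Reports per-study accuracy at
    ``prob_cut`` and ROC AUC (NaN when the held-out study has one class).
    """
    studies = studies.reindex(expr.columns)
    study_ids = list(dict.fromkeys(studies))
    if len(study_ids) < 2:
        raise ValueError("leave-one-study-out needs >= 2 studies")
    rows = []
    for held in study_ids:
        te_cols = [c for c in expr.columns if studies[c] == held]
        tr_cols = [c for c in expr.columns if studies[c] != held]
        genes = select_de_genes(
            expr[tr_cols], labels, lfc_cut=lfc_cut, padj_cut=padj_cut
        )
        model = train_en(
            expr.loc[genes, tr_cols], labels, alpha=alpha, cv_folds=cv_folds, seed=seed
        )
        prob = model.predict_proba(expr.loc[genes, te_cols])
        y = labels.reindex(te_cols).to_numpy().astype(int)
        acc = float(((prob >= prob_cut).astype(int).to_numpy() == y).mean())
        auc = roc_auc(prob.to_numpy(), y) if len(np.unique(y)) == 2 else float("nan")
        rows.append(
            {
                "study": held,
                "n_test": len(te_cols),
                "n_genes": len(genes),
                "accuracy": acc,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney U statistic, ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
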