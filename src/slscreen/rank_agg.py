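"""Order-statistics rank aggregation (Stuart method) and the RAS.

Each surviving candidate pair carries one ranking per screening criterion
(functional similarity, fold change, co-expression coefficient, exclusivity
adjusted p).  Normalized ranks r in (0, 1] are treated as order statistics of
i.i.d. uniforms; the Stuart joint probability P(U_(k) <= r_k for all k) says
how surprisingly concordant the pair's rankings are, and the rank aggregation
score RAS = -log2(p) orders the final table (higher = more concordant).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["normalize_ranks", "stuart_pvalue", "ras", "aggregate"]

#: criterion -> whether larger values are better
DEFAULT_DIRECTIONS = {
    "fss": "desc",
    "log2fc": "desc",
    "rho": "desc",
    "mutex_padj": "asc",
}

P_FLOOR = 1e-300


def normalize_ranks(
    score_table: pd.DataFrame, directions: dict[str, str] = DEFAULT_DIRECTIONS
) -> pd.DataFrame:
    """Per-criterion normalized ranks r = rank/n with rank 1 = best.

    Ties receive average ranks.  ``directions`` maps each criterion column to
    'desc' (larger is better) or 'asc' (smaller is better).
    """
    n = len(score_table)
    if n < 1:
        raise ValueError("empty score table")
    out = {}
    for col, direction in directions.items():
        if col not in score_table.columns:
            raise KeyError(f"criterion column {col!r} missing from score table")
        vals = score_table[col]
        if vals.isna().any():
            bad = score_table.index[vals.isna()][0]
            raise ValueError(f"missing {col!r} value for pair {bad!r}")
        v = vals.to_numpy(dtype=float)
        if direction == "desc":
            v = -v
        out[col] = rankdata(v, method="average") / n
    return pd.DataFrame(out, index=score_table.index)


def stuart_pvalue(r: np.ndarray | list[float]) -> float:
    """Joint order-statistic probability P(U_(k) <= r_k, all k) for m uniforms.

    Uses the recursion V_0 = 1,
    V_k = sum_{i=1..k} (-1)^(i-1) (V_{k-i} / i!) r_{m-k+1}^i, p = m! V_m,
    which is numerically stable for the small m (criteria counts) used here.
    Input must be ascending.
    """
    r = np.asarray(r, dtype=float)
    m = len(r)
    if m == 0:
        raise ValueError("empty rank vector")
    if np.any(np.diff(r) < 0):
        raise ValueError("rank vector must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    v = np.zeros(m + 1)
    v[0] = 1.0
    for k in range(1, m + 1):
        acc = 0.0
        x = r[m - k]
        for i in range(1, k + 1):
            acc += (-1) ** (i - 1) * (v[k - i] / math.factorial(i)) * x**i
        v[k] = acc
    p = math.factorial(m) * v[m]
    return float(min(1.0, max(p, 0.0)))


def ras(p: float) -> float:
    """Rank aggregation score: -log2(p); p floored at 1e-300 with a warning."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < P_FLOOR:
        import warnings

        warnings.warn(f"p-value {p} floored at {P_FLOOR}", stacklevel=2)
        p = P_FLOOR
    return -math.log2(p)


def aggregate(
    score_table: pd.DataFrame, directions: dict[str, str] = DEFAULT_DIRECTIONS
) -> pd.DataFrame:
    """Stuart p and RAS per pair, sorted by RAS descending (ties by pair id).

    ``score_table`` is indexed by pair id with one column per criterion.
    """
    ranks = normalize_ranks(score_table, directions)
    recs = []
    for pair_id, row in ranks.iterrows():
        p = stuart_pvalue(np.sort(row.to_numpy()))
        p = max(p, P_FLOOR)
        recs.append({"pair": pair_id, "stuart_p": p, "ras": ras(p)})
    out = pd.DataFrame(recs).sort_values(
        ["ras", "pair"], ascending=[False, True]
    )
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out.set_index("pair")
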