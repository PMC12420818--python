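"""Statistical layer for distance and recruitment measurements.

Distances are compared with a parametric two-tailed unpaired Student's
t-test (pooled variance); recruitment assays across >= 2 conditions use
the non-parametric Kruskal–Wallis test followed by Dunn's post hoc
z-tests on rank means, with Bonferroni adjustment over the planned
(requested) comparisons. Significance stars follow the usual mapping,
with boundary p-values assigned to the weaker category:

    p > 0.05 ns | p < 0.05 * | p < 0.01 ** | p < 0.001 *** | p < 0.0001 ****

Replicate semantics: each cell is a biological replicate for
recruitment assays (per-cell means are tested), while each kinetochore
pair is a replicate for distance measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One hypothesis test: groups, statistic, p, adjusted p, stars."""

    test_name: str
    groups: tuple[str, str] | tuple[str, ...]
    statistic: float
    p_value: float
    adjusted_p: float | None
    stars: str
    n_per_group: dict[str, int]
    degenerate: bool = False


def stars(p: float) -> str:
    """Map a p-value to a significance label.

    Boundary values map to the weaker category (p = 0.05 is ns,
    p = 0.01 is *, ...).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def unpaired_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    labels: tuple[str, str] = ("A", "B"),
) -> StatResult:
    """Two-tailed unpaired Student's t-test (pooled variance).

    Degenerate inputs (zero pooled variance) are handled by convention:
    equal means give p = 1, unequal means give p = 0 with the result
    flagged degenerate.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    n = {labels[0]: a.size, labels[1]: b.size}

    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return StatResult(
                "unpaired_ttest", labels, 0.0, 1.0, None, "ns", n, degenerate=True
            )
        return StatResult(
            "unpaired_ttest",
            labels,
            float("inf") if a.mean() > b.mean() else float("-inf"),
            0.0,
            None,
            "****",
            n,
            degenerate=True,
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return StatResult(
        "unpaired_ttest", labels, float(t), float(p), None, stars(float(p)), n
    )


def _dunn_z(
    rank_means: dict[str, float],
    sizes: dict[str, int],
    n_total: int,
    tie_term: float,
    pair: tuple[str, str],
) -> float:
    """Dunn's z for one pair: rank-mean difference over its SE with tie
    correction, SE^2 = (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j),
    T = sum(t^3 - t) over tied groups."""
    i, j = pair
    var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) * (
        1.0 / sizes[i] + 1.0 / sizes[j]
    )
    return (rank_means[i] - rank_means[j]) / np.sqrt(var)


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
) -> tuple[StatResult, list[StatResult]]:
    """Kruskal–Wallis across all groups plus Dunn's post hoc pairs.

    ``comparisons`` lists the planned pairs (default: every group vs
    the first, matching control-vs-condition reporting); Dunn p-values
    are Bonferroni-adjusted over exactly those comparisons and capped
    at 1. Returns ``(omnibus, posthoc_results)``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=np.float64) for k in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need total n >= 3")
    if comparisons is None:
        comparisons = [(names[0], g) for g in names[1:]]

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p_h = 0.0, 1.0
    else:
        h, p_h = sps.kruskal(*arrays)
    sizes = {k: a.size for k, a in zip(names, arrays)}
    omnibus = StatResult(
        "kruskal_wallis",
        tuple(names),
        float(h),
        float(p_h),
        None,
        stars(float(p_h)),
        sizes,
    )

    # mid-ranks over the pooled sample, shared by all Dunn comparisons
    ranks = sps.rankdata(pooled)
    rank_means: dict[str, float] = {}
    start = 0
    for k, a in zip(names, arrays):
        rank_means[k] = float(ranks[start : start + a.size].mean())
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n_total = pooled.size
    m = len(comparisons)

    results = []
    for pair in comparisons:
        if pooled.size and np.all(pooled == pooled[0]):
            z, p_raw = 0.0, 1.0
        else:
            z = _dunn_z(rank_means, sizes, n_total, tie_term, pair)
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(p_raw * m, 1.0)
        results.append(
            StatResult(
                "dunn",
                pair,
                float(z),
                float(p_raw),
                float(p_adj),
                stars(p_adj),
                {pair[0]: sizes[pair[0]], pair[1]: sizes[pair[1]]},
            )
        )
    return omnibus, results


def replicate_table(
    measurements: pd.DataFrame,
    level: str,
    *,
    value_col: str = "value",
    condition_col: str = "condition",
    cell_col: str = "cell_id",
    pair_col: str = "pair_id",
) -> pd.DataFrame:
    """Aggregate raw measurements to the declared replicate level.

    ``level="cell"``: one row per cell (mean over its kinetochores) —
    the replicate unit for recruitment assays. ``level="kinetochore_pair"``:
    one row per kinetochore pair — the replicate unit for distances.
    """
    df = measurements
    for col in (value_col, condition_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if level == "cell":
        if cell_col not in df.columns:
            raise ValueError(f"missing required column {cell_col!r}")
        out = (
            df.groupby([condition_col, cell_col], sort=False)[value_col]
            .mean()
            .reset_index()
        )
        return out
    if level == "kinetochore_pair":
        cols = [condition_col, value_col]
        if pair_col in df.columns:
            cols.insert(1, pair_col)
        if cell_col in df.columns:
            cols.insert(1, cell_col)
        return df[cols].reset_index(drop=True)
    raise ValueError(f"unknown replicate level {level!r}")
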