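"""Group-level comparison of network metrics across acquisition schemes.

Per-subject metric values under several conditions (sampling schemes) form a
complete block design; differences between conditions at each parcellation
scale are assessed with the nonparametric Friedman test on within-subject
ranks.  For small panels an exact permutation p-value over all (c!)^n
within-subject orderings is also computed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MetricPanel:
    """subjects x conditions values for one metric at one scale."""

    values: np.ndarray
    subject_ids: list[str]
    condition_tags: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("panel must be a 2-D subjects x conditions array")
        if np.isnan(v).any():
            bad = [
                (self.subject_ids[i], self.condition_tags[j])
                for i, j in zip(*np.nonzero(np.isnan(v)))
            ]
            raise ValueError(f"incomplete block design; missing cells: {bad}")
        if v.shape != (len(self.subject_ids), len(self.condition_tags)):
            raise ValueError("panel shape does not match subject/condition lists")
        self.values = v


def _friedman_statistic(values: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a subjects x conditions array."""
    n, c = values.shape
    ranks = sps.rankdata(values, axis=1)  # average ranks on ties
    r_j = ranks.sum(axis=0)
    stat = 12.0 / (n * c * (c + 1)) * (r_j**2).sum() - 3.0 * n * (c + 1)
    # standard tie correction: divide by 1 - sum(t^3 - t)/(n c (c^2 - 1))
    tie_sum = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * c * (c**2 - 1))
    if correction == 0.0:  # every row fully tied
        return 0.0
    return stat / correction


def friedman_test(
    panel: MetricPanel, exact_max_cells: int = 12
) -> dict:
    """Friedman test for condition differences in a complete block design.

    Returns the tie-corrected chi-square statistic, degrees of freedom c - 1,
    the asymptotic chi-square upper-tail p-value, and — when the panel has at
    most ``exact_max_cells`` cells — an exact permutation p-value enumerating
    all (c!)^n equally likely within-subject orderings.
    """
    n, c = panel.values.shape
    if n < 2:
        raise ValueError(f"need >= 2 subjects, got {n}")
    if c < 2:
        raise ValueError(f"need >= 2 conditions, got {c}")
    stat = _friedman_statistic(panel.values)
    df = c - 1
    p_asymptotic = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    out = {
        "statistic": stat,
        "df": df,
        "p_asymptotic": p_asymptotic,
        "n_subjects": n,
        "n_conditions": c,
        "p_exact": None,
    }
    if n * c <= exact_max_cells:
        out["p_exact"] = _exact_permutation_p(panel.values, stat)
    return out


def _exact_permutation_p(values: np.ndarray, observed: float) -> float:
    """Exhaustive permutation p: share of all within-subject orderings whose
    statistic is at least the observed one (includes the identity).

    Permuting a row permutes its ranks and leaves the tie correction
    unchanged, so only column rank sums need enumerating.
    """
    n, c = values.shape
    ranks = sps.rankdata(values, axis=1)
    perms = np.array(list(itertools.permutations(range(c))))
    tie_sum = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * c * (c**2 - 1))
    if correction == 0.0:
        return 1.0
    # accumulate column rank sums over the cartesian product of row orderings
    sums = ranks[0][perms]
    for i in range(1, n):
        sums = (sums[:, None, :] + ranks[i][perms][None, :, :]).reshape(-1, c)
    stats_all = (
        12.0 / (n * c * (c + 1)) * (sums**2).sum(axis=1) - 3.0 * n * (c + 1)
    ) / correction
    return float((stats_all >= observed - 1e-12).mean())


def compare_conditions(
    records: pd.DataFrame,
    metrics: list[str] | None = None,
    condition_col: str = "scheme",
    block_col: str = "scale",
    subject_col: str = "subject_id",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """One Friedman test per metric per scale across schemes.

    ``records`` holds one row per analyzed network with tag columns and
    metric columns.  Every (scale) group must contain the same subjects under
    every scheme (complete blocks).  Rows are flagged significant at
    ``alpha`` on the asymptotic p (per-comparison by default; an optional
    Bonferroni correction divides alpha by the number of tests).
    """
    if metrics is None:
        tag_cols = {condition_col, block_col, subject_col}
        metrics = [
            col
            for col in records.columns
            if col not in tag_cols and pd.api.types.is_numeric_dtype(records[col])
        ]
    rows = []
    for scale, group in records.groupby(block_col):
        conditions = sorted(group[condition_col].unique())
        if len(conditions) < 2:
            raise ValueError(
                f"scale {scale}: need >= 2 conditions, got {conditions}"
            )
        subjects = sorted(group[subject_col].unique())
        missing = [
            (s, cond)
            for s in subjects
            for cond in conditions
            if not (
                (group[subject_col] == s) & (group[condition_col] == cond)
            ).any()
        ]
        if missing:
            raise ValueError(
                f"scale {scale}: unbalanced design; missing (subject, "
                f"scheme) pairs: {missing}"
            )
        for metric in metrics:
            pivot = group.pivot_table(
                index=subject_col, columns=condition_col, values=metric
            ).loc[subjects, conditions]
            panel = MetricPanel(
                pivot.to_numpy(), list(pivot.index), list(pivot.columns)
            )
            res = friedman_test(panel)
            rows.append(
                {
                    "metric": metric,
                    block_col: scale,
                    "chi2": res["statistic"],
                    "df": res["df"],
                    "p": res["p_asymptotic"],
                    "p_exact": res["p_exact"],
                }
            )
    table = pd.DataFrame(rows)
    threshold = alpha / len(table) if bonferroni and len(table) else alpha
    table["significant"] = table["p"] < threshold
    return table
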