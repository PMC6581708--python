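"""Two-group comparison of the temporal parameters.

For every (parameter, class) cell a two-tailed Mann-Whitney-Wilcoxon
test compares the two groups; p-values are then corrected for multiple
comparisons with the Benjamini-Hochberg false-discovery-rate step-up,
applied *within each parameter's family of classes* (one family per
temporal parameter), at a 5% significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .params import PARAMETER_NAMES, SubjectParameters

EXACT_MAX_N = 12  # exact MWW enumeration up to this combined sample size


def mann_whitney_two_tailed(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, returning ``(U, p)``.

    ``method='auto'`` uses the exact null enumeration when the combined
    sample size is at most 12 and there are no ties, and the normal
    approximation with tie and continuity corrections otherwise.  ``U``
    is the number of ``(x_i, y_j)`` pairs won by ``x`` (ties count 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if method == "auto":
        method = "exact" if (x.size + y.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Adjusted values are monotone (each is the minimum of ``m/j * p_(j)``
    over larger ranks) and never smaller than the raw values; flags mark
    adjusted values at or below ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adj, reject


@dataclass
class GroupStats:
    """Per-cell group summary: means, SDs, U, raw and corrected p."""

    table: pd.DataFrame  # MultiIndex (parameter, class)
    groups: tuple[str, str]
    alpha: float

    def cell(self, parameter: str, label) -> pd.Series:
        return self.table.loc[(parameter, label)]


def build_table(
    subjects: list[SubjectParameters],
    alpha: float = 0.05,
    method: str = "auto",
) -> GroupStats:
    """The group-comparison table over all parameters and classes.

    Requires exactly two group levels with at least two subjects each.
    Subjects missing a value for a cell (class never observed) are
    dropped from that cell's test.  FDR correction is applied within
    each parameter's family of classes.
    """
    groups = sorted({s.group for s in subjects})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    for g in groups:
        if sum(1 for s in subjects if s.group == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    classes = sorted(subjects[0].table.index)

    rows = {}
    for param in PARAMETER_NAMES:
        for u in classes:
            x = np.array(
                [s.value(param, u) for s in subjects if s.group == g1], dtype=float
            )
            y = np.array(
                [s.value(param, u) for s in subjects if s.group == g2], dtype=float
            )
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            if x.size >= 1 and y.size >= 1:
                u_stat, p = mann_whitney_two_tailed(x, y, method=method)
            else:
                u_stat, p = float("nan"), float("nan")
            rows[(param, u)] = {
                f"mean_{g1}": float(np.mean(x)) if x.size else float("nan"),
                f"sd_{g1}": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
                f"mean_{g2}": float(np.mean(y)) if y.size else float("nan"),
                f"sd_{g2}": float(np.std(y, ddof=1)) if y.size > 1 else float("nan"),
                "U": u_stat,
                "p": p,
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["parameter", "class"])

    table["p_fdr"] = np.nan
    table["significant"] = False
    for param in PARAMETER_NAMES:
        fam = table.loc[param]
        ok = fam["p"].notna()
        if ok.any():
            adj, rej = fdr_bh(fam.loc[ok, "p"].to_numpy(), alpha=alpha)
            table.loc[
                [(param, u) for u in fam.index[ok]], "p_fdr"
            ] = adj
            table.loc[
                [(param, u) for u in fam.index[ok]], "significant"
            ] = rej
    return GroupStats(table=table, groups=(g1, g2), alpha=alpha)
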