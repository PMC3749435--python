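"""Group-level comparison of preprocessing grades.

Nonparametric repeated-measures tests: a related-samples Friedman test
(with midrank tie correction) as the main effect, pairwise Wilcoxon
signed-rank tests between adjacent grades as post-hocs, and step-down
Bonferroni-Holm correction over the whole family of tests within a
cohort.  Node metrics that are unobservable for a subject (e.g. the node
region falls inside a lesion) are imputed to the group median before
testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "friedman_test",
    "wilcoxon_signed_rank",
    "holm_correction",
    "impute_median",
    "grade_comparison_report",
]


def friedman_test(table) -> tuple:
    """Related-samples Friedman test with midrank tie correction.

    Parameters
    ----------
    table : (n subjects x k grades) array, no missing cells.

    Returns
    -------
    (chi2, p) — the tie-corrected statistic and its p-value from the
    chi-square distribution with k - 1 degrees of freedom.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("table must be 2-D (subjects x grades)")
    n, k = tab.shape
    if n < 2 or k < 3:
        raise ValueError("need at least 2 subjects and 3 grades")
    if np.isnan(tab).any():
        raise ValueError("missing cells; impute first")
    ranks = np.apply_along_axis(stats.rankdata, 1, tab)  # midranks
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:       # all rows entirely tied
        return 0.0, 1.0
    chi2 = float(numer / denom)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


def _signed_rank_exact_sf_table(ranks2: np.ndarray) -> np.ndarray:
    """Exact distribution of the positive rank sum by dynamic programming.

    ``ranks2`` are the midranks doubled so they are integers.  Returns the
    probability mass over all achievable doubled sums (index = sum).
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist / dist.sum()


def wilcoxon_signed_rank(x, y) -> tuple:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties in |d| get midranks.  The p-value
    is exact (full enumeration of sign assignments via dynamic
    programming) for n <= 25 nonzero differences, and a normal
    approximation with continuity and tie correction otherwise.

    Returns ``(W, p)`` with W the positive-rank sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_exact_sf_table(ranks2)
        w2 = int(round(2 * w_pos))
        p_low = dist[: w2 + 1].sum()
        p_high = dist[w2:].sum()
        p = float(min(1.0, 2.0 * min(p_low, p_high)))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0  # over tie-group sizes
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_pos, p


def holm_correction(p_values, alpha: float = 0.05):
    """Step-down Bonferroni-Holm adjustment.

    Returns ``(adjusted, reject)`` in the input order.  Adjusted values
    are ``max_{j<=i} (m - j + 1) p_(j)`` over the ascending sort, clipped
    at 1, which makes them monotone along the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def impute_median(metric_table) -> np.ndarray:
    """Replace missing (NaN) cells by the column-wise observed median.

    ``metric_table`` is subjects x items; every item must have at least
    one observed value.
    """
    tab = np.array(metric_table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("metric_table must be 2-D (subjects x items)")
    for j in range(tab.shape[1]):
        col = tab[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise ValueError(f"item {j} has no observed values")
        if miss.any():
            col[miss] = np.median(col[~miss])
    return tab


ADJACENT_PAIRS = ((0, 1), (1, 2), (2, 3), (3, 4))
PAIR_LABELS = ("P1-P2", "P2-P3", "P3-P4", "P4-P5")


def grade_comparison_report(metrics: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Friedman main effects plus adjacent-grade Wilcoxon post-hocs.

    Parameters
    ----------
    metrics : dict of str -> (n subjects x 5 grades) arrays
        One entry per detectability metric; NaN cells are imputed to the
        per-grade group median first.
    alpha : float
        Family-wise significance level.

    The Holm family is *all* Friedman and performed Wilcoxon tests
    jointly (one cohort per call).  Post-hoc tests are run only for
    metrics whose Friedman main effect survives a provisional Holm pass
    over the main effects; the final adjustment is then recomputed over
    the complete family.
    """
    if not metrics:
        raise ValueError("no metrics supplied")
    tables = {}
    for name, tab in metrics.items():
        tab = impute_median(tab)
        if tab.shape[0] < 6:
            raise ValueError(f"metric {name}: need at least 6 subjects")
        if tab.shape[1] != 5:
            raise ValueError(f"metric {name}: expected 5 grades (P1-P5)")
        tables[name] = tab

    main = {name: friedman_test(tab) for name, tab in tables.items()}
    main_p = {name: p for name, (_, p) in main.items()}
    adj0, _ = holm_correction(list(main_p.values()), alpha)
    run_posthoc = {name: a <= alpha for name, a in zip(main_p, adj0)}

    family_labels, family_p = [], []
    for name, p in main_p.items():
        family_labels.append(("friedman", name))
        family_p.append(p)
    posthoc_raw = {}
    for name, tab in tables.items():
        if not run_posthoc[name]:
            continue
        for (i, j), lab in zip(ADJACENT_PAIRS, PAIR_LABELS):
            try:
                _, p = wilcoxon_signed_rank(tab[:, i], tab[:, j])
            except ValueError:
                p = 1.0
            posthoc_raw[(name, lab)] = p
            family_labels.append(("wilcoxon", (name, lab)))
            family_p.append(p)

    adjusted, reject = holm_correction(family_p, alpha)
    adj = {lab: (a, r) for lab, a, r in zip(family_labels, adjusted, reject)}

    rows = []
    for name, tab in tables.items():
        chi2, p = main[name]
        row = {
            "metric": name,
            "chi2": chi2,
            "p_main": p,
            "p_main_holm": adj[("friedman", name)][0],
            "main_significant": bool(adj[("friedman", name)][1]),
        }
        for lab in PAIR_LABELS:
            key = (name, lab)
            if key in posthoc_raw:
                row[f"p_{lab}"] = posthoc_raw[key]
                row[f"p_{lab}_holm"] = adj[("wilcoxon", key)][0]
            else:
                row[f"p_{lab}"] = np.nan
                row[f"p_{lab}_holm"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
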