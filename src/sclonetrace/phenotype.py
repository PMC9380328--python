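"""Genotype-phenotype integration: differential expression between
mutation-defined cell groups and marker-positive cell fractions.

Differential expression is a two-sided Wilcoxon rank-sum test on
log2(TPM+1), restricted to genes whose absolute mean difference between
the groups reaches a fold threshold (default 1.5 on the log2 scale, the
convention of the cited single-cell toolkits), with Benjamini-Hochberg
correction over the tested genes. Marker positivity is log2(TPM+1)
strictly above a cutoff (default 1; a multi-marker query requires every
marker, i.e. double-positivity), compared between regions by Fisher's
exact test on the 2x2 positive/negative counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["deg_test", "marker_positive_fraction", "MarkerFractionReport"]

DEG_THRESHOLD = 1.5
DEG_ALPHA = 0.05
POSITIVE_CUTOFF = 1.0


def _check_groups(index: pd.Index, groupA, groupB) -> tuple[pd.Index, pd.Index]:
    A, B = pd.Index(groupA), pd.Index(groupB)
    overlap = A.intersection(B)
    if len(overlap):
        raise ValueError(f"groups overlap in {len(overlap)} cells, "
                         f"e.g. {list(overlap[:3])}")
    for name, g in (("A", A), ("B", B)):
        missing = g.difference(index)
        if len(missing):
            raise ValueError(f"group {name} cells absent from matrix: "
                             f"{list(missing[:3])}")
        if len(g) < 3:
            raise ValueError(f"group {name} has {len(g)} cells; need >= 3")
    return A, B


def deg_test(log_expr: pd.DataFrame, groupA, groupB,
             threshold: float = DEG_THRESHOLD,
             alpha: float = DEG_ALPHA) -> pd.DataFrame:
    """Differential expression between two disjoint cell groups.

    Parameters
    ----------
    log_expr
        cells x genes log2(TPM+1).
    groupA, groupB
        Disjoint cell-id sets, each of size >= 3.
    threshold
        Minimum absolute mean log2(TPM+1) difference for a gene to be
        tested (pre-filtering before multiple-testing correction).

    Returns a table sorted by p-value with columns ``mean_diff`` (A minus
    B), ``statistic``, ``pvalue``, ``qvalue`` (BH over tested genes),
    ``direction`` (up = higher in A) and ``significant`` (q < ``alpha``).
    """
    A, B = _check_groups(log_expr.index, groupA, groupB)
    XA = log_expr.loc[A].to_numpy(dtype=float)
    XB = log_expr.loc[B].to_numpy(dtype=float)
    diff = XA.mean(axis=0) - XB.mean(axis=0)
    tested = np.flatnonzero(np.abs(diff) >= threshold)

    rows = []
    for g in tested:
        a, b = XA[:, g], XB[:, g]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue  # no variation at all: the test is undefined
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        rows.append((log_expr.columns[g], diff[g], float(res.statistic),
                     float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["gene", "mean_diff", "statistic",
                                        "pvalue"]).set_index("gene")
    if len(table):
        table["qvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
        table["direction"] = np.where(table["mean_diff"] > 0, "up", "down")
        table["significant"] = table["qvalue"] < alpha
        # stable sort after an index sort: p-value ties break by gene id
        table = table.sort_index().sort_values("pvalue", kind="mergesort")
    else:
        table["qvalue"] = pd.Series(dtype=float)
        table["direction"] = pd.Series(dtype=object)
        table["significant"] = pd.Series(dtype=bool)
    return table


@dataclass
class MarkerFractionReport:
    fractions: pd.DataFrame     # per group: n_cells, n_positive, fraction
    comparisons: pd.DataFrame   # pairwise: group_a, group_b, odds_ratio,
                                # pvalue, qvalue, significant


def marker_positive_fraction(log_expr: pd.DataFrame, markers,
                             groups: pd.Series,
                             positive_cutoff: float = POSITIVE_CUTOFF,
                             alpha: float = DEG_ALPHA,
                             ) -> MarkerFractionReport:
    """Fraction of marker-positive cells per group with exact pairwise tests.

    A cell is positive when log2(TPM+1) > ``positive_cutoff`` for **every**
    gene in ``markers`` (double-positivity for two markers). ``groups``
    maps cell id -> region/group label. Pairwise comparisons use Fisher's
    exact test on the 2x2 positive/negative table, BH-corrected; a single
    group yields fractions only.
    """
    markers = [markers] if isinstance(markers, str) else list(markers)
    missing = [m for m in markers if m not in log_expr.columns]
    if missing:
        raise ValueError(f"marker gene(s) absent from matrix: {missing}")
    cells = log_expr.index.intersection(groups.index)
    pos = (log_expr.loc[cells, markers].to_numpy() > positive_cutoff).all(axis=1)
    positive = pd.Series(pos, index=cells)

    frows = []
    for label in pd.unique(groups.loc[cells]):
        members = cells[groups.loc[cells] == label]
        frows.append({"group": label, "n_cells": len(members),
                      "n_positive": int(positive.loc[members].sum()),
                      "fraction": float(positive.loc[members].mean())})
    fractions = pd.DataFrame(frows).set_index("group")

    crows = []
    for a, b in combinations(fractions.index, 2):
        ka, na = fractions.loc[a, "n_positive"], fractions.loc[a, "n_cells"]
        kb, nb = fractions.loc[b, "n_positive"], fractions.loc[b, "n_cells"]
        odds, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
        crows.append({"group_a": a, "group_b": b, "odds_ratio": float(odds),
                      "pvalue": float(p)})
    comparisons = pd.DataFrame(
        crows, columns=["group_a", "group_b", "odds_ratio", "pvalue"])
    if len(comparisons):
        comparisons["qvalue"] = multipletests(comparisons["pvalue"],
                                              method="fdr_bh")[1]
        comparisons["significant"] = comparisons["qvalue"] < alpha
    else:
        comparisons["qvalue"] = pd.Series(dtype=float)
        comparisons["significant"] = pd.Series(dtype=bool)
    return MarkerFractionReport(fractions=fractions, comparisons=comparisons)
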