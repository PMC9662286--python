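"""Nonparametric group comparisons for cost-effectiveness summaries.

Kruskal–Wallis across groups, Dunn's post hoc pairwise tests with the
tie-corrected z statistic, Holm step-down adjustment of the pairwise
p-values, and a compact letter display (groups sharing a letter are not
significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class KruskalDunnReport:
    """Omnibus and pairwise results plus compact letter display."""

    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, p_raw, p_holm
    letters: Dict[str, str]  # group -> letter string

    def significant_pairs(self, alpha: float = 0.05) -> List[tuple]:
        sig = self.pairwise[self.pairwise["p_holm"] < alpha]
        return list(zip(sig["group1"], sig["group2"]))


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray, groups: List) -> pd.DataFrame:
    n = values.size
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    counts = {g: int((labels == g).sum()) for g in groups}
    # tie correction for the variance of mean-rank differences
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for g1, g2 in combinations(groups, 2):
        se = np.sqrt(base_var * (1.0 / counts[g1] + 1.0 / counts[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def _compact_letters(groups: List, sig_pairs: List[tuple]) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter set holding every group and splits sets that
    contain a significantly different pair; letters are assigned a, b, c…
    Groups sharing at least one letter are not significantly different.
    """
    sets: List[set] = [set(groups)]
    for g1, g2 in sig_pairs:
        new_sets: List[set] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s
            for i, s in enumerate(new_sets)
            if not any(i != j and s < t for j, t in enumerate(new_sets))
        ]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    # order sets by the first group they contain for stable letters
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def kruskal_dunn(values, groups, alpha: float = 0.05) -> KruskalDunnReport:
    """Kruskal–Wallis omnibus test with Dunn/Holm post hoc comparisons.

    ``values`` and ``groups`` are equal-length 1-D sequences; NaNs are
    dropped.  Requires at least two groups with at least two observations
    each.  When every value is tied the omnibus is H = 0, p = 1 and all
    groups share one letter.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    if np.unique(values).size == 1:  # all tied: no variation at all
        h, p = 0.0, 1.0
        pw = pd.DataFrame(
            [
                {"group1": g1, "group2": g2, "z": 0.0, "p_raw": 1.0}
                for g1, g2 in combinations(uniq, 2)
            ]
        )
    else:
        h, p = sps.kruskal(*[values[labels == g] for g in uniq])
        pw = _dunn_pairwise(values, labels, uniq)

    pw["p_holm"] = holm_adjust(pw["p_raw"].to_numpy())
    sig_pairs = list(
        zip(pw.loc[pw["p_holm"] < alpha, "group1"], pw.loc[pw["p_holm"] < alpha, "group2"])
    )
    letters = _compact_letters(uniq, sig_pairs)
    return KruskalDunnReport(
        h_statistic=float(h), p_value=float(p), pairwise=pw, letters=letters
    )
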