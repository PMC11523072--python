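"""Cross-force-field comparison statistics on violation-fraction tables.

Each simulation (compound x solvent) scores each method (force field)
with a fraction of NOE violations in [0, 1]. Methods are compared with
a Friedman omnibus test on the complete rows, followed by pairwise
two-sided Wilcoxon signed-rank tests; p-values are reported raw (no
multiplicity adjustment by default, Holm available as an option).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FractionTable",
    "overall_fraction",
    "friedman_test",
    "pairwise_wilcoxon",
    "compare_report",
]

#: Exact Wilcoxon null enumeration is used up to this many nonzero
#: differences; the tie-corrected normal approximation above.
WILCOXON_EXACT_MAX_N = 25


@dataclass
class FractionTable:
    """Rows = simulations, columns = methods, entries = violation fractions."""

    data: pd.DataFrame

    def __post_init__(self):
        self.data = pd.DataFrame(self.data).astype(float)
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 methods (columns)")
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "FractionTable":
        """Read a long-format TSV with columns: row id, method, value."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.strip() for c in df.columns]
        idx, method, value = df.columns[:3]
        return cls(df.pivot(index=idx, columns=method, values=value))

    @property
    def methods(self) -> list[str]:
        return list(self.data.columns)

    def complete_rows(self) -> pd.DataFrame:
        """Rows without missing entries (listwise deletion)."""
        return self.data.dropna(axis=0)


def overall_fraction(table: FractionTable, method: str) -> float:
    """Unweighted mean violation fraction of one method over its available rows."""
    col = table.data[method].dropna()
    if col.empty:
        raise ValueError(f"method {method!r} has no entries")
    return float(col.mean())


def friedman_test(table: FractionTable):
    """Friedman rank test over complete rows; returns (statistic, p).

    Rows with any missing entry are dropped first (e.g. a compound that
    could not be parametrized with one force field). Ties within a row
    receive average ranks; the chi-square approximation includes the
    standard tie correction.
    """
    if len(table.methods) < 3:
        raise ValueError("Friedman test needs at least 3 methods")
    rows = table.complete_rows()
    if len(rows) < 2:
        raise ValueError(f"only {len(rows)} complete rows; need at least 2")
    cols = [rows[m].to_numpy() for m in table.methods]
    if all(np.ptp(np.vstack(cols), axis=0) == 0):
        return 0.0, 1.0  # every row fully tied; scipy rejects this degenerate case
    stat, p = stats.friedmanchisquare(*cols)
    return float(stat), float(p)


def _wilcoxon_exact_p(d):
    """Exact two-sided signed-rank p over the 2^n sign-flip null.

    Average ranks are used for tied |differences|; the null distribution
    of W+ is built by dynamic programming over doubled ranks (integers),
    equivalent to full sign-pattern enumeration. The two-sided p is
    2 * min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    ranks2 = np.rint(2.0 * stats.rankdata(np.abs(d))).astype(int)
    w_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    lo = dist[:w_obs + 1].sum()
    hi = dist[w_obs:].sum()
    return min(1.0, 2.0 * min(lo, hi))


def _wilcoxon(x, y):
    """Two-sided signed-rank p-value with zero-differences dropped."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, True  # degenerate: identical paired samples
    if d.size <= WILCOXON_EXACT_MAX_N:
        return _wilcoxon_exact_p(d), False
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method="approx")
    return float(res.pvalue), False


def pairwise_wilcoxon(table: FractionTable, alpha: float = 0.05,
                      holm: bool = False):
    """All-pairs two-sided Wilcoxon signed-rank tests.

    Pairwise deletion: each pair uses the rows where both methods have a
    value. Returns a dict with a symmetric p-value DataFrame, boolean
    significance flags (p < alpha) and the list of degenerate pairs
    (all differences zero, reported as p = 1).
    """
    methods = table.methods
    p = pd.DataFrame(np.nan, index=methods, columns=methods)
    degenerate = []
    raw = {}
    for a, b in itertools.combinations(methods, 2):
        sub = table.data[[a, b]].dropna()
        pval, degen = _wilcoxon(sub[a], sub[b])
        raw[(a, b)] = pval
        if degen:
            degenerate.append((a, b))
    if holm and raw:
        order = sorted(raw, key=raw.get)
        m = len(order)
        adj_prev = 0.0
        for rank, key in enumerate(order):
            adj = min(1.0, max(adj_prev, (m - rank) * raw[key]))
            raw[key] = adj
            adj_prev = adj
    for (a, b), pval in raw.items():
        p.loc[a, b] = p.loc[b, a] = pval
    np.fill_diagonal(p.values, 1.0)
    return {
        "p_values": p,
        "significant": p < alpha,
        "degenerate_pairs": degenerate,
        "alpha": alpha,
    }


def compare_report(table: FractionTable, alpha: float = 0.05, holm: bool = False) -> dict:
    """Overall means + Friedman omnibus + pairwise Wilcoxon, as one JSON-able dict."""
    stat, p = friedman_test(table)
    pw = pairwise_wilcoxon(table, alpha=alpha, holm=holm)
    return {
        "overall_fractions": {m: overall_fraction(table, m) for m in table.methods},
        "friedman": {"statistic": stat, "p_value": p,
                     "n_rows": int(len(table.complete_rows()))},
        "wilcoxon_p": {f"{a}|{b}": float(pw["p_values"].loc[a, b])
                       for a, b in itertools.combinations(table.methods, 2)},
        "significant_pairs": [
            f"{a}|{b}" for a, b in itertools.combinations(table.methods, 2)
            if bool(pw["significant"].loc[a, b])],
        "alpha": alpha,
    }
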