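"""One-way ANOVA across methods' fold AUROCs and Bonferroni post-hoc pairs.

Post-hoc tests use the pooled-error t statistic
``t = (m_i - m_j) / sqrt(MS_within * (1/n_i + 1/n_j))`` on ``N - k`` degrees
of freedom, with two-sided p-values multiplied by the number of unordered
pairs and capped at 1 (the SPSS "Bonferroni" convention).

Caveat: fold AUROCs from a shared cross-validation partition are treated as
independent observations, which inflates significance.  This mirrors common
reporting practice; correlated-fold corrections are deliberately not applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairwiseTable", "one_way_anova", "posthoc_bonferroni"]


@dataclass(frozen=True)
class PairwiseTable:
    """Raw and Bonferroni-adjusted p-values for all unordered group pairs."""

    names: tuple[str, ...]
    raw_p: dict[tuple[str, str], float]
    adjusted_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    anova_f: float
    anova_p: float
    alpha: float = 0.05

    @property
    def n_pairs(self) -> int:
        return len(self.raw_p)

    def _lookup(self, table: dict, a: str, b: str) -> float:
        if a == b:
            raise KeyError("diagonal entries are undefined")
        return table[(a, b)] if (a, b) in table else table[(b, a)]

    def raw(self, a: str, b: str) -> float:
        return self._lookup(self.raw_p, a, b)

    def adjusted(self, a: str, b: str) -> float:
        return self._lookup(self.adjusted_p, a, b)

    def is_significant(self, a: str, b: str) -> bool:
        return self._lookup(self.significant, a, b)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"method_a": a, "method_b": b,
                 "p_raw": self.raw_p[(a, b)],
                 "p_bonferroni": self.adjusted_p[(a, b)],
                 "significant": self.significant[(a, b)]}
                for (a, b) in self.raw_p]
        return pd.DataFrame(rows)

    def format_triangle(self) -> str:
        """Upper-triangular text table; significant cells marked with '*'."""
        width = max(max(len(n) for n in self.names), 8) + 2
        lines = [" " * width + "".join(n.rjust(width) for n in self.names[1:])]
        for i, a in enumerate(self.names[:-1]):
            cells = []
            for b in self.names[1:]:
                j = self.names.index(b)
                if j <= i:
                    cells.append(" " * width)
                else:
                    p = self.adjusted(a, b)
                    mark = "*" if self.is_significant(a, b) else " "
                    cells.append(f"{p:.3f}{mark}".rjust(width))
            lines.append(a.ljust(width) + "".join(cells))
        return "\n".join(lines)


def _group_arrays(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.ndim != 1 or g.size < 2:
            raise ValueError("each group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    return arrays


def _sums_of_squares(arrays: list[np.ndarray]):
    all_values = np.concatenate(arrays)
    grand_mean = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand_mean) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    k = len(arrays)
    n_total = all_values.size
    return ss_between, ss_within, k - 1, n_total - k


def one_way_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: returns ``(F, p)``.

    ``F = MS_between / MS_within`` on ``(k - 1, N - k)`` degrees of freedom.
    Zero within-group variance with unequal means gives ``(inf, 0.0)``;
    all values identical raises (F undefined).
    """
    arrays = _group_arrays(groups)
    ss_b, ss_w, df_b, df_w = _sums_of_squares(arrays)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ms_b == 0.0:
            raise ValueError("all values identical: F statistic undefined")
        return float("inf"), 0.0
    f_stat = ms_b / ms_w
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p


def posthoc_bonferroni(groups, alpha: float = 0.05,
                       names: list[str] | None = None) -> PairwiseTable:
    """Bonferroni-corrected pooled-error pairwise t tests after ANOVA."""
    arrays = _group_arrays(groups)
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("names must match the number of groups")

    anova_f, anova_p = one_way_anova(arrays)
    _, ss_w, _, df_w = _sums_of_squares(arrays)
    ms_w = ss_w / df_w
    n_pairs = len(arrays) * (len(arrays) - 1) // 2

    raw: dict[tuple[str, str], float] = {}
    adj: dict[tuple[str, str], float] = {}
    sig: dict[tuple[str, str], bool] = {}
    for i, j in combinations(range(len(arrays)), 2):
        gi, gj = arrays[i], arrays[j]
        diff = gi.mean() - gj.mean()
        if ms_w == 0.0:
            p = 0.0 if diff != 0.0 else 1.0
        else:
            se = np.sqrt(ms_w * (1.0 / gi.size + 1.0 / gj.size))
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), df_w))
        key = (names[i], names[j])
        raw[key] = p
        adj[key] = min(1.0, p * n_pairs)
        sig[key] = adj[key] < alpha
    return PairwiseTable(names=tuple(names), raw_p=raw, adjusted_p=adj,
                         significant=sig, anova_f=anova_f, anova_p=anova_p,
                         alpha=alpha)
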