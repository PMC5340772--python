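"""Normality-gated test selection and group comparisons at alpha = 0.05.

The gate applies the Anderson-Darling normality test to every group; if ANY
group rejects at the 5% level the nonparametric branch is taken (Wilcoxon
signed-rank / rank-sum, Kruskal-Wallis omnibus with Tukey-type pairwise
comparisons on rank-transformed data), otherwise parametric tests are used
(Student's t, one-way or repeated-measures ANOVA, Tukey HSD post hoc).
Post-hoc results are reported only when the omnibus test is significant and
there are more than two levels.

Tukey-type comparisons after Kruskal-Wallis are nonstandard; here they are
Tukey HSD applied to pooled ranks, which reproduces the chi-square omnibus +
Tukey-pairs reporting pattern while staying rank-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "ComparisonDesign",
    "StatOutcome",
    "normality_gate",
    "compare",
    "grid_compare",
    "typeI_calibration",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonDesign:
    """Layout of a comparison: factor levels and pairing structure."""

    levels: tuple[str, ...]
    paired: bool = False
    response: str = "value"

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("need >= 2 factor levels")


@dataclass
class StatOutcome:
    """Result of a gated comparison."""

    gate_result: str                      # "parametric" | "nonparametric"
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    posthoc: list[tuple[str, float]] = field(default_factory=list)
    alpha: float = ALPHA
    degenerate_groups: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_frame(self) -> pd.DataFrame:
        rows = [{"comparison": "omnibus", "gate": self.gate_result, "test": self.test_name,
                 "statistic": self.statistic, "p": self.p_value,
                 "significant": self.significant}]
        for pair, p in self.posthoc:
            rows.append({"comparison": pair, "gate": self.gate_result,
                         "test": "posthoc", "statistic": np.nan, "p": p,
                         "significant": p < self.alpha})
        return pd.DataFrame(rows)


def _ad_rejects(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """Anderson-Darling normality test rejection at the given level."""
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 pre-announces a p-value API; the critical-value table
        # comparison used here is the classical decision rule
        warnings.simplefilter("ignore", FutureWarning)
        res = ss.anderson(x, dist="norm")
    sig = np.asarray(res.significance_level, dtype=float)  # percent
    crit = np.asarray(res.critical_values, dtype=float)
    idx = int(np.argmin(np.abs(sig - 100.0 * alpha)))
    return bool(res.statistic > crit[idx])


def normality_gate(groups: Mapping[str, np.ndarray] | Sequence[np.ndarray],
                   alpha: float = ALPHA) -> tuple[str, list[str]]:
    """Route to "parametric" or "nonparametric" by per-group Anderson-Darling.

    Nonparametric iff any group rejects normality at ``alpha``. Constant
    (zero-variance) groups route nonparametric and are returned as degenerate
    flags, since the test is undefined there.
    """
    if isinstance(groups, Mapping):
        items = list(groups.items())
    else:
        items = [(str(i), g) for i, g in enumerate(groups)]
    degenerate: list[str] = []
    any_reject = False
    for name, g in items:
        g = np.asarray(g, dtype=float)
        if len(g) < 4:
            raise ValueError(f"group {name!r} has n={len(g)} < 4; gate needs >= 4")
        if np.ptp(g) == 0.0:
            degenerate.append(name)
            continue
        if _ad_rejects(g, alpha):
            any_reject = True
    route = "nonparametric" if (any_reject or degenerate) else "parametric"
    return route, degenerate


def _rank_tukey(groups: Mapping[str, np.ndarray], alpha: float) -> list[tuple[str, float]]:
    """Tukey HSD on pooled rank-transformed data (nonparametric post hoc)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[name] * len(g) for name, g in groups.items()])
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups.values()])
    ranks = ss.rankdata(values)
    res = pairwise_tukeyhsd(ranks, labels, alpha=alpha)
    return [(f"{row[0]}/{row[1]}", float(p))
            for row, p in zip(res._results_table.data[1:], res.pvalues)]


def _param_tukey(groups: Mapping[str, np.ndarray], alpha: float) -> list[tuple[str, float]]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[name] * len(g) for name, g in groups.items()])
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups.values()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    return [(f"{row[0]}/{row[1]}", float(p))
            for row, p in zip(res._results_table.data[1:], res.pvalues)]


def _rm_anova(groups: Mapping[str, np.ndarray]) -> tuple[float, tuple[float, float], float]:
    """Repeated-measures one-way ANOVA (statsmodels AnovaRM)."""
    from statsmodels.stats.anova import AnovaRM

    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("paired design requires equal group lengths")
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), len(arrays)),
        "level": np.repeat(list(groups.keys()), n),
        "value": np.concatenate(arrays),
    })
    res = AnovaRM(df, depvar="value", subject="subject", within=["level"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), (float(row["Num DF"]), float(row["Den DF"])), float(row["Pr > F"])


def compare(design: ComparisonDesign, data: Mapping[str, np.ndarray],
            alpha: float = ALPHA) -> StatOutcome:
    """Normality-gated comparison of the groups named in ``design.levels``.

    Two independent groups: t-test or rank-sum; two paired: paired t or
    Wilcoxon signed-rank; three or more: repeated-measures/one-way ANOVA or
    Kruskal-Wallis, with Tukey-style post hoc (rank-based on the nonparametric
    branch) when the omnibus is significant.
    """
    groups = {}
    for lev in design.levels:
        if lev not in data:
            raise ValueError(f"level {lev!r} missing from data")
        g = np.asarray(data[lev], dtype=float)
        if len(g) < 2:
            raise ValueError(f"level {lev!r} has fewer than 2 observations")
        groups[lev] = g
    route, degenerate = normality_gate(groups, alpha=alpha)
    k = len(groups)
    arrays = list(groups.values())
    posthoc: list[tuple[str, float]] = []

    if k == 2:
        a, b = arrays
        if design.paired:
            if len(a) != len(b):
                raise ValueError("paired design requires equal group lengths")
            if route == "parametric":
                stat, p = ss.ttest_rel(a, b)
                name, df = "paired t-test", float(len(a) - 1)
            else:
                try:
                    stat, p = ss.wilcoxon(a, b)
                except ValueError:   # all-zero differences
                    stat, p = 0.0, 1.0
                name, df = "Wilcoxon signed-rank", None
        else:
            if route == "parametric":
                stat, p = ss.ttest_ind(a, b)
                name, df = "Student t-test", float(len(a) + len(b) - 2)
            else:
                stat, p = ss.mannwhitneyu(a, b, alternative="two-sided")
                name, df = "Wilcoxon rank-sum", None
    else:
        if route == "parametric":
            if design.paired:
                stat, df, p = _rm_anova(groups)
                name = "repeated-measures ANOVA"
            else:
                stat, p = ss.f_oneway(*arrays)
                df = (float(k - 1), float(sum(len(a) for a in arrays) - k))
                name = "one-way ANOVA"
        else:
            stat, p = ss.kruskal(*arrays)
            name, df = "Kruskal-Wallis", float(k - 1)
        if p < alpha:
            posthoc = (_param_tukey(groups, alpha) if route == "parametric"
                       else _rank_tukey(groups, alpha))
    return StatOutcome(gate_result=route, test_name=name, statistic=float(stat),
                       df=df, p_value=float(p), posthoc=posthoc, alpha=alpha,
                       degenerate_groups=degenerate)


def grid_compare(cells: Mapping[str, Mapping[str, np.ndarray]],
                 paired: bool = False, alpha: float = ALPHA,
                 correction: str | None = None) -> pd.DataFrame:
    """Gated comparisons over a grid of cells (e.g. frequency x time point).

    Each entry of ``cells`` maps a cell label to its group data. Per-cell
    tests run at ``alpha`` with no multiplicity correction by default;
    ``correction="bh"`` applies Benjamini-Hochberg across the grid instead.
    Returns a tidy frame (cell, gate, test, statistic, p, p_adj, significant).
    """
    rows = []
    for label, data in cells.items():
        design = ComparisonDesign(levels=tuple(data), paired=paired)
        out = compare(design, data, alpha=alpha)
        rows.append({"cell": label, "gate": out.gate_result, "test": out.test_name,
                     "statistic": out.statistic, "p": out.p_value})
    df = pd.DataFrame(rows)
    if correction is None:
        df["p_adj"] = df["p"]
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["p"].to_numpy(), alpha=alpha,
                                    method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    df["significant"] = df["p_adj"] < alpha
    return df


def typeI_calibration(n_groups: int = 3, n_per_group: int = 20, n_reps: int = 1000,
                      seed: int = 0, dist: str | Callable[[np.random.Generator, int], np.ndarray] = "normal",
                      alpha: float = ALPHA, paired: bool = False) -> float:
    """Empirical type-I error of the gate + compare procedure under a null.

    Simulates ``n_reps`` datasets of identical groups from ``dist`` ("normal",
    "t3", or a callable (rng, n) -> array) and returns the fraction whose
    omnibus p-value falls below ``alpha``. With alpha = 0 nothing rejects.
    """
    if n_reps < 200:
        raise ValueError("n_reps must be >= 200 for a stable estimate")
    rng = np.random.default_rng(seed)
    if callable(dist):
        draw = dist
    elif dist == "normal":
        draw = lambda r, n: r.standard_normal(n)
    elif dist == "t3":
        draw = lambda r, n: r.standard_t(3, size=n)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    design = ComparisonDesign(levels=tuple(f"g{i}" for i in range(n_groups)), paired=paired)
    n_reject = 0
    for _ in range(n_reps):
        data = {f"g{i}": draw(rng, n_per_group) for i in range(n_groups)}
        out = compare(design, data, alpha=max(alpha, 1e-12))
        if alpha > 0 and out.p_value < alpha:
            n_reject += 1
    return n_reject / n_reps
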