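"""Statistical comparison of trait tables.

The battery mirrors standard practice for factorial plant-phenotyping
designs: a two-way ANOVA with interaction for genotype x developmental-stage
(or treatment x treatment) effects, a one-way ANOVA with Tukey-HSD all-pairs
comparison summarised as a compact letter display, Welch's two-sample t-test
for pairwise contrasts, and two-tailed Pearson correlations of the
rhizochron index against the conventional trait panel (reported as r^2, as
is conventional in this literature).

For unbalanced two-way designs, Type II sums of squares are used; balanced
designs are type-invariant.  Tukey comparisons use Tukey-Kramer standard
errors so unbalanced panels are handled; with two groups the adjusted p
reduces exactly to the pooled-variance t-test p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import TraitRecord

#: conventional traits correlated against the rhizochron index
CORRELATED_TRAITS = ("TRL", "PRL", "TLRL", "RD", "TLr", "PLr", "BZ", "preBZ", "postBZ")


@dataclass(frozen=True)
class AnovaTerm:
    term: str
    df: float
    sum_sq: float
    F: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Per-term ANOVA decomposition; the residual row carries no F or p."""

    terms: tuple[AnovaTerm, ...]

    def __getitem__(self, term: str) -> AnovaTerm:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.terms]).set_index("term")


@dataclass(frozen=True)
class TukeyPair:
    level_a: str
    level_b: str
    mean_diff: float
    p_adj: float


@dataclass(frozen=True)
class TukeyGroups:
    """All-pairs Tukey-HSD comparison with a compact letter display.

    Two levels share a letter if and only if their adjusted p-value is at
    least ``alpha``; every level carries at least one letter.  Letters are
    assigned in order of increasing group mean.
    """

    means: dict[str, float]
    letters: dict[str, str]
    pairs: tuple[TukeyPair, ...]
    alpha: float

    def p_adj(self, a: str, b: str) -> float:
        for pair in self.pairs:
            if {pair.level_a, pair.level_b} == {a, b}:
                return pair.p_adj
        raise KeyError((a, b))


@dataclass(frozen=True)
class CorrelationRow:
    trait: str
    p: float | None
    r2: float | None
    n: int


def two_way_anova(
    values,
    factor_a,
    factor_b,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Two-way fixed-effects ANOVA with interaction (Type II sums of squares).

    ``values`` is the response; ``factor_a``/``factor_b`` are equal-length
    label sequences.  Raises ``ValueError`` when a factor has fewer than two
    levels, a design cell is empty (naming the cells), or no residual degrees
    of freedom remain.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Series(factor_a, dtype=str)
    b = pd.Series(factor_b, dtype=str)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels must have equal length")
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    cells = pd.crosstab(a, b)
    empty = [(str(i), str(j)) for i in cells.index for j in cells.columns if cells.loc[i, j] == 0]
    if empty:
        raise ValueError(f"empty design cells make the model unestimable: {empty}")
    n_cells = cells.size
    if len(y) - n_cells < 1:
        raise ValueError("no residual degrees of freedom: need a cell with >= 2 observations")

    if np.ptp(y) == 0.0:
        # constant response: every effect is exactly null
        df_a, df_b = a.nunique() - 1, b.nunique() - 1
        return AnovaTable(
            (
                AnovaTerm(names[0], float(df_a), 0.0, 0.0, 1.0),
                AnovaTerm(names[1], float(df_b), 0.0, 0.0, 1.0),
                AnovaTerm(f"{names[0]}:{names[1]}", float(df_a * df_b), 0.0, 0.0, 1.0),
                AnovaTerm("Residual", float(len(y) - n_cells), 0.0, None, None),
            )
        )

    data = pd.DataFrame({"y": y, "A": a.to_numpy(), "B": b.to_numpy()})
    model = smf.ols("y ~ C(A) * C(B)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(A)": names[0],
        "C(B)": names[1],
        "C(A):C(B)": f"{names[0]}:{names[1]}",
        "Residual": "Residual",
    }
    resid_ss = float(table.loc["Residual", "sum_sq"])
    terms = []
    for row_name, row in table.iterrows():
        is_resid = row_name == "Residual"
        f_val = None if is_resid else float(row["F"])
        p_val = None if is_resid else float(row["PR(>F)"])
        if not is_resid and resid_ss == 0.0:
            # zero residual variance: a term with zero SS contributes nothing
            # (F = 0, p = 1); a nonzero SS is infinitely significant
            if abs(float(row["sum_sq"])) < 1e-12:
                f_val, p_val = 0.0, 1.0
            else:
                f_val, p_val = math.inf, 0.0
        terms.append(
            AnovaTerm(
                term=rename[str(row_name)],
                df=float(row["df"]),
                sum_sq=max(0.0, float(row["sum_sq"])),
                F=f_val,
                p=p_val,
            )
        )
    return AnovaTable(tuple(terms))


def _tukey_kramer(groups: dict[str, np.ndarray]) -> tuple[tuple[TukeyPair, ...], float, float]:
    """All-pairs adjusted p via the studentized range with Tukey-Kramer SEs."""
    levels = list(groups)
    k = len(levels)
    n_tot = sum(g.size for g in groups.values())
    df_w = n_tot - k
    ss_w = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    mse = ss_w / df_w
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[levels[i]], groups[levels[j]]
            diff = float(gj.mean() - gi.mean())
            se = math.sqrt(mse / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
            if se == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append(TukeyPair(levels[i], levels[j], diff, min(1.0, max(0.0, p_adj))))
    return tuple(pairs), ss_w, mse


def compact_letter_display(
    levels: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from a single column holding every level; each significantly
    different pair splits every column containing both, and columns that
    become subsets of another are absorbed.  Letters are assigned to columns
    ordered by the smallest mean they contain, so the display reads
    low-to-high.
    """
    columns: list[set[str]] = [set(levels)]
    for a, b in sorted(tuple(sorted(pair)) for pair in significant):
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop empty columns and any column contained in another
        columns = []
        for idx, col in enumerate(new_cols):
            if not col:
                continue
            redundant = any(
                (col < other) or (col == other and idx > jdx)
                for jdx, other in enumerate(new_cols)
                if jdx != idx
            )
            if not redundant:
                columns.append(col)
    columns.sort(key=lambda col: min(means[lv] for lv in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for idx, col in enumerate(columns):
        letter = alphabet[idx] if idx < len(alphabet) else f"({idx + 1})"
        for lv in sorted(col, key=lambda lv: means[lv]):
            letters[lv] += letter
    return letters


def one_way_anova_tukey(
    values, factor, alpha: float = 0.05
) -> tuple[AnovaTable, TukeyGroups]:
    """One-way ANOVA plus Tukey-HSD post hoc with a compact letter display.

    Unbalanced panels are allowed (Tukey-Kramer).  Raises ``ValueError`` if
    any level has fewer than two observations, naming the level.
    """
    y = np.asarray(values, dtype=float)
    labels = pd.Series(factor, dtype=str)
    if len(y) != len(labels):
        raise ValueError("values and factor labels must have equal length")
    groups = {str(lv): y[(labels == lv).to_numpy()] for lv in labels.unique()}
    if len(groups) < 2:
        raise ValueError("need at least two factor levels")
    for lv, g in groups.items():
        if g.size < 2:
            raise ValueError(f"level {lv!r} has fewer than two observations")

    k = len(groups)
    n_tot = y.size
    grand = y.mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    pairs, ss_w, mse = _tukey_kramer(groups)
    df_b, df_w = k - 1, n_tot - k
    if mse == 0.0:
        f_stat = 0.0 if ss_b == 0.0 else math.inf
        p = 1.0 if ss_b == 0.0 else 0.0
    else:
        f_stat = (ss_b / df_b) / mse
        p = float(sps.f.sf(f_stat, df_b, df_w))
    anova = AnovaTable(
        (
            AnovaTerm("factor", df_b, float(ss_b), float(f_stat), p),
            AnovaTerm("Residual", df_w, float(ss_w), None, None),
        )
    )
    means = {lv: float(g.mean()) for lv, g in groups.items()}
    significant = {
        frozenset({pr.level_a, pr.level_b}) for pr in pairs if pr.p_adj < alpha
    }
    letters = compact_letter_display(list(groups), means, significant)
    return anova, TukeyGroups(means, letters, pairs, alpha)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (Satterthwaite df, two-tailed p).

    Degenerate samples with zero variance in both groups follow the
    convention p = 1 when the means are equal and p = 0 otherwise.
    Returns ``(t, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), df, 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlate_m(
    records: list[TraitRecord],
    day_filter: int | str | None = "all",
    traits: tuple[str, ...] = CORRELATED_TRAITS,
) -> list[CorrelationRow]:
    """Two-tailed Pearson correlation of the rhizochron index with each trait.

    Discarded records (no fitted m) are excluded; ``day_filter`` restricts to
    one observation day or pools all stages ("all"/None).  Missing trait
    values are pairwise-deleted.  A trait with fewer than three complete
    pairs yields a row with missing p and r^2 rather than an error, but the
    filtered table as a whole must contain at least three fitted records.
    """
    rows = [r for r in records if not r.discarded and r.m is not None]
    if day_filter not in (None, "all"):
        rows = [r for r in rows if r.day == int(day_filter)]
    if len(rows) < 3:
        raise ValueError("need at least three fitted records after filtering")
    m = np.array([r.m for r in rows], dtype=float)
    out = []
    for trait in traits:
        vals = np.array(
            [getattr(r, trait) if getattr(r, trait) is not None else np.nan for r in rows],
            dtype=float,
        )
        mask = ~np.isnan(vals)
        n = int(mask.sum())
        if n < 3 or np.ptp(vals[mask]) == 0 or np.ptp(m[mask]) == 0:
            # too few complete pairs, or a constant column: correlation undefined
            out.append(CorrelationRow(trait, None, None, n))
            continue
        r, p = sps.pearsonr(m[mask], vals[mask])
        out.append(CorrelationRow(trait, float(p), float(r * r), n))
    return out


__all__ = [
    "AnovaTerm",
    "AnovaTable",
    "TukeyPair",
    "TukeyGroups",
    "CorrelationRow",
    "CORRELATED_TRAITS",
    "two_way_anova",
    "one_way_anova_tukey",
    "compact_letter_display",
    "welch_t",
    "correlate_m",
]
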