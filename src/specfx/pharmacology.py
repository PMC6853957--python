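"""Efficacy endpoint statistics for the CCl4 acute-liver-injury model.

Six indicators are tracked per animal: serum transaminases ALT and AST (U/L),
hepatic malondialdehyde MDA (lipid-peroxidation product) and the antioxidant
enzymes SOD, CAT and POD (per mg protein). Hepatoprotection lowers
ALT/AST/MDA and raises SOD/CAT/POD relative to the CCl4 model group.

Group comparisons follow the classical agronomy/pharmacology recipe:
one-way ANOVA, then Duncan's multiple-range test at alpha = 0.05, summarized
as a compact letter display (groups sharing a letter are not significantly
different). Duncan's least significant ranges are computed from the
studentized-range distribution with protection level 1 - (1-alpha)^(p-1)
rather than from printed tables, so any error df is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateInputError, ParseError

INDICATORS = ["ALT", "AST", "MDA", "SOD", "CAT", "POD"]

#: default measurement units per indicator
UNITS = {
    "ALT": "U/L",
    "AST": "U/L",
    "MDA": "nmol/mg protein",
    "SOD": "U/mg protein",
    "CAT": "U/mg protein",
    "POD": "U/mg protein",
}


@dataclass
class EfficacyTable:
    """Tidy per-animal endpoint table: (group, animal_id, indicator, value, unit)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"group", "animal_id", "indicator", "value", "unit"}
        if not need.issubset(self.data.columns):
            raise ParseError(f"efficacy table missing columns {sorted(need - set(self.data.columns))}")
        if (self.data["value"] < 0).any():
            raise ParseError("negative endpoint value")
        counts = self.data.groupby(["group", "indicator"], sort=False)["value"].size()
        if (counts < 2).any():
            g, i = counts.index[counts < 2][0]
            raise ParseError(f"cell ({g}, {i}) has fewer than 2 animals")

    @property
    def groups(self) -> list[str]:
        return list(self.data["group"].unique())

    @property
    def indicators(self) -> list[str]:
        return list(self.data["indicator"].unique())

    def values_of(self, group: str, indicator: str) -> np.ndarray:
        sel = self.data[(self.data["group"] == group) & (self.data["indicator"] == indicator)]
        if sel.empty:
            raise KeyError(f"no data for group {group!r}, indicator {indicator!r}")
        return sel["value"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_efficacy_csv(path) -> EfficacyTable:
    return EfficacyTable(pd.read_csv(path))


def group_summary(table: EfficacyTable) -> pd.DataFrame:
    """Per (group, indicator): mean, sample SD (n-1 denominator) and n."""
    g = table.data.groupby(["group", "indicator"], sort=False)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    return out


def percent_change(model_mean: float, treated_mean: float) -> float:
    """Percent reduction of a treated group's mean relative to the model group.

    Positive values mean the treatment lowered the endpoint.
    """
    if model_mean <= 0:
        raise DegenerateInputError("model mean must be positive")
    return (model_mean - treated_mean) / model_mean * 100.0


@dataclass
class AnovaResult:
    F: float
    p: float
    mse: float
    df_error: int
    df_between: int
    #: True when the within-group variance is exactly zero but means differ
    #: (F is infinite; p reported as 0.0)
    degenerate: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the standard sum-of-squares split.

    Returns F, p, the mean squared error (the pooled within-group variance
    that Duncan's test reuses) and its degrees of freedom.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise DegenerateInputError("need >= 2 groups with >= 2 values each")
    N = sum(len(a) for a in arrs)
    k = len(arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_e = k - 1, N - k
    msb = ss_between / df_b
    mse = ss_within / df_e
    if mse == 0:
        if msb == 0:
            return AnovaResult(0.0, 1.0, 0.0, df_e, df_b)
        return AnovaResult(float("inf"), 0.0, 0.0, df_e, df_b, degenerate=True)
    F = msb / mse
    p = float(stats.f.sf(F, df_b, df_e))
    return AnovaResult(float(F), p, float(mse), df_e, df_b)


@dataclass
class DuncanResult:
    """Duncan multiple-range test outcome for one indicator."""

    means: pd.Series  # sorted descending
    n: float  # common (or harmonic mean) group size
    mse: float
    df_error: int
    alpha: float
    significant: pd.DataFrame  # symmetric bool matrix, group x group
    letters: dict[str, str] = field(default_factory=dict)

    def lsr(self, p: int) -> float:
        """Least significant range for a stretch of p ordered means."""
        return duncan_lsr(p, self.df_error, self.mse, self.n, self.alpha)


def duncan_lsr(p: int, df_error: int, mse: float, n: float, alpha: float = 0.05) -> float:
    """Duncan's least significant range for a stretch of p ordered means.

    Uses the studentized-range quantile at cumulative probability
    (1-alpha)^(p-1), i.e. significance level 1-(1-alpha)^(p-1), times
    sqrt(MSE/n).
    """
    if p < 2:
        raise ConfigurationError("stretch length must be >= 2")
    q = stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_error)
    return float(q * np.sqrt(mse / n))


def duncan_mrt(
    means: Mapping[str, float],
    n: int | Mapping[str, int],
    mse: float,
    df_error: int,
    alpha: float = 0.05,
) -> DuncanResult:
    """Duncan's multiple-range test with step-down protection.

    Means are sorted descending. A stretch of p ordered means is declared
    non-significant when its endpoint difference is at most LSR_p or when it
    is contained in a stretch already declared non-significant; otherwise
    the endpoint pair differs significantly. Unbalanced designs use the
    harmonic mean of the group sizes.
    """
    if df_error < 1:
        raise DegenerateInputError("df_error must be >= 1")
    if mse < 0:
        raise ConfigurationError("MSE must be nonnegative")
    if isinstance(n, Mapping):
        sizes = np.array([n[g] for g in means], dtype=float)
        n_eff = len(sizes) / (1.0 / sizes).sum()
    else:
        n_eff = float(n)
    if n_eff <= 0:
        raise ConfigurationError("group size must be positive")

    order = sorted(means, key=lambda g: means[g], reverse=True)
    mu = np.array([means[g] for g in order])
    k = len(order)
    sig = pd.DataFrame(False, index=order, columns=order)
    nonsig_intervals: list[tuple[int, int]] = []
    for p in range(k, 1, -1):
        lsr_p = duncan_lsr(p, df_error, mse, n_eff, alpha) if mse > 0 else 0.0
        for i in range(0, k - p + 1):
            j = i + p - 1
            protected = any(a <= i and j <= b for a, b in nonsig_intervals)
            if protected:
                continue
            diff = mu[i] - mu[j]
            if mse == 0:
                is_sig = diff > 0
            else:
                is_sig = diff > lsr_p
            if is_sig:
                sig.iloc[i, j] = sig.iloc[j, i] = True
            else:
                nonsig_intervals.append((i, j))

    result = DuncanResult(
        means=pd.Series(mu, index=order),
        n=n_eff,
        mse=float(mse),
        df_error=int(df_error),
        alpha=alpha,
        significant=sig,
    )
    result.letters = compact_letter_display(result)
    return result


def compact_letter_display(result: DuncanResult) -> dict[str, str]:
    """Letter codes per group by the insert-and-absorb algorithm.

    Two groups share a letter iff they are not significantly different.
    Letter 'a' is assigned starting from the largest mean (descending order),
    matching the usual figure annotation.
    """
    sig = result.significant
    if not sig.equals(sig.T):
        raise ConfigurationError("significance matrix must be symmetric")
    groups = list(sig.index)
    letter_sets: list[set[str]] = [set(groups)]
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if not sig.loc[a, b]:
                continue
            for s in [s for s in letter_sets if a in s and b in s]:
                letter_sets.remove(s)
                for cand in (s - {a}, s - {b}):
                    if cand and not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    # absorb any set that became redundant
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < other or (s == other and i > j) for j, other in enumerate(letter_sets))
    ]
    # order letters by the highest mean they cover (descending)
    order = list(result.means.index)
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for idx, s in enumerate(letter_sets):
        for g in order:
            if g in s:
                letters[g] += alphabet[idx % len(alphabet)]
    return letters


def letters_report(table: EfficacyTable, alpha: float = 0.05) -> pd.DataFrame:
    """Mean, SD and Duncan letters per (indicator, group): the usual
    figure-annotation layout, one row per group within each indicator."""
    rows = []
    for indicator in table.indicators:
        groups = {g: table.values_of(g, indicator) for g in table.groups}
        an = one_way_anova(list(groups.values()))
        sizes = {g: len(v) for g, v in groups.items()}
        n = sizes if len(set(sizes.values())) > 1 else next(iter(sizes.values()))
        res = duncan_mrt({g: v.mean() for g, v in groups.items()}, n, an.mse, an.df_error, alpha)
        for g in table.groups:
            v = groups[g]
            rows.append(
                {"indicator": indicator, "group": g, "mean": v.mean(),
                 "sd": v.std(ddof=1), "n": len(v), "letters": res.letters[g]}
            )
    return pd.DataFrame(rows)
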