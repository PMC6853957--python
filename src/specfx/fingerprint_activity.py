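"""Fingerprint-activity relationship modeling.

Couples a chemical fingerprint (common-characteristic-peak areas) to efficacy
endpoints through two complementary screens:

* **Grey relational analysis (GCA).** Each peak's area sequence is compared
  with an indicator's value sequence after normalization. With deviations
  Delta_i(k) = |ref(k) - cmp_i(k)| and global extrema Delta_min/Delta_max
  over all peaks and sample points, the grey relational coefficient is

      xi_i(k) = (Delta_min + rho * Delta_max) / (Delta_i(k) + rho * Delta_max)

  with resolution coefficient rho (default 0.5). A peak's relational grade is
  the mean of its xi series; peaks are ranked per indicator and per ion mode,
  and the top five per indicator are screened as candidate markers.

* **Bivariate correlation analysis (BCA).** Pearson product-moment
  correlation between each peak's areas and each indicator, with a two-sided
  t-test p-value; the screening rule keeps peaks with |r| > 0.5 for at least
  one indicator (a p < alpha variant is available).

The union of both screens, deduplicated at the compound level (peaks of the
same compound seen in both ion modes collapse), is the bioactive-marker
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CompoundLibrary, dedupe_compounds, _peak_sort_key
from .exceptions import ConfigurationError, DegenerateInputError
from .fingerprint_core import FingerprintMatrix
from .pharmacology import EfficacyTable

NormScheme = Literal["mean", "minmax", "initial-value"]


@dataclass(frozen=True)
class GreyParams:
    """Grey relational analysis parameters.

    rho is the resolution coefficient in (0, 1]; smaller rho discriminates
    sequences more sharply. Normalization makes peak areas and indicator
    values dimensionless and comparable.
    """

    rho: float = 0.5
    normalization: NormScheme = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ConfigurationError("rho must be in (0, 1]")
        if self.normalization not in ("mean", "minmax", "initial-value"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")


@dataclass
class GreyRelationResult:
    """GCA outcome for one indicator: xi series, grades and ranks per peak."""

    indicator: str
    xi: pd.DataFrame        # sample point x peak
    grades: pd.Series       # peak -> relational grade, mean of xi
    ranks: pd.Series        # peak -> 1-based rank, descending grade
    params: GreyParams = field(default_factory=GreyParams)


@dataclass
class CorrelationResult:
    """BCA outcome: Pearson r, p and significance per (peak, indicator)."""

    r: pd.DataFrame           # peak x indicator
    p: pd.DataFrame
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha


@dataclass
class MarkerReport:
    """Screened peak sets and the compound-level deduplicated markers."""

    gca_selected: set[str]
    bca_selected: set[str]
    union: set[str]
    markers: list[dict]
    evidence: pd.DataFrame  # peak x (per-indicator grade and r columns)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_unknown(self) -> int:
        return sum(m["is_unknown"] for m in self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"compound": m["compound"], "compound_class": m["compound_class"],
                 "member_peaks": "+".join(m["member_peaks"]), "is_unknown": m["is_unknown"]}
                for m in self.markers
            ]
        )


# ---------------------------------------------------------------------------
# Pairing fingerprints with efficacy

DosePolicy = Literal["high", "low", "treatment-mean"]

_DOSE_PREFIX = {"high": "H", "low": "L"}


def pair_fingerprints_with_efficacy(
    matrix: FingerprintMatrix,
    efficacy: EfficacyTable,
    dose_policy: DosePolicy = "high",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align peak areas with indicator values sample by sample.

    Each fingerprint sample maps to the efficacy group of its salt treatment
    under the dose policy ("high" -> H0..H300, "low" -> L0..L300) and
    receives that group's mean indicator values; n = number of fingerprint
    samples (12 by default). Policy "treatment-mean" first averages
    fingerprint replicates per treatment, giving n = number of treatments.

    Returns ``(areas, indicators)``: two row-aligned DataFrames.
    """
    summaries = (
        efficacy.data.groupby(["group", "indicator"], sort=False)["value"].mean().unstack()
    )
    if dose_policy in _DOSE_PREFIX:
        prefix = _DOSE_PREFIX[dose_policy]
        groups = {}
        for t in matrix.sample_meta["treatment_mM"].unique():
            gname = f"{prefix}{int(t)}"
            if gname not in summaries.index:
                raise ConfigurationError(f"treatment {t} mM has no efficacy group {gname!r}")
            groups[t] = gname
        areas = matrix.areas.copy()
        ind = pd.DataFrame(
            [summaries.loc[groups[t]] for t in matrix.sample_meta["treatment_mM"]],
            index=areas.index,
        )
        return areas, ind
    if dose_policy == "treatment-mean":
        treat = matrix.sample_meta["treatment_mM"]
        areas = matrix.areas.groupby(treat).mean()
        rows = []
        for t in areas.index:
            cands = [f"{p}{int(t)}" for p in ("H", "L")]
            found = [c for c in cands if c in summaries.index]
            if not found:
                raise ConfigurationError(f"treatment {t} mM has no efficacy group")
            rows.append(summaries.loc[found].mean())
        return areas, pd.DataFrame(rows, index=areas.index)
    raise ConfigurationError(f"unknown dose policy {dose_policy!r}")


# ---------------------------------------------------------------------------
# Grey relational analysis

def grey_normalize(sequence: Sequence[float], scheme: NormScheme = "mean") -> np.ndarray:
    """Make a sequence dimensionless: mean (x/mean), minmax, or initial-value (x/x1)."""
    x = np.asarray(sequence, dtype=float)
    if scheme == "mean":
        m = x.mean()
        if m == 0:
            raise DegenerateInputError("mean normalization needs a nonzero mean")
        return x / m
    if scheme == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateInputError("minmax normalization needs max > min")
        return (x - lo) / (hi - lo)
    if scheme == "initial-value":
        if x[0] == 0:
            raise DegenerateInputError("initial-value normalization needs x[0] != 0")
        return x / x[0]
    raise ConfigurationError(f"unknown scheme {scheme!r}")


def grey_relational_grade(
    reference: Sequence[float],
    comparisons: pd.DataFrame,
    params: GreyParams = GreyParams(),
    indicator: str = "",
    normalize: bool = True,
) -> GreyRelationResult:
    """Grey relational coefficients and grades of peaks against a reference.

    ``comparisons`` holds one column per peak (rows are sample points).
    Delta_min/Delta_max are global over all peaks and points, which keeps
    grades comparable across peaks. If every comparison coincides with the
    reference (Delta_max = 0), all xi and grades are 1.
    """
    ref = np.asarray(reference, dtype=float)
    if len(ref) < 2:
        raise DegenerateInputError("sequences must have length >= 2")
    if comparisons.shape[0] != len(ref):
        raise DegenerateInputError("reference and comparisons must have equal length")
    if normalize:
        ref_n = grey_normalize(ref, params.normalization)
        cmp_n = comparisons.apply(lambda c: grey_normalize(c.to_numpy(), params.normalization), axis=0)
    else:
        ref_n = ref
        cmp_n = comparisons.astype(float)
    delta = (cmp_n.to_numpy(dtype=float) - ref_n[:, None]).__abs__()
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0:
        xi = np.ones_like(delta)
    else:
        xi = (dmin + params.rho * dmax) / (delta + params.rho * dmax)
    xi_df = pd.DataFrame(xi, index=comparisons.index, columns=comparisons.columns)
    grades = xi_df.mean(axis=0)
    ranks = grades.rank(ascending=False, method="min").astype(int)
    return GreyRelationResult(indicator, xi_df, grades, ranks, params)


def gca_all_indicators(
    areas: pd.DataFrame,
    indicators: pd.DataFrame,
    params: GreyParams = GreyParams(),
) -> dict[str, GreyRelationResult]:
    """Run GCA of every peak against every indicator (row-aligned inputs)."""
    return {
        ind: grey_relational_grade(indicators[ind], areas, params, indicator=ind)
        for ind in indicators.columns
    }


# ---------------------------------------------------------------------------
# Bivariate (Pearson) correlation analysis

def pearson_matrix(
    areas: pd.DataFrame, indicators: pd.DataFrame, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson r and two-sided p for every (peak, indicator) pair.

    p comes from t = r sqrt((n-2)/(1-r^2)) on n-2 df. A zero-variance member
    of any pair makes the correlation undefined and raises.
    """
    n = areas.shape[0]
    if n < 3:
        raise DegenerateInputError("need n >= 3 samples for correlation")
    if not areas.index.equals(indicators.index):
        raise DegenerateInputError("areas and indicators must be row-aligned")
    r = pd.DataFrame(index=areas.columns, columns=indicators.columns, dtype=float)
    p = r.copy()
    for peak in areas.columns:
        x = areas[peak].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise DegenerateInputError(f"peak {peak!r} has zero variance")
        for ind in indicators.columns:
            y = indicators[ind].to_numpy(dtype=float)
            if np.std(y) == 0:
                raise DegenerateInputError(f"indicator {ind!r} has zero variance")
            res = stats.pearsonr(x, y)
            r.at[peak, ind] = res.statistic
            p.at[peak, ind] = res.pvalue
    return CorrelationResult(r, p, n, alpha)


# ---------------------------------------------------------------------------
# Screening rules

def screen_gca(
    results: Mapping[str, GreyRelationResult] | Mapping[str, pd.Series],
    top_k: int = 5,
) -> tuple[set[str], pd.DataFrame]:
    """Top-k peaks by relational grade, per indicator and per ion mode.

    Accepts either full GCA results or plain grade Series keyed by indicator.
    Peaks tied with the k-th grade are all included. Returns the union set
    and a provenance table (indicator, mode, peak, grade, rank).
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    selected: set[str] = set()
    prov = []
    for ind, res in results.items():
        grades = res.grades if isinstance(res, GreyRelationResult) else res
        modes = pd.Series(
            ["positive" if str(p).startswith("P") else "negative" for p in grades.index],
            index=grades.index,
        )
        for mode in modes.unique():
            sub = grades[modes == mode].sort_values(ascending=False, kind="mergesort")
            if len(sub) == 0:
                continue
            kth = sub.iloc[min(top_k, len(sub)) - 1]
            keep = sub[sub >= kth]
            for rank, (peak, grade) in enumerate(keep.items(), start=1):
                selected.add(str(peak))
                prov.append(
                    {"indicator": ind, "mode": mode, "peak_id": peak,
                     "grade": float(grade), "rank": rank}
                )
    return selected, pd.DataFrame(prov)


def screen_bca(
    result: CorrelationResult,
    rule: Literal["abs_r", "p", "both"] = "abs_r",
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Peaks passing the correlation rule for at least one indicator.

    Rules: ``abs_r`` keeps |r| > threshold (the default, threshold 0.5);
    ``p`` keeps p < alpha; ``both`` requires both. Returns the peak set and
    a provenance table (peak, indicator, r, p).
    """
    if rule not in ("abs_r", "p", "both"):
        raise ConfigurationError(f"unknown rule {rule!r}")
    hits_r = result.r.abs() > threshold
    hits_p = result.p < alpha
    hits = {"abs_r": hits_r, "p": hits_p, "both": hits_r & hits_p}[rule]
    prov = []
    for peak in result.r.index:
        for ind in result.r.columns:
            if hits.at[peak, ind]:
                prov.append(
                    {"peak_id": peak, "indicator": ind,
                     "r": float(result.r.at[peak, ind]), "p": float(result.p.at[peak, ind])}
                )
    return {str(p["peak_id"]) for p in prov}, pd.DataFrame(prov)


def union_markers(*peak_sets) -> set[str]:
    """Union of screened peak sets."""
    out: set[str] = set()
    for s in peak_sets:
        out |= set(s)
    return out


def build_marker_report(
    union: set[str],
    library: CompoundLibrary,
    gca_selected: set[str] | None = None,
    bca_selected: set[str] | None = None,
    gca_results: Mapping[str, GreyRelationResult] | None = None,
    bca_result: CorrelationResult | None = None,
) -> MarkerReport:
    """Compound-level marker report from a screened peak union.

    Peaks naming the same compound across ion modes collapse into one marker
    carrying its compound class and member peaks; per-indicator grade and r
    evidence is attached when available.
    """
    markers = dedupe_compounds(union, library)
    peaks = sorted(union, key=_peak_sort_key)
    ev = pd.DataFrame(index=pd.Index(peaks, name="peak_id"))
    if gca_results:
        for ind, res in gca_results.items():
            ev[f"grade_{ind}"] = [res.grades.get(p, np.nan) for p in peaks]
    if bca_result is not None:
        for ind in bca_result.r.columns:
            ev[f"r_{ind}"] = [
                bca_result.r.at[p, ind] if p in bca_result.r.index else np.nan for p in peaks
            ]
    return MarkerReport(
        gca_selected=set(gca_selected or set()),
        bca_selected=set(bca_selected or set()),
        union=set(union),
        markers=markers,
        evidence=ev,
    )


def run_pipeline(
    matrix: FingerprintMatrix,
    efficacy: EfficacyTable,
    library: CompoundLibrary,
    dose_policy: DosePolicy = "high",
    params: GreyParams = GreyParams(),
    top_k: int = 5,
    bca_rule: Literal["abs_r", "p", "both"] = "abs_r",
    bca_threshold: float = 0.5,
) -> MarkerReport:
    """End-to-end fingerprint-activity screen: pair, GCA, BCA, union, dedupe.

    Deterministic: identical inputs give an identical report.
    """
    areas, indicators = pair_fingerprints_with_efficacy(matrix, efficacy, dose_policy)
    gca_results = gca_all_indicators(areas, indicators, params)
    gca_set, _ = screen_gca(gca_results, top_k=top_k)
    bca_result = pearson_matrix(areas, indicators)
    bca_set, _ = screen_bca(bca_result, rule=bca_rule, threshold=bca_threshold)
    union = union_markers(gca_set, bca_set)
    return build_marker_report(
        union, library, gca_set, bca_set, gca_results, bca_result
    )
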