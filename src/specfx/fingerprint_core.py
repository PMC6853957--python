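"""Chemical-fingerprint core: peak tables, common-peak detection, equalization,
median reference, similarity and hierarchical clustering.

The analysis unit is the *common characteristic peak*: a chromatographic peak
detected in every sample of a batch. Samples are rows of a sample x peak area
matrix (one matrix per ESI ion mode); the reference fingerprint is the
per-peak median across samples, and sample quality consistency is scored as
the similarity (cosine by default) of each equalized sample profile to that
reference. Hierarchical clustering uses Euclidean distance with average
linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .exceptions import AmbiguityError, DegenerateInputError, ParseError

#: length of the chromatographic gradient, minutes
GRADIENT_WINDOW_MIN = (0.0, 22.1)

#: columns of the tidy on-disk fingerprint format
FINGERPRINT_COLUMNS = [
    "sample_id",
    "treatment_mM",
    "replicate",
    "peak_id",
    "mode",
    "t_R_min",
    "mz",
    "area",
]

Mode = Literal["positive", "negative"]


def _mode_of_peak_id(peak_id: str) -> str | None:
    if peak_id.startswith("P"):
        return "positive"
    if peak_id.startswith("N"):
        return "negative"
    return None


@dataclass
class FingerprintMatrix:
    """Sample x peak area matrix with sample and peak annotations.

    Parameters
    ----------
    areas
        DataFrame of nonnegative peak areas, index = sample ids,
        columns = peak ids.
    sample_meta
        DataFrame indexed by sample id; typically carries ``treatment_mM``
        and ``replicate``.
    peak_meta
        DataFrame indexed by peak id with columns ``mode`` ("positive" or
        "negative"), ``t_R_min`` and ``mz``.
    """

    areas: pd.DataFrame
    sample_meta: pd.DataFrame
    peak_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.areas.index.name = "sample_id"
        self.areas.columns.name = "peak_id"
        self.sample_meta.index.name = "sample_id"
        self.peak_meta.index.name = "peak_id"
        if self.areas.index.has_duplicates:
            raise ParseError("duplicate sample ids")
        if self.areas.columns.has_duplicates:
            raise ParseError("duplicate peak ids")
        if not self.sample_meta.index.equals(self.areas.index):
            self.sample_meta = self.sample_meta.reindex(self.areas.index)
        if not self.peak_meta.index.equals(self.areas.columns):
            self.peak_meta = self.peak_meta.reindex(self.areas.columns)
        vals = self.areas.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ParseError("NaN areas are not allowed")
        if (vals < 0).any():
            bad = self.areas.columns[(vals < 0).any(axis=0)][0]
            raise ParseError(f"negative area in peak {bad!r}")
        # peak-id prefix convention: P* positive, N* negative
        for pid, mode in self.peak_meta["mode"].items():
            expected = _mode_of_peak_id(str(pid))
            if expected is not None and mode != expected:
                raise ParseError(
                    f"peak {pid!r} has mode {mode!r}, expected {expected!r} from its prefix"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def modes(self) -> list[str]:
        return sorted(self.peak_meta["mode"].unique())

    def by_mode(self, mode: str) -> "FingerprintMatrix":
        """Restrict to the peaks of one ion mode."""
        keep = self.peak_meta.index[self.peak_meta["mode"] == mode]
        return FingerprintMatrix(
            self.areas[keep].copy(), self.sample_meta.copy(), self.peak_meta.loc[keep].copy()
        )

    def copy(self) -> "FingerprintMatrix":
        return FingerprintMatrix(
            self.areas.copy(), self.sample_meta.copy(), self.peak_meta.copy()
        )


@dataclass
class SamplePeakList:
    """Integrated peak list of one sample: (t_R, m/z, area, mode) entries."""

    sample_id: str
    entries: pd.DataFrame  # columns t_R_min, mz, area, mode

    def __post_init__(self) -> None:
        need = {"t_R_min", "mz", "area", "mode"}
        if not need.issubset(self.entries.columns):
            raise ParseError(f"peak list missing columns {sorted(need - set(self.entries.columns))}")
        lo, hi = GRADIENT_WINDOW_MIN
        tr = self.entries["t_R_min"].to_numpy(dtype=float)
        if ((tr < lo) | (tr > hi)).any():
            raise ParseError(f"t_R outside gradient window {GRADIENT_WINDOW_MIN} in {self.sample_id}")
        self.entries = self.entries.sort_values("t_R_min", kind="mergesort").reset_index(drop=True)


@dataclass
class Dendrogram:
    """Result of agglomerative clustering, wrapping a SciPy linkage matrix."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    leaves: list[str]
    linkage_name: str = "average"
    distance_name: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in leaves_list(self.linkage_matrix)]


# ---------------------------------------------------------------------------
# I/O

def write_fingerprint_csv(matrix: FingerprintMatrix, path) -> None:
    """Write a matrix as the tidy CSV format (one row per sample x peak cell)."""
    rows = []
    for sid in matrix.sample_ids:
        smeta = matrix.sample_meta.loc[sid]
        for pid in matrix.peak_ids:
            pmeta = matrix.peak_meta.loc[pid]
            rows.append(
                {
                    "sample_id": sid,
                    "treatment_mM": smeta.get("treatment_mM", np.nan),
                    "replicate": smeta.get("replicate", np.nan),
                    "peak_id": pid,
                    "mode": pmeta["mode"],
                    "t_R_min": pmeta["t_R_min"],
                    "mz": pmeta["mz"],
                    "area": matrix.areas.at[sid, pid],
                }
            )
    pd.DataFrame(rows, columns=FINGERPRINT_COLUMNS).to_csv(path, index=False)


def read_fingerprint_csv(path) -> FingerprintMatrix:
    """Read the tidy CSV format back into a :class:`FingerprintMatrix`."""
    df = pd.read_csv(path)
    missing = set(FINGERPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"fingerprint CSV missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["sample_id", "peak_id"])
    if dup.any():
        raise ParseError(f"duplicate (sample, peak) row at index {int(df.index[dup][0])}")
    neg = df["area"] < 0
    if neg.any():
        raise ParseError(f"negative area at row {int(df.index[neg][0])}")
    areas = df.pivot(index="sample_id", columns="peak_id", values="area")
    # preserve first-appearance order of samples and peaks
    areas = areas.loc[df["sample_id"].drop_duplicates(), df["peak_id"].drop_duplicates()]
    sample_meta = (
        df[["sample_id", "treatment_mM", "replicate"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    peak_meta = (
        df[["peak_id", "mode", "t_R_min", "mz"]].drop_duplicates("peak_id").set_index("peak_id")
    )
    return FingerprintMatrix(areas, sample_meta, peak_meta)


# ---------------------------------------------------------------------------
# Common characteristic peaks

def detect_common_peaks(
    lists: Sequence[SamplePeakList],
    rt_tol: float = 0.1,
) -> FingerprintMatrix:
    """Find peaks present in every sample and assemble their area matrix.

    Peaks are matched across samples within one ion mode when their retention
    times differ by at most ``rt_tol`` minutes (nearest-t_R grouping on the
    pooled, sorted peak list). A peak group qualifies as *common
    characteristic* only when every sample contributes exactly one member.
    Detected common peaks are labeled ``P1..Pk`` / ``N1..Nk`` in t_R order,
    following the P/N prefix convention for positive/negative mode.

    Raises
    ------
    AmbiguityError
        If any sample contains two same-mode peaks closer than ``rt_tol``;
        matching would be ill-defined.
    """
    if len(lists) == 0:
        raise ParseError("need at least one sample peak list")
    if rt_tol <= 0:
        raise ParseError("rt_tol must be > 0")

    sample_ids = [pl.sample_id for pl in lists]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError("duplicate sample ids in peak lists")

    all_modes = sorted({m for pl in lists for m in pl.entries["mode"].unique()})
    prefix = {"positive": "P", "negative": "N"}

    areas_by_peak: dict[str, dict[str, float]] = {}
    peak_meta_rows: dict[str, dict] = {}

    for mode in all_modes:
        pooled = []
        for pl in lists:
            sub = pl.entries[pl.entries["mode"] == mode]
            tr = sub["t_R_min"].to_numpy(dtype=float)
            if len(tr) >= 2 and np.min(np.diff(np.sort(tr))) <= rt_tol:
                i = int(np.argmin(np.diff(np.sort(tr))))
                ts = np.sort(tr)
                raise AmbiguityError(
                    f"sample {pl.sample_id!r}: peaks at {ts[i]:.3f} and {ts[i + 1]:.3f} min "
                    f"({mode}) are within rt_tol={rt_tol}"
                )
            for _, row in sub.iterrows():
                pooled.append((float(row["t_R_min"]), pl.sample_id, float(row["mz"]), float(row["area"])))
        pooled.sort(key=lambda t: t[0])

        groups: list[list[tuple]] = []
        for entry in pooled:
            if groups:
                ref = np.mean([e[0] for e in groups[-1]])
                if abs(entry[0] - ref) <= rt_tol:
                    groups[-1].append(entry)
                    continue
            groups.append([entry])

        common = []
        for grp in groups:
            members = {e[1] for e in grp}
            if len(members) == len(grp) and members == set(sample_ids):
                common.append(grp)

        for i, grp in enumerate(sorted(common, key=lambda g: np.mean([e[0] for e in g])), start=1):
            pid = f"{prefix.get(mode, mode[:1].upper())}{i}"
            peak_meta_rows[pid] = {
                "mode": mode,
                "t_R_min": float(np.mean([e[0] for e in grp])),
                "mz": float(np.mean([e[2] for e in grp])),
            }
            areas_by_peak[pid] = {e[1]: e[3] for e in grp}

    areas = pd.DataFrame(
        {pid: [areas_by_peak[pid][sid] for sid in sample_ids] for pid in areas_by_peak},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    peak_meta = pd.DataFrame.from_dict(peak_meta_rows, orient="index")
    peak_meta.index.name = "peak_id"
    sample_meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return FingerprintMatrix(areas, sample_meta, peak_meta)


# ---------------------------------------------------------------------------
# Equalization, reference, similarity

def equalize_areas(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Normalize each sample's areas to fractions of its per-mode total.

    Within each ion mode, a sample's areas are divided by that sample's total
    common-peak area in the mode, so each (sample, mode) row sums to one.
    Idempotent, and invariant to rescaling any single sample's raw areas.
    """
    out = matrix.copy()
    for mode in matrix.modes:
        cols = matrix.peak_meta.index[matrix.peak_meta["mode"] == mode]
        totals = matrix.areas[cols].sum(axis=1)
        if (totals <= 0).any():
            sid = totals.index[totals <= 0][0]
            raise DegenerateInputError(f"sample {sid!r} has zero total area in mode {mode!r}")
        out.areas[cols] = matrix.areas[cols].div(totals, axis=0)
    return out


def median_reference(matrix: FingerprintMatrix) -> pd.Series:
    """Reference fingerprint: per-peak median across samples.

    For an even number of samples the median is the mean of the two middle
    values (the usual convention; it shapes the reference atlas).
    """
    if matrix.areas.shape[0] == 0:
        raise DegenerateInputError("empty matrix")
    return matrix.areas.median(axis=0)


def similarity(
    sample: Sequence[float],
    reference: Sequence[float],
    metric: Literal["cosine", "pearson"] = "cosine",
) -> float:
    """Similarity of a sample fingerprint to a reference fingerprint.

    ``cosine`` (the congruence coefficient, default) lies in [0, 1] for
    nonnegative profiles; ``pearson`` is the product-moment correlation.
    """
    x = np.asarray(sample, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise DegenerateInputError("vectors must have equal length >= 2")
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise DegenerateInputError("zero vector has no cosine similarity")
        return float(np.dot(x, y) / (nx * ny))
    if metric == "pearson":
        if np.std(x) == 0 or np.std(y) == 0:
            raise DegenerateInputError("constant vector has no correlation")
        return float(np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


def similarity_to_reference(
    matrix: FingerprintMatrix, metric: Literal["cosine", "pearson"] = "cosine"
) -> pd.DataFrame:
    """Per-sample, per-mode similarity to the median reference of the batch.

    Areas are equalized first; returns a DataFrame indexed by sample id with
    one column per ion mode.
    """
    eq = equalize_areas(matrix)
    out = {}
    for mode in eq.modes:
        sub = eq.by_mode(mode)
        ref = median_reference(sub)
        out[mode] = pd.Series(
            {sid: similarity(sub.areas.loc[sid], ref, metric=metric) for sid in sub.sample_ids}
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Hierarchical clustering

def hca(
    matrix: FingerprintMatrix,
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> Dendrogram:
    """Cluster samples by UPGMA (average linkage) on Euclidean distances.

    The inter-cluster distance is the mean of all pairwise sample distances
    between the two clusters. Run per ion mode (restrict with
    :meth:`FingerprintMatrix.by_mode`) — modes are never mixed in one
    distance computation.
    """
    X = matrix.areas.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DegenerateInputError("need >= 2 samples to cluster")
    if np.isnan(X).any():
        raise ParseError("NaN in areas")
    Z = linkage(pdist(X, metric=distance), method=linkage_method)
    return Dendrogram(Z, list(matrix.sample_ids), linkage_method, distance)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Flat clusters from a dendrogram by removing the k-1 highest merges.

    Returns a Series mapping sample id -> cluster label (1..k, labeled in
    leaf-appearance order).
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # apply the n-k lowest merges (linkage rows are height-sorted)
    Z = dendrogram.linkage_matrix
    for row in range(n - k):
        a, b = int(Z[row, 0]), int(Z[row, 1])
        parent[find(a)] = parent[find(b)] = n + row
    roots: dict[int, int] = {}
    labels = {}
    for i, sid in enumerate(dendrogram.leaves):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[sid] = roots[r]
    return pd.Series(labels, name="cluster")


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string.

    Branch lengths are differences between a node's merge height and its
    children's heights (leaves sit at height 0).
    """
    n = dendrogram.n_leaves
    Z = dendrogram.linkage_matrix
    heights = {i: 0.0 for i in range(n)}
    reprs = {i: dendrogram.leaves[i] for i in range(n)}
    for row in range(n - 1):
        a, b, h = int(Z[row, 0]), int(Z[row, 1]), float(Z[row, 2])
        node = n + row
        heights[node] = h
        reprs[node] = (
            f"({reprs[a]}:{h - heights[a]:g},{reprs[b]}:{h - heights[b]:g})"
        )
    return reprs[2 * n - 2] + ";"
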