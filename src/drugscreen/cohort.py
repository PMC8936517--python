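"""Cohort-level analysis: the samples x treatments DSS matrix, hierarchical
clustering (Euclidean distance, Ward linkage) and two-group comparisons
(Mann–Whitney U).

DSS values share a common 0–100 scale, so clustering operates on unscaled
values by default; z-scoring per treatment is available behind a flag.
Missing cells are imputed with the treatment-wise median before clustering
(dendrograms need complete vectors) and the imputation is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import mannwhitneyu, rankdata

from .dss import DssRecord


class CohortError(ValueError):
    pass


@dataclass
class CohortMatrix:
    """Samples x treatments DSS table with per-sample annotations."""

    dss: pd.DataFrame                      # index = sample ids, columns = treatments
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame())

    def __post_init__(self) -> None:
        vals = self.dss.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.any((vals[present] < 0) | (vals[present] > 100)):
            raise CohortError("DSS values must lie in [0, 100]")

    @property
    def samples(self) -> list[str]:
        return list(self.dss.index)

    @property
    def treatments(self) -> list[str]:
        return list(self.dss.columns)

    def missingness_report(self) -> pd.DataFrame:
        na = self.dss.isna()
        return pd.DataFrame({"treatment": self.dss.columns,
                             "n_missing": na.sum(axis=0).to_numpy()})


def assemble(records: Sequence[DssRecord] | pd.DataFrame,
             annotations: Optional[pd.DataFrame] = None) -> CohortMatrix:
    """Build the wide DSS matrix from per-treatment records.

    Duplicate (sample, treatment) pairs are rejected by name; absent cells
    become NA and are counted in the missingness report.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["sample_id", "treatment_label", "dss"]].copy()
    else:
        df = pd.DataFrame([{"sample_id": r.sample_id,
                            "treatment_label": r.treatment_label,
                            "dss": r.dss} for r in records])
    dup = df.duplicated(["sample_id", "treatment_label"])
    if dup.any():
        first = df[dup].iloc[0]
        raise CohortError(f"duplicate DSS record for sample "
                          f"{first['sample_id']!r} / treatment "
                          f"{first['treatment_label']!r}")
    if df["sample_id"].nunique() < 2 or df["treatment_label"].nunique() < 2:
        raise CohortError("need >= 2 samples and >= 2 treatments")
    wide = df.pivot(index="sample_id", columns="treatment_label", values="dss")
    ann = annotations if annotations is not None else pd.DataFrame(index=wide.index)
    ann = ann.reindex(wide.index)
    return CohortMatrix(dss=wide, annotations=ann)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: Optional[pd.Series]      # flat cluster ids when k was given
    leaf_order: list[str]
    axis: str
    imputed_cells: int = 0


def _impute_treatment_median(dss: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n_missing = int(dss.isna().to_numpy().sum())
    if n_missing == 0:
        return dss, 0
    filled = dss.apply(lambda col: col.fillna(col.median()), axis=0)
    if filled.isna().any().any():
        raise CohortError("treatment with all values missing cannot be imputed")
    return filled, n_missing


def cluster(matrix: CohortMatrix, axis: str = "samples",
            k: Optional[int] = None, z_score: bool = False) -> ClusterResult:
    """Agglomerative clustering with Euclidean distance and Ward linkage.

    ``axis`` selects whether samples or treatments are clustered; ``k``
    cuts the tree into flat clusters.  The Ward criterion is scipy's
    (Ward.D2-equivalent on squared Euclidean updates), pinned here for
    reproducibility.
    """
    if axis not in ("samples", "treatments"):
        raise CohortError("axis must be 'samples' or 'treatments'")
    data, n_imputed = _impute_treatment_median(matrix.dss)
    if z_score:
        sd = data.std(axis=0, ddof=1).replace(0.0, 1.0)
        data = (data - data.mean(axis=0)) / sd
    if axis == "treatments":
        data = data.T
    x = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise CohortError("non-finite values after imputation")
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    order = [data.index[i] for i in hierarchy.leaves_list(z)]
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=data.index, name="cluster")
    return ClusterResult(linkage=z, labels=labels, leaf_order=order,
                         axis=axis, imputed_cells=n_imputed)


def to_newick(result: ClusterResult, leaf_names: Sequence[str]) -> str:
    """Dendrogram as a Newick string (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(result.linkage)
    names = list(leaf_names)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def _exact_enumeration_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group assignments (handles ties)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = rankdata(pooled)
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n * (n + 1) / 2.0
        total += 1
        if abs(u1 - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def group_compare(values: Sequence[float],
                  labels: Sequence) -> tuple[float, float]:
    """Mann–Whitney U test between the two groups defined by ``labels``.

    Returns (U statistic of the first-named group, two-sided p).  For a
    combined sample size of at most 12 the p-value is exact (enumeration
    when ties are present); larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise CohortError(f"need exactly two groups, got {len(uniq)}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise CohortError("both groups must be non-empty")
    n_total = len(x) + len(y)
    has_ties = len(np.unique(values)) < n_total
    if n_total <= 12:
        if has_ties:
            u = float(mannwhitneyu(x, y, method="asymptotic").statistic)
            return u, float(_exact_enumeration_p(x, y, u))
        res = mannwhitneyu(x, y, method="exact", alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = mannwhitneyu(x, y, method="asymptotic", use_continuity=True,
                       alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
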