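"""Free amino-acid concentration analysis.

Samples x analyte tables in nmol/g with two group labels are compared
analyte-by-analyte with two-sided Mann-Whitney-Wilcoxon tests (exact
enumeration for small tie-free samples, normal approximation with tie
and continuity correction otherwise), Benjamini-Hochberg corrected, and
read at q < alpha.  Values below the detection limit (1 nmol/g by
default) contribute zero to totals under the default policy, or half
the detection limit under the ``half_lod`` policy.  For heatmap-style
summaries, rows are z-score normalized (mean 0, sample SD 1) and leaf
orders come from agglomerative Ward clustering on Euclidean distances —
the Ward-1 variant, i.e. the Lance-Williams update applied to unsquared
distances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CONFIG, AnalysisConfig


@dataclass
class AAConcentrationTable:
    """Samples x amino-acid concentrations (nmol/g) with group labels."""

    values: pd.DataFrame        # rows: samples, columns: analytes
    groups: pd.Series           # sample -> group label
    lod: float = 1.0

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reindex(self.values.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("concentrations must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def below_lod(self) -> pd.DataFrame:
        """Boolean mask of values below the detection limit."""
        return self.values < self.lod

    def group_labels(self) -> list[str]:
        """The two group labels, in order of first appearance."""
        seen: list[str] = []
        for label in self.groups:
            if label not in seen:
                seen.append(label)
        return seen


def effective_values(
    table: AAConcentrationTable, lod_policy: str = "zero"
) -> pd.DataFrame:
    """Concentrations with below-LOD entries replaced per policy."""
    values = table.values.astype(float).copy()
    mask = table.below_lod
    replacement = 0.0 if lod_policy == "zero" else table.lod / 2.0
    return values.mask(mask, replacement)


def total_free_aa(
    table: AAConcentrationTable, sample: str, lod_policy: str = "zero"
) -> float:
    """Total free amino acids (nmol/g) in one sample."""
    return float(effective_values(table, lod_policy).loc[sample].sum())


def mww_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Uses exact enumeration when nA + nB <= 20 and there are no ties,
    otherwise the normal approximation with tie correction and
    continuity correction.  Returns (U for group A, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if ((pvalues < 0) | (pvalues > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class GroupComparison:
    analyte: str
    median_a: float
    median_b: float
    u_statistic: float
    p: float
    q: float = float("nan")
    significant: bool = False


def compare_groups(
    table: AAConcentrationTable,
    config: AnalysisConfig = DEFAULT_CONFIG,
    lod_policy: str | None = None,
) -> pd.DataFrame:
    """Per-analyte two-group comparison with FDR correction.

    Medians are reported per group alongside U, p, BH-adjusted q, and a
    significance call at q < alpha.  FDR is applied across the analyte
    family only; a total-amino-acid test is a separate, single test.
    """
    labels = table.group_labels()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    policy = lod_policy if lod_policy is not None else config.lod_policy
    values = effective_values(table, policy)
    mask_a = table.groups == labels[0]
    mask_b = table.groups == labels[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    rows: list[GroupComparison] = []
    for analyte in table.analytes:
        a = values.loc[mask_a, analyte].to_numpy()
        b = values.loc[mask_b, analyte].to_numpy()
        u, p = mww_test(a, b)
        rows.append(
            GroupComparison(
                analyte=analyte,
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
                u_statistic=u,
                p=p,
            )
        )
    qs = bh_adjust([r.p for r in rows])
    for row, q in zip(rows, qs):
        row.q = float(q)
        row.significant = bool(q < config.alpha)
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in rows],
            f"median_{labels[0]}": [r.median_a for r in rows],
            f"median_{labels[1]}": [r.median_b for r in rows],
            "U": [r.u_statistic for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "significant": [r.significant for r in rows],
        }
    )


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score normalization (mean 0, sample SD 1).

    Constant rows cannot be normalized; they are emitted as all-zero
    rows with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    means = X.mean(axis=1, keepdims=True)
    sds = X.std(axis=1, ddof=1, keepdims=True)
    constant = (sds == 0).ravel()
    if constant.any():
        warnings.warn(
            f"constant rows emitted as zeros: {list(matrix.index[constant])}"
        )
    sds[sds == 0] = 1.0
    out = (X - means) / sds
    out[constant, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Ward-1 hierarchical clustering (Lance-Williams on unsquared distances)
# ---------------------------------------------------------------------------

@dataclass
class WardResult:
    order: list              # dendrogram leaf order (item labels)
    heights: list[float]     # merge heights, in merge order
    merges: list[tuple] = field(default_factory=list)  # (left, right) cluster ids


def _ward_linkage(dist: np.ndarray, variant: str = "ward1"):
    """Agglomerative clustering by the Ward criterion via Lance-Williams.

    ``variant='ward1'`` applies the update directly to Euclidean
    distances; ``'ward2'`` applies it to squared distances and reports
    square-root merge heights.  Ties break on the smallest cluster ids.
    Returns (merges, heights, children) with new clusters numbered from n.
    """
    n = dist.shape[0]
    working = dist.astype(float).copy()
    if variant == "ward2":
        working = working**2
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = working[i, j]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    next_id = n
    while len(active) > 1:
        best = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                dij = d[(min(i, j), max(i, j))]
                if best is None or dij < best[0] - 1e-12:
                    best = (dij, i, j)
        dij, i, j = best
        new = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            denom = ni + nj + nk
            d[(k, new)] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / denom
        active = [k for k in active if k not in (i, j)] + [new]
        sizes[new] = ni + nj
        children[new] = (i, j)
        merges.append((i, j))
        heights.append(float(np.sqrt(dij)) if variant == "ward2" else float(dij))
    return merges, heights, children


def _leaf_order(children: dict[int, tuple[int, int]], root: int) -> list[int]:
    if root not in children:
        return [root]
    left, right = children[root]
    return _leaf_order(children, left) + _leaf_order(children, right)


def ward_order(
    matrix: pd.DataFrame, axis: str = "rows", variant: str = "ward1"
) -> WardResult:
    """Dendrogram leaf order and merge heights for the rows (or columns)
    of a matrix under Ward clustering on Euclidean distances."""
    data = matrix if axis == "rows" else matrix.T
    labels = list(data.index)
    if len(labels) < 2:
        raise ValueError("clustering needs >= 2 items")
    X = data.to_numpy(dtype=float)
    n = len(labels)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist[i, j] = dist[j, i] = float(np.linalg.norm(X[i] - X[j]))
    merges, heights, children = _ward_linkage(dist, variant=variant)
    root = 2 * n - 2 if n > 1 else 0
    order_idx = _leaf_order(children, root)
    return WardResult(
        order=[labels[i] for i in order_idx],
        heights=heights,
        merges=merges,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_aa_table(path: str | Path, lod: float = 1.0) -> AAConcentrationTable:
    """Read a concentrations TSV: columns ``sample``, ``group``, then one
    column per analyte (nmol/g)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: needs 'sample' and 'group' columns")
    df = df.set_index("sample")
    groups = df.pop("group").astype(str)
    return AAConcentrationTable(values=df.astype(float), groups=groups, lod=lod)


def write_aa_table(table: AAConcentrationTable, path: str | Path) -> None:
    df = table.values.copy()
    df.insert(0, "group", table.groups)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
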