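"""Comparative statistics between consortia.

Covers the comparisons used to contrast defined communities at the
functional level: the high-prevalence module filter (modules carried by
more than 80% of the pooled isolates are uninformative and removed),
pairwise Pearson chi-squared tests on KO-by-subcategory contingency
tables, within-consortium dissimilarity indices (median Euclidean
distance between members over module KO-count vectors), Kruskal-Wallis
with Dunn's pairwise post hoc (BH-adjusted), and PCA of per-genome
KO-pathway count matrices with optional 95% confidence ellipses.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist

from .annotation_io import FunctionalHierarchy
from .config import DEFAULT_CONFIG, AnalysisConfig
from .consortium import ConsortiumProfile
from .errors import DegenerateTableError, UndefinedIndexError


# ---------------------------------------------------------------------------
# high-prevalence module filter
# ---------------------------------------------------------------------------

def high_prevalence_filter(
    presence: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG
) -> frozenset[str]:
    """Retained module ids after removing near-ubiquitous modules.

    ``presence`` is a pooled isolate x module boolean matrix (all
    consortia stacked).  A module is removed iff the number of isolates
    containing it strictly exceeds ``floor(high_prevalence_fraction * N)``
    where N is the pooled isolate count; with N = 29 and the default 0.80
    fraction, the cutoff is 23 isolates.
    """
    n_isolates = len(presence)
    cutoff = math.floor(config.high_prevalence_fraction * n_isolates)
    counts = presence.astype(bool).sum(axis=0)
    return frozenset(counts.index[counts <= cutoff])


# ---------------------------------------------------------------------------
# chi-squared on contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chisq_test(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-squared test (no continuity correction) on an r x c
    count table.  All-zero rows/columns are dropped with a warning; an
    expected cell of zero raises :class:`DegenerateTableError`."""
    table = pd.DataFrame(table)
    zero_rows = table.index[(table == 0).all(axis=1)]
    zero_cols = table.columns[(table == 0).all(axis=0)]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping all-zero rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"need >= 2 rows and columns after dropping zeros, got {table.shape}"
        )
    observed = table.to_numpy(dtype=float)
    expected = sps.contingency.expected_freq(observed)
    if (expected == 0).any():
        raise DegenerateTableError("expected frequency of zero")
    stat, p, df, _ = sps.chi2_contingency(observed, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def ko_subcategory_table(
    profiles: Sequence[ConsortiumProfile],
    hierarchy: FunctionalHierarchy,
    restrict_kos: Iterable[str] | None = None,
    multiplicity: bool = False,
) -> pd.DataFrame:
    """Consortium x subcategory KO counts for chi-squared comparisons.

    By default each distinct KO in a consortium's union counts once per
    subcategory it is annotated to; with ``multiplicity`` the total copy
    count across members is used instead.
    """
    restrict = set(restrict_kos) if restrict_kos is not None else None
    rows: dict[str, dict[str, float]] = {}
    for profile in profiles:
        bucket: dict[str, float] = {}
        for ko in sorted(profile.ko_union):
            if restrict is not None and ko not in restrict:
                continue
            weight = (
                float(profile.ko_matrix[ko].sum()) if multiplicity else 1.0
            )
            for sub in {e.subcategory for e in hierarchy.lookup(ko)}:
                bucket[sub] = bucket.get(sub, 0.0) + weight
        rows[profile.name] = bucket
    frame = pd.DataFrame(rows).T.fillna(0.0)
    frame = frame[sorted(frame.columns)]
    frame.index.name = "consortium"
    return frame


# ---------------------------------------------------------------------------
# dissimilarity indices
# ---------------------------------------------------------------------------

@dataclass
class DissimilarityIndex:
    consortium: str
    pairwise_distances: list[float]
    median: float


def dissimilarity_index(
    matrix: pd.DataFrame, name: str = ""
) -> DissimilarityIndex:
    """Median Euclidean distance between member rows of a per-isolate
    feature matrix (e.g. KO counts within retained modules)."""
    if len(matrix) < 2:
        raise UndefinedIndexError(
            f"consortium {name!r}: dissimilarity needs >= 2 members"
        )
    distances = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    return DissimilarityIndex(
        consortium=name or getattr(matrix.index, "name", "") or "",
        pairwise_distances=[float(d) for d in distances],
        median=float(np.median(distances)),
    )


def module_ko_count_matrix(
    profile: ConsortiumProfile,
    module_kos: Mapping[str, frozenset[str]],
    retained_modules: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-isolate vectors of KO counts within (retained) modules.

    One column per module: the number of the module's required KOs that
    the isolate carries (presence-based, matching distinct-KO counting).
    """
    modules = sorted(
        set(module_kos) if retained_modules is None
        else set(module_kos) & set(retained_modules)
    )
    ko_sets = {
        g: frozenset(profile.ko_matrix.columns[profile.ko_matrix.loc[g] > 0])
        for g in profile.ko_matrix.index
    }
    frame = pd.DataFrame(
        [
            [len(ko_sets[g] & module_kos[m]) for m in modules]
            for g in profile.ko_matrix.index
        ],
        index=profile.ko_matrix.index,
        columns=modules,
        dtype=float,
    )
    return frame


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn post hoc
# ---------------------------------------------------------------------------

@dataclass
class KruskalDunnResult:
    statistic: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p, q


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> KruskalDunnResult:
    """Kruskal-Wallis rank test with tie correction, followed by Dunn's
    pairwise z tests, BH-adjusted.

    If every observation is identical the test is vacuous and p = 1 is
    returned on all comparisons (no error).
    """
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    labels = list(labels) if labels is not None else [
        f"group{i + 1}" for i in range(len(groups))
    ]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    pairs = list(itertools.combinations(range(len(arrays)), 2))

    if np.all(pooled == pooled[0]):
        pairwise = pd.DataFrame(
            {
                "group_a": [labels[i] for i, _ in pairs],
                "group_b": [labels[j] for _, j in pairs],
                "z": 0.0,
                "p": 1.0,
                "q": 1.0,
            }
        )
        return KruskalDunnResult(statistic=0.0, p=1.0, pairwise=pairwise)

    statistic, p = sps.kruskal(*arrays)

    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[offsets[i]:offsets[i + 1]]))
        for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    zs, ps = [], []
    for i, j in pairs:
        se = math.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    from statsmodels.stats.multitest import multipletests

    qs = multipletests(ps, method="fdr_bh")[1] if ps else []
    pairwise = pd.DataFrame(
        {
            "group_a": [labels[i] for i, _ in pairs],
            "group_b": [labels[j] for _, j in pairs],
            "z": zs,
            "p": ps,
            "q": qs,
        }
    )
    return KruskalDunnResult(statistic=float(statistic), p=float(p), pairwise=pairwise)


# ---------------------------------------------------------------------------
# PCA of KO-pathway counts
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame  # genomes x components
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def pca_scores(matrix: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Column-centered (optionally unit-scaled) PCA of a genome x pathway
    count matrix; Euclidean geometry on raw counts by default.

    A zero-variance matrix yields all-zero scores with the result
    flagged degenerate (explained variance undefined).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 genomes and >= 2 pathways")
    X = matrix.to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0.0):
        n_comp = min(X.shape)
        scores = pd.DataFrame(
            np.zeros((X.shape[0], n_comp)),
            index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        )
        return PCAResult(
            scores=scores,
            explained_variance_ratio=np.full(n_comp, np.nan),
            degenerate=True,
        )
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    from sklearn.decomposition import PCA

    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    transformed = pca.fit_transform(X)
    scores = pd.DataFrame(
        transformed,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        degenerate=False,
    )


def group_ellipses(
    scores: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    level: float = 0.95,
) -> pd.DataFrame:
    """95% confidence ellipse parameters per group from the 2-D score
    covariance at the chi-squared quantile (2 degrees of freedom).

    Returns center, semi-axis lengths and orientation (degrees) for each
    group with >= 3 members; smaller groups yield NaN axes.
    """
    groups = pd.Series(groups)
    quantile = sps.chi2.ppf(level, df=2)
    rows = []
    for name in sorted(groups.unique()):
        members = groups.index[groups == name]
        pts = scores.loc[members, ["PC1", "PC2"]].to_numpy(dtype=float)
        center = pts.mean(axis=0)
        if len(pts) < 3:
            rows.append((name, center[0], center[1], np.nan, np.nan, np.nan))
            continue
        cov = np.cov(pts, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        semi_axes = np.sqrt(np.maximum(eigvals, 0.0) * quantile)
        angle = math.degrees(math.atan2(eigvecs[1, 0], eigvecs[0, 0]))
        rows.append((name, center[0], center[1], semi_axes[0], semi_axes[1], angle))
    return pd.DataFrame(
        rows,
        columns=["group", "center_pc1", "center_pc2",
                 "semi_major", "semi_minor", "angle_deg"],
    )
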