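"""Reporter-score pathway enrichment.

Gene-level p-values are converted to z-scores by the one-sided inverse
normal transform, ``z = Phi^-1(1 - p)``, signed by the direction of the
gene's effect (here: -1 for the pre-weaning/infant direction, +1 for the
adult direction).  A pathway with k member genes aggregates to

    Z_raw = sum(z_i) / sqrt(k)

and is corrected against a Monte-Carlo background: the mean mu_k and
standard deviation sigma_k of the same aggregate over random k-gene
subsets of the full annotated gene pool,

    Z_adj = (Z_raw - mu_k) / sigma_k.

A pathway is called enriched in the pre-weaning direction when its
signed adjusted score falls strictly below -1.6 (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import DegenerateBackgroundError

#: p-values are clamped to this open interval before the normal transform
P_CLAMP = 1e-15


@dataclass(frozen=True)
class GeneStat:
    """One gene's two-group evidence: a p-value and the sign of its effect."""

    gene_or_ko: str
    p: float
    direction: int  # -1: pre-weaning/infant-enriched, +1: adult-enriched


@dataclass
class ReporterResult:
    pathway: str
    k: int
    z_raw: float
    mu_k: float
    sigma_k: float
    z_adj: float
    enriched_preweaning: bool


def gene_z(stat: GeneStat | tuple[float, int]) -> float:
    """Signed inverse-normal transform of one gene's p-value."""
    if isinstance(stat, GeneStat):
        p, direction = stat.p, stat.direction
    else:
        p, direction = stat
    if not (0.0 < p < 1.0):
        raise ValueError(f"p-value must be in (0, 1), got {p}")
    p = min(max(p, P_CLAMP), 1.0 - P_CLAMP)
    return float(sps.norm.isf(p)) * direction


def pathway_score(zs: Sequence[float]) -> float:
    """Aggregate member gene z-scores: sum / sqrt(k)."""
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise ValueError("pathway has no member z-scores")
    return float(zs.sum() / np.sqrt(zs.size))


def background_table(
    pool: Sequence[float],
    ks: Iterable[int],
    n_samples: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[int, tuple[float, float]]:
    """Monte-Carlo background moments (mu_k, sigma_k) for several subset
    sizes at once.

    Each of ``n_samples`` draws takes the first k elements of a random
    permutation of the pool (a uniform k-subset without replacement);
    one cumulative sum serves every k, so the cost is dominated by the
    largest k requested.
    """
    pool_arr = np.asarray(pool, dtype=float)
    m = pool_arr.size
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        return {}
    k_max = ks[-1]
    if not (1 <= k_max <= m):
        raise ValueError(f"subset sizes must be in [1, {m}], got max {k_max}")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if np.all(pool_arr == pool_arr[0]):
        raise DegenerateBackgroundError("background pool is constant")
    if rng is None:
        rng = np.random.default_rng(seed)

    sqrt_k = np.sqrt(np.asarray(ks, dtype=float))
    sums = np.empty((n_samples, len(ks)))
    chunk = max(1, int(2e7 // m))
    done = 0
    while done < n_samples:
        size = min(chunk, n_samples - done)
        # first k of the argsorted uniforms = uniform random k-subset
        idx = np.argsort(rng.random((size, m)), axis=1)[:, :k_max]
        cumulative = np.cumsum(pool_arr[idx], axis=1)
        sums[done:done + size] = cumulative[:, np.asarray(ks) - 1]
        done += size
    scores = sums / sqrt_k
    out: dict[int, tuple[float, float]] = {}
    for i, k in enumerate(ks):
        mu = float(scores[:, i].mean())
        sigma = float(scores[:, i].std(ddof=1))
        if sigma == 0.0:
            raise DegenerateBackgroundError(f"sigma_k = 0 for k = {k}")
        out[k] = (mu, sigma)
    return out


def background_adjust(
    z_raw: float,
    k: int,
    gene_z_pool: Sequence[float],
    n_samples: int = 10000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Background moments and adjusted score for one pathway:
    returns (mu_k, sigma_k, z_adj)."""
    mu, sigma = background_table(gene_z_pool, [k], n_samples=n_samples, seed=seed)[k]
    return mu, sigma, (z_raw - mu) / sigma


def classify(z_adj: float, config: AnalysisConfig = DEFAULT_CONFIG) -> bool:
    """Pre-weaning enrichment call: signed adjusted score strictly below
    the negative threshold."""
    return z_adj < -config.reporter_threshold


def score_pathways(
    gene_stats: Sequence[GeneStat] | pd.DataFrame,
    membership: Mapping[str, Sequence[str]],
    config: AnalysisConfig = DEFAULT_CONFIG,
    n_samples: int = 10000,
    seed: int | None = None,
    exclude_pathway_genes: bool = False,
) -> list[ReporterResult]:
    """Score every pathway against the full annotated gene-z pool.

    ``membership`` maps pathway id -> member gene ids; members missing
    from the gene table are ignored, and pathways left with no member
    are skipped with a warning.  With ``exclude_pathway_genes`` each
    pathway's background is drawn from the pool minus its own members
    (selectable; the default samples from the full pool).
    """
    if isinstance(gene_stats, pd.DataFrame):
        gene_stats = [
            GeneStat(str(r[0]), float(r[1]), int(r[2]))
            for r in gene_stats.itertuples(index=False)
        ]
    z_by_gene = {s.gene_or_ko: gene_z(s) for s in gene_stats}
    pool = np.array(list(z_by_gene.values()), dtype=float)

    members_by_pathway: dict[str, list[str]] = {}
    for pathway in sorted(membership):
        members = [g for g in membership[pathway] if g in z_by_gene]
        if not members:
            warnings.warn(f"pathway {pathway!r} has no annotated members; skipped")
            continue
        members_by_pathway[pathway] = members

    results: list[ReporterResult] = []
    if not exclude_pathway_genes:
        ks = {len(m) for m in members_by_pathway.values()}
        moments = background_table(pool, ks, n_samples=n_samples, seed=seed)
        for pathway, members in members_by_pathway.items():
            z_raw = pathway_score([z_by_gene[g] for g in members])
            mu, sigma = moments[len(members)]
            z_adj = (z_raw - mu) / sigma
            results.append(
                ReporterResult(pathway, len(members), z_raw, mu, sigma,
                               z_adj, classify(z_adj, config))
            )
    else:
        for pathway, members in members_by_pathway.items():
            member_set = set(members)
            sub_pool = np.array(
                [z for g, z in z_by_gene.items() if g not in member_set]
            )
            z_raw = pathway_score([z_by_gene[g] for g in members])
            mu, sigma, z_adj = background_adjust(
                z_raw, len(members), sub_pool, n_samples=n_samples, seed=seed
            )
            results.append(
                ReporterResult(pathway, len(members), z_raw, mu, sigma,
                               z_adj, classify(z_adj, config))
            )
    return results


def reporter_frame(results: Sequence[ReporterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "k": [r.k for r in results],
            "z_raw": [r.z_raw for r in results],
            "mu_k": [r.mu_k for r in results],
            "sigma_k": [r.sigma_k for r in results],
            "z_adj": [r.z_adj for r in results],
            "enriched_preweaning": [r.enriched_preweaning for r in results],
        }
    )
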