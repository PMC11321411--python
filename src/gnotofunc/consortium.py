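"""Consortium-level set algebra and prevalence analysis.

Everything here treats a consortium as the union of its members'
annotations: non-redundant KO and module counts (each KO or module is
counted once no matter how many members carry it), unique-KO sets
relative to other consortia, per-KO prevalence rows (copy counts per
isolate, total gene count, number of isolates sharing the KO), module
prevalence matrices across consortia, and per-category KO allocation
through a functional hierarchy.

Uniqueness and prevalence are defined on presence (copy count >= 1);
copy counts are reported alongside because gene counts and presence
answer different questions about a consortium's functional repertoire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    ConsortiumSpec,
    FunctionalHierarchy,
    GenomeAnnotation,
    ModuleDefinition,
)
from .config import DEFAULT_CONFIG, AnalysisConfig
from .module_engine import CompletenessMatrix


def union_kos(consortium: ConsortiumSpec) -> frozenset[str]:
    """Non-redundant KO set: KOs present in at least one member."""
    out: set[str] = set()
    for member in consortium.members:
        out |= member.ko_set
    return frozenset(out)


@dataclass
class ConsortiumProfile:
    """Union KO/module sets and the per-isolate KO copy-count matrix."""

    name: str
    ko_union: frozenset[str]
    module_union: frozenset[str]
    ko_matrix: pd.DataFrame  # genomes x KOs, integer copy counts
    category_counts: pd.DataFrame | None = None


def build_profile(
    consortium: ConsortiumSpec,
    completeness: CompletenessMatrix | None = None,
    hierarchy: FunctionalHierarchy | None = None,
) -> ConsortiumProfile:
    kos = sorted(union_kos(consortium))
    matrix = pd.DataFrame(
        [[m.ko_counts.get(k, 0) for k in kos] for m in consortium.members],
        index=consortium.member_ids,
        columns=kos,
        dtype=int,
    )
    matrix.index.name = "genome_id"
    module_union = completeness.module_union() if completeness else frozenset()
    category_counts = None
    if hierarchy is not None:
        rows = {
            m.genome_id: category_allocation(m, hierarchy)[0]
            for m in consortium.members
        }
        category_counts = pd.DataFrame(rows).T.fillna(0).astype(int)
        category_counts.index.name = "genome_id"
    return ConsortiumProfile(
        name=consortium.name,
        ko_union=frozenset(kos),
        module_union=module_union,
        ko_matrix=matrix,
        category_counts=category_counts,
    )


def unique_kos(
    target: ConsortiumProfile, others: Sequence[ConsortiumProfile]
) -> frozenset[str]:
    """KOs present in the target consortium and in none of the others."""
    if not others:
        raise ValueError("need at least one other consortium")
    other_union: set[str] = set()
    for profile in others:
        other_union |= profile.ko_union
    return frozenset(target.ko_union - other_union)


@dataclass
class PrevalenceRow:
    """One KO's copy counts across the isolates of a consortium."""

    ko: str
    pathway: str
    description: str
    per_isolate_counts: tuple[int, ...]
    gene_count: int
    n_present: int
    n_total: int
    absent_in: frozenset[str] = frozenset()


def build_prevalence_table(
    consortium: ConsortiumSpec,
    ko_filter: Iterable[str] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    hierarchy: FunctionalHierarchy | None = None,
    descriptions: Mapping[str, str] | None = None,
    others: Sequence[ConsortiumProfile] = (),
) -> list[PrevalenceRow]:
    """Per-KO prevalence rows, restricted to KOs carried by at least
    ``config.prevalence_min_isolates`` members.

    Per-isolate column order follows consortium member order.  Rows sort
    by number of carrying isolates (descending), then total gene count
    (descending), then KO id.  KOs absent from every member are dropped.
    """
    kos = sorted(set(ko_filter)) if ko_filter is not None else sorted(union_kos(consortium))
    descriptions = descriptions or {}
    rows: list[PrevalenceRow] = []
    n_total = consortium.size
    for ko in kos:
        counts = tuple(m.ko_counts.get(ko, 0) for m in consortium.members)
        n_present = sum(1 for c in counts if c > 0)
        if n_present == 0 or n_present < config.prevalence_min_isolates:
            continue
        pathway = ""
        if hierarchy is not None:
            pathway = "; ".join(
                p for p in hierarchy.pathways_of(ko) if p != "unannotated"
            )
        rows.append(
            PrevalenceRow(
                ko=ko,
                pathway=pathway,
                description=descriptions.get(ko, ""),
                per_isolate_counts=counts,
                gene_count=sum(counts),
                n_present=n_present,
                n_total=n_total,
                absent_in=frozenset(
                    o.name for o in others if ko not in o.ko_union
                ),
            )
        )
    rows.sort(key=lambda r: (-r.n_present, -r.gene_count, r.ko))
    return rows


def prevalence_frame(
    rows: Sequence[PrevalenceRow], member_ids: Sequence[str]
) -> pd.DataFrame:
    """Flatten prevalence rows into a table with one column per isolate."""
    data: dict[str, list] = {
        "ko": [r.ko for r in rows],
        "pathway": [r.pathway for r in rows],
        "description": [r.description for r in rows],
    }
    for i, member in enumerate(member_ids):
        data[member] = [r.per_isolate_counts[i] for r in rows]
    data["gene_count"] = [r.gene_count for r in rows]
    data["prevalence"] = [f"{r.n_present}/{r.n_total}" for r in rows]
    data["absent_in"] = [",".join(sorted(r.absent_in)) for r in rows]
    return pd.DataFrame(data)


def gmm_prevalence_matrix(
    matrices: Sequence[CompletenessMatrix],
    modules: Sequence[ModuleDefinition],
    category_filter: str | None = None,
) -> pd.DataFrame:
    """Module x consortium matrix of carriage proportions.

    Each cell is the fraction of a consortium's members that contain the
    module.  Rows are restricted to ``category_filter`` when given and
    sorted by the first (reference) consortium's proportion descending,
    ties broken by module id.  The matrix is dense: modules carried by
    nobody keep their all-zero row.
    """
    wanted = [
        m.module_id
        for m in modules
        if category_filter is None or m.category == category_filter
    ]
    if category_filter is not None and not wanted:
        warnings.warn(f"no modules in category {category_filter!r}")
        return pd.DataFrame(columns=[mat.consortium for mat in matrices])
    columns = {}
    for mat in matrices:
        prevalence = mat.module_prevalence()
        columns[mat.consortium] = [prevalence.get(mid, 0.0) for mid in wanted]
    frame = pd.DataFrame(columns, index=wanted)
    frame.index.name = "module_id"
    reference = frame.columns[0]
    order = sorted(frame.index, key=lambda mid: (-frame.at[mid, reference], mid))
    return frame.loc[order]


def category_allocation(
    genome: GenomeAnnotation,
    hierarchy: FunctionalHierarchy,
    module_kos: Iterable[str] | None = None,
) -> tuple[pd.Series, int]:
    """Distinct-KO counts per (category, subcategory) for one genome,
    plus the count of the genome's KOs that belong to at least one module.

    A KO annotated to several categories contributes once to each (the
    per-category sums are therefore not additive-exclusive).
    """
    buckets: dict[tuple[str, str], set[str]] = {}
    for ko in genome.ko_set:
        for entry in hierarchy.lookup(ko):
            buckets.setdefault((entry.category, entry.subcategory), set()).add(ko)
    counts = pd.Series(
        {key: len(v) for key, v in sorted(buckets.items())}, dtype=int
    )
    if not counts.empty:
        counts.index = pd.MultiIndex.from_tuples(
            counts.index, names=["category", "subcategory"]
        )
    module_total = 0
    if module_kos is not None:
        module_total = len(genome.ko_set & set(module_kos))
    return counts, module_total


def module_ko_totals(
    consortium: ConsortiumSpec, modules: Sequence[ModuleDefinition]
) -> pd.Series:
    """Per-genome count of distinct KOs belonging to >= 1 module."""
    module_kos: set[str] = set()
    for module in modules:
        module_kos |= module.all_kos
    return pd.Series(
        {m.genome_id: len(m.ko_set & module_kos) for m in consortium.members},
        name=consortium.name,
    )


def consortium_module_ko_median(
    consortium: ConsortiumSpec, modules: Sequence[ModuleDefinition]
) -> float:
    """Median over members of the per-genome module-KO totals."""
    return float(np.median(module_ko_totals(consortium, modules).to_numpy()))
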