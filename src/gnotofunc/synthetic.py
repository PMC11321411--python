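"""Synthetic study generator with known ground truth.

Every input the pipeline consumes can be generated here: module
databases in the GMM dialect, defined consortia with planted per-genome
module completeness and planted unique KOs, gene-level p-value tables
with a configurable number of truly enriched pathways, and two-group
amino-acid concentration tables with multiplicative effects under
log-normal noise.  Defaults emulate the study design this package was
built around: three consortia of 9, 8 and 12 members, and metabolome
groups of 7 versus 8 mice with sigma = 0.3 log-normal noise.

Module KO sets are drawn from a namespace disjoint from background KOs
(and from each other), so planted coverage recovery is an exact test
rather than a statistical one.  All generators take explicit seeds; no
global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import (
    Alternative,
    ConsortiumSpec,
    FunctionalHierarchy,
    GenomeAnnotation,
    ModuleDefinition,
    PathwayEntry,
    Step,
)
from .errors import ParameterError
from .reporter import P_CLAMP

MODULE_CATEGORIES = (
    "carbohydrate degradation",
    "amino acid degradation",
    "lipid degradation",
    "other",
)

#: common free amino acids measured in intestinal contents
AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartic acid", "cysteine",
    "glutamic acid", "glutamine", "glycine", "histidine", "hydroxyproline",
    "isoleucine", "leucine", "lysine", "methionine", "phenylalanine",
    "proline", "serine", "taurine", "threonine", "tryptophan",
    "tyrosine", "valine",
)

_PHYLA = ("Bacillota", "Bacteroidota", "Pseudomonadota", "Actinomycetota")
_FAMILIES = (
    "Lactobacillaceae", "Lachnospiraceae", "Tannerellaceae",
    "Enterobacteriaceae", "Staphylococcaceae", "Enterococcaceae",
)


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    planted_completeness: dict = field(default_factory=dict)  # (genome, module) -> cov
    planted_unique_kos: dict = field(default_factory=dict)    # consortium -> [KO]
    planted_enriched: dict = field(default_factory=dict)      # pathway -> effect z
    planted_effects: dict = field(default_factory=dict)       # analyte -> fold change

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_completeness": {
                f"{g}|{m}": c for (g, m), c in sorted(self.planted_completeness.items())
            },
            "planted_unique_kos": {
                k: sorted(v) for k, v in sorted(self.planted_unique_kos.items())
            },
            "planted_enriched": dict(sorted(self.planted_enriched.items())),
            "planted_effects": dict(sorted(self.planted_effects.items())),
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        completeness = {
            tuple(key.split("|", 1)): value
            for key, value in payload["planted_completeness"].items()
        }
        return cls(
            seed=payload["seed"],
            planted_completeness=completeness,
            planted_unique_kos={
                k: set(v) for k, v in payload["planted_unique_kos"].items()
            },
            planted_enriched=payload["planted_enriched"],
            planted_effects=payload["planted_effects"],
        )


class _KoCounter:
    """Sequential KO ids in a reserved synthetic namespace (K50000...)."""

    def __init__(self, start: int = 50000):
        self._next = start

    def take(self, n: int = 1) -> list[str]:
        out = [f"K{self._next + i:05d}" for i in range(n)]
        self._next += n
        if self._next > 89999:
            raise ParameterError("synthetic module KO namespace exhausted")
        return out


def gen_module_db(
    n_modules: int = 24,
    steps_range: tuple[int, int] = (2, 6),
    alternatives_range: tuple[int, int] = (1, 3),
    complex_prob: float = 0.25,
    seed: int = 0,
    categories: Sequence[str] = MODULE_CATEGORIES,
) -> list[ModuleDefinition]:
    """Random, valid module database (round-trips through the GMM reader).

    KO ids are never reused across modules, steps or alternatives, so
    any two modules (and any two steps) have disjoint KO sets.
    """
    rng = np.random.default_rng(seed)
    counter = _KoCounter()
    modules: list[ModuleDefinition] = []
    for i in range(n_modules):
        n_steps = int(rng.integers(steps_range[0], steps_range[1] + 1))
        steps = []
        for _ in range(n_steps):
            n_alts = int(rng.integers(alternatives_range[0], alternatives_range[1] + 1))
            alts = []
            for _ in range(n_alts):
                size = int(rng.integers(2, 4)) if rng.random() < complex_prob else 1
                alts.append(Alternative(frozenset(counter.take(size))))
            steps.append(Step(tuple(sorted(alts, key=Alternative._key))))
        modules.append(
            ModuleDefinition(
                module_id=f"SMM{i + 1:04d}",
                name=f"synthetic module {i + 1}",
                steps=tuple(steps),
                category=categories[i % len(categories)],
            )
        )
    return modules


def gen_consortium(
    name: str,
    n_genomes: int,
    module_db: Sequence[ModuleDefinition],
    completeness_plan: Mapping[tuple[str, str], float] | None = None,
    background_ko_rate: float = 150.0,
    seed: int = 0,
    taxonomy_cycle: Sequence[tuple[str, str]] | None = None,
) -> tuple[ConsortiumSpec, SyntheticTruth]:
    """Build a consortium whose genomes contain exactly the KO sets needed
    for their planted step coverages, plus Poisson background KOs drawn
    disjoint from all module KOs.

    ``completeness_plan`` maps (genome_id, module_id) to a target
    coverage that must be a multiple of 1/steps; genome ids are
    ``{name}_g01`` ... .  Unplanned (genome, module) pairs get coverage 0.
    """
    rng = np.random.default_rng(seed)
    genome_ids = [f"{name}_g{i + 1:02d}" for i in range(n_genomes)]
    modules = {m.module_id: m for m in module_db}
    plan = dict(completeness_plan or {})
    for (genome_id, module_id) in plan:
        if genome_id not in genome_ids:
            raise ParameterError(f"unknown genome {genome_id!r} in plan")
        if module_id not in modules:
            raise ParameterError(f"unknown module {module_id!r} in plan")
    if taxonomy_cycle is None:
        taxonomy_cycle = [
            (_PHYLA[i % len(_PHYLA)], _FAMILIES[i % len(_FAMILIES)])
            for i in range(n_genomes)
        ]

    members: list[GenomeAnnotation] = []
    for idx, genome_id in enumerate(genome_ids):
        ko_counts: dict[str, int] = {}
        for (g, module_id), coverage in sorted(plan.items()):
            if g != genome_id:
                continue
            module = modules[module_id]
            required_steps = [s for s in module.steps if not s.optional]
            total = len(required_steps)
            n_satisfied = coverage * total
            if abs(n_satisfied - round(n_satisfied)) > 1e-9:
                raise ParameterError(
                    f"module {module_id}: coverage {coverage} is not a "
                    f"multiple of 1/{total}"
                )
            n_satisfied = int(round(n_satisfied))
            chosen = rng.choice(total, size=n_satisfied, replace=False)
            for step_idx in sorted(chosen):
                step = required_steps[step_idx]
                alt = step.alternatives[int(rng.integers(len(step.alternatives)))]
                for ko in sorted(alt.required_kos):
                    ko_counts[ko] = ko_counts.get(ko, 0) + 1
        n_background = int(rng.poisson(background_ko_rate))
        if n_background > 0:
            # K90000-K99999: reserved background namespace, disjoint from modules
            picks = rng.choice(10000, size=min(n_background, 10000), replace=False)
            for p in sorted(picks):
                ko_counts[f"K9{p:04d}"] = 1
        phylum, family = taxonomy_cycle[idx % len(taxonomy_cycle)]
        members.append(
            GenomeAnnotation(
                genome_id=genome_id,
                taxonomy={"phylum": phylum, "family": family},
                ko_counts=ko_counts,
            )
        )
    truth = SyntheticTruth(seed=seed, planted_completeness=dict(plan))
    return ConsortiumSpec(name, members), truth


def random_plan(
    name: str,
    n_genomes: int,
    module_db: Sequence[ModuleDefinition],
    carriage_prob: float = 0.45,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """A random achievable completeness plan: each (genome, module) pair
    carries the module with ``carriage_prob``, at a coverage drawn
    uniformly from the achievable multiples of 1/steps (excluding 0)."""
    rng = np.random.default_rng(seed)
    plan: dict[tuple[str, str], float] = {}
    for i in range(n_genomes):
        genome_id = f"{name}_g{i + 1:02d}"
        for module in module_db:
            if rng.random() >= carriage_prob:
                continue
            total = module.n_required_steps
            satisfied = int(rng.integers(1, total + 1))
            plan[(genome_id, module.module_id)] = satisfied / total
    return plan


def gen_study(
    seed: int = 0,
    n_modules: int = 24,
    sizes: Mapping[str, int] | None = None,
    background_ko_rate: float = 150.0,
):
    """Generate a full three-consortium study: a module database plus
    consortia of 9, 8 and 12 members (the defined-community design),
    each with a random achievable completeness plan.

    Returns (module_db, {name: ConsortiumSpec}, {name: SyntheticTruth}).
    """
    sizes = dict(sizes or {"pre_weaning": 9, "adult_a": 8, "adult_b": 12})
    rng = np.random.default_rng(seed)
    module_db = gen_module_db(n_modules=n_modules, seed=int(rng.integers(2**31)))
    consortia: dict[str, ConsortiumSpec] = {}
    truths: dict[str, SyntheticTruth] = {}
    for name, n in sizes.items():
        sub_seed = int(rng.integers(2**31))
        plan = random_plan(name, n, module_db, seed=sub_seed)
        consortia[name], truths[name] = gen_consortium(
            name, n, module_db,
            completeness_plan=plan,
            background_ko_rate=background_ko_rate,
            seed=sub_seed,
        )
    return module_db, consortia, truths


def gen_hierarchy(
    modules: Sequence[ModuleDefinition],
    extra_kos: Sequence[str] = (),
    n_pathways: int = 12,
    seed: int = 0,
) -> FunctionalHierarchy:
    """A KO hierarchy covering the module KOs (subcategory = module
    category) plus any extra KOs spread over generic pathways."""
    rng = np.random.default_rng(seed)
    entries: dict[str, list[PathwayEntry]] = {}
    for module in modules:
        for ko in sorted(module.all_kos):
            entry = PathwayEntry(
                f"pathway{1 + int(rng.integers(n_pathways)):03d}",
                "metabolism",
                module.category,
            )
            entries.setdefault(ko, []).append(entry)
    for ko in sorted(set(extra_kos)):
        entry = PathwayEntry(
            f"pathway{1 + int(rng.integers(n_pathways)):03d}",
            "genetic information processing",
            "other",
        )
        entries.setdefault(ko, []).append(entry)
    return FunctionalHierarchy(entries)


def gen_reporter_dataset(
    n_genes: int = 2000,
    n_pathways: int = 50,
    k_range: tuple[int, int] = (5, 50),
    n_enriched: int = 10,
    effect_mean_z: float = 1.0,
    seed: int = 0,
    enriched_k: int | None = None,
    planted_direction: int = -1,
) -> tuple[pd.DataFrame, dict[str, list[str]], SyntheticTruth]:
    """Gene-level p-value/direction table plus pathway membership.

    Null genes have p ~ uniform(0,1) with random direction; members of
    the ``n_enriched`` planted pathways get p derived from a gene z
    drawn N(effect_mean_z, 1), signed toward ``planted_direction`` (the
    pre-weaning direction, -1, by default).
    """
    if n_enriched > n_pathways:
        raise ParameterError("n_enriched must be <= n_pathways")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:06d}" for i in range(n_genes)]
    p = rng.uniform(size=n_genes)
    p = np.clip(p, P_CLAMP, 1 - P_CLAMP)
    direction = rng.choice([-1, 1], size=n_genes)

    membership: dict[str, list[str]] = {}
    enriched_ids = [f"path{i + 1:04d}" for i in range(n_enriched)]
    truth = SyntheticTruth(seed=seed)
    for j in range(n_pathways):
        pathway = f"path{j + 1:04d}"
        enriched = j < n_enriched
        if enriched and enriched_k is not None:
            k = enriched_k
        else:
            k = int(rng.integers(k_range[0], k_range[1] + 1))
        k = min(k, n_genes) if n_genes else 0
        if k == 0:
            continue
        members = rng.choice(n_genes, size=k, replace=False)
        membership[pathway] = [genes[i] for i in sorted(members)]
        if enriched:
            z0 = rng.normal(loc=effect_mean_z, scale=1.0, size=k)
            p[sorted(members)] = np.clip(sps.norm.sf(z0), P_CLAMP, 1 - P_CLAMP)
            direction[sorted(members)] = planted_direction
            truth.planted_enriched[pathway] = effect_mean_z
    if n_enriched == 0 or effect_mean_z == 0.0:
        truth.planted_enriched = {}
    table = pd.DataFrame({"gene": genes, "p": p, "direction": direction})
    assert set(truth.planted_enriched) <= set(enriched_ids)
    return table, membership, truth


def gen_aa_table(
    n_a: int = 7,
    n_b: int = 8,
    n_analytes: int = 15,
    planted_effects: Mapping[str, float] | None = None,
    noise_sigma: float = 0.3,
    seed: int = 0,
    lod: float = 1.0,
    group_names: tuple[str, str] = ("A", "B"),
):
    """Two-group amino-acid table with multiplicative planted effects.

    Group B samples scatter log-normally (sigma = ``noise_sigma``)
    around per-analyte baseline medians; group A additionally carries
    the planted fold change on the chosen analytes (fold < 1 depletes
    the analyte in group A).
    """
    from .metabolomics import AAConcentrationTable

    planted = dict(planted_effects or {})
    if any(f <= 0 for f in planted.values()):
        raise ParameterError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    analytes = list(AMINO_ACIDS[:n_analytes])
    unknown = set(planted) - set(analytes)
    if unknown:
        raise ParameterError(f"planted analytes not in table: {sorted(unknown)}")
    baseline = 10 ** rng.uniform(1.5, 3.3, size=n_analytes)  # ~30-2000 nmol/g
    samples = [f"{group_names[0]}_{i + 1:02d}" for i in range(n_a)] + [
        f"{group_names[1]}_{i + 1:02d}" for i in range(n_b)
    ]
    groups = pd.Series(
        [group_names[0]] * n_a + [group_names[1]] * n_b, index=samples
    )
    folds = np.array([planted.get(a, 1.0) for a in analytes])
    rows = []
    for sample in samples:
        scatter = np.exp(rng.normal(0.0, noise_sigma, size=n_analytes))
        mean = baseline * (folds if groups[sample] == group_names[0] else 1.0)
        rows.append(mean * scatter)
    values = pd.DataFrame(rows, index=samples, columns=analytes)
    values.index.name = "sample"
    truth = SyntheticTruth(seed=seed, planted_effects=planted)
    return AAConcentrationTable(values=values, groups=groups, lod=lod), truth
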