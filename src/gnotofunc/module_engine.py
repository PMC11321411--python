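"""Module completeness scoring and presence calls.

A module is a sequence of reaction steps; each step is satisfied by a
genome when some alternative's full required KO set is annotated.  The
default coverage is the fraction of non-optional steps satisfied
("steps" mode); "genes" mode instead uses the fraction of the module's
required KO union that the genome carries.  A module is called present
when coverage reaches the configured threshold (inclusive; the default
is 0.75, i.e. "at least 75%").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import ConsortiumSpec, GenomeAnnotation, ModuleDefinition, Step
from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import DegenerateModuleError


@dataclass(frozen=True)
class CompletenessCall:
    """Coverage and presence of one module in one genome."""

    genome_id: str
    module_id: str
    coverage: float
    present: bool
    satisfied_steps: int
    total_steps: int
    matched_kos: frozenset[str]


def step_satisfied(step: Step, kos: frozenset[str] | set[str]) -> bool:
    """True iff some alternative's required KO set is fully contained in
    ``kos``; optional components never affect satisfaction."""
    return any(alt.required_kos <= kos for alt in step.alternatives)


def module_coverage(
    module: ModuleDefinition,
    genome: GenomeAnnotation | Iterable[str],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CompletenessCall:
    """Score one module against one genome's KO content."""
    if isinstance(genome, GenomeAnnotation):
        genome_id = genome.genome_id
        kos = genome.ko_set
    else:
        genome_id = "<ko-set>"
        kos = frozenset(genome)

    required_steps = [s for s in module.steps if not s.optional]
    if not required_steps:
        raise DegenerateModuleError(
            f"module {module.module_id}: no non-optional steps"
        )
    satisfied = sum(1 for s in required_steps if step_satisfied(s, kos))
    total = len(required_steps)
    required_union = module.required_ko_union
    matched = frozenset(required_union & kos)

    if config.coverage_mode == "genes":
        coverage = len(matched) / len(required_union)
    else:
        coverage = satisfied / total
    present = coverage >= config.presence_threshold
    return CompletenessCall(
        genome_id=genome_id,
        module_id=module.module_id,
        coverage=coverage,
        present=present,
        satisfied_steps=satisfied,
        total_steps=total,
        matched_kos=matched,
    )


@dataclass
class CompletenessMatrix:
    """Dense genome x module completeness calls for one consortium."""

    consortium: str
    genome_ids: list[str]
    module_ids: list[str]
    calls: list[CompletenessCall]

    def _pivot(self, attr: str) -> pd.DataFrame:
        data = {
            (c.genome_id, c.module_id): getattr(c, attr) for c in self.calls
        }
        frame = pd.DataFrame(
            [
                [data[(g, m)] for m in self.module_ids]
                for g in self.genome_ids
            ],
            index=self.genome_ids,
            columns=self.module_ids,
        )
        frame.index.name = "genome_id"
        return frame

    def coverage_frame(self) -> pd.DataFrame:
        return self._pivot("coverage")

    def presence_frame(self) -> pd.DataFrame:
        return self._pivot("present").astype(bool)

    def module_union(self) -> frozenset[str]:
        """Modules present in at least one member."""
        return frozenset(c.module_id for c in self.calls if c.present)

    def module_prevalence(self) -> pd.Series:
        """Fraction of members carrying each module (dense over all modules)."""
        presence = self.presence_frame()
        return presence.sum(axis=0) / len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-call table for TSV output."""
        return pd.DataFrame(
            {
                "genome_id": [c.genome_id for c in self.calls],
                "module_id": [c.module_id for c in self.calls],
                "coverage": [c.coverage for c in self.calls],
                "present": [c.present for c in self.calls],
                "satisfied_steps": [c.satisfied_steps for c in self.calls],
                "total_steps": [c.total_steps for c in self.calls],
            }
        )


def profile_consortium_modules(
    consortium: ConsortiumSpec,
    modules: Sequence[ModuleDefinition],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CompletenessMatrix:
    """Score every module in every member of a consortium."""
    if not modules:
        raise ValueError("module list must be nonempty")
    calls = [
        module_coverage(module, member, config)
        for member in consortium.members
        for module in modules
    ]
    return CompletenessMatrix(
        consortium=consortium.name,
        genome_ids=consortium.member_ids,
        module_ids=[m.module_id for m in modules],
        calls=calls,
    )
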