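"""Analysis configuration shared across all pipeline stages.

Every threshold that shapes a biological conclusion lives here, with the
defaults used for the defined-consortium comparison: a module is called
present in an isolate when at least 75% of its (non-optional) reaction
steps are covered, prevalence tables keep KOs shared by >= 3 isolates,
modules carried by more than 80% of the pooled isolates are dropped as
uninformative before comparative statistics, pathways with a signed
reporter score below -1.6 are called enriched in the pre-weaning
direction, and two-group tests are read at alpha = 0.05 after FDR
correction.  Amino-acid concentrations below the 1 nmol/g detection
limit contribute zero by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

_COVERAGE_MODES = ("steps", "genes")
_LOD_POLICIES = ("zero", "half_lod")
_WARD_VARIANTS = ("ward1", "ward2")

#: short human explanation written next to each key by ``to_file``
_COMMENTS = {
    "presence_threshold": "module called present at coverage >= this fraction (inclusive)",
    "coverage_mode": "steps: satisfied steps / total steps; genes: matched KOs / required KO union",
    "prevalence_min_isolates": "prevalence-table rows need a KO in at least this many isolates",
    "high_prevalence_fraction": "modules in more than floor(fraction * N) pooled isolates are removed",
    "reporter_threshold": "pathways with signed adjusted reporter score < -threshold are enriched",
    "alpha": "significance level applied to FDR-adjusted p-values (q < alpha)",
    "lod": "detection limit for individual amino acids, nmol/g",
    "lod_policy": "zero: below-LOD values contribute 0; half_lod: contribute lod/2",
    "ward_variant": "ward1: Lance-Williams update on unsquared Euclidean distances",
    "rng_seed": "seed for every stochastic step (reporter background sampling, simulation)",
}


@dataclass
class AnalysisConfig:
    presence_threshold: float = 0.75
    coverage_mode: str = "steps"
    prevalence_min_isolates: int = 3
    high_prevalence_fraction: float = 0.80
    reporter_threshold: float = 1.6
    alpha: float = 0.05
    lod: float = 1.0
    lod_policy: str = "zero"
    ward_variant: str = "ward1"
    rng_seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if not (0.0 < self.presence_threshold <= 1.0):
            raise ConfigurationError(
                f"presence_threshold must be in (0, 1], got {self.presence_threshold}"
            )
        if self.coverage_mode not in _COVERAGE_MODES:
            raise ConfigurationError(f"coverage_mode must be one of {_COVERAGE_MODES}")
        if self.prevalence_min_isolates < 1:
            raise ConfigurationError("prevalence_min_isolates must be >= 1")
        if not (0.0 < self.high_prevalence_fraction <= 1.0):
            raise ConfigurationError("high_prevalence_fraction must be in (0, 1]")
        if self.reporter_threshold <= 0:
            raise ConfigurationError("reporter_threshold must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.lod < 0:
            raise ConfigurationError("lod must be nonnegative")
        if self.lod_policy not in _LOD_POLICIES:
            raise ConfigurationError(f"lod_policy must be one of {_LOD_POLICIES}")
        if self.ward_variant not in _WARD_VARIANTS:
            raise ConfigurationError(f"ward_variant must be one of {_WARD_VARIANTS}")
        return self

    # -- flat key = value round trip ------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = ["# gnotofunc analysis configuration"]
        for field in dataclasses.fields(self):
            lines.append(f"# {_COMMENTS[field.name]}")
            lines.append(f"{field.name} = {getattr(self, field.name)}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1
        ):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ConfigurationError(f"line {lineno}: unknown key {key!r}")
            kwargs[key] = casts[str(types[key])](value)
        return cls(**kwargs).validate()

    def provenance_lines(self) -> list[str]:
        """Comment lines recording the full config, for result-file headers."""
        return [
            f"# {field.name} = {getattr(self, field.name)}"
            for field in dataclasses.fields(self)
        ]


DEFAULT_CONFIG = AnalysisConfig()
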