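"""Rule-based detection of sialic-acid catabolism gene clusters.

A typical *nan* cluster comprises the N-acetylneuraminate lyase (nanA),
N-acetylmannosamine-6-phosphate 2-epimerase (nanE) and
N-acetylmannosamine kinase (nanK) genes; *Bacteroidota* species
catabolize sialic acid without nanK, so the rule makes nanK optional
conditional on that phylum.  Sialidase (nanH), which releases sialic
acid from substrates such as sialyllactose, is treated as a separate
single-gene rule.  Detection is co-occurrence of the symbols' KOs
within a genome's annotation; physical adjacency (operon structure) is
not evaluated because the inputs are coordinate-free KO tables.

The shipped symbol -> KO map is configuration, not ground truth: verify
it against the KO catalogue in use before drawing conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotation_io import GenomeAnnotation
from .errors import ConfigurationError, ParseError

#: default symbol -> KO mapping for the sialic-acid catabolism genes
DEFAULT_SYMBOL_TO_KO: dict[str, tuple[str, ...]] = {
    "nanA": ("K01639",),
    "nanE": ("K01788",),
    "nanK": ("K00885",),
    "nanH": ("K01186",),
}


@dataclass(frozen=True)
class TaxonPredicate:
    """True when a genome's taxonomy has ``rank`` equal to ``value``."""

    rank: str
    value: str

    def __call__(self, genome: GenomeAnnotation) -> bool:
        return genome.taxonomy.get(self.rank, "") == self.value


@dataclass
class ClusterRule:
    name: str
    required: frozenset[str]
    optional: frozenset[str] = frozenset()
    #: symbol -> predicate; the symbol is optional when the predicate is
    #: true for the genome, required otherwise
    conditional_optional: dict[str, TaxonPredicate] = field(default_factory=dict)
    symbol_to_ko: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SYMBOL_TO_KO)
    )

    def __post_init__(self) -> None:
        if self.required & self.optional:
            raise ConfigurationError(
                f"rule {self.name!r}: required and optional sets overlap"
            )
        for symbol in self.all_symbols:
            if symbol not in self.symbol_to_ko:
                raise ConfigurationError(
                    f"rule {self.name!r}: symbol {symbol!r} has no KO mapping"
                )

    @property
    def all_symbols(self) -> frozenset[str]:
        return self.required | self.optional | frozenset(self.conditional_optional)


@dataclass(frozen=True)
class ClusterCall:
    genome_id: str
    rule: str
    status: str  # complete | partial | absent
    matched: frozenset[str]
    missing_required: frozenset[str]


#: default rule: nanA + nanE required, nanK required except in Bacteroidota
NAN_CLUSTER_RULE = ClusterRule(
    name="nan_cluster",
    required=frozenset({"nanA", "nanE"}),
    conditional_optional={
        "nanK": TaxonPredicate(rank="phylum", value="Bacteroidota")
    },
)

#: permissive variant: nanE alone suffices (nanA and nanK informative only)
NAN_CLUSTER_PERMISSIVE = ClusterRule(
    name="nan_cluster_permissive",
    required=frozenset({"nanE"}),
    optional=frozenset({"nanA"}),
    conditional_optional={
        "nanK": TaxonPredicate(rank="phylum", value="Bacteroidota")
    },
)

#: sialidase as its own single-gene rule
NANH_SIALIDASE_RULE = ClusterRule(name="nanH_sialidase", required=frozenset({"nanH"}))

DEFAULT_RULES = (NAN_CLUSTER_RULE, NANH_SIALIDASE_RULE)


def _symbol_matched(
    symbol: str, rule: ClusterRule, genome: GenomeAnnotation
) -> bool:
    kos = rule.symbol_to_ko[symbol]
    return any(ko in genome.ko_counts for ko in kos)


def detect_cluster(genome: GenomeAnnotation, rule: ClusterRule) -> ClusterCall:
    """Evaluate one rule against one genome.

    The effective required set is the rule's required symbols plus every
    conditional symbol whose taxon predicate is false for this genome.
    Status is ``complete`` when all effectively-required symbols match,
    ``absent`` when no rule symbol matches at all, else ``partial``.
    """
    effective_required = set(rule.required)
    for symbol, predicate in rule.conditional_optional.items():
        if not predicate(genome):
            effective_required.add(symbol)
    matched = frozenset(
        s for s in rule.all_symbols if _symbol_matched(s, rule, genome)
    )
    missing = frozenset(effective_required - matched)
    if not matched:
        status = "absent"
    elif not missing:
        status = "complete"
    else:
        status = "partial"
    return ClusterCall(
        genome_id=genome.genome_id,
        rule=rule.name,
        status=status,
        matched=matched,
        missing_required=missing,
    )


def detect_all(
    genomes: Sequence[GenomeAnnotation],
    rules: Sequence[ClusterRule] = DEFAULT_RULES,
) -> list[ClusterCall]:
    return [detect_cluster(g, r) for g in genomes for r in rules]


def calls_frame(calls: Sequence[ClusterCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "genome_id": [c.genome_id for c in calls],
            "rule": [c.rule for c in calls],
            "status": [c.status for c in calls],
            "matched": [",".join(sorted(c.matched)) for c in calls],
            "missing_required": [",".join(sorted(c.missing_required)) for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# rule files
# ---------------------------------------------------------------------------

def read_cluster_rules(path: str | Path) -> list[ClusterRule]:
    """Read rules from structured text.

    Blocks start with ``rule: NAME``; subsequent lines:

    * ``required: SYM [SYM ...]``
    * ``optional: SYM [SYM ...]``
    * ``conditional: SYM unless RANK=VALUE``
    * ``map: SYM KO [KO ...]``

    Blank lines and ``#`` comments are ignored; a new ``rule:`` line or
    end of file closes the block.
    """
    rules: list[ClusterRule] = []
    current: dict | None = None

    def finalize(block: dict) -> None:
        mapping = dict(DEFAULT_SYMBOL_TO_KO)
        mapping.update(block["map"])
        rules.append(
            ClusterRule(
                name=block["name"],
                required=frozenset(block["required"]),
                optional=frozenset(block["optional"]),
                conditional_optional=block["conditional"],
                symbol_to_ko=mapping,
            )
        )

    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ParseError(f"{path}: line {lineno}: expected 'key: value'")
        key, value = (part.strip() for part in line.split(":", 1))
        if key == "rule":
            if current is not None:
                finalize(current)
            current = {
                "name": value,
                "required": [],
                "optional": [],
                "conditional": {},
                "map": {},
            }
            continue
        if current is None:
            raise ParseError(f"{path}: line {lineno}: {key!r} before any 'rule:'")
        if key in ("required", "optional"):
            current[key].extend(value.split())
        elif key == "conditional":
            parts = value.split()
            if len(parts) != 3 or parts[1] != "unless" or "=" not in parts[2]:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'SYM unless RANK=VALUE'"
                )
            rank, taxon = parts[2].split("=", 1)
            current["conditional"][parts[0]] = TaxonPredicate(rank, taxon)
        elif key == "map":
            parts = value.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 'SYM KO [KO ...]'")
            current["map"][parts[0]] = tuple(parts[1:])
        else:
            raise ParseError(f"{path}: line {lineno}: unknown key {key!r}")
    if current is not None:
        finalize(current)
    return rules


def symbol_to_ko_table(rules: Sequence[ClusterRule]) -> Mapping[str, tuple[str, ...]]:
    merged: dict[str, tuple[str, ...]] = {}
    for rule in rules:
        merged.update(rule.symbol_to_ko)
    return merged
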