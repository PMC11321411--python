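"""Readers, writers and domain types for annotation and module-definition formats.

Four formats are handled:

* gene -> KO assignment tables (two-column TSV, KAAS-style): one row per
  open reading frame, second column a KEGG Ortholog id or empty when the
  gene received no assignment;
* module flat files in the gut-metabolic-module (GMM) dialect: an
  ``ID<TAB>Name`` header, one line per reaction step, ``///`` terminator,
  commas separating OR-alternatives and ``+`` joining the members of a
  required enzyme complex;
* KEGG-style boolean DEFINITION strings, where spaces separate serial
  steps, commas mean OR, ``+`` marks complex members, a leading ``-``
  marks an optional component, and parentheses group;
* a KO functional hierarchy table (KO, pathway, category, subcategory).

All parsers tolerate blank lines, ``#`` comments where noted, trailing
whitespace, and CRLF line endings.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import ParseError

KO_PATTERN = re.compile(r"^K\d{5}$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alternative:
    """One way of accomplishing a reaction step: an all-required KO set
    (a complex when it has more than one member), plus optional members
    that never enter completeness denominators."""

    required_kos: frozenset[str]
    optional_kos: frozenset[str] = frozenset()

    def _key(self) -> tuple:
        return (tuple(sorted(self.required_kos)), tuple(sorted(self.optional_kos)))


@dataclass(frozen=True)
class Step:
    """One reaction step: a set of OR-alternatives.  A step with no
    alternatives (all its components were optional) is itself optional
    and excluded from completeness denominators."""

    alternatives: tuple[Alternative, ...]
    optional_kos: frozenset[str] = frozenset()

    @property
    def optional(self) -> bool:
        return not self.alternatives

    @property
    def required_union(self) -> frozenset[str]:
        out: set[str] = set()
        for alt in self.alternatives:
            out |= alt.required_kos
        return frozenset(out)


def _canonical_step(alternatives: Iterable[Alternative],
                    optional_kos: Iterable[str] = ()) -> Step:
    alts = tuple(sorted(set(alternatives), key=Alternative._key))
    return Step(alts, frozenset(optional_kos))


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module: ordered reaction steps, each a set of
    OR-alternatives over KO complexes."""

    module_id: str
    name: str
    steps: tuple[Step, ...]
    category: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ParseError(f"module {self.module_id}: needs at least one step")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def n_required_steps(self) -> int:
        return sum(1 for s in self.steps if not s.optional)

    @property
    def required_ko_union(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= step.required_union
        return frozenset(out)

    @property
    def all_kos(self) -> frozenset[str]:
        out: set[str] = set(self.required_ko_union)
        for step in self.steps:
            out |= step.optional_kos
            for alt in step.alternatives:
                out |= alt.optional_kos
        return frozenset(out)


@dataclass
class GenomeAnnotation:
    """One genome's KO copy-number profile plus taxonomy labels."""

    genome_id: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    ko_counts: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be nonempty")
        bad = [k for k, c in self.ko_counts.items() if c < 1]
        if bad:
            raise ValueError(f"KO copy counts must be >= 1, offending: {bad[:3]}")

    @property
    def ko_set(self) -> frozenset[str]:
        return frozenset(self.ko_counts)

    @property
    def n_distinct_kos(self) -> int:
        return len(self.ko_counts)


@dataclass
class ConsortiumSpec:
    """A named, defined consortium: an ordered list of member genomes."""

    name: str
    members: list[GenomeAnnotation]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"consortium {self.name!r} needs at least one member")
        ids = [m.genome_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"consortium {self.name!r} has duplicate genome ids")

    @property
    def member_ids(self) -> list[str]:
        return [m.genome_id for m in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


class PathwayEntry(NamedTuple):
    pathway: str
    category: str
    subcategory: str


#: bucket returned for KOs not present in the hierarchy; never an error
UNANNOTATED = PathwayEntry("unannotated", "unannotated", "unannotated")


@dataclass
class FunctionalHierarchy:
    """KO -> [(pathway, category, subcategory), ...] lookup.

    A KO may map to multiple pathways; an unknown KO resolves to the
    explicit ``unannotated`` bucket.
    """

    entries: dict[str, list[PathwayEntry]] = field(default_factory=dict)

    def lookup(self, ko: str) -> list[PathwayEntry]:
        return self.entries.get(ko, [UNANNOTATED])

    def pathways_of(self, ko: str) -> list[str]:
        return sorted({e.pathway for e in self.lookup(ko)})

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


# ---------------------------------------------------------------------------
# gene -> KO annotation tables
# ---------------------------------------------------------------------------

def read_ko_annotation(
    path: str | Path,
    genome_id: str,
    taxonomy: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Read a KAAS-style two-column gene->KO TSV into a :class:`GenomeAnnotation`.

    Duplicate KO assignments aggregate into copy counts; rows with an
    empty KO column increment ``n_unassigned``.  Duplicate gene ids are
    counted once, with a warning.  Row order is irrelevant.
    """
    counts: Counter[str] = Counter()
    n_unassigned = 0
    seen_genes: set[str] = set()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) > 2:
            raise ParseError(
                f"{path}: line {lineno}: expected 1-2 tab-separated columns, "
                f"got {len(fields)}"
            )
        gene = fields[0].strip()
        ko = fields[1].strip() if len(fields) == 2 else ""
        if not gene:
            raise ParseError(f"{path}: line {lineno}: empty gene id")
        if gene in seen_genes:
            warnings.warn(
                f"{path}: line {lineno}: duplicate gene id {gene!r}, counted once"
            )
            continue
        seen_genes.add(gene)
        if ko:
            if not KO_PATTERN.match(ko):
                # tolerated: EC-labelled or provisional tokens match verbatim
                warnings.warn(
                    f"{path}: line {lineno}: token {ko!r} is not a canonical KO id"
                )
            counts[ko] += 1
        else:
            n_unassigned += 1
    return GenomeAnnotation(
        genome_id=genome_id,
        taxonomy=dict(taxonomy or {}),
        ko_counts=dict(counts),
        n_unassigned=n_unassigned,
    )


def write_ko_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a gene->KO table that reads back to an identical annotation
    (gene ids are synthesized; copy counts expand to one row per copy)."""
    lines = []
    i = 0
    for ko in sorted(annotation.ko_counts):
        for _ in range(annotation.ko_counts[ko]):
            i += 1
            lines.append(f"{annotation.genome_id}_g{i:05d}\t{ko}")
    for _ in range(annotation.n_unassigned):
        i += 1
        lines.append(f"{annotation.genome_id}_g{i:05d}\t")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# GMM flat files
# ---------------------------------------------------------------------------

def _parse_gmm_step(line: str, module_id: str, lineno: int) -> Step:
    alternatives: list[Alternative] = []
    step_optional: set[str] = set()
    for token in (t.strip() for t in line.split(",")):
        if not token:
            continue
        required: set[str] = set()
        optional: set[str] = set()
        for member in (m.strip() for m in token.split("+")):
            if not member:
                continue
            if member.startswith("-"):
                optional.add(member[1:].strip())
            else:
                required.add(member)
        required.discard("")
        optional.discard("")
        if required:
            alternatives.append(Alternative(frozenset(required), frozenset(optional)))
        else:
            step_optional |= optional
    if not alternatives and not step_optional:
        raise ParseError(
            f"module {module_id}: step line {lineno} has no valid KO token"
        )
    return _canonical_step(alternatives, step_optional)


def parse_gmm_text(text: str, source: str = "<string>") -> list[ModuleDefinition]:
    modules: list[ModuleDefinition] = []
    seen_ids: set[str] = set()
    current: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "///":
            if current is None:
                raise ParseError(f"{source}: line {lineno}: '///' outside a block")
            if not current["steps"]:
                raise ParseError(
                    f"{source}: module {current['id']}: block has no steps"
                )
            if current["id"] in seen_ids:
                warnings.warn(
                    f"{source}: duplicate module id {current['id']!r}, keeping first"
                )
            else:
                seen_ids.add(current["id"])
                modules.append(
                    ModuleDefinition(
                        module_id=current["id"],
                        name=current["name"],
                        steps=tuple(current["steps"]),
                        category=current["category"],
                    )
                )
            current = None
            continue
        if current is None:
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{source}: line {lineno}: module header must be 'ID<TAB>Name'"
                )
            current = {
                "id": fields[0],
                "name": fields[1],
                "category": fields[2] if len(fields) > 2 else "",
                "steps": [],
            }
        else:
            current["steps"].append(_parse_gmm_step(line, current["id"], lineno))
    if current is not None:
        raise ParseError(
            f"{source}: module {current['id']}: block not terminated by '///'"
        )
    return modules


def read_gmm_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Read a GMM flat file (blocks of ``ID<TAB>Name``, step lines, ``///``)."""
    return parse_gmm_text(Path(path).read_text(encoding="utf-8"), source=str(path))


def _format_alternative(alt: Alternative) -> str:
    parts = sorted(alt.required_kos) + [f"-{k}" for k in sorted(alt.optional_kos)]
    return "+".join(parts)


def write_gmm_definitions(
    modules: Sequence[ModuleDefinition], path: str | Path
) -> None:
    """Write modules in the GMM flat dialect; round-trips through
    :func:`read_gmm_definitions` exactly."""
    lines: list[str] = []
    for module in modules:
        header = f"{module.module_id}\t{module.name}"
        if module.category:
            header += f"\t{module.category}"
        lines.append(header)
        for step in module.steps:
            if step.optional:
                lines.append("+".join(f"-{k}" for k in sorted(step.optional_kos)))
            else:
                tokens = [_format_alternative(a) for a in step.alternatives]
                if step.optional_kos:
                    tokens.append("+".join(f"-{k}" for k in sorted(step.optional_kos)))
                lines.append(",".join(tokens))
        lines.append("///")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_module_table(modules: Sequence[ModuleDefinition], path: str | Path) -> None:
    """TSV dump of a module database (one row per module)."""
    lines = ["module_id\tname\tcategory\tn_steps\tn_required_steps\tko_union"]
    for m in modules:
        lines.append(
            f"{m.module_id}\t{m.name}\t{m.category}\t{m.n_steps}\t"
            f"{m.n_required_steps}\t{','.join(sorted(m.required_ko_union))}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# KEGG-style boolean DEFINITION strings
# ---------------------------------------------------------------------------

def _check_balanced(s: str) -> None:
    depth = 0
    for pos, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced parenthesis at position {pos}")
    if depth != 0:
        raise ParseError(f"unbalanced parenthesis at position {len(s)}")


def _split_top(s: str, seps: str) -> list[str]:
    """Split on any of ``seps`` at parenthesis depth zero; drops empties."""
    parts: list[str] = []
    buf: list[str] = []
    depth = 0
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and ch in seps:
            if buf:
                parts.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        parts.append("".join(buf))
    return parts


def _parse_or(s: str) -> list[tuple[frozenset, frozenset]]:
    """Parse an expression into a list of (required, optional) alternatives."""
    out: list[tuple[frozenset, frozenset]] = []
    for part in _split_top(s, ","):
        out.extend(_parse_and(part))
    return out


def _parse_and(s: str) -> list[tuple[frozenset, frozenset]]:
    # '+' and space are both conjunctive inside a step expression
    factors = _split_top(s, "+ ")
    combos: list[tuple[frozenset, frozenset]] = [(frozenset(), frozenset())]
    for factor in factors:
        factor = factor.strip()
        optional_factor = factor.startswith("-")
        if optional_factor:
            factor = factor[1:].strip()
        if not factor:
            continue
        if factor.startswith("(") and factor.endswith(")"):
            sub = _parse_or(factor[1:-1])
        else:
            sub = [(frozenset({factor}), frozenset())]
        if optional_factor:
            sub = [(frozenset(), req | opt) for req, opt in sub]
        combos = [
            (req0 | req1, opt0 | opt1)
            for req0, opt0 in combos
            for req1, opt1 in sub
        ]
    return combos


def parse_kegg_definition(
    defstring: str, module_id: str, name: str, category: str = ""
) -> ModuleDefinition:
    """Parse a KEGG-style boolean DEFINITION string into a module.

    Space separates serial steps, comma is OR, ``+`` joins complex
    members, a leading ``-`` marks an optional component (excluded from
    coverage denominators), and parentheses group to arbitrary depth.
    """
    _check_balanced(defstring)
    steps: list[Step] = []
    for token in _split_top(defstring.strip(), " "):
        alternatives = _parse_or(token)
        kept = [
            Alternative(req, opt) for req, opt in alternatives if req
        ]
        step_optional: set[str] = set()
        for req, opt in alternatives:
            if not req:
                step_optional |= opt
        if not kept and not step_optional:
            continue
        steps.append(_canonical_step(kept, step_optional))
    if not steps:
        raise ParseError(f"module {module_id}: empty definition")
    return ModuleDefinition(module_id=module_id, name=name,
                            steps=tuple(steps), category=category)


# ---------------------------------------------------------------------------
# functional hierarchy
# ---------------------------------------------------------------------------

def read_hierarchy(path: str | Path) -> FunctionalHierarchy:
    """Read a KO -> pathway -> category/subcategory TSV (header row,
    >= 4 columns).  Multi-pathway KOs produce multiple entries."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 4:
        raise ParseError(
            f"{path}: hierarchy table needs >= 4 columns "
            f"(ko, pathway, category, subcategory), got {df.shape[1]}"
        )
    entries: dict[str, list[PathwayEntry]] = {}
    for row in df.itertuples(index=False):
        ko, pathway, category, subcategory = (
            str(row[0]).strip(),
            str(row[1]).strip(),
            str(row[2]).strip(),
            str(row[3]).strip(),
        )
        entry = PathwayEntry(pathway, category, subcategory)
        bucket = entries.setdefault(ko, [])
        if entry not in bucket:  # idempotent on re-read / duplicate rows
            bucket.append(entry)
    return FunctionalHierarchy(entries)


def write_hierarchy(hierarchy: FunctionalHierarchy, path: str | Path) -> None:
    lines = ["ko\tpathway\tcategory\tsubcategory"]
    for ko in sorted(hierarchy.entries):
        for entry in hierarchy.entries[ko]:
            lines.append(f"{ko}\t{entry.pathway}\t{entry.category}\t{entry.subcategory}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# consortium metadata
# ---------------------------------------------------------------------------

def read_consortium_metadata(
    path: str | Path, base_dir: str | Path | None = None
) -> dict[str, ConsortiumSpec]:
    """Read a consortium membership table and the annotation files it names.

    Columns (header row, tab-separated): genome_id, consortium, phylum,
    family, annotation_path.  Relative annotation paths resolve against
    ``base_dir`` (default: the metadata file's directory).  Returns
    consortia keyed by name, members in file order.
    """
    import pandas as pd

    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "consortium", "phylum", "family", "annotation_path"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    grouped: dict[str, list[GenomeAnnotation]] = {}
    for row in df.itertuples(index=False):
        ann_path = Path(row.annotation_path)
        if not ann_path.is_absolute():
            ann_path = base / ann_path
        annotation = read_ko_annotation(
            ann_path,
            genome_id=row.genome_id,
            taxonomy={"phylum": row.phylum, "family": row.family},
        )
        grouped.setdefault(row.consortium, []).append(annotation)
    return {name: ConsortiumSpec(name, members) for name, members in grouped.items()}
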