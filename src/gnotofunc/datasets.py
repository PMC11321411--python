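"""Bundled reference tables.

``infant_enriched_kos`` is the published per-isolate copy-count table of
KOs that are unique to the pre-weaning consortium and overrepresented in
human infant fecal metagenomes: 24 KOs by 9 isolates, plus pathway and
description columns and the consortia each KO is absent from.  The copy
counts are inputs; gene counts and prevalences are always recomputed
from them by :func:`gnotofunc.consortium.build_prevalence_table`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation_io import ConsortiumSpec, GenomeAnnotation

_META_COLUMNS = ("ko", "pathway", "description", "absent_in")


def load_infant_enriched_kos() -> pd.DataFrame:
    """The bundled per-isolate KO copy-count table (24 KOs x 9 isolates)."""
    with resources.files("gnotofunc.data").joinpath(
        "infant_enriched_kos.tsv"
    ).open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t")


def infant_enriched_consortium(name: str = "pre_weaning") -> ConsortiumSpec:
    """The 9-isolate consortium reconstructed from the bundled copy counts.

    Each member's annotation is restricted to the 24 tabulated KOs; this
    is exactly the information needed to rebuild the prevalence table.
    """
    table = load_infant_enriched_kos()
    isolates = [c for c in table.columns if c not in _META_COLUMNS]
    members = []
    for isolate in isolates:
        counts = {
            row.ko: int(getattr(row, isolate))
            for row in table.itertuples(index=False)
            if int(getattr(row, isolate)) > 0
        }
        members.append(GenomeAnnotation(genome_id=isolate, ko_counts=counts))
    return ConsortiumSpec(name, members)


def infant_enriched_descriptions() -> dict[str, str]:
    table = load_infant_enriched_kos()
    return dict(zip(table["ko"], table["description"]))
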