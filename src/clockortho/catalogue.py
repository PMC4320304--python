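"""The printed barley/Arabidopsis clock-gene catalogue and its summaries.

The package ships a transcription of the published catalogue of circadian
clock and clock-associated genes (gene names, locus identifiers and the
orthologue/paralogue relationship of each barley gene to its Arabidopsis
counterpart) plus the handful of genes named only in the running text.
:func:`summarize` recomputes the headline tallies from those entries —
the number of barley homologues, the families with a single one-to-one
barley orthologue, and the fraction of the ten-component ancestral core
clock represented by true orthologues — rather than storing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .records import InvalidInputError

__all__ = [
    "CatalogueEntry",
    "SummaryReport",
    "CORE_FAMILIES",
    "load_catalogue",
    "summarize",
]

RELATIONS = ("one_to_one_orthologue", "orthologue_ambiguous", "paralogue",
             "absent")

#: Ten clock components attributed to the common ancestor of monocots and
#: dicots (PRR3/7 and PRR9/5 are each a single ancestral gene).
CORE_FAMILIES = ("LHY", "TOC1", "PRR3/7", "PRR9/5", "GI", "LUX", "ELF3",
                 "FKF1", "ZTL", "ELF4-like")


@dataclass(frozen=True)
class CatalogueEntry:
    family: str
    species: str
    gene_name: str
    identifier: str
    relation: str
    partial: bool = False
    core_clock: bool = False
    source: str = "table1"

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise InvalidInputError(
                f"{self.gene_name}: unknown relation {self.relation!r}")
        if self.relation == "absent" and self.identifier:
            raise InvalidInputError(
                f"{self.gene_name}: absent entries carry no identifier")


def load_catalogue(path: str | Path | None = None) -> list[CatalogueEntry]:
    """Load catalogue entries from TSV (the packaged fixture by default).

    Validates the schema and rejects duplicate identifiers within a
    species, naming the offending row.
    """
    if path is None:
        ref = resources.files("clockortho").joinpath("data/table1_catalogue.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries: list[CatalogueEntry] = []
    seen_ids: dict[tuple[str, str], int] = {}
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            expected = ["family", "species", "gene_name", "identifier",
                        "relation", "partial", "core_clock", "source"]
            if header != expected:
                raise InvalidInputError(
                    f"catalogue header {header} != expected {expected}")
            continue
        if len(fields) != len(header):
            raise InvalidInputError(f"row {lineno}: wrong column count")
        row = dict(zip(header, fields))
        entry = CatalogueEntry(
            family=row["family"], species=row["species"],
            gene_name=row["gene_name"], identifier=row["identifier"],
            relation=row["relation"], partial=row["partial"] == "1",
            core_clock=row["core_clock"] == "1", source=row["source"],
        )
        if entry.identifier:
            key = (entry.species, entry.identifier)
            if key in seen_ids:
                raise InvalidInputError(
                    f"row {lineno}: duplicate identifier {entry.identifier} "
                    f"for {entry.species} (first at row {seen_ids[key]})")
            seen_ids[key] = lineno
        entries.append(entry)
    return entries


@dataclass(frozen=True)
class SummaryReport:
    """Recomputed catalogue tallies (percentages derived, never stored)."""

    n_entries: int
    barley_gene_count: int
    counts_by_relation: dict
    copies_per_family: dict      # (species, family) -> gene count
    one_to_one_families: tuple[str, ...]
    core_families: tuple[str, ...]
    provenance_notes: tuple[str, ...] = ()

    @property
    def core_orthologue_fraction(self) -> float:
        core_one_to_one = [f for f in self.one_to_one_families
                           if f in self.core_families]
        return len(core_one_to_one) / len(self.core_families)

    @property
    def core_orthologue_percent(self) -> float:
        return 100.0 * self.core_orthologue_fraction

    def describe(self) -> str:
        core_hits = [f for f in self.one_to_one_families
                     if f in self.core_families]
        lines = [
            f"catalogue entries: {self.n_entries}",
            f"barley homologues: {self.barley_gene_count}",
            f"families with a single one-to-one barley orthologue: "
            f"{', '.join(self.one_to_one_families) or 'none'}",
            f"ancestral core set ({len(self.core_families)}): "
            f"{', '.join(self.core_families)}",
            f"core one-to-one orthologues: {len(core_hits)}/"
            f"{len(self.core_families)} = {self.core_orthologue_percent:.0f}%",
        ]
        return "\n".join(lines)


def summarize(entries: Sequence[CatalogueEntry],
              families: Iterable[str] | None = None,
              species: Iterable[str] | None = None) -> SummaryReport:
    """Recompute catalogue tallies, optionally restricted in scope.

    A family counts as having a one-to-one barley orthologue when barley
    has exactly one (non-absent) gene in the family and that gene is a
    one-to-one orthologue of its Arabidopsis counterpart.  The headline
    core fraction divides those families by the ten-component ancestral
    core set, both of which the report carries explicitly.
    """
    fam_filter = set(families) if families is not None else None
    sp_filter = set(species) if species is not None else None
    scoped = [e for e in entries
              if (fam_filter is None or e.family in fam_filter)
              and (sp_filter is None or e.species in sp_filter)]

    present = [e for e in scoped if e.relation != "absent"]
    barley = [e for e in present if e.species == "barley"]

    counts_by_relation: dict = {}
    for e in scoped:
        counts_by_relation.setdefault(e.species, {}).setdefault(e.relation, 0)
        counts_by_relation[e.species][e.relation] += 1

    copies: dict = {}
    for e in present:
        key = (e.species, e.family)
        copies[key] = copies.get(key, 0) + 1

    one_to_one = []
    for fam in sorted({e.family for e in scoped}):
        fam_barley = [e for e in barley if e.family == fam]
        if (len(fam_barley) == 1
                and fam_barley[0].relation == "one_to_one_orthologue"):
            one_to_one.append(fam)

    core = tuple(f for f in CORE_FAMILIES
                 if fam_filter is None or f in fam_filter)
    notes = tuple(sorted({f"{e.gene_name}: from running text"
                          for e in barley if e.source == "text"}))
    return SummaryReport(
        n_entries=len(scoped),
        barley_gene_count=len(barley),
        counts_by_relation=counts_by_relation,
        copies_per_family=copies,
        one_to_one_families=tuple(one_to_one),
        core_families=core,
        provenance_notes=notes,
    )
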