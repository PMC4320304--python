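"""Iterative cross-species reciprocal-best-hit orthology classification.

The procedure mirrors the in-silico workflow used to catalogue plant
circadian-clock genes: seed genes are searched against every other
species' database; each top hit (and every additional hit with a similar
E-value) is searched back and onwards against all databases; when a
reciprocal search lands on a *different* gene in the seed's species, that
gene and its whole home-species family join the search frontier.  The
fixed point of this expansion is a reciprocity graph from which
orthologue, paralogue and unresolved calls are read off:

* **orthologue** — mutual top hits between two species, ideally as part of
  a clique in which every member is every other member's top hit in its
  own species.  One-to-many cases (an E-value tie reciprocating to the
  same partner) are still emitted as orthologues but carry an explicit
  ambiguity flag, never silently resolved.
* **paralogue** — same-species genes with similar E-values against a
  common query that reciprocate into the same partner set (i.e. lineage-
  specific duplicates).
* **unresolved** — any other pair that co-occurs in the tested graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from .records import InvalidInputError, SequenceRecord, SpeciesDatabase
from .search import (DEFAULT_SCORING, HitList, ScoringParams, SearchHit,
                     search, top_hit)

__all__ = [
    "OrthologyConfig",
    "OrthologyCall",
    "ReciprocityGraph",
    "FamilyExpansionState",
    "similar_evalue_hits",
    "reciprocal_check",
    "expand_family",
    "classify",
    "write_calls_tsv",
]


@dataclass(frozen=True)
class OrthologyConfig:
    """Tunables of the reciprocity classification.

    ``evalue_ratio`` encodes "similar E-value" as a maximum ratio to the
    top hit (default one order of magnitude).  When the top E-value
    underflows to zero the ``bitscore_delta`` fallback (within 2 bits of
    the top hit) applies instead.
    """

    evalue_ratio: float = 10.0
    bitscore_delta: float = 2.0
    family_ratio: float = 1e8
    scoring: ScoringParams = DEFAULT_SCORING
    report_threshold: float | None = None

    def __post_init__(self):
        if self.evalue_ratio < 1:
            raise InvalidInputError("evalue_ratio must be >= 1")
        if self.family_ratio < self.evalue_ratio:
            raise InvalidInputError("family_ratio must be >= evalue_ratio")


def similar_evalue_hits(hl: HitList, ratio: float = 10.0,
                        bitscore_delta: float = 2.0) -> list[SearchHit]:
    """Hits whose E-value is within ``ratio`` of the top hit's.

    Always contains the top hit itself; empty list for an empty hit list.
    A zero top E-value switches to the bit-score-within-delta rule.
    """
    if ratio < 1:
        raise InvalidInputError("ratio must be >= 1")
    if not hl.hits:
        return []
    top = hl.hits[0]
    if top.evalue == 0.0:
        return [h for h in hl.hits if h.bitscore >= top.bitscore - bitscore_delta]
    return [h for h in hl.hits if h.evalue <= ratio * top.evalue]


@dataclass(frozen=True)
class OrthologyCall:
    """A classified relationship between two genes with its evidence trail."""

    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    relation: str  # orthologue | paralogue | unresolved
    ambiguous: bool = False
    evidence: tuple[str, ...] = ()

    def __post_init__(self):
        if self.relation not in ("orthologue", "paralogue", "unresolved"):
            raise InvalidInputError(f"bad relation {self.relation!r}")
        if self.relation != "unresolved" and not self.evidence:
            raise InvalidInputError("non-unresolved call requires evidence")

    def involves(self, gene: str) -> bool:
        return gene in (self.gene_a, self.gene_b)


class ReciprocityGraph:
    """Directed top-hit edges plus the full hit lists behind them."""

    def __init__(self) -> None:
        self.species_of: dict[str, str] = {}
        self.hitlists: dict[tuple[str, str], HitList] = {}
        self.no_hit: set[tuple[str, str]] = set()

    def add_node(self, gene: str, species: str) -> None:
        prev = self.species_of.get(gene)
        if prev is not None and prev != species:
            raise InvalidInputError(f"{gene}: conflicting species {prev}/{species}")
        self.species_of[gene] = species

    def record(self, hl: HitList, query_species: str) -> None:
        self.add_node(hl.query_id, query_species)
        self.hitlists[(hl.query_id, hl.target_species)] = hl
        if not hl.hits:
            self.no_hit.add((hl.query_id, hl.target_species))
        for h in hl.hits:
            self.add_node(h.subject_id, h.subject_species)

    def hitlist(self, gene: str, target_species: str) -> Optional[HitList]:
        return self.hitlists.get((gene, target_species))

    def top(self, gene: str, target_species: str) -> Optional[SearchHit]:
        hl = self.hitlists.get((gene, target_species))
        return top_hit(hl) if hl else None

    def edges(self) -> list[tuple[str, str, SearchHit]]:
        """All top-hit edges as (query, target_species, hit)."""
        out = []
        for (g, sp), hl in sorted(self.hitlists.items()):
            t = top_hit(hl)
            if t is not None:
                out.append((g, sp, t))
        return out

    def write_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("query\tquery_species\ttarget_species\ttop_hit\tevalue\tbitscore\n")
            for g, sp, h in self.edges():
                fh.write(f"{g}\t{self.species_of[g]}\t{sp}\t{h.subject_id}\t"
                         f"{h.evalue:.3e}\t{h.bitscore:.1f}\n")


@dataclass
class FamilyExpansionState:
    """Book-keeping of the iterative family expansion.

    ``tested`` holds (query gene, target species) pairs already searched;
    it grows monotonically and is never retried, which bounds the whole
    procedure by gene count x species count.
    """

    seed_genes: tuple[str, ...]
    frontier: set[str] = field(default_factory=set)
    queried: set[str] = field(default_factory=set)
    tested: set[tuple[str, str]] = field(default_factory=set)
    iteration_count: int = 0

    def enqueue(self, gene: str) -> None:
        if gene not in self.queried:
            self.frontier.add(gene)

    def pop(self) -> str:
        gene = min(self.frontier)  # deterministic order
        self.frontier.discard(gene)
        self.queried.add(gene)
        return gene


def reciprocal_check(gene_a: str, species_b: str, graph: ReciprocityGraph,
                     search_fn: Callable[[str, str], HitList]
                     ) -> tuple[bool, Optional[str]]:
    """Does the top hit of ``gene_a`` in ``species_b`` point straight back?

    Returns ``(holds, partner)``.  When the check fails because the return
    top hit is a different gene ``a'`` of ``gene_a``'s species, ``a'`` is
    reported as the expansion trigger; when it holds, ``partner`` is the
    mutual top hit ``b``.
    """
    if gene_a not in graph.species_of:
        raise InvalidInputError(f"{gene_a} not present in graph")
    species_a = graph.species_of[gene_a]
    fwd = graph.hitlist(gene_a, species_b) or search_fn(gene_a, species_b)
    b = top_hit(fwd)
    if b is None:
        return False, None
    back = graph.hitlist(b.subject_id, species_a) or search_fn(b.subject_id, species_a)
    a2 = top_hit(back)
    if a2 is not None and a2.subject_id == gene_a:
        return True, b.subject_id
    return False, (a2.subject_id if a2 is not None else None)


def expand_family(state: FamilyExpansionState, trigger_gene: str,
                  family_membership_fn: Callable[[str], Iterable[str]]
                  ) -> FamilyExpansionState:
    """Queue a reciprocity-breaking gene and its whole home family.

    Idempotent for already-queried genes; the iteration counter always
    advances so expansion activity is visible in the state.
    """
    state.iteration_count += 1
    state.enqueue(trigger_gene)
    for member in sorted(family_membership_fn(trigger_gene)):
        state.enqueue(member)
    return state


# ---------------------------------------------------------------------------

class _Engine:
    """Caches searches and runs the expansion to its fixed point."""

    def __init__(self, databases: dict[str, SpeciesDatabase],
                 config: OrthologyConfig):
        self.dbs = databases
        self.cfg = config
        self.graph = ReciprocityGraph()
        self._gene_index: dict[str, SequenceRecord] = {}
        for db in databases.values():
            for rec in db:
                if rec.id in self._gene_index:
                    raise InvalidInputError(f"gene id {rec.id} in multiple databases")
                self._gene_index[rec.id] = rec

    def record_of(self, gene: str) -> SequenceRecord:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise InvalidInputError(f"unknown gene id {gene!r}") from None

    def run_search(self, gene: str, target_species: str) -> HitList:
        cached = self.graph.hitlist(gene, target_species)
        if cached is not None:
            return cached
        rec = self.record_of(gene)
        hl = search(rec, self.dbs[target_species], self.cfg.scoring,
                    self.cfg.report_threshold)
        self.graph.record(hl, rec.species)
        return hl

    def similar(self, hl: HitList) -> list[SearchHit]:
        return similar_evalue_hits(hl, self.cfg.evalue_ratio,
                                   self.cfg.bitscore_delta)

    def home_family(self, gene: str) -> list[str]:
        """Family members of a gene within its own species: every home-
        database hit above the reporting threshold."""
        rec = self.record_of(gene)
        hl = self.run_search(gene, rec.species)
        return [gene] + [h.subject_id for h in hl.hits]


def classify(databases: dict[str, SpeciesDatabase] | Iterable[SpeciesDatabase],
             seeds: Iterable[str],
             config: OrthologyConfig = OrthologyConfig()
             ) -> tuple[list[OrthologyCall], ReciprocityGraph]:
    """Run the full iterative reciprocal classification from seed genes.

    Every gene discovered as a top or similar-E-value hit is itself
    searched against every database until no untested gene remains, then
    each pair of co-occurring genes receives exactly one call.  Output is
    invariant under seed ordering (all tie-breaks are fixed).
    """
    if not isinstance(databases, dict):
        databases = {db.species: db for db in databases}
    if len(databases) < 2:
        raise InvalidInputError("need at least two species databases")
    eng = _Engine(databases, config)
    seeds = sorted(set(seeds))
    for s in seeds:
        rec = eng.record_of(s)  # raises for unknown seeds
        eng.graph.add_node(s, rec.species)

    state = FamilyExpansionState(seed_genes=tuple(seeds), frontier=set(seeds))
    species_names = sorted(databases)

    while state.frontier:
        gene = state.pop()
        state.iteration_count += 1
        home = eng.record_of(gene).species
        # family members of every candidate are themselves subjected to
        # cross-species reciprocal searches
        for member in eng.home_family(gene):
            state.enqueue(member)
        for sp in species_names:
            if sp == home:
                continue
            if (gene, sp) in state.tested:
                continue
            state.tested.add((gene, sp))
            hl = eng.run_search(gene, sp)
            for h in hl.hits:
                # every reported hit is itself subjected to cross-species
                # reciprocal searches once it reaches the frontier
                state.enqueue(h.subject_id)
            for h in eng.similar(hl):
                back = eng.run_search(h.subject_id, home)
                t = top_hit(back)
                if t is not None and t.subject_id != gene:
                    # reciprocity broke: the return search identified a
                    # different home-species gene -> expand its family
                    expand_family(state, t.subject_id, eng.home_family)

    calls = _read_off_calls(eng, state)
    return calls, eng.graph


def _read_off_calls(eng: _Engine, state: FamilyExpansionState
                    ) -> list[OrthologyCall]:
    graph = eng.graph
    genes = sorted(state.queried)
    sp = graph.species_of

    def tophit(g: str, s: str) -> Optional[str]:
        t = graph.top(g, s)
        return t.subject_id if t else None

    def sims(g: str, s: str) -> list[str]:
        hl = graph.hitlist(g, s)
        return [h.subject_id for h in eng.similar(hl)] if hl else []

    def famsims(g: str, s: str) -> list[str]:
        # looser second tier: plausible within-species duplicates of the
        # top hit, used only by the shared-partner co-orthology rule
        hl = graph.hitlist(g, s)
        if not hl:
            return []
        hits = similar_evalue_hits(hl, eng.cfg.family_ratio,
                                   math.log2(eng.cfg.family_ratio))
        return [h.subject_id for h in hits]

    calls: list[OrthologyCall] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            sa, sb = sp[a], sp[b]
            if sa == sb:
                calls.append(_same_species_call(a, b, sa, genes, sp, tophit,
                                                famsims))
            else:
                calls.append(_cross_species_call(a, b, sa, sb, tophit, sims,
                                                 famsims))
    return calls


def _cross_species_call(a, b, sa, sb, tophit, sims, famsims) -> OrthologyCall:
    ab_top = tophit(a, sb) == b
    ba_top = tophit(b, sa) == a
    ab_sim = b in sims(a, sb)
    ba_sim = a in sims(b, sa)
    if ab_top and ba_top:
        # mutual top hits; tie ambiguity if either side had co-equal hits
        tie = len(sims(a, sb)) > 1 or len(sims(b, sa)) > 1
        ev = (f"mutual_top_hit:{a}<->{b}",)
        if tie:
            ev += ("evalue_tie_present",)
        return OrthologyCall(a, sa, b, sb, "orthologue", ambiguous=tie,
                             evidence=ev)
    # one-to-many co-orthology: b points straight at a, the gene a prefers
    # in b's species itself reciprocates to a (shared partner), and b is a
    # plausible within-species duplicate of that preferred gene (second-
    # tier E-value window) — emitted as orthologue with an ambiguity flag
    x = tophit(a, sb)
    y = tophit(b, sa)
    if (ba_top and x is not None and tophit(x, sa) == a
            and b in famsims(a, sb)):
        return OrthologyCall(a, sa, b, sb, "orthologue", ambiguous=True,
                             evidence=(f"shared_partner:{a}~{{{b},{x}}}",
                                       "one_to_many"))
    if (ab_top and y is not None and tophit(y, sb) == b
            and a in famsims(b, sa)):
        return OrthologyCall(a, sa, b, sb, "orthologue", ambiguous=True,
                             evidence=(f"shared_partner:{b}~{{{a},{y}}}",
                                       "one_to_many"))
    if (ab_sim and ba_top) or (ba_sim and ab_top):
        # E-value tie member reciprocating to the shared partner
        return OrthologyCall(a, sa, b, sb, "orthologue", ambiguous=True,
                             evidence=(f"tie_reciprocal:{a}~{b}",
                                       "one_to_many"))
    return OrthologyCall(a, sa, b, sb, "unresolved")


def _same_species_call(a, b, s, genes, sp, tophit, famsims) -> OrthologyCall:
    # family co-membership: in each other's home hit lists, or jointly in
    # the family tier of some query from another species
    comember = b in famsims(a, s) or a in famsims(b, s)
    joint_of = None
    if not comember:
        for g in genes:
            if sp[g] != s:
                gs = famsims(g, s)
                if a in gs and b in gs:
                    joint_of = g
                    break
    if comember or joint_of is not None:
        # shared partner set: agree on the top hit in at least one species
        shared = [t for t in sorted({sp[g] for g in genes if sp[g] != s})
                  if tophit(a, t) is not None and tophit(a, t) == tophit(b, t)]
        if shared:
            ev = (f"shared_partner_in:{','.join(shared)}",)
            ev += (f"tie_clique_of:{joint_of}",) if joint_of else ("home_tie_clique",)
            return OrthologyCall(a, s, b, s, "paralogue", evidence=ev)
    return OrthologyCall(a, s, b, s, "unresolved")


def write_calls_tsv(calls: Iterable[OrthologyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tspecies_a\tgene_b\tspecies_b\trelation\t"
                 "ambiguous\tevidence\n")
        for c in calls:
            fh.write(f"{c.gene_a}\t{c.species_a}\t{c.gene_b}\t{c.species_b}\t"
                     f"{c.relation}\t{int(c.ambiguous)}\t"
                     f"{';'.join(c.evidence)}\n")
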