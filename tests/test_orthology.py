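"""Reciprocal-hit classification: tie rules, expansion, fixed-point
classification against simulator truth."""

import pytest

from clockortho.orthology import (FamilyExpansionState, OrthologyCall,
                                  OrthologyConfig, classify, expand_family,
                                  reciprocal_check, similar_evalue_hits,
                                  write_calls_tsv)
from clockortho.records import InvalidInputError, SequenceRecord, SpeciesDatabase
from clockortho.search import HitList, SearchHit
from clockortho.simulate import simulate_family

from .conftest import databases_for
from .oracles import lca_relation


def _hit(sid, ev, bits=100.0):
    return SearchHit(query_id="q", subject_id=sid, subject_species="B",
                     raw_score=100, bitscore=bits, evalue=ev,
                     query_span=(1, 10), subject_span=(1, 10))


class TestSimilarEvalueHits:
    def test_order_of_magnitude_tie_included(self):
        hl = HitList("q", "B", [_hit("top", 1e-50), _hit("near", 1e-49)])
        assert [h.subject_id for h in similar_evalue_hits(hl, 10)] == \
               ["top", "near"]

    def test_distant_second_hit_excluded(self):
        hl = HitList("q", "B", [_hit("top", 1e-50), _hit("far", 1e-20)])
        assert [h.subject_id for h in similar_evalue_hits(hl, 10)] == ["top"]

    def test_empty_hitlist_gives_empty_list(self):
        assert similar_evalue_hits(HitList("q", "B", []), 10) == []

    def test_zero_top_evalue_uses_bitscore_window(self):
        hl = HitList("q", "B", [_hit("top", 0.0, bits=500.0),
                                _hit("close", 0.0, bits=498.5),
                                _hit("far", 1e-200, bits=400.0)])
        assert [h.subject_id for h in similar_evalue_hits(hl, 10)] == \
               ["top", "close"]

    def test_ratio_below_one_rejected(self):
        with pytest.raises(InvalidInputError):
            similar_evalue_hits(HitList("q", "B", [_hit("x", 1e-5)]), 0.5)

    def test_recent_duplicates_both_returned(self, rng):
        # two subject copies ~2% diverged from each other: near-equal scores
        from clockortho.search import search
        from clockortho.simulate import JC, _evolve_seq, _random_root_cds
        root = _random_root_cds(150, rng)
        anc = _evolve_seq(root, 0.30, JC, rng)   # shared subject ancestry
        c1 = _evolve_seq(anc, 0.01, JC, rng)
        c2 = _evolve_seq(anc, 0.01, JC, rng)     # copies ~2% apart
        db = SpeciesDatabase("B", [
            SequenceRecord(id="b1", species="B", moltype="cds", residues=c1),
            SequenceRecord(id="b2", species="B", moltype="cds", residues=c2),
        ])
        q = SequenceRecord(id="q", species="A", moltype="cds", residues=root)
        sims = similar_evalue_hits(search(q, db), 10)
        assert {h.subject_id for h in sims} == {"b1", "b2"}


class TestReciprocalCheck:
    def test_mutual_nearest_pair_holds(self, single_copy_family):
        _, genes = single_copy_family
        dbs = databases_for(genes)
        calls, graph = classify(dbs, [genes[0].gene_id])

        def search_fn(gene, sp):
            return graph.hitlist(gene, sp)

        a = genes[0].gene_id
        other = next(g for g in genes if g.species != genes[0].species)
        holds, partner = reciprocal_check(a, other.species, graph, search_fn)
        assert holds and partner == other.gene_id

    def test_unknown_gene_rejected(self):
        from clockortho.orthology import ReciprocityGraph
        with pytest.raises(InvalidInputError):
            reciprocal_check("ghost", "B", ReciprocityGraph(), lambda g, s: None)


class TestExpandFamily:
    def test_trigger_and_family_enter_frontier(self):
        state = FamilyExpansionState(seed_genes=("s",))
        expand_family(state, "a2", lambda g: ["a2", "a3"])
        assert state.frontier == {"a2", "a3"}
        assert state.iteration_count == 1

    def test_already_queried_genes_not_requeued(self):
        state = FamilyExpansionState(seed_genes=("s",))
        state.queried.update({"a2", "a3"})
        expand_family(state, "a2", lambda g: ["a2", "a3"])
        assert state.frontier == set()
        assert state.iteration_count == 1  # activity still visible


class TestClassify:
    def test_single_copy_family_all_orthologues_no_paralogues(
            self, single_copy_family):
        hist, genes = single_copy_family
        calls, _ = classify(databases_for(genes), [genes[0].gene_id])
        cross = [c for c in calls if c.species_a != c.species_b]
        assert cross and all(c.relation == "orthologue" for c in cross)
        assert not any(c.relation == "paralogue" for c in calls)
        # agrees with the independent last-common-event oracle
        for c in cross:
            assert lca_relation(hist.gene_tree, c.gene_a, c.gene_b) == \
                "orthologue"

    def test_duplication_yields_paralogue_and_flagged_coorthologues(
            self, duplicated_family):
        hist, genes = duplicated_family
        calls, _ = classify(databases_for(genes), [genes[0].gene_id])
        truth_para = {frozenset(p) for p, r in hist.relation.items()
                      if r == "paralogue"}
        same_species_pairs = {
            frozenset((c.gene_a, c.gene_b)) for c in calls
            if c.species_a == c.species_b and c.relation == "paralogue"}
        same_species_truth = {p for p in truth_para
                              if len({g.species for g in genes
                                      if g.gene_id in p}) == 1}
        assert same_species_truth and \
            same_species_truth <= same_species_pairs
        # one-to-many co-orthologue calls carry the ambiguity flag
        flagged = [c for c in calls if c.relation == "orthologue"
                   and c.ambiguous]
        trio = [c for c in calls if c.relation == "orthologue"]
        assert all(c.evidence for c in trio)
        assert all("one_to_many" in c.evidence or
                   "evalue_tie_present" in c.evidence for c in flagged)

    def test_seed_order_and_choice_invariance(self, duplicated_family):
        _, genes = duplicated_family
        dbs = databases_for(genes)
        base = classify(dbs, [genes[0].gene_id])[0]
        for seed in (genes[-1].gene_id, genes[len(genes) // 2].gene_id):
            other = classify(dbs, [seed])[0]
            assert base == other

    def test_calls_cover_every_co_occurring_pair_exactly_once(
            self, single_copy_family):
        _, genes = single_copy_family
        calls, _ = classify(databases_for(genes), [genes[0].gene_id])
        pairs = [frozenset((c.gene_a, c.gene_b)) for c in calls]
        assert len(pairs) == len(set(pairs))
        n = len(genes)
        assert len(pairs) == n * (n - 1) // 2

    def test_species_with_empty_database_recorded_as_no_hit(self,
                                                            single_copy_family):
        _, genes = single_copy_family
        dbs = databases_for(genes)
        dbs["emptyland"] = SpeciesDatabase("emptyland")
        calls, graph = classify(dbs, [genes[0].gene_id])
        assert any(sp == "emptyland" for (_, sp) in graph.no_hit)
        assert not any("emptyland" in (c.species_a, c.species_b)
                       for c in calls)

    def test_fewer_than_two_species_rejected(self, single_copy_family):
        _, genes = single_copy_family
        only = {genes[0].species: databases_for(genes)[genes[0].species]}
        with pytest.raises(InvalidInputError):
            classify(only, [genes[0].gene_id])

    def test_termination_is_bounded(self, duplicated_family):
        _, genes = duplicated_family
        dbs = databases_for(genes)
        calls, graph = classify(dbs, [genes[0].gene_id])
        n_species = len(dbs)
        assert len(graph.hitlists) <= len(genes) * n_species


class TestExpansionScenarios:
    def test_reference_duplication_redirects_to_sibling_copy(self, rng):
        """Seeding with the minor copy of a reference-species duplication
        finds the major copy by reciprocity failure and expands to it
        (the pattern where every reciprocal search identifies the sister
        gene instead of the original query)."""
        from clockortho.simulate import JC, _evolve_seq, _random_root_cds
        root = _random_root_cds(150, rng)
        anc_a = _evolve_seq(root, 0.05, JC, rng)
        lhy = _evolve_seq(anc_a, 0.02, JC, rng)    # major copy
        cca1 = _evolve_seq(anc_a, 0.15, JC, rng)   # faster-evolving copy
        hv = _evolve_seq(root, 0.06, JC, rng)
        dbs = {
            "A": SpeciesDatabase("A", [
                SequenceRecord(id="LHY", species="A", moltype="cds", residues=lhy),
                SequenceRecord(id="CCA1", species="A", moltype="cds", residues=cca1),
            ]),
            "H": SpeciesDatabase("H", [
                SequenceRecord(id="HvLHY", species="H", moltype="cds", residues=hv),
            ]),
        }
        calls, graph = classify(dbs, ["CCA1"])
        # HvLHY's reciprocal lands on LHY, not CCA1
        assert graph.top("HvLHY", "A").subject_id == "LHY"
        rel = {frozenset((c.gene_a, c.gene_b)): c for c in calls}
        assert rel[frozenset(("LHY", "HvLHY"))].relation == "orthologue"
        assert rel[frozenset(("LHY", "CCA1"))].relation == "paralogue"

    def test_dicot_only_subfamily_expansion(self, rng):
        """A monocot hit that reciprocates to a different family member
        discovers the second subfamily (the pattern of a dicot-specific
        gene whose monocot best hits belong to a sister subfamily)."""
        from clockortho.simulate import JC, _evolve_seq, _random_root_cds
        root = _random_root_cds(150, rng)
        anc34 = _evolve_seq(root, 0.25, JC, rng)   # ELF4-like3 subfamily
        anc4 = _evolve_seq(root, 0.25, JC, rng)    # ELF4 subfamily (dicots)
        at_elf4 = _evolve_seq(anc4, 0.05, JC, rng)
        tom_elf4 = _evolve_seq(anc4, 0.05, JC, rng)
        at_l3 = _evolve_seq(anc34, 0.05, JC, rng)
        tom_l3 = _evolve_seq(anc34, 0.05, JC, rng)
        hv_l3 = _evolve_seq(anc34, 0.07, JC, rng)
        dbs = {
            "arabidopsis": SpeciesDatabase("arabidopsis", [
                SequenceRecord(id="AtELF4", species="arabidopsis",
                               moltype="cds", residues=at_elf4),
                SequenceRecord(id="AtELF4like3", species="arabidopsis",
                               moltype="cds", residues=at_l3),
            ]),
            "tomato": SpeciesDatabase("tomato", [
                SequenceRecord(id="SlELF4", species="tomato", moltype="cds",
                               residues=tom_elf4),
                SequenceRecord(id="SlELF4like3", species="tomato",
                               moltype="cds", residues=tom_l3),
            ]),
            "barley": SpeciesDatabase("barley", [
                SequenceRecord(id="HvELF4like3", species="barley",
                               moltype="cds", residues=hv_l3),
            ]),
        }
        calls, graph = classify(dbs, ["AtELF4"])
        rel = {frozenset((c.gene_a, c.gene_b)): c.relation for c in calls}
        # dicot-only reciprocity for the seed subfamily
        assert rel[frozenset(("AtELF4", "SlELF4"))] == "orthologue"
        # expansion discovered the sister subfamily orthologue set
        assert rel[frozenset(("AtELF4like3", "HvELF4like3"))] == "orthologue"
        assert rel[frozenset(("SlELF4like3", "HvELF4like3"))] == "orthologue"
        # the barley gene is not called an orthologue of the seed subfamily
        assert rel[frozenset(("AtELF4", "HvELF4like3"))] != "orthologue"


def test_calls_tsv_is_symmetric_record(tmp_path, single_copy_family):
    _, genes = single_copy_family
    calls, _ = classify(databases_for(genes), [genes[0].gene_id])
    out = tmp_path / "calls.tsv"
    write_calls_tsv(calls, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == ["gene_a", "species_a", "gene_b",
                                    "species_b", "relation", "ambiguous",
                                    "evidence"]
    assert len(lines) == 1 + len(calls)
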