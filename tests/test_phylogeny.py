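"""Distance estimation and NJ trees: closed-form oracles, exhaustive
minimum-evolution search, bootstrap behaviour, rooting."""

import numpy as np
import pytest

from clockortho.alignment import CodonAlignment
from clockortho.phylogeny import (DistanceMatrix, OutgroupError, PhyloConfig,
                                  SaturatedDistanceError, SupportTree,
                                  bootstrap, exclude_pseudogenes,
                                  mcl_distances, nj_tree, root_on_edge,
                                  root_with_outgroup,
                                  write_phylip_distances)
from clockortho.records import InvalidInputError, SequenceRecord
from clockortho.simulate import (JC, SubstitutionModel, _evolve_seq,
                                 _random_root_cds, simulate_family)

from .oracles import (jc_distance, min_evolution_bipartitions,
                      random_additive_matrix, tn93_distance)


class TestMclDistances:
    def test_identical_rows_have_zero_distance(self):
        ca = CodonAlignment(rows={"a": "ATGAAACCC" * 30,
                                  "b": "ATGAAACCC" * 30})
        dm = mcl_distances(ca)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_jc_simulation_matches_closed_form_within_two_percent(self, rng):
        root = _random_root_cds(2000, rng)  # 6 kb
        child = _evolve_seq(root, 0.3, JC, rng)
        dm = mcl_distances(CodonAlignment(rows={"a": root, "b": child}))
        p = sum(x != y for x, y in zip(root, child)) / len(root)
        assert dm.d[0, 1] == pytest.approx(jc_distance(p), rel=0.02)

    def test_two_row_case_equals_tn93_closed_form(self, rng):
        model = SubstitutionModel(kappa1=4.0, kappa2=2.0,
                                  freqs=(0.3, 0.2, 0.2, 0.3))
        root = _random_root_cds(3000, rng)
        child = _evolve_seq(root, 0.25, model, rng)
        dm = mcl_distances(CodonAlignment(rows={"a": root, "b": child}))
        expected = tn93_distance(root, child)
        assert dm.d[0, 1] == pytest.approx(expected, rel=0.02)

    def test_monotone_in_divergence_time(self, rng):
        root = _random_root_cds(1000, rng)
        times = np.linspace(0.05, 0.95, 10)
        rows = {"root": root}
        ds = []
        for i, t in enumerate(times):
            child = _evolve_seq(root, t, JC, rng)
            dm = mcl_distances(CodonAlignment(rows={"a": root, "b": child}))
            ds.append(dm.d[0, 1])
        from scipy.stats import spearmanr
        rho, _ = spearmanr(times, ds)
        assert rho == pytest.approx(1.0)

    def test_gapped_alignment_rejected(self):
        with pytest.raises(InvalidInputError):
            mcl_distances(CodonAlignment(rows={"a": "ATG---", "b": "ATGCCC"}))

    def test_saturated_pair_flagged_and_tree_refused(self, rng):
        # unrelated random sequences: likelihood pushes the distance to
        # the bound
        a = _random_root_cds(200, rng)
        b = _random_root_cds(200, rng)
        c = _evolve_seq(a, 0.05, JC, rng)
        dm = mcl_distances(CodonAlignment(rows={"a": a, "b": b, "c": c}))
        assert dm.any_saturated
        with pytest.raises(SaturatedDistanceError):
            nj_tree(dm)

    def test_pooled_parameter_recovery_within_ten_percent(self, rng):
        model = SubstitutionModel(kappa1=5.0, kappa2=2.5)
        root = _random_root_cds(17000, rng)  # ~50 kb
        a = _evolve_seq(root, 0.15, model, rng)
        b = _evolve_seq(root, 0.15, model, rng)
        from clockortho.phylogeny import estimate_pooled_model
        est = estimate_pooled_model(CodonAlignment(rows={"a": a, "b": b}))
        assert est.kappa1 == pytest.approx(5.0, rel=0.10)
        assert est.kappa2 == pytest.approx(2.5, rel=0.10)


class TestNjTree:
    def test_recovers_drawn_additive_four_taxon_tree(self):
        # distances from the additive tree with leaf branches 1,2,3,4 and
        # internal branch 1 joining (A,B) against (C,D)
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels, d))
        assert t.bipartitions().keys() == {frozenset({"C", "D"})}
        lengths = {t.label[l]: list(t.adj[l].values())[0].length
                   for l in t.leaf_ids()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        (a, b, e), = [x for x in t.edges()
                      if x[0] not in t.label and x[1] not in t.label]
        assert e.length == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels, d))
        lengths = {t.label[l]: list(t.adj[l].values())[0].length
                   for l in t.leaf_ids()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for rep in range(10):
            D, true_biparts = random_additive_matrix(labels, rng)
            t = nj_tree(DistanceMatrix(labels, D))
            assert set(t.bipartitions()) == true_biparts

    def test_matches_exhaustive_minimum_evolution_search(self):
        rng = np.random.default_rng(99)
        labels = [f"t{i}" for i in range(6)]
        for rep in range(3):
            D, _ = random_additive_matrix(labels, rng)
            nj_biparts = set(nj_tree(DistanceMatrix(labels, D)).bipartitions())
            me_biparts = min_evolution_bipartitions(labels, D)
            assert nj_biparts == me_biparts

    def test_negative_branch_clamped_with_warning(self):
        # a strongly non-additive matrix forces a negative branch estimate
        labels = ["A", "B", "C", "D"]
        d = np.array([[0.00, 1.95, 0.88, 0.22],
                      [1.95, 0.00, 0.15, 2.46],
                      [0.88, 0.15, 0.00, 2.75],
                      [0.22, 2.46, 2.75, 0.00]])
        with pytest.warns(UserWarning, match="negative branch"):
            t = nj_tree(DistanceMatrix(labels, d))
        for a, b, e in t.edges():
            assert e.length >= 0

    def test_two_taxa_refused(self):
        with pytest.raises(InvalidInputError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.]])))


@pytest.fixture(scope="module")
def small_codon_alignment():
    from clockortho.alignment import (align_proteins, backtranslate,
                                      mask_incomplete_columns)
    hist, genes = simulate_family(dup_rate=0, seed=3, root_cds_length=900)
    pa = align_proteins([g.protein for g in genes])
    ca = mask_incomplete_columns(
        backtranslate(pa, {g.gene_id: g.cds for g in genes}))
    return hist, genes, ca


class TestBootstrap:
    def test_clean_separation_gives_full_support(self, rng):
        # two divergent clades, zero within-clade variation
        a = _random_root_cds(200, rng)
        b = _evolve_seq(a, 0.4, JC, rng)
        ca = CodonAlignment(rows={"a1": a, "a2": a, "b1": b, "b2": b})
        t = bootstrap(ca, PhyloConfig(bootstrap_replicates=25, rng_seed=0))
        (support,) = [e.support for e in t.bipartitions().values()]
        assert support == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(
            self, small_codon_alignment):
        _, _, ca = small_codon_alignment
        t = bootstrap(ca, PhyloConfig(bootstrap_replicates=1, rng_seed=5))
        for e in t.bipartitions().values():
            assert e.support in (0.0, 100.0)

    def test_supports_invariant_under_leaf_relabelling(
            self, small_codon_alignment):
        _, _, ca = small_codon_alignment
        cfg = PhyloConfig(bootstrap_replicates=20, rng_seed=2)
        t1 = bootstrap(ca, cfg)
        mapping = {gid: f"z{gid}" for gid in ca.rows}
        ca2 = CodonAlignment(rows={mapping[g]: r for g, r in ca.rows.items()})
        t2 = bootstrap(ca2, cfg)
        sup1 = {frozenset(mapping[x] for x in k): e.support
                for k, e in t1.bipartitions().items()}
        # re-canonicalize against t2's reference leaf
        all2 = frozenset(ca2.rows)
        ref2 = min(all2)
        sup1 = {k if ref2 not in k else all2 - k: v for k, v in sup1.items()}
        sup2 = {k: e.support for k, e in t2.bipartitions().items()}
        assert sup1 == sup2

    def test_low_supports_retained_but_suppressed_in_rendering(
            self, small_codon_alignment):
        _, _, ca = small_codon_alignment
        t = bootstrap(ca, PhyloConfig(bootstrap_replicates=10, rng_seed=1))
        newick_all = t.to_newick(support_threshold=None)
        newick_cut = t.to_newick(support_threshold=101.0)
        assert any(e.support is not None for e in t.bipartitions().values())
        # thresholded rendering drops every support label
        import re
        assert not re.search(r"\)\d", newick_cut)
        assert re.search(r"\)\d", newick_all)


class TestRooting:
    def _tree(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        return nj_tree(DistanceMatrix(labels, d))

    def test_single_leaf_outgroup(self):
        t = root_with_outgroup(self._tree(), ["A"])
        assert t.is_rooted
        kids = sorted(t.adj[t.root])
        sides = [t._side_leaves(t.root, k) for k in kids]
        assert frozenset({"A"}) in sides

    def test_monophyletic_pair_outgroup_roots_on_internal_edge(self):
        t = root_with_outgroup(self._tree(), ["C", "D"])
        assert t.is_rooted
        sides = [t._side_leaves(t.root, k) for k in t.adj[t.root]]
        assert frozenset({"C", "D"}) in sides

    def test_non_monophyletic_outgroup_errors(self):
        with pytest.raises(OutgroupError, match="monophyletic"):
            root_with_outgroup(self._tree(), ["A", "C"])

    def test_manual_root_edge_override(self):
        # no outgroup available: place the root on a chosen family branch
        t = root_on_edge(self._tree(), frozenset({"C", "D"}))
        assert t.is_rooted

    def test_missing_outgroup_label_errors(self):
        with pytest.raises(OutgroupError, match="not in tree"):
            root_with_outgroup(self._tree(), ["Z"])

    def test_supports_preserved_across_rooting(self, small_codon_alignment):
        _, genes, ca = small_codon_alignment
        t = bootstrap(ca, PhyloConfig(bootstrap_replicates=20, rng_seed=3))
        before = {k: e.support for k, e in t.bipartitions().items()}
        moss = [g.gene_id for g in genes if g.species == "moss"]
        rooted = root_with_outgroup(t, moss)
        after = {k: e.support for k, e in rooted.bipartitions().items()}
        for k, v in before.items():
            assert after.get(k) == v


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_survive(self,
                                                   small_codon_alignment):
        _, _, ca = small_codon_alignment
        t = bootstrap(ca, PhyloConfig(bootstrap_replicates=10, rng_seed=4))
        back = SupportTree.from_newick(t.to_newick())
        assert set(back.leaf_labels()) == set(t.leaf_labels())
        b1 = {k: (round(e.length, 9), e.support)
              for k, e in t.bipartitions().items()}
        b2 = {k: (round(e.length, 9), e.support)
              for k, e in back.bipartitions().items()}
        assert b1 == b2


class TestExcludePseudogenes:
    def _recs(self):
        return [SequenceRecord(id=f"g{i}", species="s", moltype="protein",
                               residues="MKWVTF", pseudogene=(i == 1))
                for i in range(3)]

    def test_no_flags_is_identity(self):
        recs = [SequenceRecord(id="a", species="s", moltype="protein",
                               residues="MKWVTF")]
        assert exclude_pseudogenes(recs) == recs

    def test_flagged_records_removed(self):
        out = exclude_pseudogenes(self._recs())
        assert [r.id for r in out] == ["g0", "g2"]

    def test_all_flagged_warns_and_empties(self):
        recs = [SequenceRecord(id="a", species="s", moltype="protein",
                               residues="MKWVTF", pseudogene=True)]
        with pytest.warns(UserWarning):
            assert exclude_pseudogenes(recs) == []

    def test_half_length_truncated_copy_removed_from_tree_input(self):
        from clockortho.simulate import make_pseudogene
        hist, genes = simulate_family(dup_rate=0, seed=3,
                                      root_cds_length=300)
        psi = make_pseudogene(genes[0], seed=1)
        records = [g.protein for g in genes] + [psi.protein]
        kept = exclude_pseudogenes(records)
        assert psi.protein.id not in {r.id for r in kept}
        assert len(kept) == len(genes)


def test_phylip_distance_writer(tmp_path):
    dm = DistanceMatrix(["a", "b", "c"],
                        np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.]]))
    out = tmp_path / "dm.phy"
    write_phylip_distances(dm, out)
    lines = out.read_text().splitlines()
    assert lines[0].strip() == "3"
    assert lines[1].startswith("a")
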