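"""Synthetic gene families with known evolutionary histories.

A gene family is grown along a user-supplied species tree: duplications
and losses arrive as Poisson events on each branch (rates per unit branch
length, i.e. per expected substitution per site), and coding sequences
evolve along the resulting gene tree under a TN93 nucleotide model
(Jukes–Cantor by default) with stop-codon-avoiding rejection.  Each
surviving gene can additionally be given a genomic context: GT..AG
introns inserted at random phases plus flanking sequence, with the true
exon coordinates recorded as a :class:`~clockortho.annotation.GeneModel`.

Because every divergence in the gene tree is labelled speciation or
duplication, the true orthology relation of every gene pair is known and
serves as ground truth for the reciprocal-search classifier, the
re-annotator and the tree builder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import dendropy
import numpy as np

from .annotation import GeneModel, write_gff3
from .records import InvalidInputError, SequenceRecord, write_fasta, translate_cds

__all__ = [
    "SpeciesTreeSpec",
    "SubstitutionModel",
    "JC",
    "GeneTreeNode",
    "FamilyHistory",
    "SimulatedGene",
    "simulate_family",
    "insert_introns",
    "make_pseudogene",
    "write_family",
    "DEFAULT_SPECIES_TREE",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

#: Six-species panel emulating a moss outgroup, a grass (monocot) clade and
#: a dicot clade.  Branch lengths are in observed CDS substitutions per
#: site for conserved (purifying-selected) genes — far below neutral
#: divergence, in line with published clock-gene trees where even the
#: moss-to-crop distance stays around 0.5-0.7 substitutions per site.
DEFAULT_SPECIES_TREE = ("(moss:0.28,((barley:0.08,wheat:0.08):0.12,"
                        "(arabidopsis:0.14,(tomato:0.05,potato:0.05):0.09)"
                        ":0.05):0.12);")


@dataclass(frozen=True)
class SpeciesTreeSpec:
    """A rooted species tree in Newick with branch lengths in subst/site."""

    newick: str

    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(data=self.newick, schema="newick",
                              preserve_underscores=True)
        names = [lf.taxon.label for lf in t.leaf_node_iter()]
        if len(names) != len(set(names)):
            raise InvalidInputError("duplicate species names in tree")
        return t

    def species(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree().leaf_node_iter()]


class SubstitutionModel:
    """TN93 nucleotide substitution model (base order A, C, G, T).

    ``kappa1`` is the A<->G transition/transversion rate ratio, ``kappa2``
    the C<->T one; equal frequencies and kappas of 1 give Jukes-Cantor.
    The rate matrix is scaled so branch lengths are in expected
    substitutions per site.
    """

    def __init__(self, kappa1: float = 1.0, kappa2: float = 1.0,
                 freqs: tuple[float, float, float, float] = (0.25,) * 4):
        if min(freqs) <= 0 or abs(sum(freqs) - 1) > 1e-8:
            raise InvalidInputError("frequencies must be positive and sum to 1")
        if kappa1 <= 0 or kappa2 <= 0:
            raise InvalidInputError("rate ratios must be positive")
        self.kappa1, self.kappa2 = float(kappa1), float(kappa2)
        self.freqs = np.asarray(freqs, dtype=float)
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pair = {i, j}
                if pair == {0, 2}:      # A<->G
                    rate = kappa1
                elif pair == {1, 3}:    # C<->T
                    rate = kappa2
                else:
                    rate = 1.0
                Q[i, j] = rate * self.freqs[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        self.Q = Q / mu
        lam, U = np.linalg.eig(self.Q)
        self._lam = lam.real
        self._U = U.real
        self._Uinv = np.linalg.inv(U).real

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), rows = ancestral base, columns = descendant."""
        if t < 0:
            raise InvalidInputError("branch length must be non-negative")
        P = (self._U * np.exp(self._lam * t)) @ self._Uinv
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


JC = SubstitutionModel()


# ---------------------------------------------------------------------------
# gene tree

@dataclass
class GeneTreeNode:
    """Node of a simulated gene tree; ``length`` is the branch to parent."""

    event: str                      # root | speciation | duplication | leaf
    length: float = 0.0
    children: list["GeneTreeNode"] = field(default_factory=list)
    name: str = ""
    species: Optional[str] = None

    def leaves(self) -> list["GeneTreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def _fmt(node):
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(_fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"
        return _fmt(self) + ";"


@dataclass
class SimulatedGene:
    """One surviving gene with its CDS, protein, genomic context and truth."""

    gene_id: str
    species: str
    cds: SequenceRecord
    protein: SequenceRecord
    genomic: Optional[SequenceRecord] = None
    model: Optional[GeneModel] = None
    pseudogene: bool = False


@dataclass
class FamilyHistory:
    """Event list, gene tree and true orthology relation of one family."""

    species_tree: SpeciesTreeSpec
    events: list[tuple]                       # ("duplication"|"loss", species-branch, t)
    gene_tree: Optional[GeneTreeNode]
    relation: dict[frozenset, str]            # {gene_a, gene_b} -> orthologue|paralogue
    extinct: bool = False

    def genes_by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        if self.gene_tree is None:
            return out
        for lf in self.gene_tree.leaves():
            out.setdefault(lf.species, []).append(lf.name)
        return out

    def pair_relation(self, a: str, b: str) -> Optional[str]:
        return self.relation.get(frozenset((a, b)))

    def orthologous_pairs(self) -> set[frozenset]:
        return {p for p, r in self.relation.items() if r == "orthologue"}


def _branch_label(sp_node) -> str:
    if sp_node.taxon is not None:
        return sp_node.taxon.label
    return "+".join(sorted(lf.taxon.label for lf in sp_node.leaf_iter()))


def _grow(sp_node, remaining: float, dup_rate: float, loss_rate: float,
          rng: np.random.Generator, events: list,
          consumed: float = 0.0) -> Optional[GeneTreeNode]:
    """Evolve one gene lineage along the branch above ``sp_node``."""
    total = dup_rate + loss_rate
    t_event = rng.exponential(1.0 / total) if total > 0 else np.inf
    if t_event < remaining:
        here = consumed + t_event
        if rng.random() < dup_rate / total:
            events.append(("duplication", _branch_label(sp_node), here))
            node = GeneTreeNode(event="duplication", length=here)
            for _ in range(2):
                child = _grow(sp_node, remaining - t_event, dup_rate,
                              loss_rate, rng, events, 0.0)
                if child is not None:
                    node.children.append(child)
            return _collapse(node)
        events.append(("loss", _branch_label(sp_node), here))
        return None
    # reached the bottom of the species-tree branch
    used = consumed + remaining
    if sp_node.is_leaf():
        return GeneTreeNode(event="leaf", length=used,
                            species=sp_node.taxon.label)
    node = GeneTreeNode(event="speciation", length=used)
    for child_sp in sp_node.child_nodes():
        child = _grow(child_sp, child_sp.edge.length or 0.0, dup_rate,
                      loss_rate, rng, events, 0.0)
        if child is not None:
            node.children.append(child)
    return _collapse(node)


def _collapse(node: GeneTreeNode) -> Optional[GeneTreeNode]:
    """Prune extinct subtrees and suppress unifurcations (summing lengths)."""
    if not node.children and node.event != "leaf":
        return None
    if len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        return child
    return node


def _truth_relation(root: GeneTreeNode) -> dict[frozenset, str]:
    """Orthology by the event at the last common ancestor of each pair."""
    rel: dict[frozenset, str] = {}

    def _post(node) -> list[str]:
        if not node.children:
            return [node.name]
        clades = [_post(c) for c in node.children]
        # the gene-tree root divergence is the species-tree root speciation
        label = "paralogue" if node.event == "duplication" else "orthologue"
        for i in range(len(clades)):
            for j in range(i + 1, len(clades)):
                for a in clades[i]:
                    for b in clades[j]:
                        rel[frozenset((a, b))] = label
        return [x for cl in clades for x in cl]

    _post(root)
    return rel


# ---------------------------------------------------------------------------
# sequence evolution

def _random_root_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        cod = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if cod not in _STOPS:
            codons.append(cod)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)


def _evolve_seq(parent: str, t: float, model: SubstitutionModel,
                rng: np.random.Generator) -> str:
    """Evolve a CDS for time t, keeping start/stop codons and avoiding
    internal stop codons by per-codon rejection."""
    if t <= 0:
        return parent
    P = model.transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    idx = np.frombuffer(parent.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for k, b in enumerate(_BASES):
        lut[ord(b)] = k
    pidx = lut[idx]
    u = rng.random(len(pidx))
    new = (u[:, None] > cum[pidx]).sum(axis=1)
    seq = list("".join(_BASES[i] for i in new))
    # generator guarantee: terminal codons immutable
    seq[:3] = parent[:3]
    seq[-3:] = parent[-3:]
    n_codons = len(seq) // 3
    for ci in range(1, n_codons - 1):
        tries = 0
        while "".join(seq[3 * ci:3 * ci + 3]) in _STOPS:
            tries += 1
            if tries > 100:
                seq[3 * ci:3 * ci + 3] = parent[3 * ci:3 * ci + 3]
                break
            pc = pidx[3 * ci:3 * ci + 3]
            uu = rng.random(3)
            nc = (uu[:, None] > cum[pc]).sum(axis=1)
            seq[3 * ci:3 * ci + 3] = [_BASES[i] for i in nc]
    return "".join(seq)


def simulate_family(st: SpeciesTreeSpec | str = DEFAULT_SPECIES_TREE,
                    dup_rate: float = 0.0, loss_rate: float = 0.0,
                    root_cds_length: int = 600, seed: int = 0,
                    model: SubstitutionModel = JC,
                    n_introns: int = 2,
                    family: str = "fam") -> tuple[FamilyHistory, list[SimulatedGene]]:
    """Simulate one gene family along a species tree.

    Returns the family history (events, gene tree, true orthology) and the
    surviving genes with CDS, protein, intron-bearing genomic sequence and
    true gene model.  Identical inputs and seed give identical output.
    """
    if isinstance(st, str):
        st = SpeciesTreeSpec(st)
    if dup_rate < 0 or loss_rate < 0:
        raise InvalidInputError("rates must be non-negative")
    if root_cds_length % 3 or root_cds_length < 9:
        raise InvalidInputError("root CDS length must be >= 9 and divisible by 3")
    rng = np.random.default_rng(seed)
    sp_tree = st.tree()
    events: list[tuple] = []
    root_sp = sp_tree.seed_node
    root = GeneTreeNode(event="root", length=0.0)
    for child_sp in root_sp.child_nodes():
        child = _grow(child_sp, child_sp.edge.length or 0.0, dup_rate,
                      loss_rate, rng, events, 0.0)
        if child is not None:
            root.children.append(child)
    collapsed = _collapse(root)
    if collapsed is None or not collapsed.leaves() or collapsed.event == "leaf" \
            and collapsed.species is None:
        return FamilyHistory(st, events, None, {}, extinct=True), []
    root = collapsed
    if root.event == "duplication" or root.event == "leaf":
        pass  # a root-level structure is still a valid gene tree
    root.event = {"leaf": "leaf"}.get(root.event, root.event)

    # deterministic leaf naming: traversal order, per-species counter
    counters: dict[str, int] = {}
    for lf in root.leaves():
        k = counters.get(lf.species, 0) + 1
        counters[lf.species] = k
        lf.name = f"{family}_{lf.species}_g{k}"
        lf.event = "leaf"
    relation = _truth_relation(root) if root.children else {}

    root_cds = _random_root_cds(root_cds_length // 3, rng)

    genes: list[SimulatedGene] = []

    def _descend(node: GeneTreeNode, seq: str) -> None:
        seq = _evolve_seq(seq, node.length, model, rng)
        if not node.children:
            cds = SequenceRecord(id=node.name, species=node.species,
                                 moltype="cds", residues=seq)
            prot = translate_cds(cds)
            genomic, gm = insert_introns(cds, n_introns, rng=rng)
            genes.append(SimulatedGene(gene_id=node.name, species=node.species,
                                       cds=cds, protein=prot, genomic=genomic,
                                       model=gm))
            return
        for c in node.children:
            _descend(c, seq)

    if root.children:
        for c in root.children:
            _descend(c, root_cds)
    else:  # single surviving lineage
        _descend(root, root_cds)

    return FamilyHistory(st, events, root, relation), genes


# ---------------------------------------------------------------------------
# genomic context

def _default_intron_length(rng: np.random.Generator) -> int:
    return int(rng.integers(60, 201))


def insert_introns(cds: SequenceRecord, n_introns: int,
                   rng: np.random.Generator | int = 0,
                   length_sampler: Callable[[np.random.Generator], int] | None = None,
                   flank_range: tuple[int, int] = (80, 200),
                   strand: str = "+",
                   ) -> tuple[SequenceRecord, GeneModel]:
    """Insert GT..AG introns into a CDS and wrap it in flanking sequence.

    Insertion points are uniform over interior positions (any phase) with
    a minimum exon length of 9 nt; splicing the returned genomic record by
    the returned true model reproduces the CDS exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n_introns < 0:
        raise InvalidInputError("n_introns must be >= 0")
    if length_sampler is None:
        length_sampler = _default_intron_length
    seq = cds.residues
    m = len(seq)
    if n_introns > 0 and m < 9 * (n_introns + 1):
        raise InvalidInputError("CDS too short for requested intron count")
    points: list[int] = []
    guard = 0
    while len(points) < n_introns:
        guard += 1
        if guard > 10000:
            raise InvalidInputError("could not place introns with spacing")
        cand = int(rng.integers(9, m - 8))
        if all(abs(cand - p) >= 9 for p in points):
            points.append(cand)
    points.sort()
    flank5 = "".join(_BASES[i] for i in rng.integers(0, 4, int(rng.integers(*flank_range))))
    flank3 = "".join(_BASES[i] for i in rng.integers(0, 4, int(rng.integers(*flank_range))))
    pieces = []
    exon_bounds = []
    pos = len(flank5)
    prev = 0
    pieces.append(flank5)
    for pt in points + [m]:
        exon = seq[prev:pt]
        exon_bounds.append((pos + 1, pos + len(exon)))
        pieces.append(exon)
        pos += len(exon)
        if pt != m:
            ilen = max(int(length_sampler(rng)), 8)
            intron = "GT" + "".join(
                _BASES[i] for i in rng.integers(0, 4, ilen - 4)) + "AG"
            pieces.append(intron)
            pos += len(intron)
        prev = pt
    pieces.append(flank3)
    genomic_seq = "".join(pieces)
    if strand == "-":
        n = len(genomic_seq)
        genomic_seq = _rc(genomic_seq)
        exon_bounds = [(n - e + 1, n - s + 1) for s, e in exon_bounds][::-1]
    genomic = SequenceRecord(id=f"{cds.id}_genomic", species=cds.species,
                             moltype="genomic", residues=genomic_seq)
    model = GeneModel(gene_id=cds.id, genomic=genomic, strand=strand,
                      exons=tuple(exon_bounds), cds_exons=tuple(exon_bounds))
    return genomic, model


def _rc(s: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return s.translate(comp)[::-1]


def make_pseudogene(g: SimulatedGene, seed: int = 0) -> SimulatedGene:
    """Truncate a gene to ~half length and flag it as a pseudogene.

    Emulates a half-size predicted protein that is excluded from
    phylogenetic analysis.
    """
    rng = np.random.default_rng(seed)
    n_codons = len(g.cds.residues) // 3
    keep = max(3, n_codons // 2)
    trunc = g.cds.residues[:3 * keep]
    cds = SequenceRecord(id=f"{g.gene_id}_psi", species=g.species,
                         moltype="cds", residues=trunc, pseudogene=True)
    prot = translate_cds(cds)
    return SimulatedGene(gene_id=cds.id, species=g.species, cds=cds,
                         protein=prot, pseudogene=True)


# ---------------------------------------------------------------------------
# on-disk form

def write_family(history: FamilyHistory, genes: list[SimulatedGene],
                 outdir: str | Path) -> Path:
    """Write FASTA/GFF3/Newick/TSV truth tables plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([g.cds for g in genes], outdir / "cds.fasta")
    write_fasta([g.protein for g in genes], outdir / "protein.fasta")
    write_fasta([g.genomic for g in genes if g.genomic], outdir / "genomic.fasta")
    write_gff3([g.model for g in genes if g.model], outdir / "models.gff3")
    (outdir / "species_tree.nwk").write_text(history.species_tree.newick + "\n")
    if history.gene_tree is not None:
        (outdir / "gene_tree.nwk").write_text(history.gene_tree.newick() + "\n")
    with open(outdir / "orthology_truth.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\trelation\n")
        for pair in sorted(history.relation, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{history.relation[pair]}\n")
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("event\tbranch\ttime\n")
        for ev in history.events:
            fh.write(f"{ev[0]}\t{ev[1]}\t{ev[2]:.6f}\n")
    manifest = {
        "n_genes": len(genes),
        "species": sorted({g.species for g in genes}),
        "extinct": history.extinct,
        "files": ["cds.fasta", "protein.fasta", "genomic.fasta", "models.gff3",
                  "species_tree.nwk", "gene_tree.nwk", "orthology_truth.tsv",
                  "events.tsv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
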