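"""Distance-based tree estimation: composite-likelihood TN93 distances,
Saitou–Nei neighbour joining, bootstrap supports and outgroup rooting.

Distances follow the composite-likelihood approach used for the original
trees: TN93 substitution parameters (the two transition/transversion rate
ratios and the base frequencies) are estimated once from the pooled sum
of all pairwise site-pattern counts, then each pairwise distance is the
one-dimensional maximum-likelihood fit under those shared parameters, in
units of substitutions per site.  Bootstrap supports come from codon-
column resampling (the alignment preserves codon structure) with
bipartition frequencies mapped back onto the full-data tree; supports
below the display threshold are retained in the object but suppressed by
the default renderer.  Trees are rooted on the outgroup edge when the
outgroup is monophyletic; a manual root-edge override covers families
where no true outgroup gene exists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import CodonAlignment
from .records import InvalidInputError, SequenceRecord
from .simulate import SubstitutionModel

__all__ = [
    "DistanceMatrix",
    "SupportTree",
    "PhyloConfig",
    "SaturatedDistanceError",
    "OutgroupError",
    "mcl_distances",
    "nj_tree",
    "bootstrap",
    "root_with_outgroup",
    "root_on_edge",
    "exclude_pseudogenes",
    "write_phylip_distances",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_MAX_DISTANCE = 10.0


class SaturatedDistanceError(InvalidInputError):
    """A pairwise distance hit the saturation bound."""


class OutgroupError(InvalidInputError):
    """The requested outgroup is absent or not monophyletic."""


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with a saturation mask."""

    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray = None  # bool matrix

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InvalidInputError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise InvalidInputError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InvalidInputError("diagonal must be zero")
        if np.any(self.d < 0):
            raise InvalidInputError("distances must be non-negative")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    @property
    def any_saturated(self) -> bool:
        return bool(self.saturated.any())


@dataclass(frozen=True)
class PhyloConfig:
    """Bootstrap and display settings (defaults follow the study protocol:
    2000 replicates, supports shown when above 50%)."""

    bootstrap_replicates: int = 2000
    support_display_threshold: float = 50.0
    rng_seed: int = 0
    rate_model: str = "uniform"
    resample_unit: str = "codon"  # or "nucleotide"

    def __post_init__(self):
        if self.bootstrap_replicates < 1:
            raise InvalidInputError("need at least one bootstrap replicate")
        if not 0 <= self.support_display_threshold <= 100:
            raise InvalidInputError("display threshold must be in [0, 100]")


# ---------------------------------------------------------------------------
# composite-likelihood distances

def _pattern_counts(a: str, b: str) -> np.ndarray:
    ia = np.frombuffer(a.encode(), dtype=np.uint8)
    ib = np.frombuffer(b.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for k, base in enumerate(_BASES):
        lut[ord(base)] = k
    xa, xb = lut[ia], lut[ib]
    ok = (xa >= 0) & (xb >= 0)
    C = np.zeros((4, 4))
    np.add.at(C, (xa[ok], xb[ok]), 1.0)
    return C


def _loglik(C: np.ndarray, model: SubstitutionModel, t: float) -> float:
    J = model.freqs[:, None] * model.transition_matrix(t)
    return float((C * np.log(np.clip(J, 1e-300, None))).sum())


def _rows_of(ca) -> dict[str, str]:
    rows = ca.rows if hasattr(ca, "rows") else dict(ca)
    for gid, row in rows.items():
        if "-" in row:
            raise InvalidInputError(
                f"{gid}: alignment still contains gaps; apply complete "
                "deletion before distance estimation")
    return rows


def estimate_pooled_model(ca) -> SubstitutionModel:
    """TN93 parameters from the pooled sum of all pairwise pattern counts."""
    rows = _rows_of(ca)
    ids = sorted(rows)
    pooled = np.zeros((4, 4))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pooled += _pattern_counts(rows[ids[i]], rows[ids[j]])
    total = pooled.sum()
    if total == 0:
        raise InvalidInputError("no comparable sites")
    marg = pooled.sum(axis=0) + pooled.sum(axis=1)
    freqs = np.clip(marg / marg.sum(), 1e-4, None)
    freqs = freqs / freqs.sum()

    sym = pooled + pooled.T
    p1 = sym[0, 2] / total / 2 * 2  # A<->G
    p2 = sym[1, 3] / total / 2 * 2  # C<->T
    q = (sym.sum() - np.trace(sym) - sym[0, 2] * 2 - sym[1, 3] * 2) / total / 2
    # crude moment initialisation for the rate ratios
    k1_0 = max(2 * p1 / max(q, 1e-6), 0.1)
    k2_0 = max(2 * p2 / max(q, 1e-6), 0.1)

    def neg(params):
        lt, lk1, lk2 = params
        try:
            m = SubstitutionModel(np.exp(lk1), np.exp(lk2), tuple(freqs))
        except InvalidInputError:
            return 1e12
        return -_loglik(pooled, m, np.exp(lt))

    p_dist = 1.0 - np.trace(pooled) / total
    t0 = max(-0.75 * np.log(max(1 - 4 * p_dist / 3, 1e-6)), 1e-3)
    res = minimize(neg, x0=np.log([t0, k1_0, k2_0]), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
    _, lk1, lk2 = res.x
    return SubstitutionModel(float(np.exp(lk1)), float(np.exp(lk2)),
                             tuple(freqs))


def _pair_distance(C: np.ndarray, model: SubstitutionModel) -> tuple[float, bool]:
    if C.sum() == 0:
        raise InvalidInputError("empty pairwise comparison")
    res = minimize_scalar(lambda t: -_loglik(C, model, t),
                          bounds=(0.0, _MAX_DISTANCE), method="bounded",
                          options={"xatol": 1e-8})
    d = float(res.x)
    # saturation: the observed mismatch fraction is indistinguishable from
    # the model's stationary (infinite-time) expectation, or the fit hit
    # the distance bound
    p_obs = 1.0 - np.trace(C) / C.sum()
    p_max = 1.0 - float((model.freqs ** 2).sum())
    saturated = d >= 0.99 * _MAX_DISTANCE or p_obs >= 0.95 * p_max
    return d, saturated


def mcl_distances(ca, model: SubstitutionModel | None = None) -> DistanceMatrix:
    """Pairwise distances under shared pooled TN93 parameters.

    ``model`` overrides the pooled estimation (used by the bootstrap to
    keep replicate estimates comparable is NOT done — each call
    re-estimates, matching the one-dataset-one-model contract).
    Saturated pairs are flagged rather than silently clamped.
    """
    rows = _rows_of(ca)
    ids = sorted(rows)
    if len(ids) < 2:
        raise InvalidInputError("need at least two sequences")
    if model is None:
        model = estimate_pooled_model(ca)
    n = len(ids)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            C = _pattern_counts(rows[ids[i]], rows[ids[j]])
            dij, s = _pair_distance(C, model)
            d[i, j] = d[j, i] = dij
            sat[i, j] = sat[j, i] = s
    return DistanceMatrix(labels=ids, d=d, saturated=sat)


# ---------------------------------------------------------------------------
# trees

@dataclass
class _Edge:
    length: float
    support: Optional[float] = None


class SupportTree:
    """Phylogeny held as an undirected adjacency with a designated root.

    Leaves carry labels; internal edges may carry bootstrap supports (a
    percentage).  The same object serves rooted and unrooted trees: an
    unrooted tree is one whose root node has three or more neighbours.
    """

    def __init__(self):
        self.adj: dict[int, dict[int, _Edge]] = {}
        self.label: dict[int, str] = {}
        self.root: int = 0
        self._next = 0

    # -- construction ------------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.label[nid] = label
        return nid

    def connect(self, a: int, b: int, length: float,
                support: float | None = None) -> None:
        e = _Edge(length=length, support=support)
        self.adj[a][b] = e
        self.adj[b][a] = e

    # -- basic queries ------------------------------------------------------

    def leaf_ids(self) -> list[int]:
        return sorted(n for n in self.adj
                      if n in self.label and len(self.adj[n]) <= 1)

    def leaf_labels(self) -> list[str]:
        return sorted(self.label[n] for n in self.leaf_ids())

    @property
    def is_rooted(self) -> bool:
        return len(self.adj[self.root]) == 2

    def _side_leaves(self, u: int, v: int) -> frozenset:
        """Leaf labels on the v side of edge (u, v)."""
        seen = {u}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in self.label and len(self.adj[x]) <= 1:
                out.append(self.label[x])
            stack.extend(self.adj[x])
        return frozenset(out)

    def edges(self) -> list[tuple[int, int, _Edge]]:
        out = []
        for a in sorted(self.adj):
            for b, e in sorted(self.adj[a].items()):
                if a < b:
                    out.append((a, b, e))
        return out

    def bipartitions(self) -> dict[frozenset, _Edge]:
        """Canonical internal-edge bipartitions (side without the
        lexicographically smallest leaf)."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out = {}
        for a, b, e in self.edges():
            side = self._side_leaves(a, b)
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = side if ref not in side else all_leaves - side
            out[key] = e
        return out

    # -- serialisation -------------------------------------------------------

    def to_newick(self, support_threshold: float | None = None,
                  include_supports: bool = True) -> str:
        def fmt(node: int, parent: Optional[int]) -> str:
            kids = [k for k in sorted(self.adj[node]) if k != parent]
            if not kids:
                core = self.label.get(node, "")
            else:
                core = "(" + ",".join(fmt(k, node) for k in kids) + ")"
                e = self.adj[node][parent] if parent is not None else None
                if (include_supports and e is not None
                        and e.support is not None
                        and (support_threshold is None
                             or e.support > support_threshold)):
                    core += f"{e.support:g}"
            if parent is not None:
                core += f":{self.adj[node][parent].length:.10g}"
            return core
        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "SupportTree":
        import dendropy
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
        t = cls()

        def build(dnode) -> int:
            if dnode.is_leaf():
                return t.new_node(dnode.taxon.label if dnode.taxon else dnode.label)
            nid = t.new_node()
            for child in dnode.child_nodes():
                cid = build(child)
                sup = None
                if not child.is_leaf() and child.label not in (None, ""):
                    try:
                        sup = float(child.label)
                    except ValueError:
                        sup = None
                t.connect(nid, cid, child.edge.length or 0.0, support=sup)
            return nid

        t.root = build(dt.seed_node)
        return t

    def ascii(self) -> str:
        import dendropy
        dt = dendropy.Tree.get(data=self.to_newick(include_supports=False),
                               schema="newick", preserve_underscores=True)
        return dt.as_ascii_plot()

    def __repr__(self):
        return f"SupportTree({self.to_newick()})"


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Saitou–Nei neighbour joining with deterministic tie-breaks.

    Ties in the Q criterion are resolved by the lexicographically smallest
    pair of subtree labels; negative branch lengths are clamped to zero
    with a warning.  Refuses matrices containing saturated entries.
    """
    if dm.any_saturated:
        raise SaturatedDistanceError(
            "distance matrix contains saturated entries; resolve them "
            "(longer alignment or removing the offending sequence) first")
    n0 = len(dm.labels)
    if n0 < 3:
        raise InvalidInputError("neighbour joining needs at least 3 taxa")
    t = SupportTree()
    nodes = {i: t.new_node(lbl) for i, lbl in enumerate(dm.labels)}
    sortlab = {i: dm.labels[i] for i in nodes}
    D: dict[tuple[int, int], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            D[(i, j)] = float(dm.d[i, j])

    def dget(i, j):
        return D[(i, j) if i < j else (j, i)]

    def dset(i, j, v):
        D[(i, j) if i < j else (j, i)] = v

    active = list(range(n0))
    nxt = n0

    def clamp(v, what):
        if v < 0:
            warnings.warn(f"negative branch length {v:.4g} at {what} "
                          "clamped to 0")
            return 0.0
        return v

    while len(active) > 3:
        n = len(active)
        r = {i: sum(dget(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(n):
            for bi in range(ai + 1, n):
                i, j = active[ai], active[bi]
                q = (n - 2) * dget(i, j) - r[i] - r[j]
                tie = tuple(sorted((sortlab[i], sortlab[j])))
                if best is None or (q, tie) < (best[0], best[1]):
                    best = (q, tie, i, j)
        _, _, i, j = best
        dij = dget(i, j)
        vi = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (n - 2)),
                   f"{sortlab[i]}")
        vj = clamp(dij - vi if dij - vi >= 0 else 0.0, f"{sortlab[j]}")
        u = nxt
        nxt += 1
        uid = t.new_node()
        t.connect(uid, nodes[i], vi)
        t.connect(uid, nodes[j], vj)
        nodes[u] = uid
        sortlab[u] = min(sortlab[i], sortlab[j])
        for k in active:
            if k in (i, j):
                continue
            dset(u, k, 0.5 * (dget(i, k) + dget(j, k) - dij))
        active = [a for a in active if a not in (i, j)] + [u]

    i, j, k = active
    vi = clamp(0.5 * (dget(i, j) + dget(i, k) - dget(j, k)), sortlab[i])
    vj = clamp(0.5 * (dget(i, j) + dget(j, k) - dget(i, k)), sortlab[j])
    vk = clamp(0.5 * (dget(i, k) + dget(j, k) - dget(i, j)), sortlab[k])
    center = t.new_node()
    t.connect(center, nodes[i], vi)
    t.connect(center, nodes[j], vj)
    t.connect(center, nodes[k], vk)
    t.root = center
    return t


# ---------------------------------------------------------------------------
# bootstrap

def _resample(ca: CodonAlignment, rng: np.random.Generator,
              unit: str) -> CodonAlignment:
    ids = sorted(ca.rows)
    L = ca.n_columns
    if unit == "codon":
        ncod = L // 3
        pick = rng.integers(0, ncod, size=ncod)
        rows = {g: "".join(ca.rows[g][3 * c:3 * c + 3] for c in pick)
                for g in ids}
    else:
        pick = rng.integers(0, L, size=L)
        # keep the frame by padding to a codon multiple
        keep = 3 * (L // 3)
        rows = {g: "".join(ca.rows[g][c] for c in pick)[:keep] for g in ids}
    return CodonAlignment(rows=rows)


def bootstrap(ca: CodonAlignment, cfg: PhyloConfig = PhyloConfig()
              ) -> SupportTree:
    """Full-data NJ tree with bootstrap supports on internal edges.

    Codon columns are resampled with replacement per replicate (a config
    switch selects plain nucleotide columns); each replicate re-estimates
    distances and a tree, and bipartition frequencies are mapped onto the
    full-data topology.  Degenerate replicates (saturated distances) count
    as non-supporting and are logged.
    """
    if ca.n_columns < 3:
        raise InvalidInputError("alignment has no columns to resample")
    full = nj_tree(mcl_distances(ca))
    target = full.bipartitions()
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(cfg.rng_seed)
    degenerate = 0
    for _ in range(cfg.bootstrap_replicates):
        rep = _resample(ca, rng, cfg.resample_unit)
        try:
            dm = mcl_distances(rep)
            tree = nj_tree(dm)
        except (SaturatedDistanceError, InvalidInputError):
            degenerate += 1
            continue
        found = tree.bipartitions()
        for key in counts:
            if key in found:
                counts[key] += 1
    if degenerate:
        logger.info("bootstrap: %d/%d degenerate replicates counted as "
                    "non-supporting", degenerate, cfg.bootstrap_replicates)
    for key, edge in target.items():
        edge.support = 100.0 * counts[key] / cfg.bootstrap_replicates
    return full


# ---------------------------------------------------------------------------
# rooting and filtering

def root_on_edge(t: SupportTree, side: frozenset) -> SupportTree:
    """Root on the edge whose far-side leaf set equals ``side``.

    The edge is split in half; its support (if any) is retained on both
    halves.  This is the manual override for families lacking a true
    outgroup gene.
    """
    all_leaves = frozenset(t.leaf_labels())
    for a, b, e in t.edges():
        if t._side_leaves(b, a) == side:
            a, b = b, a
        if t._side_leaves(a, b) == side:
            mid = t.new_node()
            del t.adj[a][b]
            del t.adj[b][a]
            t.connect(mid, b, e.length / 2, support=e.support)
            t.connect(mid, a, e.length / 2, support=e.support)
            t.root = mid
            return t
    raise OutgroupError(
        f"no edge separates {sorted(side)} from {sorted(all_leaves - side)}")


def root_with_outgroup(t: SupportTree, outgroup_labels: Iterable[str]
                       ) -> SupportTree:
    """Place the root on the edge separating the outgroup from the ingroup.

    Errors when outgroup labels are missing or not monophyletic in the
    unrooted tree (the tree is left unchanged; use :func:`root_on_edge`
    to override manually in that case).
    """
    og = frozenset(outgroup_labels)
    leaves = frozenset(t.leaf_labels())
    if not og:
        raise OutgroupError("empty outgroup")
    missing = og - leaves
    if missing:
        raise OutgroupError(f"outgroup labels not in tree: {sorted(missing)}")
    if og == leaves:
        raise OutgroupError("outgroup cannot be the whole tree")
    for a, b, e in t.edges():
        if t._side_leaves(a, b) in (og, leaves - og):
            return root_on_edge(t, og)
    raise OutgroupError(
        f"outgroup {sorted(og)} is not monophyletic in the tree")


def exclude_pseudogenes(records: Sequence[SequenceRecord],
                        flags: Mapping[str, bool] | None = None
                        ) -> list[SequenceRecord]:
    """Drop pseudogene-flagged records before tree building.

    The flag comes from the record itself or an explicit mapping; removal
    counts are logged, and an all-pseudogene input triggers a warning.
    """
    out = []
    removed = 0
    for rec in records:
        flagged = flags.get(rec.id, rec.pseudogene) if flags else rec.pseudogene
        if flagged:
            removed += 1
        else:
            out.append(rec)
    if removed:
        logger.info("excluded %d pseudogene(s) from phylogenetic analysis",
                    removed)
    if records and not out:
        warnings.warn("all records were flagged as pseudogenes; nothing left")
    return out


def write_phylip_distances(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f" {len(dm.labels)}\n")
        for i, lbl in enumerate(dm.labels):
            row = " ".join(f"{dm.d[i, j]:.6f}" for j in range(len(dm.labels)))
            fh.write(f"{lbl}  {row}\n")
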