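"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (plain
loops, closed-form formulas, exhaustive enumeration) and kept independent
of the package's own code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# alignment oracles (gap of length k costs open + k * extend)

def sw_affine_score(a: str, b: str, score_fn, gap_open: float,
                    gap_extend: float) -> float:
    """Smith-Waterman local alignment score, plain three-state Gotoh."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_affine_score(a: str, b: str, score_fn, gap_open: float,
                    gap_extend: float) -> float:
    """Global affine-gap alignment score (Gotoh), same gap convention."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                          Iy[i - 1][j - 1]) + score_fn(a[i - 1], b[j - 1])
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                           Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                           Ix[i][j - 1] - gap_open - gap_extend,
                           Iy[i][j - 1] - gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


# ---------------------------------------------------------------------------
# distance oracles

def jc_distance(p: float) -> float:
    """Jukes-Cantor distance from an observed mismatch proportion."""
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def tn93_distance(a: str, b: str) -> float:
    """Closed-form Tamura-Nei (1993) pairwise distance."""
    n = len(a)
    assert len(b) == n and n > 0
    counts = {"P1": 0, "P2": 0, "Q": 0}
    freq = {x: 0 for x in "ACGT"}
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    for x, y in zip(a, b):
        freq[x] += 1
        freq[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair == purines:
            counts["P1"] += 1
        elif pair == pyrimidines:
            counts["P2"] += 1
        else:
            counts["Q"] += 1
    gA, gC, gG, gT = (freq[x] / (2 * n) for x in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = (counts[k] / n for k in ("P1", "P2", "Q"))
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# ---------------------------------------------------------------------------
# exhaustive tree search

def _all_topologies(labels):
    """All unrooted binary topologies as edge lists over labelled leaves.

    Nodes are labels (leaves) or integers (internal); built by inserting
    leaves one at a time into every edge.
    """
    labels = list(labels)
    assert len(labels) >= 3
    first = [(labels[0], "i0"), (labels[1], "i0"), (labels[2], "i0")]
    tops = [first]
    counter = 1
    for leaf in labels[3:]:
        new_tops = []
        for edges in tops:
            for k, (u, v) in enumerate(edges):
                mid = f"i{counter}x{k}x{leaf}"
                rest = edges[:k] + edges[k + 1:]
                new_tops.append(rest + [(u, mid), (v, mid), (leaf, mid)])
        tops = new_tops
        counter += 1
    return tops


def _leafsets(edges, leaves):
    """Bipartition leaf set for each edge (the side away from leaves[0])."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    ref = leaves[0]
    out = []
    leafset = set(leaves)
    for u, v in edges:
        # collect leaves on v side without crossing edge (u, v)
        seen, stack, got = {u}, [v], set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in leafset:
                got.add(x)
            stack.extend(adj[x])
        side = frozenset(got) if ref not in got else frozenset(leafset - got)
        out.append(side)
    return out


def min_evolution_bipartitions(labels, dmat) -> set:
    """Exhaustive minimum-evolution search: OLS branch lengths on every
    unrooted topology, minimal total length wins; ties broken by
    sorted-bipartition representation for determinism.

    ``dmat[i][j]`` indexed by positions of ``labels``.
    """
    labels = list(labels)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    pairs = list(itertools.combinations(labels, 2))
    d = np.array([dmat[idx[x]][idx[y]] for x, y in pairs])
    best = None
    for edges in _all_topologies(labels):
        sides = _leafsets(edges, labels)
        A = np.zeros((len(pairs), len(edges)))
        for pi, (x, y) in enumerate(pairs):
            for ei, side in enumerate(sides):
                if (x in side) != (y in side):
                    A[pi, ei] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(np.linalg.norm(A @ x - d))
        length = float(x.sum())
        internal = {s for s in sides if 2 <= len(s) <= len(labels) - 2}
        key = (round(length, 9), round(resid, 9), tuple(sorted(map(sorted, internal))))
        if best is None or key < best[0]:
            best = (key, internal)
    return best[1]


def random_additive_matrix(labels, rng):
    """Random binary tree over labels -> (distance matrix, bipartitions)."""
    labels = list(labels)
    edges = []
    nodes = [labels[0], labels[1], labels[2]]
    edges = [(labels[0], "c"), (labels[1], "c"), (labels[2], "c")]
    cnt = 0
    for leaf in labels[3:]:
        k = rng.integers(0, len(edges))
        u, v = edges.pop(int(k))
        mid = f"m{cnt}"
        cnt += 1
        edges += [(u, mid), (v, mid), (leaf, mid)]
    lengths = {e: float(rng.uniform(0.1, 2.0)) for e in edges}
    adj = {}
    for (u, v), w in lengths.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(labels)
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    sides = {s for s in _leafsets(edges, labels)
             if 2 <= len(s) <= len(labels) - 2}
    return D, sides


# ---------------------------------------------------------------------------
# orthology truth oracle

def lca_relation(root, a: str, b: str) -> str:
    """Relation of two leaves from the event at their last common ancestor,
    found by explicit root-to-leaf paths (independent of the simulator's
    own partition-based labelling)."""

    def path_to(node, target, acc):
        acc.append(node)
        if not node.children and node.name == target:
            return True
        for c in node.children:
            if path_to(c, target, acc):
                return True
        acc.pop()
        return False

    pa: list = []
    pb: list = []
    assert path_to(root, a, pa) and path_to(root, b, pb)
    lca = None
    for x, y in zip(pa, pb):
        if x is y:
            lca = x
        else:
            break
    return "paralogue" if lca.event == "duplication" else "orthologue"
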