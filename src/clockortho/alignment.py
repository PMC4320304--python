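"""Protein-guided multiple alignment with a codon-preserving projection.

Coding sequences are aligned in protein space — progressive profile–
profile alignment (BLOSUM62, affine gaps) over a neighbour-joining guide
tree built from shared k-mer distances — and the nucleotide alignment is
obtained by back-translation, so every gap run has length divisible by
three and column triplets map one-to-one onto protein columns.
Complete deletion (masking every codon column containing a gap or
ambiguity in any row) prepares the alignment for distance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .records import InvalidInputError, SequenceRecord, translate_cds

__all__ = [
    "AlignScoring",
    "ProteinAlignment",
    "CodonAlignment",
    "align_proteins",
    "backtranslate",
    "mask_incomplete_columns",
    "write_aligned_fasta",
    "write_phylip",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
NEG_INF = -1e30


@dataclass(frozen=True)
class AlignScoring:
    """Progressive-alignment parameters; gap of length k costs open + k*extend."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    kmer: int = 3


@dataclass
class _BaseAlignment:
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise InvalidInputError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, gene_id: str) -> str:
        return self.rows[gene_id].replace("-", "")

    def __len__(self) -> int:
        return len(self.rows)


class ProteinAlignment(_BaseAlignment):
    """Gapped amino-acid rows of equal length keyed by gene id."""


class CodonAlignment(_BaseAlignment):
    """Gapped nucleotide rows whose columns come in codon triplets."""

    def __post_init__(self):
        super().__post_init__()
        if self.n_columns % 3:
            raise InvalidInputError("codon alignment length not divisible by 3")
        for gid, row in self.rows.items():
            pos = 0
            while pos < len(row):
                if row[pos] == "-":
                    run = 0
                    while pos < len(row) and row[pos] == "-":
                        run += 1
                        pos += 1
                    if run % 3:
                        raise InvalidInputError(
                            f"{gid}: gap run of length {run} breaks codon structure")
                else:
                    pos += 1

    @property
    def degenerate(self) -> bool:
        return self.n_columns == 0


# ---------------------------------------------------------------------------
# pairwise / profile-profile machinery

def _blosum_array(name: str) -> np.ndarray:
    m = substitution_matrices.load(name)
    arr = np.zeros((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            arr[i, j] = m[a, b]
    return arr


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """Column x 20 amino-acid count matrix; gaps and X contribute nothing."""
    L = len(rows[0])
    counts = np.zeros((L, len(_AA)))
    for row in rows:
        for pos, aa in enumerate(row):
            k = _AA_INDEX.get(aa)
            if k is not None:
                counts[pos, k] += 1
    return counts


def _gotoh_profile(ca: np.ndarray, cb: np.ndarray, na: int, nb: int,
                   blosum: np.ndarray, open_: float, ext: float):
    """Global affine profile-profile alignment (canonical three-state DP).

    Returns (score, path) with path entries 'D', 'U' (gap in B), 'L'
    (gap in A).  Deterministic tie-break: match > vertical > horizontal.
    """
    La, Lb = ca.shape[0], cb.shape[0]
    S = (ca @ blosum @ cb.T) / (na * nb)
    M = np.full((La + 1, Lb + 1), NEG_INF)
    Ix = np.full((La + 1, Lb + 1), NEG_INF)  # gap in B (consume A)
    Iy = np.full((La + 1, Lb + 1), NEG_INF)  # gap in A (consume B)
    M[0, 0] = 0.0
    jj = np.arange(Lb + 1)
    Iy[0, 1:] = -(open_ + ext * jj[1:])
    Ix[1:, 0] = -(open_ + ext * np.arange(1, La + 1))
    for i in range(1, La + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + S[i - 1]
        Ix[i] = np.maximum(M[i - 1] - open_ - ext, Ix[i - 1] - ext)
        # horizontal gaps within the row via prefix-max scan
        t = np.maximum(M[i], Ix[i]) + ext * jj
        np.maximum.accumulate(t, out=t)
        Iy[i, 1:] = t[:-1] - open_ - ext * jj[1:]
        Iy[i, 0] = NEG_INF if i > 0 else Iy[i, 0]
    i, j = La, Lb
    finals = (M[i, j], Ix[i, j], Iy[i, j])
    state = int(np.argmax(finals))  # 0=M,1=Ix,2=Iy (tie: M wins)
    score = float(finals[state])
    path: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                state = 2 if i == 0 else 1
                continue
            path.append("D")
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            path.append("U")
            if abs(Ix[i, j] - (M[i - 1, j] - open_ - ext)) < 1e-9:
                state = 0
            i -= 1
        else:
            path.append("L")
            if abs(Iy[i, j] - (np.maximum(M[i, j - 1], Ix[i, j - 1])
                               - open_ - ext)) < 1e-9:
                state = 0 if M[i, j - 1] >= Ix[i, j - 1] else 1
            j -= 1
    path.reverse()
    return score, path


def _merge(rows_a: dict[str, str], rows_b: dict[str, str],
           path: list[str]) -> dict[str, str]:
    out = {}
    for gid, row in rows_a.items():
        buf, k = [], 0
        for move in path:
            if move in ("D", "U"):
                buf.append(row[k]); k += 1
            else:
                buf.append("-")
        out[gid] = "".join(buf)
    for gid, row in rows_b.items():
        buf, k = [], 0
        for move in path:
            if move in ("D", "L"):
                buf.append(row[k]); k += 1
            else:
                buf.append("-")
        out[gid] = "".join(buf)
    return out


# ---------------------------------------------------------------------------
# guide tree

def _kmer_distance(a: str, b: str, k: int) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _guide_tree(ids: list[str], d: np.ndarray):
    """NJ merge order as nested tuples over sequence ids (lexicographic ties)."""
    nodes: list = list(ids)
    dist = {frozenset((i, j)): d[i, j]
            for i in range(len(ids)) for j in range(i + 1, len(ids))}
    key_of = {ids[i]: i for i in range(len(ids))}
    active = list(range(len(ids)))
    labels: dict[int, str] = {i: ids[i] for i in active}
    trees: dict[int, object] = {i: ids[i] for i in active}
    D = d.copy()
    nxt = len(ids)
    while len(active) > 2:
        n = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(n):
            for bi in range(ai + 1, n):
                i, j = active[ai], active[bi]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                tie = tuple(sorted((labels[i], labels[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        new = nxt; nxt += 1
        Dn = np.pad(D, ((0, 1), (0, 1)))
        for k2 in active:
            if k2 in (i, j):
                continue
            Dn[new, k2] = Dn[k2, new] = 0.5 * (D[i, k2] + D[j, k2] - D[i, j])
        D = Dn
        trees[new] = (trees[i], trees[j])
        labels[new] = min(labels[i], labels[j])
        active = [a for a in active if a not in (i, j)] + [new]
    if len(active) == 2:
        i, j = active
        return (trees[i], trees[j])
    return trees[active[0]]


def align_proteins(seqs: Sequence[SequenceRecord],
                   scoring: AlignScoring = AlignScoring()) -> ProteinAlignment:
    """Progressive multiple alignment of protein records.

    Pairs are aligned by exact global DP; larger sets follow an NJ guide
    tree on shared-k-mer distances with profile-profile alignment at each
    internal node.  Fully deterministic for fixed input order-independent
    ids (ties broken lexicographically).
    """
    if len(seqs) < 2:
        raise InvalidInputError("need at least two sequences to align")
    prots = {}
    for s in seqs:
        rec = translate_cds(s) if s.moltype == "cds" else s
        if rec.moltype != "protein":
            raise InvalidInputError(f"{s.id}: cannot align moltype {s.moltype}")
        residues = rec.residues.rstrip("*")
        bad = set(residues) - set(_AA) - {"X"}
        if bad:
            raise InvalidInputError(
                f"{s.id}: non-amino-acid symbols {sorted(bad)}")
        if rec.id in prots:
            raise InvalidInputError(f"duplicate id {rec.id}")
        prots[rec.id] = residues
    blosum = _blosum_array(scoring.matrix_name)
    ids = sorted(prots)
    if len(ids) == 2:
        tree = (ids[0], ids[1])
    else:
        d = np.zeros((len(ids), len(ids)))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d[i, j] = d[j, i] = _kmer_distance(
                    prots[ids[i]], prots[ids[j]], scoring.kmer)
        tree = _guide_tree(ids, d)

    def _align_node(node) -> dict[str, str]:
        if isinstance(node, str):
            return {node: prots[node]}
        rows_a = _align_node(node[0])
        rows_b = _align_node(node[1])
        ca = _profile_counts(list(rows_a.values()))
        cb = _profile_counts(list(rows_b.values()))
        _, path = _gotoh_profile(ca, cb, len(rows_a), len(rows_b), blosum,
                                 scoring.gap_open, scoring.gap_extend)
        return _merge(rows_a, rows_b, path)

    merged = _align_node(tree)
    return ProteinAlignment(rows={gid: merged[gid] for gid in sorted(merged)})


# ---------------------------------------------------------------------------

def backtranslate(pa: ProteinAlignment,
                  cds_map: Mapping[str, SequenceRecord | str]) -> CodonAlignment:
    """Project a protein alignment onto codons of the source CDS.

    Every amino-acid column becomes its source codon, every protein gap a
    ``---`` triplet.  The CDS must translate exactly to the ungapped
    protein row (a trailing stop codon is tolerated and trimmed); any
    mismatch is a hard error naming the gene and position.
    """
    rows = {}
    for gid, prow in pa.rows.items():
        if gid not in cds_map:
            raise InvalidInputError(f"{gid}: no CDS supplied")
        cds = cds_map[gid]
        cds_seq = cds.residues if isinstance(cds, SequenceRecord) else cds
        prot = prow.replace("-", "")
        rec = SequenceRecord(id=gid, species="", moltype="cds",
                             residues=cds_seq, complete=False)
        trans = translate_cds(rec).residues
        if trans != prot:
            pos = next((k for k, (x, y) in enumerate(zip(trans, prot))
                        if x != y), min(len(trans), len(prot)))
            raise InvalidInputError(
                f"{gid}: CDS translation differs from aligned protein at "
                f"position {pos + 1}")
        codons = [cds_seq[3 * i:3 * i + 3] for i in range(len(prot))]
        buf, k = [], 0
        for aa in prow:
            if aa == "-":
                buf.append("---")
            else:
                buf.append(codons[k]); k += 1
        rows[gid] = "".join(buf)
    return CodonAlignment(rows=rows)


def mask_incomplete_columns(ca: CodonAlignment) -> CodonAlignment:
    """Complete deletion: drop every codon column with a gap or ambiguity.

    The result can be empty (degenerate) when some row is all gaps; it is
    flagged via :attr:`CodonAlignment.degenerate`.
    """
    ids = list(ca.rows)
    ncod = ca.n_columns // 3
    keep = []
    for c in range(ncod):
        ok = True
        for gid in ids:
            cod = ca.rows[gid][3 * c:3 * c + 3]
            if "-" in cod or "N" in cod:
                ok = False
                break
        if ok:
            keep.append(c)
    rows = {gid: "".join(ca.rows[gid][3 * c:3 * c + 3] for c in keep)
            for gid in ids}
    return CodonAlignment(rows=rows)


def write_aligned_fasta(aln: _BaseAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, row in aln.rows.items():
            fh.write(f">{gid}\n{row}\n")


def write_phylip(aln: _BaseAlignment, path: str | Path) -> None:
    """Sequential PHYLIP with full-length (relaxed) names."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.rows)} {aln.n_columns}\n")
        for gid, row in aln.rows.items():
            fh.write(f"{gid}  {row}\n")
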