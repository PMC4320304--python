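"""Deterministic local-alignment database search with E-value ranking.

An in-package stand-in for a protein BLAST run: full Smith–Waterman
dynamic programming (no heuristic seeding) under BLOSUM62 with affine
gaps, scored with Karlin–Altschul statistics so that hits can be ranked
and thresholded by E-value.  CDS records are translated to protein before
searching; genomic records are not searchable.

The tie-breaking order everywhere is (E-value ascending, bit score
descending, subject id ascending), which makes every downstream
reciprocal-hit decision bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .records import InvalidInputError, SequenceRecord, SpeciesDatabase, translate_cds

__all__ = [
    "ScoringParams",
    "SearchHit",
    "HitList",
    "align_local",
    "evalue_of",
    "bitscore_of",
    "search",
    "top_hit",
    "write_hit_table",
    "read_hit_table",
]

# Karlin-Altschul constants for ungapped BLOSUM62; applied to gapped
# scores as a stated approximation (only ranking and ratio ties matter
# downstream).
_BLOSUM62_LAMBDA = 0.3176
_BLOSUM62_K = 0.134


@dataclass(frozen=True)
class ScoringParams:
    """Alignment and E-value scoring parameters.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = _BLOSUM62_LAMBDA
    ka_k: float = _BLOSUM62_K
    report_threshold: float = 1e-5

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # Biopython charges open_gap_score on the first gapped position.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCORING = ScoringParams()


@dataclass(frozen=True)
class SearchHit:
    """One scored local-alignment hit (an edge of the reciprocity graph)."""

    query_id: str
    subject_id: str
    subject_species: str
    raw_score: int
    bitscore: float
    evalue: float
    query_span: Optional[tuple[int, int]]  # 1-based closed; None if empty
    subject_span: Optional[tuple[int, int]]
    identity_pct: float = 0.0
    aln_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    @property
    def sort_key(self) -> tuple:
        return (self.evalue, -self.bitscore, self.subject_id)


@dataclass
class HitList:
    """Hits of one query against one species database, canonically sorted."""

    query_id: str
    target_species: str
    hits: list[SearchHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: h.sort_key)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __bool__(self) -> bool:
        return bool(self.hits)


def _check_alphabet(residues: str, matrix) -> None:
    bad = set(residues) - set(matrix.alphabet)
    if bad:
        raise InvalidInputError(
            f"symbols {sorted(bad)} not present in scoring matrix alphabet"
        )


def align_local(a: str, b: str, scoring: ScoringParams = DEFAULT_SCORING):
    """Optimal Smith–Waterman local alignment under affine gaps.

    Returns ``(raw_score, a_span, b_span)`` where spans are 1-based closed
    intervals of the aligned region, or ``None`` spans when no cell scores
    above zero.  Among co-optimal alignments the one with the lowest start
    coordinates (query first) is reported; the score is unique.
    """
    if not a or not b:
        raise InvalidInputError("cannot align empty sequences")
    matrix = scoring.matrix
    _check_alphabet(a, matrix)
    _check_alphabet(b, matrix)
    aligner = scoring.aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return 0, None, None
    alignments = aligner.align(a, b)
    # Co-optimal tracebacks can be numerous; scan a bounded prefix for the
    # lowest-start representative.  The score is the same for all of them.
    best = None
    for i, aln in enumerate(alignments):
        blocks_a, blocks_b = aln.aligned
        key = (int(blocks_a[0][0]), int(blocks_b[0][0]))
        if best is None or key < best[0]:
            best = (key, aln)
        if i >= 15:
            break
    aln = best[1]
    blocks_a, blocks_b = aln.aligned
    a_span = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return int(round(score)), a_span, b_span


def _alignment_stats(aln) -> tuple[float, int, int, int]:
    """(identity %, alignment length, mismatches, gap opens) of one alignment."""
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    ident = 100.0 * counts.identities / length if length else 0.0
    blocks_a, _ = aln.aligned
    gap_opens = max(len(blocks_a) - 1, 0)
    return ident, length, counts.mismatches, gap_opens


def evalue_of(raw_score: float, query_len: int, db_residue_count: int,
              scoring: ScoringParams = DEFAULT_SCORING) -> float:
    """Karlin–Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    if query_len <= 0 or db_residue_count <= 0:
        raise InvalidInputError("sequence and database lengths must be positive")
    if raw_score < 0:
        raise InvalidInputError("raw score must be non-negative")
    return scoring.ka_k * query_len * db_residue_count * math.exp(
        -scoring.ka_lambda * raw_score
    )


def bitscore_of(raw_score: float, scoring: ScoringParams = DEFAULT_SCORING) -> float:
    return (scoring.ka_lambda * raw_score - math.log(scoring.ka_k)) / math.log(2.0)


def _as_protein(rec: SequenceRecord) -> SequenceRecord:
    if rec.moltype == "protein":
        return rec
    if rec.moltype == "cds":
        return translate_cds(rec)
    raise InvalidInputError(f"{rec.id}: genomic records are not searchable")


def search(query: SequenceRecord, db: SpeciesDatabase,
           scoring: ScoringParams = DEFAULT_SCORING,
           report_threshold: float | None = None) -> HitList:
    """Align a query against every record of one species database.

    Hits at or below the reporting E-value threshold are returned in
    canonical order.  The query itself is excluded when it searches its
    home database; an empty database yields an empty hit list.
    """
    if report_threshold is None:
        report_threshold = scoring.report_threshold
    q = _as_protein(query)
    subjects = [_as_protein(r) for r in db]
    db_residues = sum(len(s) for s in subjects)
    aligner = scoring.aligner()
    hits: list[SearchHit] = []
    for subj in subjects:
        if subj.id == query.id:
            continue
        score = aligner.score(q.residues, subj.residues)
        if score <= 0:
            continue
        raw = int(round(score))
        ev = evalue_of(raw, len(q), db_residues, scoring)
        if ev > report_threshold:
            continue
        aln = next(iter(aligner.align(q.residues, subj.residues)))
        blocks_q, blocks_s = aln.aligned
        ident, length, mism, gaps = _alignment_stats(aln)
        hits.append(SearchHit(
            query_id=query.id,
            subject_id=subj.id,
            subject_species=db.species,
            raw_score=raw,
            bitscore=bitscore_of(raw, scoring),
            evalue=ev,
            query_span=(int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])),
            subject_span=(int(blocks_s[0][0]) + 1, int(blocks_s[-1][1])),
            identity_pct=ident,
            aln_length=length,
            mismatches=mism,
            gap_opens=gaps,
        ))
    return HitList(query_id=query.id, target_species=db.species, hits=hits)


def top_hit(hl: HitList) -> Optional[SearchHit]:
    """First hit under the canonical sort order, or None if empty."""
    return hl.hits[0] if hl.hits else None


_TAB_COLUMNS = ("qseqid sseqid pident length mismatch gapopen "
                "qstart qend sstart send evalue bitscore").split()


def write_hit_table(hitlists: Iterable[HitList], path: str | Path) -> None:
    """Serialize hits as 12-column tab-separated records (tabular format)."""
    with open(path, "w") as fh:
        for hl in hitlists:
            for h in hl:
                qs = h.query_span or (0, 0)
                ss = h.subject_span or (0, 0)
                fh.write("\t".join(str(x) for x in (
                    h.query_id, h.subject_id, f"{h.identity_pct:.2f}",
                    h.aln_length, h.mismatches, h.gap_opens,
                    qs[0], qs[1], ss[0], ss[1],
                    f"{h.evalue:.3e}", f"{h.bitscore:.1f}",
                )) + "\n")


def read_hit_table(path: str | Path, subject_species: str = "") -> list[SearchHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise InvalidInputError(f"malformed hit-table row: {line!r}")
            hits.append(SearchHit(
                query_id=f[0], subject_id=f[1], subject_species=subject_species,
                identity_pct=float(f[2]), aln_length=int(f[3]),
                mismatches=int(f[4]), gap_opens=int(f[5]),
                query_span=(int(f[6]), int(f[7])),
                subject_span=(int(f[8]), int(f[9])),
                evalue=float(f[10]), bitscore=float(f[11]),
                raw_score=0,
            ))
    return hits
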