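"""Gene models, splice-site validation and evidence-guided re-annotation.

Gene structures are held as 1-based closed exon intervals on the forward
genomic strand with a strand flag (GFF3 convention); all splicing logic is
transcript-oriented after strand normalisation.

Validation applies the two sequence-intrinsic re-annotation criteria:
canonical GT..AG dinucleotides at every intron boundary, and maintenance
of an open reading frame across the spliced CDS (no internal stops; ATG
start and stop-codon end when the model claims to be complete).
Re-annotation itself searches, by exact dynamic programming over
candidate splice points, for the exon/intron structure whose spliced CDS
best matches an evidence CDS (a transcript or an orthologue's coding
sequence) subject to those hard constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .records import InvalidInputError, SequenceRecord

__all__ = [
    "GeneModel",
    "AnnotationVerdict",
    "StructureDiff",
    "validate_model",
    "reannotate",
    "compare_structures",
    "write_gff3",
    "read_gff3",
    "SplicedAlignParams",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one gene on a genomic sequence.

    ``exons`` and ``cds_exons`` are 1-based closed intervals in ascending
    forward-strand order; ``cds_exons`` must be contained in the exon
    union.  UTR intervals are derived, never stored.
    """

    gene_id: str
    genomic: SequenceRecord
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_exons: tuple[tuple[int, int], ...]
    complete: bool = True
    partial: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise InvalidInputError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise InvalidInputError(f"{self.gene_id}: no exons")
        n = len(self.genomic.residues)
        last_end = 0
        for s, e in self.exons:
            if not (1 <= s <= e <= n):
                raise InvalidInputError(
                    f"{self.gene_id}: exon {s}-{e} outside genomic sequence (1-{n})")
            if s <= last_end:
                raise InvalidInputError(
                    f"{self.gene_id}: exons overlap or are unsorted at {s}-{e}")
            last_end = e
        for s, e in zip(self.exons[:-1], self.exons[1:]):
            if e[0] - s[1] - 1 < 4:
                raise InvalidInputError(
                    f"{self.gene_id}: intron between {s} and {e} shorter than 4 nt")
        exon_cover = set()
        for s, e in self.exons:
            exon_cover.update(range(s, e + 1))
        for s, e in self.cds_exons:
            if not set(range(s, e + 1)) <= exon_cover:
                raise InvalidInputError(
                    f"{self.gene_id}: CDS interval {s}-{e} outside exon union")

    # -- derived structure -------------------------------------------------

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons, ascending order."""
        return [(a[1] + 1, b[0] - 1)
                for a, b in zip(self.exons[:-1], self.exons[1:])]

    def _extract(self, intervals: Sequence[tuple[int, int]]) -> str:
        g = self.genomic.residues
        seq = "".join(g[s - 1:e] for s, e in intervals)
        return _revcomp(seq) if self.strand == "-" else seq

    def spliced(self) -> str:
        """Full spliced transcript sequence, transcript orientation."""
        return self._extract(self.exons)

    def spliced_cds(self) -> str:
        """Spliced coding sequence, transcript orientation."""
        return self._extract(self.cds_exons)

    def intron_sequence(self, idx: int) -> str:
        """Transcript-oriented sequence of intron ``idx`` (transcript order)."""
        intr = self.introns()
        if self.strand == "-":
            intr = intr[::-1]
        s, e = intr[idx]
        seq = self.genomic.residues[s - 1:e]
        return _revcomp(seq) if self.strand == "-" else seq

    def n_introns(self) -> int:
        return len(self.exons) - 1

    def utrs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5' UTR, 3' UTR) interval lists, forward-strand coordinates."""
        if not self.cds_exons:
            return list(self.exons), []
        cds_lo = min(s for s, _ in self.cds_exons)
        cds_hi = max(e for _, e in self.cds_exons)
        before, after = [], []
        for s, e in self.exons:
            if e < cds_lo:
                before.append((s, e))
            elif s < cds_lo:
                before.append((s, cds_lo - 1))
            if s > cds_hi:
                after.append((s, e))
            elif e > cds_hi:
                after.append((cds_hi + 1, e))
        return (before, after) if self.strand == "+" else (after, before)


@dataclass(frozen=True)
class AnnotationVerdict:
    """Result of validating a gene model against the splice/ORF rules."""

    model: GeneModel
    violations: tuple[dict, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_model(m: GeneModel) -> AnnotationVerdict:
    """Check canonical splice sites (rule: GT..AG) and ORF maintenance.

    Intron boundaries are examined in transcript orientation, so a minus-
    strand intron is reverse-complemented before the GT/AG test.  The
    spliced CDS must translate without internal stop codons; a model
    flagged ``complete`` must additionally start with ATG, end with a stop
    codon, and have length divisible by three.
    """
    violations: list[dict] = []
    for idx in range(m.n_introns()):
        seq = m.intron_sequence(idx)
        if seq[:2] != "GT" or seq[-2:] != "AG":
            violations.append({
                "rule": 2, "location": f"intron {idx + 1}",
                "detail": f"boundary {seq[:2]}..{seq[-2:]} is not GT..AG",
            })
    cds = m.spliced_cds()
    if cds:
        if m.complete and len(cds) % 3:
            violations.append({"rule": 3, "location": "cds",
                               "detail": f"length {len(cds)} not divisible by 3"})
        ncod = len(cds) // 3
        codons = [cds[3 * i:3 * i + 3] for i in range(ncod)]
        for i, cod in enumerate(codons[:-1]):
            if cod in STOP_CODONS:
                violations.append({"rule": 3, "location": f"codon {i + 1}",
                                   "detail": f"internal stop codon {cod}"})
                break
        if m.complete and codons:
            if codons[0] != "ATG":
                violations.append({"rule": 3, "location": "codon 1",
                                   "detail": f"start codon is {codons[0]}, not ATG"})
            if codons[-1] not in STOP_CODONS:
                violations.append({"rule": 3, "location": f"codon {ncod}",
                                   "detail": "no terminal stop codon"})
    return AnnotationVerdict(model=m, violations=tuple(violations))


# ---------------------------------------------------------------------------
# evidence-guided re-annotation (spliced alignment by exact DP)

@dataclass(frozen=True)
class SplicedAlignParams:
    """Scores of the spliced-alignment DP used by :func:`reannotate`."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_genomic: float = -6.0   # per genomic nt skipped inside an exon
    gap_cds: float = -6.0       # per evidence nt with no genomic partner
    intron_open: float = -12.0  # flat cost of one GT..AG intron
    min_intron: int = 20


def _spliced_align(genomic: str, cds: str, p: SplicedAlignParams):
    """Best local spliced alignment of ``cds`` onto ``genomic``.

    Introns are jumps over genomic segments that begin GT and end AG, at
    least ``min_intron`` long, each costing a flat penalty.  Returns
    ``(score, exons, cds_span)`` with exons as 1-based closed genomic
    intervals and cds_span the 1-based closed matched interval of the
    evidence, or ``(0, [], None)`` when nothing aligns.
    """
    n, m = len(genomic), len(cds)
    g = np.frombuffer(genomic.encode(), dtype=np.uint8)
    c = np.frombuffer(cds.encode(), dtype=np.uint8)
    H = np.zeros((n + 1, m + 1), dtype=np.float32)
    # donor site after row i: genomic[i:i+2] == "GT" (0-based)
    donor = np.zeros(n + 1, dtype=bool)
    donor[0:n - 1] = (g[:-1] == ord("G")) & (g[1:] == ord("T"))
    # acceptor ending at row i: genomic[i-2:i] == "AG"
    acceptor = np.zeros(n + 1, dtype=bool)
    if n >= 2:
        acceptor[2:] = (g[:-1] == ord("A")) & (g[1:] == ord("G"))
    D = np.full(m + 1, -np.inf, dtype=np.float32)   # best eligible donor score
    Darg = np.full(m + 1, -1, dtype=np.int32)       # its row index
    intron_rows: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    jj = np.arange(m + 1, dtype=np.float32)
    for i in range(1, n + 1):
        newly = i - p.min_intron
        if newly >= 0 and donor[newly]:
            cand = H[newly] + p.intron_open
            upd = cand > D
            D[upd] = cand[upd]
            Darg[upd] = newly
        prev = H[i - 1]
        s_row = np.where(c == g[i - 1], p.match, p.mismatch).astype(np.float32)
        cur = np.maximum(prev + p.gap_genomic, 0.0)
        np.maximum(cur[1:], prev[:-1] + s_row, out=cur[1:])
        if acceptor[i] and np.isfinite(D).any():
            np.maximum(cur, np.where(np.isfinite(D), D, 0.0), out=cur)
            intron_rows[i] = (D.copy(), Darg.copy())
        # cds-only gaps via a prefix-max scan (linear gap cost)
        t = cur - p.gap_cds * jj
        np.maximum.accumulate(t, out=t)
        np.maximum(cur, t + p.gap_cds * jj, out=cur)
        H[i] = cur
    best = float(H.max())
    if best <= 0:
        return 0.0, [], None
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    j_end = j
    exons: list[tuple[int, int]] = []
    exon_end: Optional[int] = None
    eps = 1e-4
    while i > 0 and j > 0 and H[i, j] > eps:
        h = H[i, j]
        s = p.match if g[i - 1] == c[j - 1] else p.mismatch
        if abs(h - (H[i - 1, j - 1] + s)) < eps:
            if exon_end is None:
                exon_end = i
            i, j = i - 1, j - 1
            continue
        ir = intron_rows.get(i)
        if ir is not None and abs(h - ir[0][j]) < eps and ir[1][j] >= 0:
            if exon_end is not None:
                exons.append((i + 1, exon_end))
                exon_end = None
            i = int(ir[1][j])
            exon_end = None
            continue
        if abs(h - (H[i - 1, j] + p.gap_genomic)) < eps:
            if exon_end is None:
                exon_end = i
            i -= 1
            continue
        if j > 0 and abs(h - (H[i, j - 1] + p.gap_cds)) < eps:
            j -= 1
            continue
        break  # local start (score dropped to zero)
    if exon_end is not None:
        exons.append((i + 1, exon_end))
    exons.reverse()
    merged: list[tuple[int, int]] = []
    for s0, e0 in exons:
        if merged and s0 <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e0)
        else:
            merged.append((s0, e0))
    return best, merged, (j + 1, j_end)


@dataclass(frozen=True)
class ReannotationResult:
    model: GeneModel
    evidence_id: str
    score: float
    runner_ups: tuple[tuple[str, float], ...] = ()


def reannotate(genomic: SequenceRecord,
               evidence_cds: Sequence[SequenceRecord],
               params: SplicedAlignParams = SplicedAlignParams(),
               gene_id: str | None = None) -> ReannotationResult:
    """Infer the exon/intron structure of a genomic sequence from evidence.

    Every evidence CDS is spliced-aligned to both strands of the genomic
    sequence; the highest-scoring constraint-satisfying structure wins
    (runner-up evidence scores are reported).  A model whose spliced CDS
    does not reproduce a clean full-length ORF covering the whole best
    evidence is returned flagged ``partial`` rather than silently invalid.
    """
    if genomic.moltype != "genomic":
        raise InvalidInputError(f"{genomic.id}: expected a genomic record")
    if not evidence_cds:
        raise InvalidInputError("re-annotation requires at least one evidence CDS")
    gene_id = gene_id or genomic.id
    n = len(genomic.residues)
    scored = []
    for ev in evidence_cds:
        if ev.moltype not in ("cds", "genomic"):
            raise InvalidInputError(f"{ev.id}: evidence must be nucleotide CDS")
        for strand in "+-":
            target = genomic.residues if strand == "+" else _revcomp(genomic.residues)
            score, exons, span = _spliced_align(target, ev.residues, params)
            scored.append((score, ev, strand, exons, span))
    scored.sort(key=lambda t: (-t[0], t[1].id, t[2]))
    best_score, best_ev, strand, exons, span = scored[0]
    if not exons:
        raise InvalidInputError(
            f"{gene_id}: no evidence aligns to the genomic sequence")
    if strand == "-":
        exons = [(n - e + 1, n - s + 1) for s, e in exons][::-1]
    model = GeneModel(
        gene_id=gene_id, genomic=genomic, strand=strand,
        exons=tuple(exons), cds_exons=tuple(exons),
        complete=True,
    )
    verdict = validate_model(model)
    full_cover = span is not None and span[0] == 1 and span[1] == len(best_ev.residues)
    if not verdict.passed or not full_cover:
        model = GeneModel(
            gene_id=gene_id, genomic=genomic, strand=strand,
            exons=tuple(exons), cds_exons=tuple(exons),
            complete=False, partial=True,
        )
    runner_ups = tuple((ev.id, sc) for sc, ev, st, _, _ in scored[1:]
                       if st == "+" or sc > 0)
    return ReannotationResult(model=model, evidence_id=best_ev.id,
                              score=best_score, runner_ups=runner_ups[:4])


# ---------------------------------------------------------------------------
# structure comparison

@dataclass(frozen=True)
class StructureDiff:
    """Intron-level differences between two aligned gene models."""

    gene_a: str
    gene_b: str
    conserved: tuple[dict, ...]   # {pos_a, pos_b, len_a, len_b, length_ratio}
    only_in_a: tuple[dict, ...]   # {pos_a, len_a}
    only_in_b: tuple[dict, ...]
    utr5_lengths: tuple[int, int]
    utr3_lengths: tuple[int, int]

    @property
    def n_differences(self) -> int:
        return len(self.only_in_a) + len(self.only_in_b)


def _cds_intron_positions(m: GeneModel) -> list[tuple[int, int, int]]:
    """(codon index 1-based, phase 0/1/2, length) of each CDS intron.

    Position is the count of spliced CDS nucleotides 5' of the intron.
    """
    cds_exons = list(m.cds_exons)
    if m.strand == "-":
        cds_exons = cds_exons[::-1]
    out = []
    consumed = 0
    for k, (s, e) in enumerate(cds_exons[:-1]):
        consumed += e - s + 1
        if m.strand == "+":
            nxt = cds_exons[k + 1]
            ilen = nxt[0] - e - 1
        else:
            nxt = cds_exons[k + 1]
            ilen = s - nxt[1] - 1
        out.append((consumed // 3 + 1, consumed % 3, ilen))
    return out


def compare_structures(a: GeneModel, b: GeneModel,
                       pairing: dict[int, int] | None = None) -> StructureDiff:
    """Report intron gains/losses and length ratios between two models.

    ``pairing`` maps 1-based codon indices of ``a`` onto ``b`` (from an
    aligned-protein coordinate map); identity is assumed when omitted.
    Two introns correspond when they interrupt homologous codons at the
    same phase.  Symmetric up to swapping the labels.
    """
    ia = _cds_intron_positions(a)
    ib = _cds_intron_positions(b)
    if pairing is None:
        pairing = {}
    b_index = {(codon, phase): (k, length)
               for k, (codon, phase, length) in enumerate(ib)}
    used_b = set()
    conserved, only_a = [], []
    for codon, phase, length in ia:
        mapped = pairing.get(codon, codon)
        hit = b_index.get((mapped, phase))
        if hit is not None and hit[0] not in used_b:
            used_b.add(hit[0])
            conserved.append({
                "pos_a": codon, "pos_b": mapped, "phase": phase,
                "len_a": length, "len_b": hit[1],
                "length_ratio": hit[1] / length if length else float("inf"),
            })
        else:
            only_a.append({"pos_a": codon, "phase": phase, "len_a": length})
    only_b = [{"pos_b": codon, "phase": phase, "len_b": length}
              for k, (codon, phase, length) in enumerate(ib) if k not in used_b]

    def _utr_len(iv):
        return sum(e - s + 1 for s, e in iv)

    u5a, u3a = a.utrs()
    u5b, u3b = b.utrs()
    return StructureDiff(
        gene_a=a.gene_id, gene_b=b.gene_id,
        conserved=tuple(conserved), only_in_a=tuple(only_a),
        only_in_b=tuple(only_b),
        utr5_lengths=(_utr_len(u5a), _utr_len(u5b)),
        utr3_lengths=(_utr_len(u3a), _utr_len(u3b)),
    )


def write_structure_diff(diff: StructureDiff, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tpos_a\tpos_b\tphase\tlen_a\tlen_b\tlength_ratio\n")
        for d in diff.conserved:
            fh.write(f"conserved\t{d['pos_a']}\t{d['pos_b']}\t{d['phase']}\t"
                     f"{d['len_a']}\t{d['len_b']}\t{d['length_ratio']:.3f}\n")
        for d in diff.only_in_a:
            fh.write(f"gain_in_a\t{d['pos_a']}\t.\t{d['phase']}\t{d['len_a']}\t.\t.\n")
        for d in diff.only_in_b:
            fh.write(f"gain_in_b\t.\t{d['pos_b']}\t{d['phase']}\t.\t{d['len_b']}\t.\n")


# ---------------------------------------------------------------------------
# GFF3 round trip

def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            seqid = m.genomic.id
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            gid = m.gene_id
            attrs = f"ID=gene:{gid}"
            if m.partial:
                attrs += ";partial=true"
            fh.write(f"{seqid}\tclockortho\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n")
            fh.write(f"{seqid}\tclockortho\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID=mrna:{gid};Parent=gene:{gid}\n")
            for s, e in m.exons:
                fh.write(f"{seqid}\tclockortho\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"Parent=mrna:{gid}\n")
            for s, e in m.cds_exons:
                fh.write(f"{seqid}\tclockortho\tCDS\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"Parent=mrna:{gid}\n")
            u5, u3 = m.utrs()
            for s, e in u5:
                fh.write(f"{seqid}\tclockortho\tfive_prime_UTR\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\tParent=mrna:{gid}\n")
            for s, e in u3:
                fh.write(f"{seqid}\tclockortho\tthree_prime_UTR\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\tParent=mrna:{gid}\n")


def read_gff3(path: str | Path,
              genomics: dict[str, SequenceRecord]) -> list[GeneModel]:
    """Read gene models back from GFF3 written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise InvalidInputError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = f
            amap = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = amap["ID"].removeprefix("gene:")
                genes[gid] = {"seqid": seqid, "strand": strand,
                              "partial": amap.get("partial") == "true",
                              "exons": [], "cds": []}
            elif ftype in ("exon", "CDS"):
                gid = amap["Parent"].removeprefix("mrna:")
                key = "exons" if ftype == "exon" else "cds"
                genes[gid][key].append((int(start), int(end)))
    models = []
    for gid, d in genes.items():
        if d["seqid"] not in genomics:
            raise InvalidInputError(f"{gid}: genomic sequence {d['seqid']} not supplied")
        models.append(GeneModel(
            gene_id=gid, genomic=genomics[d["seqid"]], strand=d["strand"],
            exons=tuple(sorted(d["exons"])), cds_exons=tuple(sorted(d["cds"])),
            complete=not d["partial"], partial=d["partial"],
        ))
    return models
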