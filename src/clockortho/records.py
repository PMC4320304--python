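"""Species-tagged sequence records and per-species databases.

A :class:`SequenceRecord` is the atom of every search: a protein, CDS or
genomic sequence carrying its species of origin.  A
:class:`SpeciesDatabase` is the searchable unit — one ordered collection of
records of a single molecule type for a single species, emulating the
per-species gene databases that cross-species reciprocal searches run
against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Seq import Seq
from Bio.SeqIO import parse as _fasta_parse
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio import SeqIO as _SeqIO

__all__ = [
    "InvalidInputError",
    "SequenceRecord",
    "SpeciesDatabase",
    "read_fasta",
    "write_fasta",
    "translate_cds",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_SPECIES_TAG = re.compile(r"\[species=([^\]]+)\]")


class InvalidInputError(ValueError):
    """Raised when a sequence, alphabet or coordinate precondition fails."""


def _alphabet_for(moltype: str) -> frozenset:
    if moltype == "protein":
        return PROTEIN_ALPHABET
    if moltype in ("cds", "genomic"):
        return NUCLEOTIDE_ALPHABET
    raise InvalidInputError(f"unknown moltype: {moltype!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """One species-tagged sequence.

    Parameters
    ----------
    id:
        Unique identifier within its database.
    species:
        Species label (e.g. ``"barley"``).
    moltype:
        One of ``"protein"``, ``"cds"``, ``"genomic"``.
    residues:
        Upper-case sequence over the alphabet of ``moltype``.
    complete:
        For CDS records, whether the sequence is a full-length ORF
        (length divisible by three); partial sequences may violate this.
    pseudogene:
        Flag used by the phylogeny filter; pseudogenes are excluded from
        tree building.
    """

    id: str
    species: str
    moltype: str
    residues: str
    complete: bool = True
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidInputError(f"{self.id}: empty sequence")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        bad = set(residues) - _alphabet_for(self.moltype)
        if bad:
            raise InvalidInputError(
                f"{self.id}: symbols {sorted(bad)} not in {self.moltype} alphabet"
            )
        if self.moltype == "cds" and self.complete and len(residues) % 3:
            raise InvalidInputError(
                f"{self.id}: complete CDS length {len(residues)} not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.residues)


def translate_cds(record: SequenceRecord, *, trim_stop: bool = True) -> SequenceRecord:
    """Translate a CDS record into its protein record (standard code).

    A single trailing stop codon is trimmed by default; internal stops are
    preserved (``*``) so that downstream validation can see them.
    """
    if record.moltype == "protein":
        return record
    if record.moltype != "cds":
        raise InvalidInputError(f"{record.id}: cannot translate moltype {record.moltype}")
    n = len(record.residues) - len(record.residues) % 3
    aa = str(Seq(record.residues[:n]).translate())
    if trim_stop and aa.endswith("*"):
        aa = aa[:-1]
    if not aa:
        raise InvalidInputError(f"{record.id}: translation is empty")
    return SequenceRecord(
        id=record.id,
        species=record.species,
        moltype="protein",
        residues=aa,
        complete=record.complete,
        pseudogene=record.pseudogene,
    )


class SpeciesDatabase:
    """Ordered collection of same-species, same-moltype records.

    Lookup by id is total on contained ids; duplicate ids are rejected.
    """

    def __init__(self, species: str, records: Iterable[SequenceRecord] = ()):
        self.species = species
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.species != self.species:
            raise InvalidInputError(
                f"record {rec.id} is from {rec.species!r}, database is {self.species!r}"
            )
        if self._records and rec.moltype != self.moltype:
            raise InvalidInputError(
                f"record {rec.id} moltype {rec.moltype} != database moltype {self.moltype}"
            )
        if rec.id in self._records:
            raise InvalidInputError(f"duplicate id {rec.id} in {self.species} database")
        self._records[rec.id] = rec

    @property
    def moltype(self) -> str:
        if not self._records:
            return "protein"
        return next(iter(self._records.values())).moltype

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> SequenceRecord:
        return self._records[gene_id]

    def ids(self) -> list[str]:
        return list(self._records)

    @classmethod
    def from_fasta(cls, path: str | Path, species: str | None = None,
                   moltype: str = "protein") -> "SpeciesDatabase":
        recs = read_fasta(path, species=species, moltype=moltype)
        if not recs:
            raise InvalidInputError(f"{path}: no records")
        db = cls(recs[0].species)
        for r in recs:
            db.add(r)
        return db


def read_fasta(path: str | Path, species: str | None = None,
               moltype: str = "protein") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    The species is taken, in order of precedence, from a ``[species=...]``
    tag in the header description, the ``species`` argument, or the file
    stem.
    """
    path = Path(path)
    out: list[SequenceRecord] = []
    for rec in _fasta_parse(str(path), "fasta"):
        m = _SPECIES_TAG.search(rec.description)
        sp = m.group(1) if m else (species or path.stem)
        out.append(SequenceRecord(id=rec.id, species=sp, moltype=moltype,
                                  residues=str(rec.seq)))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, embedding the species as a header tag."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id,
                      description=f"[species={r.species}]")
        for r in records
    ]
    _SeqIO.write(bio, str(Path(path)), "fasta")
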