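"""Sequence and annotation I/O, CDS partitioning and flank extraction.

All genomic coordinates inside this package are 0-based, half-open
``[start, end)``.  Dialect converters (GFF3 is 1-based inclusive, BED is
already half-open) own the off-by-one arithmetic, so no other module
needs to know where an interval came from.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

NUCLEOTIDE_CORE = frozenset("ACGT")
#: IUPAC nucleotide ambiguity codes; kept in place, flagged as ambiguous.
NUCLEOTIDE_AMBIGUOUS = frozenset("NRYSWKMBDHV")
PROTEIN_CORE = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_AMBIGUOUS = frozenset("XBZJUO")

_ALLOWED = {
    NUCLEOTIDE: NUCLEOTIDE_CORE | NUCLEOTIDE_AMBIGUOUS,
    PROTEIN: PROTEIN_CORE | PROTEIN_AMBIGUOUS,
}
_AMBIGUOUS = {NUCLEOTIDE: NUCLEOTIDE_AMBIGUOUS, PROTEIN: PROTEIN_AMBIGUOUS}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Sequence symbols do not fit the declared (or any) alphabet."""


@dataclass(frozen=True)
class SymbolicSequence:
    """A validated symbolic sequence with an explicit alphabet tag.

    Parameters
    ----------
    symbols:
        Uppercase sequence text.
    alphabet:
        ``"nucleotide"`` (A, C, G, T plus IUPAC ambiguity codes) or
        ``"protein"`` (20 standard one-letter codes plus X-type codes).
    name:
        Free-text identifier carried through I/O.
    """

    symbols: str
    alphabet: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in _ALLOWED:
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.symbols) - _ALLOWED[self.alphabet]
        if bad:
            raise AlphabetError(
                f"sequence {self.name!r}: symbols {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def is_ambiguous(self) -> "list[bool]":
        amb = _AMBIGUOUS[self.alphabet]
        return [s in amb for s in self.symbols]

    def has_ambiguity(self) -> bool:
        return bool(set(self.symbols) & _AMBIGUOUS[self.alphabet])

    def slice(self, start: int, end: int, name: str | None = None) -> "SymbolicSequence":
        return replace(
            self,
            symbols=self.symbols[start:end],
            name=name if name is not None else f"{self.name}[{start}:{end}]",
        )

    def reverse_complement(self) -> "SymbolicSequence":
        if self.alphabet != NUCLEOTIDE:
            raise AlphabetError("reverse complement requires a nucleotide sequence")
        if self.has_ambiguity():
            raise AlphabetError("reverse complement of ambiguous symbols is undefined here")
        return replace(
            self,
            symbols=self.symbols[::-1].translate(_COMPLEMENT),
            name=f"{self.name}_rc",
        )


@dataclass(frozen=True)
class FeatureInterval:
    """Half-open genomic interval ``[start, end)`` on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_name!r}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


def infer_alphabet(symbols: str) -> str:
    """Infer the alphabet of an uppercase string, nucleotide-first."""
    chars = set(symbols)
    if chars <= _ALLOWED[NUCLEOTIDE]:
        return NUCLEOTIDE
    if chars <= _ALLOWED[PROTEIN]:
        return PROTEIN
    bad = chars - _ALLOWED[PROTEIN] - _ALLOWED[NUCLEOTIDE]
    raise AlphabetError(f"symbols {sorted(bad)} fit neither alphabet")


def read_fasta(path: str | os.PathLike, alphabet: str | None = None) -> list[SymbolicSequence]:
    """Read a (multi-record) FASTA file into :class:`SymbolicSequence` objects.

    Symbols are uppercased; the alphabet is inferred per record unless
    forced.  Record order is preserved; an empty file yields an empty list.
    """
    sequences: list[SymbolicSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        symbols = str(record.seq).upper()
        try:
            alpha = alphabet if alphabet is not None else infer_alphabet(symbols)
            sequences.append(SymbolicSequence(symbols, alpha, name=record.id))
        except AlphabetError as exc:
            raise AlphabetError(f"record {record.id!r}: {exc}") from exc
    return sequences


def write_fasta(path: str | os.PathLike, sequences: Iterable[SymbolicSequence]) -> None:
    records = [
        SeqRecord(Seq(s.symbols), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def _cds_from_gff3(path: str) -> list[FeatureInterval]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        # GFF3 start is 1-based inclusive; end inclusive == half-open end.
        out.append(
            FeatureInterval(
                seq_name=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
                kind="CDS",
            )
        )
    return out


def _cds_from_bed(path: str) -> list[FeatureInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            out.append(
                FeatureInterval(
                    seq_name=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                    kind="CDS",
                )
            )
    return out


def read_cds_intervals(path: str | os.PathLike, dialect: str) -> list[FeatureInterval]:
    """Read CDS intervals from GFF3 or BED3, normalised to half-open coordinates.

    Only CDS-type features are returned for GFF3; every BED line is taken
    as a CDS interval.  Unknown ``seq_name`` values are allowed here and
    checked at partition time.
    """
    if dialect == "gff3":
        return _cds_from_gff3(str(path))
    if dialect == "bed":
        return _cds_from_bed(str(path))
    raise ValueError(f"unknown annotation dialect {dialect!r} (expected gff3 or bed)")


def interval_to_gff3_coords(interval: FeatureInterval) -> tuple[int, int]:
    """Internal half-open -> GFF3 1-based inclusive (inverse of the reader)."""
    return interval.start + 1, interval.end


def merge_intervals(intervals: Sequence[FeatureInterval]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint (start, end) pairs."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def partition_cds(
    seq: SymbolicSequence, intervals: Sequence[FeatureInterval]
) -> tuple[SymbolicSequence, SymbolicSequence]:
    """Split a sequence into coding and non-coding concatenates.

    The coding part is the concatenation, in genomic order, of the union
    of the CDS intervals; the non-coding part is the complement.  Every
    position lands in exactly one class, so the lengths sum to ``len(seq)``.
    Minus-strand CDS are taken as forward-strand text: the downstream
    combined binary spectrum and the flexibility spectrum are invariant
    under reverse complement, so the choice cannot affect spectra.
    """
    n = len(seq)
    for iv in intervals:
        if iv.seq_name and seq.name and iv.seq_name != seq.name:
            raise ValueError(
                f"interval on {iv.seq_name!r} does not reference sequence {seq.name!r}"
            )
        if iv.end > n:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) out of bounds for length {n}"
            )
    merged = merge_intervals(intervals)
    coding_parts: list[str] = []
    noncoding_parts: list[str] = []
    cursor = 0
    for start, end in merged:
        noncoding_parts.append(seq.symbols[cursor:start])
        coding_parts.append(seq.symbols[start:end])
        cursor = end
    noncoding_parts.append(seq.symbols[cursor:])
    coding = replace(seq, symbols="".join(coding_parts), name=f"{seq.name}_coding")
    noncoding = replace(seq, symbols="".join(noncoding_parts), name=f"{seq.name}_noncoding")
    return coding, noncoding


def extract_flanks(
    seq: SymbolicSequence, flank: int = 4000
) -> tuple[SymbolicSequence, SymbolicSequence]:
    """First and last ``flank`` symbols (clamped to the sequence length).

    The 4000 nt default targets the chromosome extremities where the
    tandem-repeat blocks responsible for the 1/21 comb are located.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    k = min(flank, len(seq))
    head = replace(seq, symbols=seq.symbols[:k], name=f"{seq.name}_head")
    tail = replace(seq, symbols=seq.symbols[len(seq) - k :], name=f"{seq.name}_tail")
    return head, tail
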