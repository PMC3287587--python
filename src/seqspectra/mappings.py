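"""Symbolic-to-numeric mappings.

Two families of encodings are provided:

* **Binary indicators** (multichannel / Voss mapping): one 0/1 series per
  alphabet symbol, ``u[alpha, n] = 1`` iff the symbol at position ``n`` is
  ``alpha``.  Four channels for nucleotides, twenty for proteins.  This
  encoding turns an isolated symbol repeating with period ``p`` into a
  spike train, whose spectrum is itself a frequency comb — the origin of
  the mapping-induced overtone aliases this package diagnoses.
* **Flexibility profile**: each nearest-neighbour dimer step is replaced
  by its elastic constant (eV/nm^2), producing one smooth-ish numeric
  series of length N-1 in which isolated symbols no longer create spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .seqio import NUCLEOTIDE, PROTEIN, AlphabetError, SymbolicSequence

NUCLEOTIDE_CHANNELS: tuple[str, ...] = ("A", "C", "G", "T")
PROTEIN_CHANNELS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class IndicatorChannels:
    """Per-symbol binary indicator series.

    ``data`` has shape ``(n_channels, N)`` with values in {0, 1}; row order
    follows ``labels``.  Positions holding an ambiguous symbol have an
    all-zero column, so unambiguous columns sum to 1 and ambiguous ones to 0.
    """

    labels: tuple[str, ...]
    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, N) matching labels")

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def decode(self) -> str:
        """Recover the symbols (ambiguous positions come back as 'N'/'X')."""
        placeholder = "N" if self.labels == NUCLEOTIDE_CHANNELS else "X"
        out = np.full(self.n, placeholder, dtype="<U1")
        for label, row in zip(self.labels, self.data):
            out[row.astype(bool)] = label
        return "".join(out)


def _encode(seq: SymbolicSequence, labels: tuple[str, ...]) -> IndicatorChannels:
    arr = np.frombuffer(seq.symbols.encode("ascii"), dtype="S1")
    data = np.zeros((len(labels), len(seq)), dtype=np.uint8)
    for i, label in enumerate(labels):
        data[i] = arr == label.encode("ascii")
    return IndicatorChannels(labels=labels, data=data, name=seq.name)


def encode_binary(seq: SymbolicSequence) -> IndicatorChannels:
    """Four-channel (A, C, G, T) binary indicator encoding of a nucleotide sequence.

    Ambiguity codes yield all-zero columns, preserving positions and length.
    """
    if seq.alphabet != NUCLEOTIDE:
        raise AlphabetError("encode_binary requires a nucleotide sequence")
    return _encode(seq, NUCLEOTIDE_CHANNELS)


def encode_protein_binary(seq: SymbolicSequence) -> IndicatorChannels:
    """Twenty-channel binary indicator encoding of a protein sequence.

    With 20 channels an amino acid is far more likely to appear isolated
    within its repeat unit than a nucleotide is, which is why protein
    spectra computed this way are especially prone to comb aliases.
    """
    if seq.alphabet != PROTEIN:
        raise AlphabetError("encode_protein_binary requires a protein sequence")
    return _encode(seq, PROTEIN_CHANNELS)


# ---------------------------------------------------------------------------
# Flexibility mapping


@dataclass(frozen=True)
class FlexibilityTable:
    """Elastic constants for all 16 nearest-neighbour dimers.

    Built from the 10 unique entries of the shipped resource; the six
    dimers absent from the unique set (TpT, GpT, CpT, TpG, TpC, GpG) take
    the value of their reverse complement, the standard nearest-neighbour
    uniqueness convention under strand symmetry.
    """

    values: dict  # dimer (e.g. "AT") -> k in eV/nm^2

    def __getitem__(self, dimer: str) -> float:
        return self.values[dimer]


def _reverse_complement_dimer(dimer: str) -> str:
    return _COMPLEMENT[dimer[1]] + _COMPLEMENT[dimer[0]]


def load_flexibility_table(path: str | None = None) -> FlexibilityTable:
    """Load a dimer -> elastic constant table (default: the shipped one).

    The resource format is plain text, ``dimer<TAB>value`` with ``#``
    comments, so alternative dinucleotide property tables can be swapped in.
    """
    if path is None:
        text = (
            resources.files("seqspectra.data")
            .joinpath("dimer_flexibility.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    unique: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dimer, value = line.split("\t")
        unique[dimer] = float(value)
    full = dict(unique)
    for a in "ACGT":
        for b in "ACGT":
            dimer = a + b
            if dimer not in full:
                full[dimer] = unique[_reverse_complement_dimer(dimer)]
    return FlexibilityTable(values=full)


_DEFAULT_TABLE: FlexibilityTable | None = None


def default_flexibility_table() -> FlexibilityTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_flexibility_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class FlexibilityProfile:
    """Numeric series of dimer elastic constants, length M = N - 1.

    Masked (ambiguity-adjacent) steps are NaN under the ``mask`` policy.
    """

    values: np.ndarray
    name: str = ""

    @property
    def m(self) -> int:
        return len(self.values)


def encode_flexibility(
    seq: SymbolicSequence,
    table: FlexibilityTable | None = None,
    policy: str = "mask",
) -> FlexibilityProfile:
    """Map each nearest-neighbour step to its elastic constant.

    ``values[m]`` is the constant of the dimer (symbol m, symbol m+1), so a
    sequence of length N yields M = N - 1 values.  Steps touching an
    ambiguous symbol are NaN-masked by default (``policy="mask"``); with
    ``policy="strict"`` they raise instead.  Spectra refuse NaN, so masked
    profiles must be split with :func:`split_on_ambiguity` first.
    """
    if seq.alphabet != NUCLEOTIDE:
        raise AlphabetError("encode_flexibility requires a nucleotide sequence")
    if policy not in {"mask", "strict"}:
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    if table is None:
        table = default_flexibility_table()
    n = len(seq)
    values = np.empty(max(n - 1, 0), dtype=float)
    ambiguous = seq.is_ambiguous()
    for m in range(n - 1):
        if ambiguous[m] or ambiguous[m + 1]:
            if policy == "strict":
                raise ValueError(
                    f"ambiguous symbol inside dimer at position {m} of {seq.name!r}"
                )
            values[m] = np.nan
        else:
            values[m] = table[seq.symbols[m : m + 2]]
    return FlexibilityProfile(values=values, name=seq.name)


def split_on_ambiguity(seq: SymbolicSequence) -> list[tuple[int, SymbolicSequence]]:
    """Maximal unambiguous segments as (offset, sequence) pairs."""
    segments: list[tuple[int, SymbolicSequence]] = []
    ambiguous = seq.is_ambiguous()
    start: int | None = None
    for i in range(len(seq) + 1):
        inside = i < len(seq) and not ambiguous[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            segments.append(
                (start, replace(seq, symbols=seq.symbols[start:i],
                                name=f"{seq.name}_{start}"))
            )
            start = None
    return segments
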