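"""Synthetic sequence generators.

Everything the pipeline needs can be generated without downloads:

* rectangle-train repeat sequences (R copies of a p-nt unit with m
  consecutive copies of one symbol) — the construction that demonstrates
  how comb overtones emerge as the marked run shrinks to a spike;
* CA_n microsatellite units (period p = n + 1), the minimal units for
  which overtones already appear;
* tandem arrays of the consensus units found at *P. falciparum*
  chromosome extremities (shipped as a FASTA resource, stored exactly as
  printed including 20 nt units flagged ``short_unit`` despite the
  nominal 21 nt periodicity);
* AT-rich i.i.d. background genomes with repeat blocks planted near the
  extremities, emulating the telomere-proximal localization of the real
  repeats, for windowed-track recovery tests.

All randomness is seeded; there are no unseeded entry points.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio import NUCLEOTIDE, FeatureInterval, SymbolicSequence


@dataclass(frozen=True)
class RepeatUnitSpec:
    """R repeats of a p-nt unit: m run symbols then p - m fill symbols."""

    unit_length: int
    run_symbol: str
    run_length: int
    fill_symbol: str
    repeats: int

    def __post_init__(self) -> None:
        if not 1 <= self.run_length <= self.unit_length:
            raise ValueError("need 1 <= run_length <= unit_length")
        if self.repeats < 1:
            raise ValueError("need repeats >= 1")
        for sym in (self.run_symbol, self.fill_symbol):
            if sym not in "ACGT" or len(sym) != 1:
                raise ValueError(f"symbols must be single nucleotides, got {sym!r}")
        if self.run_symbol == self.fill_symbol:
            raise ValueError("run and fill symbols must differ")


def generate_repeat_sequence(spec: RepeatUnitSpec) -> SymbolicSequence:
    """Concatenate R copies of ``run_symbol * m + fill_symbol * (p - m)``."""
    unit = spec.run_symbol * spec.run_length + spec.fill_symbol * (
        spec.unit_length - spec.run_length
    )
    return SymbolicSequence(
        unit * spec.repeats,
        NUCLEOTIDE,
        name=f"rect_p{spec.unit_length}_m{spec.run_length}_R{spec.repeats}",
    )


def generate_ca_n(n: int, repeats: int) -> SymbolicSequence:
    """R copies of C followed by n adenines (period p = n + 1)."""
    if n < 1 or repeats < 1:
        raise ValueError("need n >= 1 and repeats >= 1")
    return SymbolicSequence(("C" + "A" * n) * repeats, NUCLEOTIDE, name=f"CA{n}_R{repeats}")


def repeated_consensus(consensus: SymbolicSequence, repeats: int) -> SymbolicSequence:
    """Tandem array of R copies of a consensus unit."""
    if len(consensus) == 0:
        raise ValueError("consensus must be non-empty")
    if repeats < 1:
        raise ValueError("need repeats >= 1")
    return SymbolicSequence(
        consensus.symbols * repeats,
        consensus.alphabet,
        name=f"{consensus.name}_x{repeats}",
    )


def consensus_units() -> dict:
    """Shipped telomere-proximal consensus repeat units, keyed by record id.

    Record descriptions carry the relative chromosome position and the
    repetition count reported by external tandem-repeat finding on the
    real chromosomes; the counts are metadata only, never recomputed here.
    """
    from Bio import SeqIO

    units: dict[str, SymbolicSequence] = {}
    path = resources.files("seqspectra.data").joinpath("consensus_units.fasta")
    with resources.as_file(path) as fasta:
        for record in SeqIO.parse(str(fasta), "fasta"):
            units[record.id] = SymbolicSequence(
                str(record.seq).upper(), NUCLEOTIDE, name=record.id
            )
    return units


@dataclass(frozen=True)
class PlantedBlock:
    """One tandem array to overwrite into the background at ``start``."""

    unit: str
    repeats: int
    start: int

    @property
    def length(self) -> int:
        return len(self.unit) * self.repeats


@dataclass(frozen=True)
class PlantedGenomeSpec:
    """AT-rich i.i.d. background with non-overlapping planted repeat blocks.

    The background draws A and T each with probability ``at_fraction / 2``
    and C, G each with ``(1 - at_fraction) / 2``; 0.8 matches the extreme
    AT richness of the *P. falciparum* genome.
    """

    length: int
    blocks: tuple = ()
    at_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must be in [0, 1]")
        spans = sorted((b.start, b.start + b.length) for b in self.blocks)
        for (s, e), nxt in zip(spans, spans[1:] + [None]):
            if s < 0 or e > self.length:
                raise ValueError(f"planted block [{s}, {e}) exceeds genome length")
            if nxt is not None and e > nxt[0]:
                raise ValueError("planted blocks overlap")


def generate_planted_genome(
    spec: PlantedGenomeSpec,
) -> tuple[SymbolicSequence, list[FeatureInterval]]:
    """Draw the background, overwrite the blocks, return sequence + truth.

    Deterministic for a given spec (the seed lives in the spec); the truth
    intervals delimit each planted block for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    at = spec.at_fraction
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    symbols = rng.choice(np.array(list("ACGT")), size=spec.length, p=probs)
    truth: list[FeatureInterval] = []
    name = f"planted_L{spec.length}_seed{spec.seed}"
    for block in spec.blocks:
        text = block.unit * block.repeats
        symbols[block.start : block.start + len(text)] = list(text)
        truth.append(
            FeatureInterval(
                seq_name=name,
                start=block.start,
                end=block.start + len(text),
                kind="other",
            )
        )
    return SymbolicSequence("".join(symbols), NUCLEOTIDE, name=name), truth
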