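"""Genetic-code tables, nucleotide/codon algebra and codon-usage extraction.

The standard bacterial genetic code (NCBI translation table 11, whose
codon-to-amino-acid assignments coincide with table 1) partitions the 64
codons into 61 sense codons and the 3 stops {TAA, TAG, TGA}.  All matrices
in this package index codons in fixed lexicographic order (AAA, AAC, ...,
TTT), with the stops removed for 61-state objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: unordered transition pairs (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = {frozenset("AG"), frozenset("CT")}

STOP_LABEL = "*"

CODONS64: tuple[str, ...] = tuple(
    "".join(p) for p in product(NUCLEOTIDES, repeat=3)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS64)}

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS64 if c not in STOP_CODONS
)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


class InvalidCodonError(ValueError):
    """Raised for triplets containing symbols outside {A, C, G, T}."""


def _check_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(n not in COMPLEMENT for n in codon):
        raise InvalidCodonError(f"not a valid DNA codon: {codon!r}")
    return codon


def complement(nuc: str) -> str:
    """Watson-Crick complement of a single nucleotide."""
    try:
        return COMPLEMENT[nuc]
    except KeyError:
        raise InvalidCodonError(f"not a valid nucleotide: {nuc!r}") from None


def reverse_complement(codon: str) -> str:
    """Positionwise complement of the reversed triplet (an involution)."""
    codon = _check_codon(codon)
    return "".join(COMPLEMENT[n] for n in reversed(codon))


def is_transition(a: str, b: str) -> bool:
    """True if the substitution a->b is a transition (A<->G or C<->T)."""
    return frozenset((a, b)) in TRANSITIONS


def single_nucleotide_difference(x: str, y: str) -> int | None:
    """Position (0-2) of the single differing site, or None if the codons
    are identical or differ at more than one position."""
    diffs = [i for i in range(3) if x[i] != y[i]]
    return diffs[0] if len(diffs) == 1 else None


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid mapping with stop set.

    The default is the standard/bacterial code; ``translate`` returns a
    one-letter amino-acid symbol or ``"*"`` for stops.
    """

    table_id: int = 11
    forward: Mapping[str, str] = field(default_factory=dict)
    stops: frozenset[str] = frozenset(STOP_CODONS)

    def __post_init__(self):
        if not self.forward:
            ncbi = CodonTable.unambiguous_dna_by_id[self.table_id]
            object.__setattr__(self, "forward", dict(ncbi.forward_table))
            object.__setattr__(self, "stops", frozenset(ncbi.stop_codons))

    def translate(self, codon: str) -> str:
        codon = _check_codon(codon)
        if codon in self.stops:
            return STOP_LABEL
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return _check_codon(codon) in self.stops

    @property
    def amino_acids(self) -> tuple[str, ...]:
        """The 20 amino-acid symbols, sorted."""
        return tuple(sorted(set(self.forward.values())))

    @property
    def symbols_with_stop(self) -> tuple[str, ...]:
        """The extended alphabet: 20 amino acids plus the stop label."""
        return self.amino_acids + (STOP_LABEL,)

    def synonymous(self, x: str, y: str) -> bool:
        """True if codons x and y encode the same symbol (stop counts as a
        symbol of its own)."""
        return self.translate(x) == self.translate(y)


STANDARD_CODE = GeneticCode()


@dataclass(frozen=True)
class CodonUsage:
    """Probability vector over the 61 sense codons (lexicographic order).

    No mass on stop codons by construction; entries are >= 0 and sum to 1.
    """

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (61,):
            raise ValueError(f"expected 61 frequencies, got shape {f.shape}")
        if np.any(f < 0):
            raise ValueError("codon frequencies must be non-negative")
        s = f.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"codon frequencies must sum to 1 (got {s})")
        object.__setattr__(self, "freqs", f / s)

    def __getitem__(self, codon: str) -> float:
        return float(self.freqs[SENSE_INDEX[_check_codon(codon)]])

    @property
    def vector64(self) -> np.ndarray:
        """Frequencies embedded in the full 64-codon order (stops get 0)."""
        v = np.zeros(64)
        for c, i in SENSE_INDEX.items():
            v[CODON_INDEX[c]] = self.freqs[i]
        return v

    @classmethod
    def uniform(cls) -> "CodonUsage":
        return cls(np.full(61, 1.0 / 61.0))

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "CodonUsage":
        v = np.zeros(61)
        for codon, n in counts.items():
            codon = _check_codon(codon)
            if codon in STOP_CODONS:
                continue
            v[SENSE_INDEX[codon]] += n
        total = v.sum()
        if total <= 0:
            raise ValueError("no sense codons counted")
        return cls(v / total)

    def with_floor(self, eps: float = 1e-8) -> "CodonUsage":
        """Replace zero entries by ``eps`` and renormalize (numerical
        stability for downstream log/inverse operations)."""
        v = np.maximum(self.freqs, eps)
        return CodonUsage(v / v.sum())

    # -- plain-text round trip -------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tfrequency\n")
            for c, f in zip(SENSE_CODONS, self.freqs):
                fh.write(f"{c}\t{f:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsage":
        counts: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("codon"):
                fh.seek(0)
            for line in fh:
                if not line.strip():
                    continue
                codon, freq = line.split("\t")
                counts[codon.strip()] = float(freq)
        return cls.from_counts(counts)


def count_cds_codons(
    sequences: Iterable[str], code: GeneticCode = STANDARD_CODE
) -> dict[str, int]:
    """Count in-frame codons over coding sequences.

    The initiation codon is included; stop codons and codons containing
    ambiguity symbols (N etc.) are excluded.  A CDS whose length is not a
    multiple of 3 triggers a warning and its trailing bases are dropped.
    """
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = str(seq).upper().replace("U", "T")
        if len(seq) % 3:
            warnings.warn(
                f"CDS length {len(seq)} not divisible by 3; "
                "truncating trailing bases",
                stacklevel=2,
            )
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(n not in COMPLEMENT for n in codon):
                continue  # skip ambiguous codons, no imputation
            if codon in code.stops:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_usage_from_cds(
    sequences: Iterable[str], code: GeneticCode = STANDARD_CODE
) -> CodonUsage:
    """Codon usage from strand-corrected CDS nucleotide sequences."""
    counts = count_cds_codons(sequences, code)
    if not counts:
        raise ValueError("no codons counted: empty CDS input")
    return CodonUsage.from_counts(counts)


def _genbank_cds_sequences(path: str | Path) -> Iterable[str]:
    for record in SeqIO.parse(str(path), "genbank"):
        for feature in record.features:
            if feature.type != "CDS":
                continue
            yield str(feature.extract(record.seq))


def codon_usage_from_genbank(
    path: str | Path, code: GeneticCode = STANDARD_CODE
) -> CodonUsage:
    """Codon usage over all annotated CDS features of a GenBank record.

    Features are extracted strand-aware (Biopython handles the
    1-based-inclusive to 0-based-half-open conversion and reverse
    complementation of minus-strand features).
    """
    return codon_usage_from_cds(_genbank_cds_sequences(path), code)


def codon_usage_from_fasta(
    path: str | Path, code: GeneticCode = STANDARD_CODE
) -> CodonUsage:
    """Codon usage from a multi-FASTA of pre-extracted CDS sequences."""
    seqs = (str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
    return codon_usage_from_cds(seqs, code)


def genome_summary(path: str | Path, fmt: str = "genbank") -> dict[str, float]:
    """Total length (bp) and GC content (%) of a genome file."""
    length = 0
    gc = 0
    for record in SeqIO.parse(str(path), fmt):
        s = str(record.seq).upper()
        length += len(s)
        gc += s.count("G") + s.count("C")
    if length == 0:
        raise ValueError(f"no sequence found in {path}")
    return {"length_bp": length, "gc_percent": 100.0 * gc / length}
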