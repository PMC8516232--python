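"""Genome sequence input/output and basic composition statistics.

Sequences are held as uppercase DNA over the alphabet ``ACGTN``.  Lowercase
input is uppercased and any IUPAC ambiguity code other than ``N`` (R, Y, S,
W, K, M, B, D, H, V) is mapped to ``N``; k-mer windows containing ``N`` are
skipped downstream, so this matches the behaviour of standard k-mer counting
tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "FastaFormatError",
    "AlphabetError",
    "read_fasta",
    "write_fasta",
    "gc_content",
]

_VALID = set("ACGTN")
_IUPAC_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")

# fraction of characters outside the IUPAC nucleotide alphabet above which a
# record is assumed not to be DNA (e.g. protein FASTA)
_MAX_INVALID_FRACTION = 0.10


class FastaFormatError(ValueError):
    """Raised for empty or unparsable FASTA input."""


class AlphabetError(ValueError):
    """Raised when input does not look like nucleotide sequence."""


@dataclass
class GenomeRecord:
    """A genome as an ordered collection of disjoint DNA sequences.

    Every FASTA record (chromosome, plasmid, contig) is kept as one disjoint
    sequence of the same genome; the sliding k-mer window never crosses a
    sequence boundary.
    """

    genome_id: str
    sequences: list[str]
    sequence_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FastaFormatError("a genome needs at least one sequence")
        if not self.sequence_ids:
            self.sequence_ids = [
                f"{self.genome_id}_{i + 1}" for i in range(len(self.sequences))
            ]
        if len(self.sequence_ids) != len(self.sequences):
            raise ValueError("sequence_ids and sequences lengths differ")
        for seq in self.sequences:
            if not seq:
                raise FastaFormatError("empty sequence record")
            bad = set(seq) - _VALID
            if bad:
                raise AlphabetError(f"non-ACGTN characters after normalization: {sorted(bad)}")

    @property
    def total_length(self) -> int:
        """Summed length L of all sequences (bp), Ns included."""
        return sum(len(s) for s in self.sequences)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def gc_content(self) -> float:
        return gc_content(self)


def normalize_sequence(raw: str) -> str:
    """Uppercase and map non-ACGTN IUPAC codes to N.

    Raises :class:`AlphabetError` if more than 10% of characters are not
    IUPAC nucleotide codes at all.
    """
    up = raw.upper().replace("-", "").replace(".", "")
    if not up:
        return ""
    norm = up.translate(_IUPAC_TO_N)
    invalid = sum(1 for c in norm if c not in _VALID)
    if invalid > _MAX_INVALID_FRACTION * len(norm):
        raise AlphabetError(
            f"{invalid}/{len(norm)} characters outside the nucleotide alphabet; "
            "input does not look like DNA"
        )
    # residual oddballs (rare) are masked like ambiguity codes
    if invalid:
        norm = "".join(c if c in _VALID else "N" for c in norm)
    return norm


def read_fasta(path: str | os.PathLike, genome_id: str | None = None) -> GenomeRecord:
    """Read a (multi-record) FASTA file into a :class:`GenomeRecord`.

    Parameters
    ----------
    path:
        FASTA file, wrapped or unwrapped.
    genome_id:
        Identifier for the genome; defaults to the file basename without
        extension.  Pass the first record id explicitly if preferred.
    """
    seqs: list[str] = []
    ids: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        norm = normalize_sequence(str(rec.seq))
        if not norm:
            continue
        seqs.append(norm)
        ids.append(rec.id)
    if not seqs:
        raise FastaFormatError(f"no parsable FASTA record with sequence in {path!r}")
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(path)))[0]
    return GenomeRecord(genome_id=genome_id, sequences=seqs, sequence_ids=ids)


def write_fasta(record: GenomeRecord, path: str | os.PathLike, width: int = 60) -> None:
    """Write a genome back to FASTA with canonical 60-column wrapping."""
    with open(path, "w") as fh:
        for sid, seq in zip(record.sequence_ids, record.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gc_content(record: GenomeRecord | str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); Ns are excluded from the denominator.

    Invariant under reversal and complementation of the sequence.
    """
    if isinstance(record, GenomeRecord):
        seqs = record.sequences
    else:
        seqs = [record]
    gc = 0
    acgt = 0
    for seq in seqs:
        gc += seq.count("G") + seq.count("C")
        acgt += len(seq) - seq.count("N")
    if acgt == 0:
        raise AlphabetError("all-N sequence: GC content undefined")
    return gc / acgt


def reverse_complement(seq: str) -> str:
    """Reverse complement over ACGTN (N maps to N)."""
    return str(Seq(seq).reverse_complement())
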