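"""Synthetic genome generation with controlled taxonomic structure.

Two kinds of inputs are produced: (a) i.i.d. random sequences of given
length and GC content, used to calibrate the random-coverage expectation,
and (b) clades of genomes diverged from a common ancestral sequence by
independent per-site substitution at rank-dependent rates, together with
the matching ranked taxonomy table and the true tree.

Divergence is substitution-only by default (no indels), which keeps the
Poisson relationship between k-mer Jaccard similarity and nucleotide
divergence exact and makes the generated clades a clean ground truth for
the comparison, clustering and LCA analyses.  Optional perturbations mimic
two well-known confounders of k-mer similarity: horizontal transfer of a
contiguous segment between distant genomes (raises similarity) and
endosymbiont-style genome reduction (lowers similarity to close relatives).

Every operation takes an explicit ``numpy.random.Generator`` (or a seed in
``CladeSpec``); generation is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import dendropy

from .lca_taxonomy import RANKS, TaxonomyTable
from .sequence_io import GenomeRecord
from .tree_analysis import from_newick

__all__ = [
    "random_sequence",
    "mutate",
    "CladeSpec",
    "simulate_clade",
    "apply_hgt",
    "apply_reduction",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        raise ValueError("mutate/simulate operate on N-free ACGT sequences")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_sequence(length: int, gc: float = 0.5, rng: np.random.Generator | None = None) -> str:
    """An i.i.d. random DNA sequence with P(G) = P(C) = gc/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)
    return _decode(codes)


def mutate(sequence: str, p_sub: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution to a uniformly chosen *different*
    base with probability ``p_sub``; length is preserved."""
    if not (0.0 <= p_sub < 0.75):
        raise ValueError("p_sub must be in [0, 0.75)")
    if p_sub == 0.0:
        return sequence
    codes = _encode(sequence)
    hit = rng.random(codes.size) < p_sub
    n_hit = int(hit.sum())
    if n_hit:
        # adding 1..3 mod 4 always lands on a different base
        offsets = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        codes[hit] = (codes[hit] + offsets) % 4
    return _decode(codes)


# ---------------------------------------------------------------------- #
# clade simulation
# ---------------------------------------------------------------------- #
# Default per-branch substitution probabilities by rank.  Chosen so that the
# implied pairwise ANI bands are realistic and unambiguous: strains of one
# species ~99% ANI, congeneric species ~92%, cross-genus ~80%, and
# cross-superkingdom pairs share only a residual trace of k-mers at k = 21.
DEFAULT_DIVERGENCE: dict[str, float] = {
    "superkingdom": 0.15,
    "phylum": 0.10,
    "class": 0.08,
    "order": 0.06,
    "family": 0.05,
    "genus": 0.05,
    "species": 0.035,
    "strain": 0.005,
}

_RANK_PREFIX = {
    "superkingdom": "SK",
    "phylum": "PH",
    "class": "CL",
    "order": "OR",
    "family": "FA",
    "genus": "GEN",
    "species": "SP",
}


@dataclass
class CladeSpec:
    """Specification of a simulated clade.

    ``ranks`` lists the taxonomic levels actually simulated, coarse to fine
    (any subset of superkingdom ... species, in rank order); below the last
    rank, ``branching["strain"]`` genomes are emitted per terminal taxon.
    ``divergence`` gives the per-site substitution probability applied on
    each branch at that level.
    """

    ranks: tuple[str, ...] = ("superkingdom", "genus", "species")
    branching: Mapping[str, int] = field(
        default_factory=lambda: {"superkingdom": 2, "genus": 2, "species": 2, "strain": 2}
    )
    divergence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    root_length: int = 100_000
    gc: float = 0.5
    hgt_events: Sequence[tuple[str, str, float]] = ()        # (recipient, donor, fraction)
    reduction_events: Sequence[tuple[str, float]] = ()       # (genome_id, fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        order = {r: i for i, r in enumerate(reversed(RANKS))}  # superkingdom first
        if not self.ranks:
            raise ValueError("need at least one rank")
        for r in self.ranks:
            if r not in order:
                raise ValueError(f"unknown rank {r!r}")
        if list(self.ranks) != sorted(self.ranks, key=order.__getitem__):
            raise ValueError("ranks must be ordered coarse to fine")
        levels = [*self.ranks, "strain"]
        for level in levels:
            if level not in self.branching:
                raise ValueError(f"branching missing for level {level!r}")
            if int(self.branching[level]) < 1:
                raise ValueError(f"branching must be >= 1 at {level!r}")
            if level not in self.divergence:
                raise ValueError(f"divergence missing for level {level!r}")
            p = float(self.divergence[level])
            if not (0.0 <= p < 0.75):
                raise ValueError(f"divergence at {level!r} must be in [0, 0.75)")

    @property
    def n_genomes(self) -> int:
        n = 1
        for level in (*self.ranks, "strain"):
            n *= int(self.branching[level])
        return n


def simulate_clade(spec: CladeSpec) -> tuple[list[GenomeRecord], TaxonomyTable, dendropy.Tree]:
    """Simulate a clade of genomes, its taxonomy table and true tree.

    A root sequence is generated, then each level of the spec branches every
    current lineage ``branching[level]`` ways, substituting each branch copy
    at the level's divergence.  Leaves become genomes; each carries the
    lineage labels generated along its path.  The returned tree has the
    simulated taxa as internal node names and the genome ids as leaves.
    """
    rng = np.random.default_rng(spec.seed)
    root = random_sequence(spec.root_length, spec.gc, rng)
    levels = [*spec.ranks, "strain"]

    # each entry: (sequence, lineage dict, newick fragment children list)
    nodes: list[tuple[str, dict[str, str]]] = [(root, {})]
    counters = {level: 0 for level in levels}
    for level in levels:
        b = int(spec.branching[level])
        p = float(spec.divergence[level])
        nxt: list[tuple[str, dict[str, str]]] = []
        for seq, lineage in nodes:
            for _ in range(b):
                counters[level] += 1
                child_lineage = dict(lineage)
                if level != "strain":
                    child_lineage[level] = f"{_RANK_PREFIX[level]}{counters[level]:02d}"
                else:
                    child_lineage["strain"] = f"g{counters[level]:03d}"
                nxt.append((mutate(seq, p, rng), child_lineage))
        nodes = nxt

    records: list[GenomeRecord] = []
    rows = []
    for seq, lineage in nodes:
        gid = lineage["strain"]
        records.append(GenomeRecord(genome_id=gid, sequences=[seq], sequence_ids=[gid]))
        row = {"genome_id": gid}
        for rank in RANKS:
            row[rank] = lineage.get(rank, pd.NA)
        rows.append(row)
    taxonomy = TaxonomyTable(pd.DataFrame(rows))

    by_id = {r.genome_id: r for r in records}
    for gid, fraction in spec.reduction_events:
        by_id[gid] = apply_reduction(by_id[gid], fraction, rng)
    for recipient, donor, fraction in spec.hgt_events:
        by_id[recipient] = apply_hgt(by_id[recipient], by_id[donor], fraction, rng)
    records = [by_id[r.genome_id] for r in records]

    truth = _truth_tree(taxonomy, spec.ranks)
    return records, taxonomy, truth


def _truth_tree(taxonomy: TaxonomyTable, ranks: tuple[str, ...]) -> dendropy.Tree:
    df = taxonomy.table

    def build(sub: pd.DataFrame, level: int) -> str:
        if level == len(ranks):
            return ",".join(sub["genome_id"])
        rank = ranks[level]
        parts = [
            f"({build(g, level + 1)}){taxon}" if len(g) > 1 else build(g, level + 1)
            for taxon, g in sub.groupby(rank, sort=True)
        ]
        return ",".join(parts)

    return from_newick(f"({build(df, 0)})root;")


def apply_hgt(
    recipient: GenomeRecord,
    donor: GenomeRecord,
    fraction: float,
    rng: np.random.Generator,
) -> GenomeRecord:
    """Horizontal transfer: a contiguous donor segment of ``fraction`` of the
    recipient's length replaces a random recipient segment."""
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    seg_len = int(round(fraction * recipient.total_length))
    if seg_len < 1:
        raise ValueError("fraction too small: empty segment")
    donor_seqs = [s for s in donor.sequences if len(s) >= seg_len]
    if not donor_seqs:
        raise ValueError("donor has no sequence long enough for the segment")
    dseq = donor_seqs[int(rng.integers(0, len(donor_seqs)))]
    dstart = int(rng.integers(0, len(dseq) - seg_len + 1))
    segment = dseq[dstart : dstart + seg_len]

    targets = [i for i, s in enumerate(recipient.sequences) if len(s) >= seg_len]
    if not targets:
        raise ValueError("recipient has no sequence long enough for the segment")
    ti = targets[int(rng.integers(0, len(targets)))]
    rseq = recipient.sequences[ti]
    rstart = int(rng.integers(0, len(rseq) - seg_len + 1))
    new_seq = rseq[:rstart] + segment + rseq[rstart + seg_len :]
    seqs = list(recipient.sequences)
    seqs[ti] = new_seq
    return GenomeRecord(
        genome_id=recipient.genome_id,
        sequences=seqs,
        sequence_ids=list(recipient.sequence_ids),
    )


def apply_reduction(record: GenomeRecord, fraction: float, rng: np.random.Generator) -> GenomeRecord:
    """Genome reduction: delete a contiguous segment of ``fraction`` of the
    genome length from one sequence (massive gene loss, endosymbiont-style)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    cut = int(round(fraction * record.total_length))
    targets = [i for i, s in enumerate(record.sequences) if len(s) > cut]
    if not targets:
        raise ValueError("no sequence long enough to absorb the deletion")
    ti = targets[int(rng.integers(0, len(targets)))]
    seq = record.sequences[ti]
    start = int(rng.integers(0, len(seq) - cut + 1))
    seqs = list(record.sequences)
    seqs[ti] = seq[:start] + seq[start + cut :]
    return GenomeRecord(
        genome_id=record.genome_id,
        sequences=seqs,
        sequence_ids=list(record.sequence_ids),
    )
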