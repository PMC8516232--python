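"""Pairwise Jaccard similarity of canonical k-mer sets and the Jaccard <->
ANI conversion.

The Jaccard similarity JS(A, B) = |A ∩ B| / |A ∪ B| of two genomes' k-mer
sets estimates their average nucleotide identity (ANI) under the Poisson
substitution model:

    ANI / 100 = 1 + (1/k) * ln( 2 JS / (1 + JS) )

Pairs sharing zero k-mers have undefined ANI (log of zero); they are carried
through as NaN sentinels and counted, never clamped, so that log-domain
analyses can exclude them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kmer_engine import KmerSet, intersection_cardinality

__all__ = [
    "jaccard",
    "ani_from_jaccard",
    "jaccard_from_ani",
    "SimilarityMatrix",
    "pairwise_matrix",
]


def jaccard(a: KmerSet, b: KmerSet) -> float:
    """|A ∩ B| / |A ∪ B| over canonical k-mer sets (exact, no sketching)."""
    if a.N_D == 0 and b.N_D == 0:
        raise ValueError("Jaccard similarity undefined: both k-mer sets are empty")
    inter = intersection_cardinality(a, b)
    union_size = a.N_D + b.N_D - inter
    return inter / union_size


def ani_from_jaccard(js: float, k: int) -> float:
    """Estimated ANI (percent) from a Jaccard similarity at k-mer length k.

    Strictly increasing in JS and equal to 100 at JS = 1.  JS = 0 returns
    NaN (the undefined-similarity sentinel).
    """
    if not (0.0 <= js <= 1.0):
        raise ValueError(f"Jaccard similarity must be in [0, 1], got {js}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if js == 0.0:
        return float("nan")
    return 100.0 * (1.0 + math.log(2.0 * js / (1.0 + js)) / k)


def jaccard_from_ani(ani: float, k: int) -> float:
    """Exact inverse of :func:`ani_from_jaccard`.

    With t = exp(k * (ANI/100 - 1)), JS = t / (2 - t).  Round-trips with the
    forward conversion to at least 10 decimals.
    """
    if ani > 100.0:
        raise ValueError("ANI cannot exceed 100")
    if k < 1:
        raise ValueError("k must be >= 1")
    t = math.exp(k * (ani / 100.0 - 1.0))
    return t / (2.0 - t)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Jaccard matrix over labelled genomes."""

    genome_ids: list[str]
    k: int
    J: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genome_ids)
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (n, n):
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(self.J < 0) or np.any(self.J > 1):
            raise ValueError("Jaccard values must lie in [0, 1]")
        if not np.allclose(np.diag(self.J), 1.0):
            raise ValueError("diagonal must be 1 (self similarity)")

    @property
    def n(self) -> int:
        return len(self.genome_ids)

    def value(self, id_a: str, id_b: str) -> float:
        i = self.genome_ids.index(id_a)
        j = self.genome_ids.index(id_b)
        return float(self.J[i, j])

    def pairs(self) -> pd.DataFrame:
        """Long-format table of the upper triangle.

        Columns: id_a, id_b, k, JS, log10_js (NaN for JS = 0), ANI_est (NaN
        for JS = 0).
        """
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                js = float(self.J[i, j])
                rows.append(
                    {
                        "id_a": self.genome_ids[i],
                        "id_b": self.genome_ids[j],
                        "k": self.k,
                        "JS": js,
                        "log10_js": math.log10(js) if js > 0 else float("nan"),
                        "ANI_est": ani_from_jaccard(js, self.k),
                    }
                )
        return pd.DataFrame(rows)

    def n_zero_pairs(self) -> int:
        """Number of unordered pairs sharing zero k-mers."""
        iu = np.triu_indices(self.n, 1)
        return int(np.sum(self.J[iu] == 0.0))

    # -------------------------------------------------------------- #
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.J, index=self.genome_ids, columns=self.genome_ids)
        df.index.name = f"k={self.k}"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        index_name = df.index.name or ""
        if not index_name.startswith("k="):
            raise ValueError(f"{path!r}: missing 'k=' tag in matrix header")
        k = int(index_name[2:])
        return cls(genome_ids=[str(c) for c in df.columns], k=k, J=df.to_numpy())


def pairwise_matrix(sets: Sequence[tuple[str, KmerSet]]) -> SimilarityMatrix:
    """All-vs-all Jaccard similarity over labelled k-mer sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 k-mer sets")
    ks = {s.k for _, s in sets}
    if len(ks) != 1:
        raise ValueError(f"mixed k-mer lengths: {sorted(ks)}")
    ids = [name for name, _ in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(sets)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard(sets[i][1], sets[j][1])
    return SimilarityMatrix(genome_ids=ids, k=ks.pop(), J=J)
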