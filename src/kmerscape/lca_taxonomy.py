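"""LCA-level analysis of pairwise genome similarity against a ranked taxonomy.

Every genome pair is assigned the rank of its lowest common ancestor (LCA):
1 = species (two strains), 2 = genus, ... 7 = superkingdom, 8 = organism
(no shared label below the root of cellular organisms).  If taxonomy and
similarity agree, a genome's median similarity to its rank-r relatives
decreases monotonically as r grows; violations of that monotonicity — and
pairs whose estimated ANI falls on the wrong side of the 95% species
boundary for their labelled rank — flag potential misclassifications.

Pairs sharing zero k-mers have no finite log similarity; they are excluded
from the log-domain statistics and reported separately, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "RANKS",
    "RANK_INDEX",
    "ROOT_RANK",
    "TaxonomyTable",
    "lca_rank",
    "RankDensity",
    "rank_distributions",
    "LCATrajectory",
    "trajectories",
    "MisclassificationReport",
    "flag_misclassifications",
]

# ranks ordered from closest (1) to most distant; 8 = "organism" root level
RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
)
RANK_INDEX: dict[str, int] = {name: i + 1 for i, name in enumerate(RANKS)}
ROOT_RANK = 8
RANK_NAMES: dict[int, str] = {**{i + 1: n for i, n in enumerate(RANKS)}, ROOT_RANK: "organism"}

DEFAULT_DELTA_THRESHOLDS: tuple[float, ...] = (0.0, -0.05, -0.1, -0.5)
SPECIES_ANI_THRESHOLD = 95.0
LOW_ANI_THRESHOLD = 90.0

KDE_SUPPORT = (-8.0, 0.0)


class TaxonomyTable:
    """Ranked lineage (species ... superkingdom) per organism.

    Labels may be missing below superkingdom; a missing rank is skipped when
    matching lineages, i.e. comparisons group at the nearest populated
    shared rank.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "genome_id" not in df.columns:
            raise ValueError("taxonomy table needs a genome_id column")
        for rank in RANKS:
            if rank not in df.columns:
                df[rank] = pd.NA
        df["genome_id"] = df["genome_id"].astype(str)
        if df["genome_id"].duplicated().any():
            dupes = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
            raise ValueError(f"duplicate genome_ids: {dupes}")
        # empty strings count as missing labels
        for rank in RANKS:
            df[rank] = df[rank].replace("", pd.NA)
        self.table = df.reset_index(drop=True)
        self._lineages: dict[str, dict[str, str | None]] = {}
        for d in self.table.to_dict("records"):  # "class" is a keyword: no itertuples
            self._lineages[d["genome_id"]] = {
                rank: (None if pd.isna(d[rank]) else str(d[rank])) for rank in RANKS
            }

    @property
    def genome_ids(self) -> list[str]:
        return list(self.table["genome_id"])

    def lineage(self, genome_id: str) -> dict[str, str | None]:
        return self._lineages[genome_id]

    def lca_rank(self, id_a: str, id_b: str) -> int:
        return lca_rank(self.lineage(id_a), self.lineage(id_b))

    def to_tsv(self, path) -> None:
        self.table[["genome_id", *RANKS]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def lca_rank(a_lineage: Mapping[str, str | None], b_lineage: Mapping[str, str | None]) -> int:
    """Rank index of the lowest common ancestor of two lineages.

    Walks from superkingdom (7) toward species (1); a rank where either
    lineage is unlabelled is skipped, a mismatch stops the walk.  Two
    lineages disagreeing at superkingdom (or everywhere labelled) meet only
    at the root: rank 8, the "organism" level.
    """
    matched = ROOT_RANK
    for r in range(len(RANKS), 0, -1):
        rank = RANKS[r - 1]
        la, lb = a_lineage.get(rank), b_lineage.get(rank)
        if la is None or lb is None:
            continue
        if la == lb:
            matched = r
        else:
            break
    return matched


# ---------------------------------------------------------------------- #
# per-rank similarity distributions
# ---------------------------------------------------------------------- #
@dataclass
class RankDensity:
    rank: int
    rank_name: str
    n_pairs: int
    n_zero_excluded: int
    grid: np.ndarray
    density: np.ndarray
    median_log10_js: float


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    std = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(std, iqr / 1.349) if iqr > 0 else std
    if scale <= 0:
        return 0.05  # degenerate sample: narrow fixed kernel
    return 0.9 * scale * n ** (-1 / 5)


def _bounded_kde(x: np.ndarray, grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Gaussian KDE with boundary correction by reflection at lo and hi.

    The bandwidth is Silverman's rule, floored at the grid step so that very
    tight clusters of values remain resolvable on the returned grid.
    """
    bw = max(_silverman_bandwidth(x), float(grid[1] - grid[0]))

    def gauss(at: np.ndarray) -> np.ndarray:
        z = (at[:, None] - x[None, :]) / bw
        return np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * math.sqrt(2 * math.pi))

    dens = gauss(grid) + gauss(2 * lo - grid) + gauss(2 * hi - grid)
    return dens


def _pair_table(S: SimilarityMatrix, T: TaxonomyTable) -> pd.DataFrame:
    missing = set(S.genome_ids) - set(T.genome_ids)
    if missing:
        raise ValueError(f"taxonomy does not cover genomes: {sorted(missing)}")
    df = S.pairs()
    df["lca_rank"] = [
        T.lca_rank(a, b) for a, b in zip(df["id_a"], df["id_b"])
    ]
    return df


def rank_distributions(
    S: SimilarityMatrix,
    T: TaxonomyTable,
    grid_size: int = 512,
) -> dict[int, RankDensity]:
    """Kernel density estimates of log10 Jaccard similarity per LCA rank.

    Gaussian KDE with Silverman's bandwidth on the log10 values, support
    bounded to [-8, 0] with boundary reflection.  Zero-Jaccard pairs are
    excluded from estimation and returned in the excluded count; ranks with
    no nonzero pair are omitted.
    """
    lo, hi = KDE_SUPPORT
    grid = np.linspace(lo, hi, grid_size)
    df = _pair_table(S, T)
    out: dict[int, RankDensity] = {}
    for rank, group in df.groupby("lca_rank"):
        zeros = int((group["JS"] == 0).sum())
        vals = group.loc[group["JS"] > 0, "log10_js"].to_numpy()
        if vals.size == 0:
            continue
        out[int(rank)] = RankDensity(
            rank=int(rank),
            rank_name=RANK_NAMES[int(rank)],
            n_pairs=int(vals.size),
            n_zero_excluded=zeros,
            grid=grid,
            density=_bounded_kde(np.clip(vals, lo, hi), grid, lo, hi),
            median_log10_js=float(np.median(vals)),
        )
    return out


# ---------------------------------------------------------------------- #
# per-genome median-similarity trajectories
# ---------------------------------------------------------------------- #
@dataclass
class LCATrajectory:
    """Median/maximum log10 similarity of one genome per available LCA rank.

    ``deltas[(r1, r2)] = median(r1) - median(r2)`` for consecutive available
    ranks r1 < r2; a delta below a threshold t < 0 (or below zero) marks a
    potential taxonomic inconsistency for this genome.
    """

    genome_id: str
    median_log10_js: dict[int, float] = field(default_factory=dict)
    max_log10_js: dict[int, float] = field(default_factory=dict)
    n_pairs: dict[int, int] = field(default_factory=dict)
    deltas: dict[tuple[int, int], float] = field(default_factory=dict)
    max_deltas: dict[tuple[int, int], float] = field(default_factory=dict)

    def violations(self, threshold: float = 0.0, use_max: bool = False) -> list[tuple[int, int]]:
        source = self.max_deltas if use_max else self.deltas
        return [pair for pair, delta in source.items() if delta < threshold]

    @property
    def is_monotone(self) -> bool:
        return not self.violations(0.0)


def trajectories(S: SimilarityMatrix, T: TaxonomyTable) -> list[LCATrajectory]:
    """Per-genome similarity trajectories across LCA ranks.

    Genomes with fewer than two populated ranks carry no deltas (and are
    thereby excluded from violation counting).  Zero-Jaccard pairs are
    excluded from the medians/maxima.
    """
    df = _pair_table(S, T)
    nonzero = df[df["JS"] > 0]
    per_genome: dict[str, dict[int, list[float]]] = {g: {} for g in S.genome_ids}
    for row in nonzero.itertuples(index=False):
        r = int(row.lca_rank)
        per_genome[row.id_a].setdefault(r, []).append(row.log10_js)
        per_genome[row.id_b].setdefault(r, []).append(row.log10_js)
    out = []
    for gid in S.genome_ids:
        by_rank = per_genome[gid]
        traj = LCATrajectory(genome_id=gid)
        for r in sorted(by_rank):
            vals = np.asarray(by_rank[r])
            traj.median_log10_js[r] = float(np.median(vals))
            traj.max_log10_js[r] = float(np.max(vals))
            traj.n_pairs[r] = int(vals.size)
        ranks = sorted(traj.median_log10_js)
        for r1, r2 in zip(ranks, ranks[1:]):
            traj.deltas[(r1, r2)] = traj.median_log10_js[r1] - traj.median_log10_js[r2]
            traj.max_deltas[(r1, r2)] = traj.max_log10_js[r1] - traj.max_log10_js[r2]
        out.append(traj)
    return out


def delta_violation_counts(
    trajs: Sequence[LCATrajectory],
    thresholds: Sequence[float] = DEFAULT_DELTA_THRESHOLDS,
) -> pd.DataFrame:
    """Count genomes with >= 1 median (and max) delta below each threshold."""
    rows = []
    for t in thresholds:
        rows.append(
            {
                "threshold": t,
                "n_genomes_median_below": sum(1 for tr in trajs if tr.violations(t)),
                "n_genomes_max_below": sum(1 for tr in trajs if tr.violations(t, use_max=True)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# misclassification flagging
# ---------------------------------------------------------------------- #
@dataclass
class MisclassificationReport:
    """Pairs whose estimated ANI contradicts their taxonomic labels.

    ``strain_pairs_low_ani``: same-species strain pairs below the 95% ANI
    species threshold (the sub-90% subset is the strongest misclassification
    signal).  ``cross_genus_high_ani``: pairs from different genera above
    95% ANI (modulo a user-supplied allowlist of genus pairs known to
    violate the threshold, e.g. Escherichia/Shigella-style splits).
    ``same_genus_species_high_ani``: congeneric species pairs with at least
    one strain pair above 95%.
    """

    k: int
    strain_pairs_low_ani: pd.DataFrame
    cross_genus_high_ani: pd.DataFrame
    same_genus_species_high_ani: pd.DataFrame
    delta_violation_counts: pd.DataFrame

    @property
    def species_below_95(self) -> list[str]:
        df = self.strain_pairs_low_ani
        return sorted(df["species"].unique()) if len(df) else []

    @property
    def species_below_90(self) -> list[str]:
        df = self.strain_pairs_low_ani
        if not len(df):
            return []
        return sorted(df.loc[df["ANI_est"] < LOW_ANI_THRESHOLD, "species"].unique())

    @property
    def n_flagged_pairs(self) -> int:
        return len(self.strain_pairs_low_ani) + len(self.cross_genus_high_ani)


def flag_misclassifications(
    S: SimilarityMatrix,
    T: TaxonomyTable,
    thresholds: Sequence[float] = DEFAULT_DELTA_THRESHOLDS,
    genus_allowlist: Iterable[tuple[str, str]] = (),
) -> MisclassificationReport:
    """Screen a similarity matrix for taxonomy/similarity contradictions.

    ANI is estimated from the Jaccard values at the matrix's k.  Zero-
    Jaccard pairs carry NaN ANI and never trigger the high-ANI rules; a
    same-species pair sharing zero k-mers is treated as (severely) below
    the species threshold.
    """
    df = _pair_table(S, T)
    allow = {frozenset(p) for p in genus_allowlist}

    def genus_of(gid: str) -> str | None:
        return T.lineage(gid)["genus"]

    def species_of(gid: str) -> str | None:
        return T.lineage(gid)["species"]

    within_species = df[df["lca_rank"] == 1].copy()
    low = within_species[
        (within_species["ANI_est"] < SPECIES_ANI_THRESHOLD)
        | (within_species["JS"] == 0)
    ].copy()
    if len(low):
        low["species"] = [species_of(a) or "" for a in low["id_a"]]
        low = low[["id_a", "id_b", "species", "JS", "ANI_est", "lca_rank"]]
    else:
        low = pd.DataFrame(columns=["id_a", "id_b", "species", "JS", "ANI_est", "lca_rank"])

    cross_genus = df[(df["lca_rank"] >= 3) & (df["ANI_est"] > SPECIES_ANI_THRESHOLD)].copy()
    if len(cross_genus):
        keep = []
        for row in cross_genus.itertuples(index=False):
            ga, gb = genus_of(row.id_a), genus_of(row.id_b)
            keep.append(frozenset((ga, gb)) not in allow)
        cross_genus = cross_genus[np.asarray(keep, dtype=bool)]
        cross_genus = cross_genus[["id_a", "id_b", "JS", "ANI_est", "lca_rank"]]
    else:
        cross_genus = pd.DataFrame(columns=["id_a", "id_b", "JS", "ANI_est", "lca_rank"])

    same_genus = df[(df["lca_rank"] == 2) & (df["ANI_est"] > SPECIES_ANI_THRESHOLD)].copy()
    if len(same_genus):
        rows = []
        for row in same_genus.itertuples(index=False):
            rows.append(
                {
                    "genus": genus_of(row.id_a) or "",
                    "species_a": species_of(row.id_a) or "",
                    "species_b": species_of(row.id_b) or "",
                    "id_a": row.id_a,
                    "id_b": row.id_b,
                    "JS": row.JS,
                    "ANI_est": row.ANI_est,
                }
            )
        same_genus = pd.DataFrame(rows)
        # one row per congeneric species pair, keeping its highest-ANI strain pair
        same_genus["_pair"] = [
            tuple(sorted((a, b)))
            for a, b in zip(same_genus["species_a"], same_genus["species_b"])
        ]
        same_genus = (
            same_genus.sort_values("ANI_est", ascending=False)
            .drop_duplicates(["genus", "_pair"])
            .drop(columns="_pair")
            .reset_index(drop=True)
        )
    else:
        same_genus = pd.DataFrame(
            columns=["genus", "species_a", "species_b", "id_a", "id_b", "JS", "ANI_est"]
        )

    trajs = trajectories(S, T)
    counts = delta_violation_counts(trajs, thresholds)
    return MisclassificationReport(
        k=S.k,
        strain_pairs_low_ani=low.reset_index(drop=True),
        cross_genus_high_ani=cross_genus.reset_index(drop=True),
        same_genus_species_high_ani=same_genus.reset_index(drop=True),
        delta_violation_counts=counts,
    )
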