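"""End-to-end pipeline: count -> coverage -> compare -> tree -> taxcheck.

A run takes a set of genome FASTA files plus a taxonomy table and produces,
in one output directory: per-genome coverage/k* tables, the pairwise
similarity matrix and long-format pair table, clustered and reference trees
(Newick) with their generalized RF distance, and the LCA misclassification
reports.  The resolved configuration is written next to the outputs and
every stage is logged with input/output checksums, so a run is fully
reproducible from its directory.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage_stats import (
    combined_nssc,
    coverage_profile,
    fit_kstar_regression,
    k_star,
    recommend_k,
)
from .kmer_engine import extract_canonical_kmers, save_kmerset
from .lca_taxonomy import (
    DEFAULT_DELTA_THRESHOLDS,
    TaxonomyTable,
    delta_violation_counts,
    flag_misclassifications,
    trajectories,
)
from .sequence_io import read_fasta
from .similarity import pairwise_matrix
from .tree_analysis import (
    generalized_rf,
    optimal_leaf_order,
    reference_tree,
    similarity_to_dissimilarity,
    to_newick,
    ward_cluster,
)

__all__ = ["PipelineConfig", "run_full", "PipelineError"]

logger = logging.getLogger("kmerscape.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    ``k`` may be an integer or ``"auto"``; auto fits the k* regression over
    the input genomes' (log10 N_T, k*) points and takes the smallest odd
    integer at or above the prediction for the pooled total k-mer count.
    """

    fasta: list[str] = field(default_factory=list)     # files or glob patterns
    taxonomy: str | None = None
    out_dir: str = "kmerscape_run"
    k: int | str = 21
    k_grid: list[int] = field(default_factory=lambda: list(range(3, 32, 2)))
    transform: str = "one-minus"
    olo: bool = True
    thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_DELTA_THRESHOLDS))
    genus_allowlist: list[list[str]] = field(default_factory=list)
    save_kmer_sets: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_fasta(patterns: list[str]) -> list[Path]:
    paths: list[Path] = []
    for pat in patterns:
        hits = sorted(glob.glob(pat))
        if not hits and os.path.exists(pat):
            hits = [pat]
        paths.extend(Path(p) for p in hits)
    return paths


def run_full(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Raises :class:`PipelineError` naming the failing stage; outputs of the
    completed stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)
        logger.info("wrote %s md5=%s", path, _md5(path))

    try:
        logger.info("kmerscape %s seed=%s", __version__, config.seed)
        config.to_yaml(out / "config.resolved.yaml")

        # ---- stage: input -------------------------------------------- #
        stage = "input"
        fasta_paths = _resolve_fasta(config.fasta)
        if len(fasta_paths) < 2:
            raise PipelineError(stage, f"need >= 2 FASTA inputs, found {len(fasta_paths)}")
        for p in fasta_paths:
            logger.info("input %s md5=%s", p, _md5(p))
        records = [read_fasta(p) for p in fasta_paths]
        taxonomy = None
        if config.taxonomy is not None:
            if not os.path.exists(config.taxonomy):
                raise PipelineError(stage, f"taxonomy file not found: {config.taxonomy}")
            taxonomy = TaxonomyTable.from_tsv(config.taxonomy)

        # ---- stage: coverage ----------------------------------------- #
        stage = "coverage"
        profiles = [coverage_profile(r, config.k_grid) for r in records]
        cov_rows = [row for p in profiles for row in p.to_rows()]
        pd.DataFrame(cov_rows).to_csv(out / "coverage.tsv", sep="\t", index=False)
        emit(out / "coverage.tsv")
        kstar_rows = []
        for p in profiles:
            nt = p.per_k[p.k_star].N_T
            kstar_rows.append(
                {
                    "genome_id": p.genome_id,
                    "k_star": p.k_star,
                    "min_nssc": p.min_nssc,
                    "log10_NT": float(np.log10(max(nt, 1))),
                }
            )
        kstar_df = pd.DataFrame(kstar_rows)
        kstar_df.to_csv(out / "kstar.tsv", sep="\t", index=False)
        emit(out / "kstar.tsv")

        # ---- stage: choose-k ----------------------------------------- #
        stage = "choose-k"
        if config.k == "auto":
            xs = kstar_df["log10_NT"].to_numpy()
            total_nt = sum(p.per_k[p.k_star].N_T for p in profiles)
            if float(np.ptp(xs)) >= 0.5:
                # enough genome-length spread for the k* trend line
                pts = list(zip(kstar_df["log10_NT"], kstar_df["k_star"]))
                reg = fit_kstar_regression(pts)
                prediction = reg.predict(float(np.log10(total_nt)))
                k = recommend_k(prediction)
                logger.info(
                    "auto k (k* regression): slope=%.4f intercept=%.4f x=%.3f "
                    "prediction=%.3f -> k=%d",
                    reg.slope, reg.intercept, float(np.log10(total_nt)), prediction, k,
                )
            else:
                # near-equal genome lengths: the regression is uninformative;
                # use the pooled-collection NSSC minimum instead and step one
                # odd k above it for specificity
                pooled_nssc = {}
                for kk in config.k_grid:
                    ksets = [extract_canonical_kmers(r, kk) for r in records]
                    pooled_nssc[kk] = combined_nssc(ksets, kk)
                k_min = k_star(pooled_nssc)
                k = min(k_min + 2, max(config.k_grid))
                logger.info(
                    "auto k (pooled NSSC, lengths near-equal): min at %d -> k=%d",
                    k_min, k,
                )
        else:
            k = int(config.k)
        (out / "chosen_k.json").write_text(json.dumps({"k": k}) + "\n")
        emit(out / "chosen_k.json")

        # ---- stage: count -------------------------------------------- #
        stage = "count"
        sets = [(r.genome_id, extract_canonical_kmers(r, k)) for r in records]
        if config.save_kmer_sets:
            ksdir = out / "ksets"
            ksdir.mkdir(exist_ok=True)
            for name, kset in sets:
                save_kmerset(kset, ksdir / f"{name}.k{k}.kset")

        # ---- stage: compare ------------------------------------------ #
        stage = "compare"
        S = pairwise_matrix(sets)
        S.to_tsv(out / "similarity_matrix.tsv")
        emit(out / "similarity_matrix.tsv")
        S.pairs().to_csv(out / "similarity_pairs.tsv", sep="\t", index=False)
        emit(out / "similarity_pairs.tsv")

        # ---- stage: tree --------------------------------------------- #
        stage = "tree"
        D = similarity_to_dissimilarity(S, mode=config.transform)
        tree = ward_cluster(D, S.genome_ids)
        if config.olo:
            tree = optimal_leaf_order(tree, D)
        (out / "cluster_tree.nwk").write_text(tree.to_newick() + "\n")
        emit(out / "cluster_tree.nwk")
        pd.DataFrame({"leaf_order": tree.leaf_order}).to_csv(
            out / "leaf_order.tsv", sep="\t", index=False
        )
        emit(out / "leaf_order.tsv")
        if taxonomy is not None:
            ref = reference_tree(taxonomy)
            (out / "reference_tree.nwk").write_text(to_newick(ref) + "\n")
            emit(out / "reference_tree.nwk")
            grf = generalized_rf(tree, ref)
            (out / "tree_distance.json").write_text(
                json.dumps({"generalized_rf_to_reference": grf}) + "\n"
            )
            emit(out / "tree_distance.json")

        # ---- stage: taxcheck ----------------------------------------- #
        stage = "taxcheck"
        if taxonomy is not None:
            report = flag_misclassifications(
                S,
                taxonomy,
                thresholds=config.thresholds,
                genus_allowlist=[tuple(p) for p in config.genus_allowlist],
            )
            report.strain_pairs_low_ani.to_csv(
                out / "strain_pairs_low_ani.tsv", sep="\t", index=False
            )
            emit(out / "strain_pairs_low_ani.tsv")
            report.cross_genus_high_ani.to_csv(
                out / "cross_genus_high_ani.tsv", sep="\t", index=False
            )
            emit(out / "cross_genus_high_ani.tsv")
            report.same_genus_species_high_ani.to_csv(
                out / "same_genus_species_high_ani.tsv", sep="\t", index=False
            )
            emit(out / "same_genus_species_high_ani.tsv")
            report.delta_violation_counts.to_csv(
                out / "delta_violation_counts.tsv", sep="\t", index=False
            )
            emit(out / "delta_violation_counts.tsv")

        logger.info("run complete: %d artifacts", len(written))
        return out
    except PipelineError:
        logger.exception("pipeline failed")
        raise
    except Exception as exc:
        logger.exception("pipeline failed in stage %r", stage)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
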