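"""End-to-end orchestration: similarity -> consensus -> dyadic inference.

A single seeded run generates (or loads) the pattern matrices, builds the
pairwise dyad table with the Anna Karenina predictor, fits the doubled
dyadic mixed model, estimates each target's consensus representation and
fits the participant-level consensus-similarity model, and writes tidy
result files plus a manifest of row counts, exclusions and seeds.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import ConsensusRepresentation
from .inference import AnnaKareninaModel, ConsensusSimilarityModel
from .io import write_json, write_meta_csv, write_pattern_tsv
from .similarity import PatternMatrix, mean_pair_predictor, pairwise_similarity
from .synthetic import (SyntheticConfig, SyntheticDataset,
                        generate_dissociation_scenario, generate_patterns)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "exclude_low_variance", "analyze_dataset",
           "run_pipeline", "plot_mds"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    metric: str = "pearson"
    consensus_method: str = "kernel_weighted"
    grid_resolution: int = 100
    tail: str = "one_negative"
    out_dir: str | None = None
    make_plots: bool = False
    seed: int = 0


def exclude_low_variance(ratings: pd.DataFrame,
                         z_threshold: float = -2.0) -> tuple[list, list]:
    """Drop zero-variance raters, then low-variance raters by z-score.

    Participants with no variance across rating items are excluded first;
    the remaining per-participant variances are z-scored and participants
    at or below ``z_threshold`` standard deviations under the mean are
    also excluded.  Returns ``(kept_ids, excluded_ids)``.
    """
    if len(ratings) < 3:
        raise ValueError("need >= 3 participants")
    mat = ratings.set_index("participant") if "participant" in ratings.columns \
        else ratings
    var = mat.var(axis=1, ddof=0)
    if (var == 0).all():
        raise ValueError("all participants have zero rating variance")
    zero = var.index[var == 0].tolist()
    rest = var[var > 0]
    sd = rest.std(ddof=0)
    z = (rest - rest.mean()) / sd if sd > 0 else rest * 0.0
    low = z.index[z <= z_threshold].tolist()
    excluded = zero + low
    kept = [p for p in var.index if p not in set(excluded)]
    if excluded:
        logger.info("excluded %d zero-variance and %d low-variance "
                    "participants", len(zero), len(low))
    return kept, excluded


def build_dyad_table(dataset: SyntheticDataset, metric="pearson") -> pd.DataFrame:
    """Undoubled dyad table across all targets with the pair-mean predictor."""
    meta = pd.DataFrame({"participant": dataset.participant_ids,
                         "loneliness": dataset.loneliness})
    tables = []
    for target, values in dataset.patterns.items():
        pm = PatternMatrix(values, dataset.participant_ids, target)
        tables.append(pairwise_similarity(pm, metric))
    dyads = pd.concat(tables, ignore_index=True)
    return mean_pair_predictor(meta, dyads, "loneliness")


def build_consensus_table(dataset: SyntheticDataset, cfg: RunConfig
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-participant similarity-to-consensus table plus fitted estimators."""
    rows, estimators = [], {}
    for target, values in dataset.patterns.items():
        pm = PatternMatrix(values, dataset.participant_ids, target)
        est = ConsensusRepresentation(method=cfg.consensus_method,
                                      metric=cfg.metric,
                                      grid_resolution=cfg.grid_resolution,
                                      random_state=cfg.seed)
        rows.append(est.fit_transform(pm))
        estimators[target] = est
    table = pd.concat(rows, ignore_index=True)
    lon = pd.Series(dataset.loneliness, index=dataset.participant_ids)
    table["loneliness"] = table["participant"].map(lon)
    return table, estimators


def analyze_dataset(dataset: SyntheticDataset, cfg: RunConfig) -> dict:
    """Run the pairwise AK fit and the consensus-similarity fit."""
    dyads = build_dyad_table(dataset, cfg.metric)
    ak = AnnaKareninaModel(tail=cfg.tail).fit(dyads)
    cons_table, estimators = build_consensus_table(dataset, cfg)
    cons = ConsensusSimilarityModel(tail=cfg.tail).fit(cons_table)
    return {"dyads": dyads, "consensus_table": cons_table,
            "ak_model": ak, "consensus_model": cons,
            "consensus_estimators": estimators}


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate, analyze and (optionally) write results and a manifest."""
    scfg = cfg.synthetic
    if scfg.scenario in ("ak", "null"):
        dataset = generate_patterns(scfg)
    else:
        dataset = generate_dissociation_scenario(scfg)

    results = analyze_dataset(dataset, cfg)
    n = scfg.n_participants
    n_pairs = n * (n - 1) // 2
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "scenario": scfg.scenario,
        "n_participants": n,
        "n_targets": scfg.n_targets,
        "n_pairs_per_target": n_pairs,
        "n_dyad_rows": int(len(results["dyads"])),
        "n_doubled_rows": int(results["ak_model"].fit_.n_obs),
        "n_consensus_rows": int(len(results["consensus_table"])),
        "n_excluded_dyads": int(results["dyads"]["flag_undefined"].sum()),
        "ak_fit": results["ak_model"].fit_.to_dict(),
        "consensus_fit": results["consensus_model"].fit_.to_dict(),
        "files": {},
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = pd.DataFrame({"participant": dataset.participant_ids,
                             "loneliness": dataset.loneliness})
        files = {"meta.csv": write_meta_csv(meta, out / "meta.csv"),
                 "dyads.csv": out / "dyads.csv",
                 "consensus_similarity.csv": out / "consensus_similarity.csv"}
        results["dyads"].to_csv(files["dyads.csv"], index=False)
        results["consensus_table"].to_csv(
            files["consensus_similarity.csv"], index=False)
        for target, values in dataset.patterns.items():
            pm = PatternMatrix(values, dataset.participant_ids, target)
            files[f"patterns_{target}.tsv"] = write_pattern_tsv(
                pm, out / f"patterns_{target}.tsv")
        if cfg.make_plots:
            for target, est in results["consensus_estimators"].items():
                if hasattr(est, "embedding_"):
                    files[f"mds_{target}.png"] = plot_mds(
                        est, dataset, out / f"mds_{target}.png")
        manifest["files"] = {k: _file_hash(Path(v)) for k, v in files.items()}
        write_json(manifest, out / "manifest.json")
    return {"manifest": manifest, **results, "dataset": dataset}


def plot_mds(est: ConsensusRepresentation, dataset: SyntheticDataset,
             path) -> Path:
    """MDS plane colored by loneliness, with the densest point starred."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    emb, dens = est.embedding_, est.density_
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(emb.coords[:, 0], emb.coords[:, 1],
                    c=dataset.loneliness, cmap="coolwarm_r", s=40,
                    edgecolor="k", linewidth=0.3)
    ax.plot(*dens.densest_point, marker="*", color="green", markersize=16)
    fig.colorbar(sc, ax=ax, label="loneliness")
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    ax.set_title(f"target {est.target_id_}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
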