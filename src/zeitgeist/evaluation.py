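"""Simulation studies of the pipeline's operating characteristics.

These routines regenerate data and rerun the full analysis many times to
measure type-I error calibration, power at a planted Anna Karenina effect,
the closed-form pairwise-similarity expectation, the AK/consensus model
dissociation, and reliability-based ROI recovery.  They back both the
acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .inference import AnnaKareninaModel, ConsensusSimilarityModel
from .pipeline import RunConfig, build_consensus_table, build_dyad_table
from .rbvs import ReliabilityVoxelSelector
from .synthetic import (SyntheticConfig, generate_dissociation_scenario,
                        generate_patterns, generate_splithalf_volumes,
                        slope_for_effect)

__all__ = [
    "null_calibration",
    "ak_power",
    "mean_pairwise_similarity",
    "dissociation_rates",
    "rbvs_blob_recovery",
]

def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds below 2**31 from one master seed."""
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)

def null_calibration(n_replicates: int = 400, seed: int = 0,
                     n_participants: int = 30, n_targets: int = 3,
                     n_features: int = 200, alpha: float = 0.05) -> dict:
    """Two-tailed AK rejection rate on loneliness-independent patterns."""
    rejections = 0
    for s in _spawn_seeds(seed, n_replicates):
        cfg = SyntheticConfig(n_participants=n_participants,
                              n_features=n_features, n_targets=n_targets,
                              scenario="null", seed=int(s))
        dyads = build_dyad_table(generate_patterns(cfg))
        model = AnnaKareninaModel(tail="two").fit(dyads)
        rejections += model.p_two_ < alpha
    return {"rate": rejections / n_replicates, "n": n_replicates}

def ak_power(n_replicates: int = 200, seed: int = 0, effect: float = -0.2,
             n_participants: int = 40, n_targets: int = 5,
             n_features: int = 200, alpha: float = 0.05) -> dict:
    """One-tailed detection rate at a planted standardized AK effect."""
    probe = SyntheticConfig(n_participants=n_participants,
                            n_features=n_features, n_targets=n_targets,
                            scenario="ak", idiosyncrasy_slope=1e-9)
    slope = slope_for_effect(effect, probe)
    hits, betas = 0, []
    for s in _spawn_seeds(seed, n_replicates):
        cfg = SyntheticConfig(n_participants=n_participants,
                              n_features=n_features, n_targets=n_targets,
                              scenario="ak", idiosyncrasy_slope=slope,
                              seed=int(s))
        dyads = build_dyad_table(generate_patterns(cfg))
        model = AnnaKareninaModel(tail="one_negative").fit(dyads)
        betas.append(model.beta_)
        hits += (model.beta_ < 0) and (model.p_one_ < alpha)
    return {"rate": hits / n_replicates, "mean_beta": float(np.mean(betas)),
            "n": n_replicates}

def mean_pairwise_similarity(seed: int = 0, n_participants: int = 40,
                             n_features: int = 500, n_targets: int = 2,
                             prototype_sd: float = 1.0,
                             base_noise_sd: float = 1.0) -> dict:
    """Mean pairwise Pearson similarity vs E[r] = v_p / (v_p + sigma^2)."""
    cfg = SyntheticConfig(n_participants=n_participants,
                          n_features=n_features, n_targets=n_targets,
                          prototype_sd=prototype_sd,
                          base_noise_sd=base_noise_sd,
                          scenario="null", seed=seed)
    ds = generate_patterns(cfg)
    rs = []
    for mat in ds.patterns.values():
        c = np.corrcoef(mat)
        rs.append(c[np.triu_indices_from(c, 1)])
    expected = prototype_sd ** 2 / (prototype_sd ** 2 + base_noise_sd ** 2)
    return {"mean_similarity": float(np.concatenate(rs).mean()),
            "expected": expected,
            "n": n_participants * (n_participants - 1) // 2 * n_targets}

def dissociation_rates(scenario: str, n_replicates: int = 200, seed: int = 0,
                       n_participants: int = 30, n_targets: int = 3,
                       n_features: int = 200, alpha: float = 0.05) -> dict:
    """One-tailed rejection rates of the AK and consensus models.

    In the cluster scenario only the consensus model should reject (the
    displaced group is mutually similar but far from the consensus); in
    the ring scenario the AK model should reject while the consensus
    association is weak.
    """
    ak_hits = cons_hits = 0
    for s in _spawn_seeds(seed, n_replicates):
        cfg = SyntheticConfig(n_participants=n_participants,
                              n_features=n_features, n_targets=n_targets,
                              scenario=scenario, seed=int(s))
        ds = generate_dissociation_scenario(cfg)
        ak = AnnaKareninaModel(tail="one_negative").fit(build_dyad_table(ds))
        ak_hits += (ak.beta_ < 0) and (ak.p_one_ < alpha)
        table, _ = build_consensus_table(ds, RunConfig(seed=int(s)))
        cons = ConsensusSimilarityModel(tail="one_negative").fit(table)
        cons_hits += (cons.beta_ < 0) and (cons.p_one_ < alpha)
    return {"ak_rate": ak_hits / n_replicates,
            "consensus_rate": cons_hits / n_replicates,
            "n": n_replicates}

def rbvs_blob_recovery(seed: int = 0, grid=(10, 10, 10), center=(4, 4, 4),
                       radius: float = 2.5, signal_sd: float = 2.0,
                       noise_sd: float = 1.0, n_participants: int = 12,
                       n_conditions: int = 16) -> dict:
    """Jaccard overlap of the selected ROI with the planted reliable blob."""
    half1, half2, blob = generate_splithalf_volumes(
        grid, center, radius, signal_sd, noise_sd, n_participants,
        n_conditions, seed=seed)
    sel = ReliabilityVoxelSelector(
        region_masks={"blob": np.ones(grid, bool)},
        threshold_range=(0.2, 0.7), threshold_step=0.05, min_voxels=5)
    sel.fit((half1, half2), grid_shape=grid)
    mask = sel.masks_["blob"]
    jac = float((mask & blob).sum() / (mask | blob).sum())
    return {"jaccard": jac, "selected_threshold": sel.selected_threshold_,
            "n_voxels": int(mask.sum()), "n": int(np.prod(grid))}
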