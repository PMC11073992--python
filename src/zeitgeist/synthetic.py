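"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate a study in which every participant holds a
multivariate representation (neural pattern, text embedding, or binary
trait profile) of each of a small set of shared cultural targets, and
trait loneliness modulates how far each participant's representation
strays from a shared prototype.

Scenarios
---------
``ak``
    Anna Karenina structure: ``pattern[i, t] = prototype[t] + sigma(l_i) * eps``
    with ``sigma(l) = base_noise_sd + idiosyncrasy_slope * z(l)``.  Lonelier
    participants are noisier, hence dissimilar both to each other and to
    everyone else.
``null``
    Same, with ``idiosyncrasy_slope = 0``: loneliness is unrelated to the
    patterns.
``cluster``
    High-loneliness participants form a tight secondary cluster displaced
    from the main mass: they are *far from the consensus* but *similar to
    one another*, so the consensus effect is present while the pairwise
    Anna Karenina effect is absent or reversed.
``ring``
    High-loneliness participants sit at mutually repelled directions at the
    same expected distance from the prototype as everyone else: pairwise
    similarity among them is depressed while similarity to the consensus is
    unchanged, so the Anna Karenina effect is present without a consensus
    effect.

The ``cluster``/``ring`` constructions are synthetic stand-ins built to
realize the two stated dissociation patterns; they are not a reconstruction
of any particular empirical dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "sample_loneliness",
    "generate_patterns",
    "generate_dissociation_scenario",
    "generate_trait_responses",
    "generate_splithalf_volumes",
    "slope_for_effect",
]

_SCENARIOS = ("ak", "null", "cluster", "ring")


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic study.

    Defaults follow the study conditions the pipeline is meant for: 40
    participants, 5 targets, UCLA-range loneliness (mean 40.73, sd 8.32,
    observed range 25-57), and 200 features per pattern (large enough for
    pairwise correlations to concentrate, small enough for desk-scale
    simulation studies).
    """

    n_participants: int = 40
    n_features: int = 200
    n_targets: int = 5
    loneliness_mean: float = 40.73
    loneliness_sd: float = 8.32
    loneliness_bounds: tuple[float, float] = (25.0, 57.0)
    prototype_sd: float = 1.0
    base_noise_sd: float = 2.45
    idiosyncrasy_slope: float = 0.0
    scenario: str = "null"
    missing_rate: float = 0.0
    seed: int = 0
    # sd of the participant-stable lognormal noise-scale multiplier;
    # emulates stable individual differences in data quality (SNR, motion,
    # engagement) that persist across targets
    noise_heterogeneity_sd: float = 0.18
    # cluster/ring construction knobs.  In the cluster scenario the
    # high-loneliness group shares a "deviant prototype" drawn
    # independently of the main one (hence near-orthogonal in high
    # dimension, i.e. displaced from the main mass) with feature sd
    # cluster_offset_sd, around which they scatter tightly with noise sd
    # cluster_noise_sd, making them mutually similar yet far from the
    # consensus of the main mass.
    # cluster_repulsion tilts the deviant prototype against the shared one
    # (correlation distance beyond 1), so the displaced group lands well
    # outside the main cloud in the embedding
    lonely_fraction: float = 0.25
    cluster_offset_sd: float = 3.6
    cluster_noise_sd: float = 1.4
    cluster_repulsion: float = 0.7

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.base_noise_sd < 0:
            raise ValueError("base_noise_sd must be >= 0")
        if self.idiosyncrasy_slope < 0:
            raise ValueError("idiosyncrasy_slope must be >= 0")
        if self.scenario == "null" and self.idiosyncrasy_slope != 0:
            raise ValueError("scenario='null' requires idiosyncrasy_slope=0")
        lo, hi = self.loneliness_bounds
        if not lo < hi:
            raise ValueError("loneliness_bounds must satisfy min < max")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Patterns plus the parameters that generated them."""

    patterns: dict[str, np.ndarray]     # target id -> (n_participants, n_features)
    loneliness: np.ndarray
    participant_ids: list[str]
    truth: dict = field(default_factory=dict)
    trait_responses: np.ndarray | None = None   # float with NaN for missing
    halves: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        n = len(self.loneliness)
        for t, m in self.patterns.items():
            if m.shape[0] != n:
                raise ValueError(f"pattern matrix for {t!r} does not share "
                                 "the participant index")


def sample_loneliness(cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw truncated-normal loneliness scores by rejection sampling."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.loneliness_bounds
    out = np.empty(cfg.n_participants)
    filled = 0
    while filled < cfg.n_participants:
        draw = rng.normal(cfg.loneliness_mean, cfg.loneliness_sd,
                          size=max(cfg.n_participants, 64))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), cfg.n_participants - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _prototype(cfg, rng):
    proto = rng.normal(0.0, cfg.prototype_sd, size=cfg.n_features)
    if np.all(proto == 0):
        raise ValueError("all-zero prototype")
    return proto


def generate_patterns(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate per-target pattern matrices under the ak or null scenario."""
    if cfg.scenario not in ("ak", "null"):
        raise ValueError("generate_patterns handles scenarios 'ak' and 'null'")
    rng = np.random.default_rng(cfg.seed)
    loneliness = sample_loneliness(cfg, rng)
    z = _zscore(loneliness)
    sigma_raw = cfg.base_noise_sd + cfg.idiosyncrasy_slope * z
    if np.any(sigma_raw < 0):
        logger.warning("noise sd went negative for %d participants; floored at 0",
                       int(np.sum(sigma_raw < 0)))
    sigma = np.maximum(sigma_raw, 0.0)
    if cfg.noise_heterogeneity_sd > 0:
        h = cfg.noise_heterogeneity_sd
        # mean-one lognormal multiplier, stable across targets
        sigma = sigma * rng.lognormal(-h ** 2 / 2.0, h,
                                      size=cfg.n_participants)

    ids = [f"P{i:03d}" for i in range(cfg.n_participants)]
    patterns, protos = {}, {}
    for t in range(cfg.n_targets):
        proto = _prototype(cfg, rng)
        noise = rng.standard_normal((cfg.n_participants, cfg.n_features))
        patterns[f"T{t:02d}"] = proto[None, :] + sigma[:, None] * noise
        protos[f"T{t:02d}"] = proto
    truth = {"config": asdict(cfg), "sigma": sigma, "loneliness_z": z,
             "prototypes": protos}
    return SyntheticDataset(patterns=patterns, loneliness=loneliness,
                            participant_ids=ids, truth=truth)


def slope_for_effect(effect: float, cfg: SyntheticConfig) -> float:
    """Idiosyncrasy slope producing a given standardized pairwise effect.

    Delta-method calibration for the ak scenario: pairwise Pearson
    similarity has expectation ``r(s_i, s_j) = v_p / sqrt((v_p+s_i^2)(v_p+s_j^2))``
    (``v_p`` prototype variance, ``s_i`` participant noise sd), and the
    pair-mean standardized-loneliness predictor has variance 1/2.  The
    standardized regression slope of similarity on the pair mean is

        beta(s) = g*s / (sqrt(1/2) * sd_r),   g = -v_p*s0 / (v_p + s0^2)^2,

    with ``sd_r^2 = (1 - r0^2)^2 / n_features + 2 (g s)^2 + 2 (g s0 h)^2``
    combining the feature-sampling noise of a correlation, the
    loneliness-induced spread, and the participant noise-heterogeneity
    spread (``h = noise_heterogeneity_sd``).  Solved for ``s`` by bisection.
    """
    if effect >= 0:
        raise ValueError("the planted Anna Karenina effect must be negative")
    vp = cfg.prototype_sd ** 2
    s0 = cfg.base_noise_sd
    r0 = vp / (vp + s0 ** 2)
    g = -vp * s0 / (vp + s0 ** 2) ** 2
    samp_var = (1 - r0 ** 2) ** 2 / cfg.n_features
    het_var = 2 * (g * s0 * cfg.noise_heterogeneity_sd) ** 2
    # within-target participant effects: each member's noise realization
    # interacting with the prototype contributes var v_p*s0^2/((v_p+s0^2)^2 F)
    within_var = 2 * vp * s0 ** 2 / ((vp + s0 ** 2) ** 2 * cfg.n_features)

    def beta(s):
        sd_r = np.sqrt(samp_var + het_var + within_var + 2 * (g * s) ** 2)
        return g * s / (np.sqrt(0.5) * sd_r)

    # beta(s) is monotone decreasing toward the asymptote -1/... ; check range
    b_max = g * 1e3 / (np.sqrt(0.5) * np.sqrt(samp_var + 2 * (g * 1e3) ** 2))
    if effect <= b_max:
        raise ValueError(f"effect {effect} unreachable (asymptote {b_max:.3f})")
    return float(optimize.brentq(lambda s: beta(s) - effect, 1e-9, 1e3))


def generate_dissociation_scenario(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the cluster or ring dissociation construction."""
    if cfg.scenario not in ("cluster", "ring"):
        raise ValueError("scenario must be 'cluster' or 'ring'")
    if cfg.n_participants < 6:
        raise ValueError("need >= 6 participants to form both groups")
    rng = np.random.default_rng(cfg.seed)
    loneliness = sample_loneliness(cfg, rng)
    cut = np.quantile(loneliness, 1.0 - cfg.lonely_fraction)
    lonely = loneliness > cut
    if lonely.sum() < 2:       # all-equal scores degenerate to one cluster
        lonely = np.zeros(cfg.n_participants, dtype=bool)
    k = int(lonely.sum())

    ids = [f"P{i:03d}" for i in range(cfg.n_participants)]
    s0 = cfg.base_noise_sd
    patterns, protos = {}, {}
    for t in range(cfg.n_targets):
        proto = _prototype(cfg, rng)
        protos[f"T{t:02d}"] = proto
        mat = proto[None, :] + s0 * rng.standard_normal(
            (cfg.n_participants, cfg.n_features))
        if k >= 2:
            if cfg.scenario == "cluster":
                deviant = rng.normal(0.0, cfg.cluster_offset_sd,
                                     size=cfg.n_features)
                mat[lonely] = (deviant[None, :]
                               - cfg.cluster_repulsion * proto[None, :]
                               + cfg.cluster_noise_sd
                               * rng.standard_normal((k, cfg.n_features)))
            else:  # ring: mutually repelled noise, marginal sd preserved
                e = rng.standard_normal((k, cfg.n_features))
                e -= e.mean(axis=0, keepdims=True)
                e *= s0 / np.sqrt(1.0 - 1.0 / k)
                mat[lonely] = proto[None, :] + e
        patterns[f"T{t:02d}"] = mat
    truth = {"config": asdict(cfg), "lonely": lonely, "prototypes": protos,
             "planted": ("consensus_without_ak" if cfg.scenario == "cluster"
                         else "ak_without_consensus")}
    return SyntheticDataset(patterns=patterns, loneliness=loneliness,
                            participant_ids=ids, truth=truth)


def generate_trait_responses(
    cfg: SyntheticConfig,
    consensus_prob: np.ndarray,
    flip_rate: float,
    missing_rate: float | None = None,
) -> np.ndarray:
    """Binary trait responses around a shared group profile.

    A single group profile is drawn from per-trait Bernoulli probabilities;
    each participant copies it with independent flips at ``flip_rate`` and
    entries go missing (NaN) at ``missing_rate``.  The flip rate does not
    depend on loneliness, matching a null association between loneliness
    and trait-response similarity.
    """
    missing_rate = cfg.missing_rate if missing_rate is None else missing_rate
    consensus_prob = np.asarray(consensus_prob, dtype=float)
    if np.any((consensus_prob < 0) | (consensus_prob > 1)):
        raise ValueError("consensus probabilities must lie in [0, 1]")
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must lie in [0, 1]")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    profile = (rng.random(consensus_prob.shape) < consensus_prob).astype(float)
    n, m = cfg.n_participants, len(consensus_prob)
    flips = rng.random((n, m)) < flip_rate
    resp = np.where(flips, 1.0 - profile[None, :], profile[None, :])
    resp[rng.random((n, m)) < missing_rate] = np.nan
    return resp


def generate_splithalf_volumes(
    grid_shape: tuple[int, int, int],
    blob_center: tuple[int, int, int],
    blob_radius: float,
    signal_sd: float,
    noise_sd: float,
    n_participants: int,
    n_conditions: int = 16,
    seed: int = 0,
):
    """Two split-half condition x voxel datasets with one reliable blob.

    Voxels inside the spherical blob share a condition-level signal across
    the two halves (split-half reliability ``signal_sd^2 / (signal_sd^2 +
    noise_sd^2)`` in expectation); voxels outside are independent noise.

    Returns ``(half1, half2, blob_mask)`` with halves shaped
    ``(n_participants, n_conditions, n_voxels)`` and the mask shaped like
    the grid.
    """
    if signal_sd == 0 and noise_sd == 0:
        raise ValueError("signal_sd and noise_sd cannot both be zero")
    grid_shape = tuple(int(s) for s in grid_shape)
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in grid_shape],
                                  indexing="ij"), axis=-1)
    dist = np.linalg.norm(coords - np.asarray(blob_center), axis=-1)
    blob = dist <= blob_radius
    if not blob.any():
        raise ValueError("blob does not fit in the grid")
    n_vox = int(np.prod(grid_shape))
    blob_flat = blob.ravel()
    rng = np.random.default_rng(seed)
    shape = (n_participants, n_conditions, n_vox)
    half1 = rng.normal(0.0, noise_sd, size=shape)
    half2 = rng.normal(0.0, noise_sd, size=shape)
    signal = rng.normal(0.0, signal_sd,
                        size=(n_participants, n_conditions, int(blob_flat.sum())))
    half1[:, :, blob_flat] += signal
    half2[:, :, blob_flat] += signal
    return half1, half2, blob
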