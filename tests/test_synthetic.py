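"""Generator behavior: determinism, closed forms, planted structure."""

import dataclasses
import itertools

import numpy as np
import pytest

import zeitgeist as zg
from zeitgeist.similarity import PatternMatrix, similarity_matrix


def corr_upper(mat):
    c = np.corrcoef(mat)
    return c[np.triu_indices_from(c, 1)]


class TestLoneliness:
    def test_deterministic_given_seed(self):
        cfg = zg.SyntheticConfig(seed=42)
        assert np.array_equal(zg.sample_loneliness(cfg),
                              zg.sample_loneliness(cfg))

    def test_truncation_forced(self):
        cfg = zg.SyntheticConfig(n_participants=500, loneliness_mean=40,
                                 loneliness_sd=9, loneliness_bounds=(20, 80),
                                 seed=0)
        x = zg.sample_loneliness(cfg)
        assert x.min() >= 20 and x.max() <= 80

    def test_large_sample_mean(self):
        # mild truncation at the default UCLA-style bounds barely shifts the
        # mean; 0.3 covers sd/sqrt(n) plus the truncation correction
        cfg = zg.SyntheticConfig(n_participants=10_000, loneliness_mean=40.7,
                                 loneliness_sd=8.3,
                                 loneliness_bounds=(16, 80), seed=3)
        assert abs(zg.sample_loneliness(cfg).mean() - 40.7) < 0.3

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            zg.SyntheticConfig(loneliness_bounds=(30, 30))


class TestPatterns:
    def test_noiseless_patterns_equal_prototype(self):
        cfg = zg.SyntheticConfig(n_participants=5, n_features=50,
                                 n_targets=2, base_noise_sd=0.0,
                                 noise_heterogeneity_sd=0.0, scenario="null",
                                 seed=1)
        ds = zg.generate_patterns(cfg)
        for mat in ds.patterns.values():
            assert np.allclose(mat, mat[0])
            assert np.allclose(corr_upper(mat), 1.0)

    def test_mean_pairwise_correlation_closed_form(self):
        """E[r] = var_p / (var_p + sigma^2) for additive independent noise."""
        cfg = zg.SyntheticConfig(n_participants=40, n_features=500,
                                 n_targets=2, prototype_sd=1.0,
                                 base_noise_sd=1.0,
                                 noise_heterogeneity_sd=0.0,
                                 scenario="null", seed=5)
        ds = zg.generate_patterns(cfg)
        rs = np.concatenate([corr_upper(m) for m in ds.patterns.values()])
        assert abs(rs.mean() - 0.5) < 0.03

    def test_closed_form_tracks_sigma_grid(self):
        for s0 in (0.5, 1.0, 2.0):
            cfg = zg.SyntheticConfig(n_participants=30, n_features=500,
                                     n_targets=2, prototype_sd=1.0,
                                     base_noise_sd=s0,
                                     noise_heterogeneity_sd=0.0,
                                     scenario="null", seed=int(s0 * 10))
            ds = zg.generate_patterns(cfg)
            rs = np.concatenate([corr_upper(m) for m in ds.patterns.values()])
            assert abs(rs.mean() - 1 / (1 + s0 ** 2)) < 0.04

    def test_null_similarity_independent_of_loneliness(self):
        """Across replicates, pair-mean loneliness and similarity decouple."""
        rs = []
        for seed in range(60):
            cfg = zg.SyntheticConfig(n_participants=15, n_features=100,
                                     n_targets=1, scenario="null", seed=seed)
            ds = zg.generate_patterns(cfg)
            sims = corr_upper(ds.patterns["T00"])
            pair_mean = np.array([(ds.loneliness[i] + ds.loneliness[j]) / 2
                                  for i, j in itertools.combinations(range(15), 2)])
            rs.append(np.corrcoef(pair_mean, sims)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_byte_identical_datasets(self):
        cfg = zg.SyntheticConfig(n_participants=8, n_features=30, n_targets=2,
                                 scenario="null", seed=9)
        a, b = zg.generate_patterns(cfg), zg.generate_patterns(cfg)
        for t in a.patterns:
            assert a.patterns[t].tobytes() == b.patterns[t].tobytes()

    def test_truth_roundtrips_config(self):
        cfg = zg.SyntheticConfig(n_participants=8, n_features=30, seed=2)
        ds = zg.generate_patterns(cfg)
        assert ds.truth["config"] == dataclasses.asdict(cfg)


class TestSlopeCalibration:
    def test_planted_effect_recovered(self):
        """Fitting the AK model on generated data recovers the planted
        standardized effect to first order."""
        from zeitgeist.inference import AnnaKareninaModel
        from zeitgeist.pipeline import build_dyad_table
        probe = zg.SyntheticConfig(scenario="ak", idiosyncrasy_slope=1e-9)
        slope = zg.slope_for_effect(-0.15, probe)
        betas = []
        for seed in range(20):
            cfg = zg.SyntheticConfig(scenario="ak", idiosyncrasy_slope=slope,
                                     seed=seed)
            m = AnnaKareninaModel(tail="two").fit(
                build_dyad_table(zg.generate_patterns(cfg)))
            betas.append(m.beta_)
        assert -0.25 < np.mean(betas) < -0.08

    def test_positive_effect_rejected(self):
        with pytest.raises(ValueError):
            zg.slope_for_effect(0.1, zg.SyntheticConfig())


class TestDissociation:
    def test_cluster_geometry(self):
        """Lonely are mutually similar yet far from the consensus."""
        from zeitgeist.consensus import ConsensusRepresentation
        hits = 0
        for seed in range(10):
            cfg = zg.SyntheticConfig(n_participants=24, n_features=200,
                                     n_targets=1, scenario="cluster",
                                     seed=seed)
            ds = zg.generate_dissociation_scenario(cfg)
            lon = ds.truth["lonely"]
            sim = similarity_matrix(PatternMatrix(
                ds.patterns["T00"], ds.participant_ids, "T00"))
            triu = np.triu_indices(lon.sum(), 1)
            within_lonely = sim[np.ix_(lon, lon)][triu].mean()
            grand = sim[np.triu_indices_from(sim, 1)].mean()
            pm = PatternMatrix(ds.patterns["T00"], ds.participant_ids, "T00")
            cons_sim = ConsensusRepresentation(random_state=seed).fit_transform(
                pm)["similarity"].values
            hits += (within_lonely >= grand
                     and cons_sim[lon].mean() < cons_sim[~lon].mean())
        assert hits >= 8  # majority rule over replicates

    def test_ring_geometry(self):
        """Lonely spread from each other at preserved distance-to-consensus."""
        gaps_cons, gaps_pair = [], []
        for seed in range(10):
            cfg = zg.SyntheticConfig(n_participants=24, n_features=200,
                                     n_targets=1, scenario="ring", seed=seed)
            ds = zg.generate_dissociation_scenario(cfg)
            lon = ds.truth["lonely"]
            pm = PatternMatrix(ds.patterns["T00"], ds.participant_ids, "T00")
            sim = similarity_matrix(pm)
            dist = 1 - sim
            kl = np.triu_indices(lon.sum(), 1)
            km = np.triu_indices((~lon).sum(), 1)
            wl = dist[np.ix_(lon, lon)][kl]
            wm = dist[np.ix_(~lon, ~lon)][km]
            pooled = np.concatenate([wl, wm]).std()
            gaps_pair.append((wl.mean() - wm.mean()) / pooled)
            # distance to the noise-free consensus (the true prototype)
            proto = ds.truth["prototypes"]["T00"]
            r = np.array([np.corrcoef(row, proto)[0, 1]
                          for row in ds.patterns["T00"]])
            d = 1 - r
            gaps_cons.append((d[lon].mean() - d[~lon].mean())
                             / d.std())
        assert np.mean(gaps_pair) > 0.5
        assert abs(np.mean(gaps_cons)) < 0.2

    def test_equal_scores_degenerate_to_single_cluster(self):
        cfg = zg.SyntheticConfig(n_participants=12, n_features=50,
                                 n_targets=1, scenario="cluster",
                                 loneliness_mean=40.0, loneliness_sd=0.0,
                                 seed=4)
        ds = zg.generate_dissociation_scenario(cfg)
        assert not ds.truth["lonely"].any()

    def test_too_few_participants_rejected(self):
        cfg = zg.SyntheticConfig(n_participants=5, scenario="ring")
        with pytest.raises(ValueError):
            zg.generate_dissociation_scenario(cfg)


class TestTraitResponses:
    def test_no_flips_no_missing_identical(self):
        cfg = zg.SyntheticConfig(n_participants=6, seed=0)
        r = zg.generate_trait_responses(cfg, np.full(40, 0.5), 0.0, 0.0)
        assert np.array_equal(r, np.tile(r[0], (6, 1)))

    def test_independent_uniform_jaccard_third(self):
        """Fair independent binary vectors give expected Jaccard 1/3."""
        cfg = zg.SyntheticConfig(n_participants=40, seed=1)
        r = zg.generate_trait_responses(cfg, np.full(400, 0.5), 0.5, 0.0)
        from zeitgeist.similarity import pairwise_similarity
        pm = PatternMatrix(r, [f"P{i}" for i in range(40)], "traits",
                           space="trait_binary")
        j = pairwise_similarity(pm, "jaccard")["similarity"]
        assert abs(j.mean() - 1 / 3) < 0.01

    def test_missingness_rate(self):
        cfg = zg.SyntheticConfig(n_participants=200, seed=2)
        r = zg.generate_trait_responses(cfg, np.full(50, 0.5), 0.1, 0.1)
        per_participant = np.isnan(r).sum(axis=1)
        assert abs(per_participant.mean() - 5.0) < 0.5

    def test_invalid_rates_rejected(self):
        cfg = zg.SyntheticConfig(n_participants=5)
        with pytest.raises(ValueError):
            zg.generate_trait_responses(cfg, np.full(10, 0.5), 1.5, 0.0)


class TestSplitHalfVolumes:
    def test_noiseless_blob_perfectly_reliable(self):
        h1n, h2n, blob = zg.generate_splithalf_volumes(
            (6, 6, 6), (3, 3, 3), 2.0, signal_sd=1.0, noise_sd=0.0,
            n_participants=4, n_conditions=16, seed=0)
        rel = zg.voxelwise_reliability_map(h1n, h2n, (6, 6, 6))
        assert np.allclose(rel[blob], 1.0)

    def test_outside_blob_near_zero(self):
        h1, h2, blob = zg.generate_splithalf_volumes(
            (5, 5, 4), (2, 2, 2), 1.5, signal_sd=1.0, noise_sd=1.0,
            n_participants=100, n_conditions=16, seed=1)
        rel = zg.voxelwise_reliability_map(h1, h2, (5, 5, 4))
        assert abs(rel[~blob].mean()) < 0.05

    def test_equal_signal_noise_reliability_half(self):
        """Split-half r = s^2/(s^2+n^2) = 0.5 at matched sds."""
        h1, h2, blob = zg.generate_splithalf_volumes(
            (5, 5, 4), (2, 2, 2), 1.5, signal_sd=1.0, noise_sd=1.0,
            n_participants=200, n_conditions=16, seed=2)
        rel = zg.voxelwise_reliability_map(h1, h2, (5, 5, 4))
        assert abs(rel[blob].mean() - 0.5) < 0.04

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            zg.generate_splithalf_volumes((4, 4, 4), (2, 2, 2), 1.5,
                                          signal_sd=0.0, noise_sd=0.0,
                                          n_participants=3, n_conditions=8,
                                          seed=0)
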