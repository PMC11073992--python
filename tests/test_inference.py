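"""Dyadic model assembly, doubling bookkeeping, tails, moderation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import zeitgeist as zg
from zeitgeist.inference import (AnnaKareninaModel, ModelSpec,
                                 build_doubled_dyads,
                                 compare_target_distributions,
                                 consensus_moderation, fit_mixed_model,
                                 median_split_targets, tail_adjust)
from zeitgeist.pipeline import build_dyad_table


def make_dyads(n, targets, fn, seed=0):
    rng = np.random.default_rng(seed)
    lon = rng.normal(0, 1, n)
    rows = []
    for t in range(targets):
        for i, j in itertools.combinations(range(n), 2):
            x = (lon[i] + lon[j]) / 2
            rows.append((f"P{i}", f"P{j}", f"T{t}", fn(i, j, t, x, rng), x))
    return pd.DataFrame(rows, columns=["participant1", "participant2",
                                       "target", "similarity",
                                       "mean_loneliness"])


class TestDoubling:
    def test_row_count_doubles(self):
        dyads = make_dyads(4, 1, lambda i, j, t, x, r: r.normal())
        assert len(dyads) == 6
        assert len(build_doubled_dyads(dyads)) == 12

    def test_twin_rows_share_pair_values(self):
        dyads = make_dyads(5, 2, lambda i, j, t, x, r: r.normal())
        doubled = build_doubled_dyads(dyads)
        key = doubled.set_index(["participant1", "participant2", "target"])
        for row in dyads.itertuples(index=False):
            twin = key.loc[(row.participant2, row.participant1, row.target)]
            assert twin.similarity == row.similarity
            assert twin.mean_loneliness == row.mean_loneliness

    def test_study_scale_bookkeeping(self):
        """40 participants x 5 targets: 780 pairs/target, 3900 undoubled,
        7800 doubled observations."""
        dyads = make_dyads(40, 5, lambda i, j, t, x, r: 0.0)
        assert len(dyads) == 780 * 5 == 3900
        assert len(build_doubled_dyads(dyads)) == 7800

    def test_already_doubled_rejected(self):
        dyads = make_dyads(4, 1, lambda i, j, t, x, r: 0.0)
        with pytest.raises(ValueError):
            build_doubled_dyads(build_doubled_dyads(dyads))


class TestTailAdjust:
    def test_symmetric_at_zero(self):
        assert tail_adjust(1.0, 0.0, "one_negative") == 0.5

    def test_matches_t_cdf(self):
        t = -1.645
        p_two = 2 * stats.t.sf(abs(t), 10_000)
        assert tail_adjust(p_two, t, "one_negative") == pytest.approx(
            0.05, abs=0.001)

    def test_wrong_direction_above_half(self):
        t = 3.0
        p_two = 2 * stats.t.sf(t, 50)
        p_one = tail_adjust(p_two, t, "one_negative")
        assert p_one == pytest.approx(1 - p_two / 2)
        assert p_one > 0.5

    def test_two_tailed_unset(self):
        assert tail_adjust(0.3, 1.0, "two") is None


class TestFitMixedModel:
    def test_constant_outcome_zero_betas(self):
        dyads = make_dyads(6, 2, lambda i, j, t, x, r: 1.0)
        spec = ModelSpec(outcome="similarity", fixed=["mean_loneliness"],
                         doubled=False,
                         random_intercepts=("participant1", "participant2"))
        fit = fit_mixed_model(dyads, spec)
        assert abs(fit.effect("mean_loneliness").beta) < 1e-8

    def test_ols_closed_form_without_random_variance(self):
        """Single target, no clustering: slope = OLS slope of z(y) on z(x)."""
        dyads = make_dyads(12, 1,
                           lambda i, j, t, x, r: -0.4 * x + r.normal(0, 0.3))
        spec = ModelSpec(outcome="similarity", fixed=["mean_loneliness"],
                         doubled=False,
                         random_intercepts=("participant1", "participant2"),
                         tail="two")
        fit = fit_mixed_model(dyads, spec)
        zy = (dyads.similarity - dyads.similarity.mean()) / dyads.similarity.std(ddof=0)
        zx = (dyads.mean_loneliness - dyads.mean_loneliness.mean()) \
            / dyads.mean_loneliness.std(ddof=0)
        beta_ols = float(np.polyfit(zx, zy, 1)[0])
        # clustering variance is small but estimated, so allow modest slack
        assert fit.effect("mean_loneliness").beta == pytest.approx(
            beta_ols, abs=0.02)

    def test_doubled_df_is_half_satterthwaite(self, crossed_dyads):
        model = AnnaKareninaModel(tail="one_negative").fit(crossed_dyads)
        eff = model.fit_.effect("mean_loneliness")
        assert eff.df_adj == pytest.approx(eff.df_sat / 2)
        assert eff.ci_low <= eff.beta <= eff.ci_high
        assert eff.p_one == pytest.approx(
            eff.p_two / 2 if eff.t < 0 else 1 - eff.p_two / 2)

    def test_doubling_preserves_point_estimate(self):
        """Doubling affects the information accounting, not the slope."""
        for seed in range(5):
            dyads = make_dyads(
                10, 2, lambda i, j, t, x, r: -0.3 * x + r.normal(0, 0.5),
                seed=seed)
            doubled = AnnaKareninaModel(doubled=True).fit(dyads)
            spec = ModelSpec(outcome="similarity", fixed=["mean_loneliness"],
                             random_intercepts=("participant1",
                                                "participant2", "target"),
                             doubled=False)
            undoubled = fit_mixed_model(dyads, spec)
            b1 = doubled.beta_
            b2 = undoubled.effect("mean_loneliness").beta
            assert np.sign(b1) == np.sign(b2)
            assert abs(b1 - b2) <= 0.05 * max(abs(b1), abs(b2))

    def test_flagged_rows_excluded(self):
        dyads = make_dyads(6, 1, lambda i, j, t, x, r: r.normal())
        dyads["flag_undefined"] = False
        dyads.loc[0, "flag_undefined"] = True
        spec = ModelSpec(outcome="similarity", fixed=["mean_loneliness"],
                         doubled=False,
                         random_intercepts=("participant1", "participant2"))
        fit = fit_mixed_model(dyads, spec)
        assert fit.n_obs == len(dyads) - 1


class TestModeration:
    def test_coding_attached_and_missing_target_rejected(self):
        dyads = make_dyads(8, 2, lambda i, j, t, x, r: r.normal())
        fit = consensus_moderation(dyads, {"T0": 1.0, "T1": -1.0})
        assert "mean_loneliness:consensus" in [e.name for e in fit.effects]
        with pytest.raises(ValueError):
            consensus_moderation(dyads, {"T0": 1.0})

    def test_null_interaction_when_slopes_equal(self):
        hits = 0
        for seed in range(25):
            dyads = make_dyads(
                15, 2, lambda i, j, t, x, r: -0.2 * x + r.normal(0, 0.5),
                seed=seed)
            fit = consensus_moderation(dyads, {"T0": 1.0, "T1": -1.0})
            eff = fit.effect("mean_loneliness:consensus")
            hits += abs(eff.beta) < 2 * eff.se
        assert hits >= 22

    def test_planted_interaction_detected_negative(self):
        hits = 0
        for seed in range(25):
            dyads = make_dyads(
                15, 2,
                lambda i, j, t, x, r: (-0.6 * x if t == 0 else 0.0)
                + r.normal(0, 0.5),
                seed=seed)
            fit = consensus_moderation(dyads, {"T0": 1.0, "T1": -1.0})
            hits += fit.effect("mean_loneliness:consensus").beta < 0
        assert hits >= 22


class TestTargetComparisons:
    def test_identical_distributions_null_beta(self):
        dyads = make_dyads(10, 2, lambda i, j, t, x, r: r.normal(0, 0.1))
        out = compare_target_distributions(dyads)
        assert len(out) == 1
        assert abs(out.beta.iloc[0]) < 0.2

    def test_planted_shift_recovered(self):
        betas = []
        for seed in range(10):
            dyads = make_dyads(
                12, 2, lambda i, j, t, x, r: 0.04 * t + r.normal(0, 0.04),
                seed=seed)
            out = compare_target_distributions(dyads)
            betas.append(out.beta.iloc[0])
        # 0.04 shift between targets, residual sd 0.04: the z-scored outcome
        # has sd sqrt(0.04^2 + 0.02^2) and the +-1 coded predictor moves the
        # mean by half the shift per unit, giving slope 0.02/0.0447 = 0.447
        assert np.mean(betas) == pytest.approx(0.447, rel=0.25)
        assert all(b > 0 for b in betas)

    def test_five_targets_give_ten_comparisons(self):
        dyads = make_dyads(6, 5, lambda i, j, t, x, r: r.normal())
        assert len(compare_target_distributions(dyads)) == 10

    def test_single_target_rejected(self):
        dyads = make_dyads(6, 1, lambda i, j, t, x, r: r.normal())
        with pytest.raises(ValueError):
            compare_target_distributions(dyads)


class TestMedianSplit:
    @staticmethod
    def dyads_with_means(means):
        rows = []
        for t, m in enumerate(means):
            rows += [(f"P{i}", f"P{i+1}", f"T{t:02d}", m)
                     for i in range(3)]
        return pd.DataFrame(rows, columns=["participant1", "participant2",
                                           "target", "similarity"])

    def test_even_split(self):
        labels = median_split_targets(self.dyads_with_means(range(1, 11)))
        assert sum(v == "high" for v in labels.values()) == 5
        assert labels["T09"] == "high" and labels["T00"] == "low"

    def test_odd_count_median_goes_high(self):
        labels = median_split_targets(self.dyads_with_means([1, 2, 3]))
        assert [labels[t] for t in ("T00", "T01", "T02")] == \
            ["low", "high", "high"]

    def test_tie_broken_by_label_order(self):
        labels = median_split_targets(self.dyads_with_means([0.5, 0.5]))
        assert labels["T00"] == "high" and labels["T01"] == "low"


class TestEndToEndRecovery:
    def test_planted_ak_effect_sign(self):
        from conftest import ak_dataset
        negative = 0
        for seed in range(10):
            _, dyads = ak_dataset(seed, n=30, targets=3, effect=-0.2)
            negative += AnnaKareninaModel().fit(dyads).beta_ < 0
        assert negative >= 9
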