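"""Two-phase scoring: decay fit, residual scores, significance, ranking."""

import math

import numpy as np
import pytest
from scipy import stats

from threedfunc.scoring import (
    FitModel,
    VariantGenePair,
    evaluate_ranking,
    fit_ec_ic,
    if_change,
    score_pairs,
    score_significance,
)


def make_pairs(ic, ec, cell_line="CL"):
    return [
        VariantGenePair(f"v{i}", f"g{i}", float(e), float(c), 0.0, cell_line)
        for i, (c, e) in enumerate(zip(ic, ec))
    ]


class TestIFChange:
    @pytest.mark.parametrize("ci,ni,expected", [(0.8, 0.3, 0.5), (0.3, 0.8, 0.5), (0.4, 0.4, 0.0)])
    def test_absolute_difference(self, ci, ni, expected):
        assert if_change(ci, ni) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            if_change(-0.1, 0.5)


class TestFit:
    def test_noiseless_recovery_to_machine_precision(self):
        ic = np.linspace(0, 2, 50)
        ec = 0.9 * np.exp(-ic / 0.5)
        model = fit_ec_ic(make_pairs(ic, ec))
        assert model.converged
        assert model.A == pytest.approx(0.9, abs=1e-6)
        assert model.tau == pytest.approx(0.5, abs=1e-6)
        assert model.rss < 1e-12

    def test_noisy_recovery_within_tolerance_across_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ic = rng.uniform(0, 2, 200)
            ec = 0.9 * np.exp(-ic / 0.5) + rng.normal(0, 0.02, 200)
            model = fit_ec_ic(make_pairs(ic, ec))
            assert model.converged
            assert abs(model.A - 0.9) < 0.05
            assert abs(model.tau - 0.5) < 0.05

    def test_rss_matches_independent_recomputation(self):
        rng = np.random.default_rng(4)
        ic = rng.uniform(0, 2, 80)
        ec = 0.8 * np.exp(-ic / 0.7) + rng.normal(0, 0.05, 80)
        pairs = make_pairs(ic, ec)
        model = fit_ec_ic(pairs)
        rss = sum((p.EC - model.A * math.exp(-p.IC / model.tau)) ** 2 for p in pairs)
        assert model.rss == pytest.approx(rss, abs=1e-9)
        assert model.residual_sd == pytest.approx(math.sqrt(rss / (len(pairs) - 2)))

    def test_constant_ec_hits_tau_cap_and_is_flagged(self):
        ic = np.linspace(0.1, 2, 30)
        ec = np.full(30, 0.4)
        model = fit_ec_ic(make_pairs(ic, ec))
        assert not model.converged
        assert model.tau == pytest.approx(100 * 2.0, rel=0.01)  # at the cap
        assert model.A == pytest.approx(0.4, abs=0.05)

    def test_too_few_pairs_or_degenerate_ic_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_ec_ic(make_pairs([0.1, 0.2], [0.5, 0.4]))
        with pytest.raises(ValueError, match="identical"):
            fit_ec_ic(make_pairs([0.5, 0.5, 0.5], [0.5, 0.4, 0.3]))


class TestScorePairs:
    @pytest.fixture
    def model(self):
        return FitModel(A=0.9, tau=0.5, rss=0.1, n_points=50, converged=True, residual_sd=0.05)

    def test_on_curve_pair_scores_zero(self, model):
        ic = 0.7
        pairs = make_pairs([ic], [0.9 * math.exp(-ic / 0.5)]) + make_pairs([0.1], [0.2])
        scored = score_pairs(model, pairs)
        assert scored[0].score == pytest.approx(0.0, abs=1e-12)

    def test_score_is_absolute_residual_with_sign_retained(self, model):
        # expected at IC=0: 0.9; observed 0.2 -> score 0.7, signed +0.7
        scored = score_pairs(model, make_pairs([0.0], [0.2]))
        assert scored[0].expected_EC == pytest.approx(0.9)
        assert scored[0].score == pytest.approx(0.7)
        assert scored[0].signed_residual == pytest.approx(0.7)

    def test_ranks_are_a_permutation_and_order_invariant(self, model):
        rng = np.random.default_rng(8)
        pairs = make_pairs(rng.uniform(0, 2, 40), rng.uniform(0, 1, 40))
        scored = score_pairs(model, pairs)
        assert sorted(s.rank for s in scored) == list(range(1, 41))
        by_id = {s.pair.variant_id: s.score for s in scored}
        reordered = score_pairs(model, pairs[::-1])
        assert {s.pair.variant_id: s.score for s in reordered} == by_id
        n_top = sum(s.top_decile for s in scored)
        assert n_top == math.ceil(0.1 * 40)

    def test_idempotent_and_side_effect_free(self, model):
        pairs = make_pairs([0.1, 0.5, 1.0], [0.8, 0.5, 0.2])
        first = score_pairs(model, pairs)
        second = score_pairs(model, pairs)
        assert first == second

    def test_unconverged_model_requires_force(self, model):
        from dataclasses import replace

        bad = replace(model, converged=False)
        pairs = make_pairs([0.1], [0.5])
        with pytest.raises(ValueError, match="force"):
            score_pairs(bad, pairs)
        assert score_pairs(bad, pairs, force=True)


class TestSignificance:
    @pytest.fixture
    def model(self):
        return FitModel(A=0.9, tau=0.5, rss=0.1, n_points=50, converged=True, residual_sd=0.1)

    def test_zero_residual_gives_p_one(self, model):
        ic = 1.0
        scored = score_pairs(model, make_pairs([ic, 0.2, 0.4], [0.9 * math.exp(-ic / 0.5), 0.3, 0.5]))
        out = score_significance(scored, model)
        assert out[0].p_value == pytest.approx(1.0)

    def test_chi_square_quantile(self, model):
        # z^2 = 3.841 is the 95th percentile of chi-square(1): p ~ 0.05
        z = math.sqrt(stats.chi2.ppf(0.95, 1))
        residual = z * model.residual_sd
        ic = 0.5
        scored = score_pairs(model, make_pairs([ic], [0.9 * math.exp(-ic / 0.5) - residual]))
        out = score_significance(scored, model)
        assert out[0].p_value == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_residual_magnitude(self, model):
        scored = score_pairs(model, make_pairs([0.0, 0.0, 0.0], [0.8, 0.6, 0.3]))
        out = sorted(score_significance(scored, model), key=lambda s: s.score)
        assert out[0].p_value > out[1].p_value > out[2].p_value

    def test_zero_residual_sd_warns_and_returns_ones(self, model):
        from dataclasses import replace

        flat = replace(model, residual_sd=0.0)
        scored = score_pairs(model, make_pairs([0.1], [0.5]))
        with pytest.warns(UserWarning, match="residual SD"):
            out = score_significance(scored, flat)
        assert out[0].p_value == 1.0


class TestEvaluateRanking:
    def _scored(self, scores):
        model = FitModel(A=1.0, tau=1.0, rss=1.0, n_points=len(scores), converged=True, residual_sd=0.1)
        # build pairs whose |expected - EC| equals the requested scores at IC=0
        pairs = make_pairs([0.0] * len(scores), [1.0 - s for s in scores])
        return score_pairs(model, pairs)

    def test_perfect_separation_gives_auroc_one(self):
        scored = self._scored([0.9, 0.8, 0.7, 0.2, 0.1])
        metrics = evaluate_ranking(scored, [True, True, True, False, False])
        assert metrics["auroc"] == 1.0
        assert metrics["auprc"] == 1.0

    def test_top_decile_bucket_arithmetic(self):
        # 10 pairs -> top bucket of ceil(1) = 1; lone causal pair ranked first
        scores = [0.9] + [0.1 * i / 10 for i in range(9)]
        labels = [True] + [False] * 9
        metrics = evaluate_ranking(self._scored(scores), labels)
        assert metrics["top_decile_causal_fraction"] == 1.0

    def test_label_free_scores_give_chance_auroc(self):
        rng = np.random.default_rng(99)
        aurocs = []
        for seed in range(20):
            rng_i = np.random.default_rng(seed)
            scored = self._scored(rng_i.uniform(0, 1, 200))
            labels = rng_i.random(200) < 0.3
            if labels.all() or not labels.any():
                continue
            aurocs.append(evaluate_ranking(scored, labels.tolist())["auroc"])
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_labels_rejected(self):
        scored = self._scored([0.5, 0.4])
        with pytest.raises(ValueError):
            evaluate_ranking(scored, [True, True])


class TestPlantedOutlierRecovery:
    def test_displaced_pairs_dominate_top_decile(self):
        """Pairs displaced off the decay curve must be recovered by rank."""
        recovered, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            ic = rng.uniform(0, 2, n)
            ec = 0.9 * np.exp(-ic / 0.5) + rng.normal(0, 0.02, n)
            displaced = rng.choice(n, size=10, replace=False)
            for i in displaced:
                ec[i] += 0.4 if ec[i] + 0.4 < 0.995 else -0.4
            ec = np.clip(ec, 1e-4, 1 - 1e-4)
            pairs = make_pairs(ic, ec)
            model = fit_ec_ic(pairs)
            scored = score_pairs(model, pairs, force=True)
            in_top = {s.pair.variant_id for s in scored if s.top_decile}
            recovered += sum(1 for i in displaced if f"v{i}" in in_top)
            total += len(displaced)
        assert recovered / total >= 0.9
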