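import numpy as np
import pandas as pd
import pytest

import rpskit as rk
from rpskit.scoring import (
    foreground_background,
    median_center,
    raw_deviation,
    score_cohort,
    score_sample,
    scores_to_frame,
)


def brute_force_deviation(e, w):
    """Reference implementation with explicit loops (no vectorization)."""
    g = len(e)
    fg_total = sum(e[k] * w[k] for k in range(g))
    bg_total = sum(e[k] * (1 - w[k]) for k in range(g))
    best = 0.0
    best_abs = -1.0
    fg = 0.0
    bg = 0.0
    for i in range(g):
        fg += e[i] * w[i]
        bg += e[i] * (1 - w[i])
        d = fg / fg_total - bg / bg_total
        if abs(d) > best_abs:
            best_abs = abs(d)
            best = d
    return best


class TestMedianCenter:
    def test_odd_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(median_center(m).iloc[0], [-1, 0, 1])

    def test_constant_row(self):
        m = pd.DataFrame([[4.0, 4.0, 4.0]])
        np.testing.assert_allclose(median_center(m).iloc[0], [0, 0, 0])

    def test_even_row_uses_middle_pair_mean(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]])
        np.testing.assert_allclose(median_center(m).iloc[0], [-1.5, -0.5, 0.5, 1.5])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            median_center(pd.DataFrame([[1.0]]))


class TestForegroundBackground:
    def test_top_loaded_weight(self):
        f, b = foreground_background([4, 3, 2, 1], [1, 0, 0, 0])
        np.testing.assert_allclose(f, [1, 1, 1, 1])
        np.testing.assert_allclose(b, [0, 0.5, 5 / 6, 1])

    def test_bottom_loaded_weight(self):
        f, b = foreground_background([4, 3, 2, 1], [0, 0, 0, 1])
        np.testing.assert_allclose(f, [0, 0, 0, 1])
        np.testing.assert_allclose(b, [4 / 9, 7 / 9, 1, 1])

    def test_uniform_weights_collapse(self):
        f, b = foreground_background([5, 4, 1], [0.3, 0.3, 0.3])
        np.testing.assert_allclose(f, b)

    def test_curves_end_at_one(self, rng):
        e = np.sort(rng.random(50))[::-1]
        w = rng.random(50)
        f, b = foreground_background(e, w)
        assert f[-1] == pytest.approx(1.0)
        assert b[-1] == pytest.approx(1.0)

    def test_ascending_input_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            foreground_background([1, 2, 3], [1, 0, 0])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="empty signature side"):
            foreground_background([3, 2, 1], [0, 0, 0])


class TestRawDeviation:
    def test_positive_worked_example(self):
        f, b = foreground_background([4, 3, 2, 1], [1, 0, 0, 0])
        assert raw_deviation(f, b) == pytest.approx(1.0)

    def test_negative_worked_example(self):
        f, b = foreground_background([4, 3, 2, 1], [0, 0, 0, 1])
        assert raw_deviation(f, b) == pytest.approx(-1.0)

    def test_identical_curves(self):
        assert raw_deviation([0.2, 1.0], [0.2, 1.0]) == 0.0

    def test_max_signed_mode(self):
        f = np.array([0.0, 0.3, 1.0])
        b = np.array([0.5, 0.2, 1.0])
        assert raw_deviation(f, b) == pytest.approx(-0.5)
        assert raw_deviation(f, b, mode="max_signed") == pytest.approx(0.1)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            e = np.sort(rng.random(100))[::-1]
            w = (rng.random(100) < 0.2) * rng.random(100)
            if not w.any():
                w[0] = 0.5
            expected = brute_force_deviation(e, w)
            got = raw_deviation(*foreground_background(e, w))
            assert got == pytest.approx(expected, abs=1e-12)


def weights_frame(n, rng, frac=0.15):
    w_plus = np.where(rng.random(n) < frac, rng.random(n), 0.0)
    w_minus = np.where((rng.random(n) < frac) & (w_plus == 0), rng.random(n), 0.0)
    w_plus[0] = max(w_plus[0], 0.5)
    w_minus[1] = max(w_minus[1], 0.5)
    return pd.DataFrame(
        {"w_plus": w_plus, "w_minus": w_minus},
        index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
    )


class TestScoreSample:
    def test_uniform_weights_score_zero(self, rng):
        n = 60
        w = pd.DataFrame(
            {"w_plus": np.full(n, 0.4), "w_minus": np.full(n, 0.4)},
            index=[f"g{i}" for i in range(n)],
        )
        profile = pd.Series(rng.normal(size=n), index=w.index)
        s = score_sample(profile, w, n_perm=50, seed=1)
        assert s.raw_plus == pytest.approx(0.0, abs=1e-12)
        assert s.rps == 0.0

    def test_planted_profile_scores_extreme(self, rng):
        w = weights_frame(200, rng)
        # up-weighted genes on top, down-weighted at the bottom
        up = w.index[w["w_plus"] > 0]
        down = w.index[w["w_minus"] > 0]
        rest = w.index.difference(up.union(down))
        values = {}
        for i, g in enumerate(up):
            values[g] = 10.0 - i * 0.01
        for i, g in enumerate(rest):
            values[g] = 5.0 - i * 0.01
        for i, g in enumerate(down):
            values[g] = 1.0 - i * 0.01
        profile = pd.Series(values).reindex(w.index)
        s = score_sample(profile, w, n_perm=300, seed=2)
        null_rps = []
        for k in range(200):
            perm = pd.Series(
                np.random.default_rng(k).permutation(profile.to_numpy()),
                index=profile.index,
            )
            null_rps.append(score_sample(perm, w, n_perm=100, seed=k).rps)
        assert s.rps_plus > 0
        assert s.rps_minus < 0
        assert s.rps > np.quantile(null_rps, 0.99)

    def test_seed_reproducibility(self, rng):
        w = weights_frame(100, rng)
        profile = pd.Series(rng.normal(size=100), index=w.index)
        a = score_sample(profile, w, n_perm=100, seed=9)
        b = score_sample(profile, w, n_perm=100, seed=9)
        assert a == b

    def test_no_overlap_rejected(self, rng):
        w = weights_frame(10, rng)
        profile = pd.Series([1.0], index=["other"])
        with pytest.raises(ValueError, match="shared"):
            score_sample(profile, w, n_perm=10, seed=0)

    def test_empty_side_rejected(self, rng):
        w = weights_frame(60, rng)
        w["w_minus"] = 0.0
        profile = pd.Series(rng.normal(size=60), index=w.index)
        with pytest.raises(ValueError, match="w_minus"):
            score_sample(profile, w, n_perm=10, seed=0)

    def test_rps_is_exact_difference(self, rng):
        w = weights_frame(80, rng)
        profile = pd.Series(rng.normal(size=80), index=w.index)
        s = score_sample(profile, w, n_perm=100, seed=4)
        assert s.rps == s.rps_plus - s.rps_minus


class TestScoreCohort:
    def test_duplicate_samples_get_identical_scores(self, rng):
        w = weights_frame(120, rng)
        col = rng.normal(size=120)
        m = pd.DataFrame(
            {f"s{i}": col for i in range(2)}
            | {f"other{i}": rng.normal(size=120) for i in range(8)},
            index=w.index,
        )
        frame = scores_to_frame(score_cohort(m, w, n_perm=100, seed=6))
        dup = frame.loc[["s0", "s1"]]
        assert dup["rps"].abs().iloc[0] > 0
        assert (dup.iloc[0] == dup.iloc[1]).all()

    def test_gene_order_invariance(self, rng):
        w = weights_frame(90, rng)
        m = pd.DataFrame(rng.normal(size=(90, 4)), index=w.index,
                         columns=list("abcd"))
        shuffled = m.sample(frac=1.0, random_state=1)
        a = scores_to_frame(score_cohort(m, w, n_perm=100, seed=8))
        b = scores_to_frame(score_cohort(shuffled, w, n_perm=100, seed=8))
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_order_invariance(self, rng):
        w = weights_frame(90, rng)
        m = pd.DataFrame(rng.normal(size=(90, 4)), index=w.index,
                         columns=list("abcd"))
        a = scores_to_frame(score_cohort(m, w, n_perm=100, seed=8))
        b = scores_to_frame(score_cohort(m[list("dcba")], w, n_perm=100, seed=8))
        pd.testing.assert_frame_equal(a.loc[list("abcd")], b.loc[list("abcd")])

    def test_planted_cohort_separates_classes(self, small_cohort, fitted_weights):
        from rpskit.evaluation import rank_sum_test

        expr, ann, _ = small_cohort
        frame = scores_to_frame(
            score_cohort(expr, fitted_weights, n_perm=200, seed=3)
        )
        rps = frame["rps"]
        pcr = rps[ann["response"] == "pCR"]
        rd = rps[ann["response"] == "RD"]
        assert pcr.mean() > rd.mean()
        assert rank_sum_test(pcr, rd) < 0.01

    def test_monotone_in_effect_size(self):
        diffs = []
        for effect in (0.0, 0.5, 1.0, 1.5, 2.0):
            cfg = rk.SimulationConfig(
                n_genes=200, n_samples=40, n_de_genes=30,
                effect_size=effect, seed=13,
            )
            expr, ann, _ = rk.simulate_cohort(cfg)
            w = rk.build_weight_profiles(rk.fit_logistic_weights(expr, ann["response"]))
            frame = scores_to_frame(score_cohort(expr, w, n_perm=100, seed=2))
            rps = frame["rps"]
            diffs.append(
                rps[ann["response"] == "pCR"].mean()
                - rps[ann["response"] == "RD"].mean()
            )
        assert (np.diff(diffs) > 0).all()
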