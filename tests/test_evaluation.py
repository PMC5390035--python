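import numpy as np
import pytest
from scipy.stats import hypergeom

import cdr3boost.evaluation as ev
from cdr3boost.evaluation import (
    clopper_pearson,
    fisher_exact_2x2,
    loo_classify,
    randomized_label_control,
    two_stage_classify,
    vj_usage_compare,
)
from cdr3boost.repertoires import Cdr3, Repertoire


def fisher_oracle(table):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestFisher:
    def test_perfect_separation(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_independence(self):
        assert fisher_exact_2x2([[3, 3], [3, 3]]) == pytest.approx(1.0)

    def test_tiny_margins(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(50):
            table = rng.integers(0, 6, size=(2, 2))
            if table.sum() == 0:
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_oracle(table), abs=1e-9
            )


def test_clopper_pearson_brackets_the_estimate():
    lo, hi = clopper_pearson(8, 12)
    assert lo < 8 / 12 < hi
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0


class TestLooClassify:
    def test_signal_cohort_is_classified(self, signal_loo):
        result, models = signal_loo
        assert result.n_total == 12
        assert result.n_correct >= 10
        assert all(m.converged for m in models)

    def test_votes_sum_to_n_samples_and_never_tie(self, signal_loo):
        result, _ = signal_loo
        for true, pred, vp, vn in result.per_mouse.values():
            assert vp + vn == 99
            assert vp != vn  # odd vote count cannot tie
            assert pred == (1 if vp > vn else -1)
            assert true in (-1, 1)

    def test_accuracy_bookkeeping(self, signal_loo):
        result, _ = signal_loo
        assert result.accuracy == result.n_correct / result.n_total
        assert result.table.sum() == result.n_total
        assert result.ci95[0] <= result.accuracy <= result.ci95[1]

    def test_requires_two_mice_per_class(self):
        reps = [
            Repertoire("a", +1, [Cdr3("CASAF", 1), Cdr3("CASWF", 1)]),
            Repertoire("b", -1, [Cdr3("CASCF", 1), Cdr3("CASMF", 1)]),
        ]
        from cdr3boost.repertoires import Cohort

        with pytest.raises(ValueError):
            loo_classify(Cohort(reps))

    def test_filters_restrict_eligible_sequences(self, small_null_cohort):
        cohort, _, _ = small_null_cohort
        # singlets: runs on count==1 clones only, reducing sample_size as needed
        res = loo_classify(
            cohort, filter="singlets", n_samples=3, sample_size=10_000, seed=0,
            max_iter=30,
        )
        assert res.n_total == cohort.m

    def test_top5_forces_single_whole_set_sample(self, small_null_cohort):
        cohort, _, _ = small_null_cohort
        res = loo_classify(cohort, filter="top5", n_samples=9, seed=0, max_iter=30)
        for _true, _pred, vp, vn in res.per_mouse.values():
            assert vp + vn == 1


class TestTwoStage:
    def test_two_stage_runs_and_matches_stage1_on_strong_signal(self, signal_cohort):
        cohort, _, _ = signal_cohort
        res = two_stage_classify(cohort, n_samples=9, sample_size=500, seed=3)
        assert res.n_correct >= 9

    def test_zero_selected_columns_falls_back_to_majority(self, monkeypatch, rng):
        def fake_train(F, y, **kwargs):
            from cdr3boost.lpboost import LPBoostModel

            return LPBoostModel(
                p=3, columns=[(0, 1)], a=np.zeros(1), rho=0.0, beta=0.0, D=0.5,
                theta=0.0, xi=np.zeros(len(y)), u=np.full(len(y), 1 / len(y)),
                converged=True, n_iter=1, duality_gap=0.0,
            )

        monkeypatch.setattr(ev.lpboost, "lpboost_train", fake_train)
        F = rng.random((8, 10))
        y = np.array([1, 1, 1, 1, 1, -1, -1, -1])
        preds, _ = ev._train_predict(
            F, y, rng.random((4, 10)), "lpboost_svm", None, 0.5, 1.0, "linear", 3, 10
        )
        np.testing.assert_array_equal(preds, np.ones(4))


class TestRandomizedLabels:
    def test_deterministic_given_seed(self, small_null_cohort):
        cohort, _, _ = small_null_cohort
        kwargs = dict(n_permutations=2, n_samples=3, sample_size=50, max_iter=40)
        a = randomized_label_control(cohort, seed=4, **kwargs)
        b = randomized_label_control(cohort, seed=4, **kwargs)
        assert a == b and len(a) == 2

    def test_accuracies_are_valid_fractions(self, small_null_cohort):
        cohort, _, _ = small_null_cohort
        accs = randomized_label_control(
            cohort, n_permutations=3, seed=1, n_samples=3, sample_size=50, max_iter=40
        )
        assert all(0 <= a <= 1 for a in accs)


class TestBalancedTrainingRows:
    def test_classes_are_balanced_after_trimming(self):
        blocks = [np.ones((5, 2)) * i for i in range(5)]
        labels = np.array([1, 1, 1, -1, -1])
        F, y = ev._balanced_training_rows(blocks, labels, hold=4)
        # training mice: 3 pos (15 rows) vs 1 neg (5 rows) -> trim pos to 5
        assert (y == 1).sum() == (y == -1).sum() == 5
        assert len(F) == 10


class TestVjUsage:
    def make_rep(self, mouse_id, genes_counts):
        clones = [
            Cdr3(f"CAS{a}{i}F".replace(str(i), "AFWY"[i % 4]), c, v_gene=g, j_gene="TRBJ1")
            for i, (a, g, c) in enumerate(genes_counts)
        ]
        return Repertoire(mouse_id, +1, clones)

    def test_single_gene_has_frequency_one_sd_zero(self):
        rep = Repertoire(
            "a", +1, [Cdr3("CASWF", 5, v_gene="TRBV1", j_gene="TRBJ1")]
        )
        out = vj_usage_compare([rep], [rep], n_resamples=5, resample_size=100, seed=0)
        assert out["mean_a"].tolist() == [1.0]
        assert out["sd_a"].tolist() == [0.0]

    def test_identical_pools_have_close_means(self):
        rep = self.make_rep(
            "a",
            [("A", "TRBV1", 30), ("C", "TRBV2", 30), ("D", "TRBV3", 40)],
        )
        out = vj_usage_compare([rep], [rep], n_resamples=20, resample_size=500, seed=1)
        gap = (out["mean_a"] - out["mean_b"]).abs()
        assert (gap < 3 * (out["sd_a"] + out["sd_b"]) + 1e-12).all()

    def test_missing_annotation_raises_with_mouse_id(self):
        rep = Repertoire("nogene", +1, [Cdr3("CASWF", 1)])
        with pytest.raises(ValueError, match="nogene"):
            vj_usage_compare([rep], [rep])

    def test_resample_size_one_matches_pool_frequency(self):
        rep = self.make_rep("a", [("A", "TRBV1", 80), ("C", "TRBV2", 20)])
        out = vj_usage_compare([rep], [rep], n_resamples=200, resample_size=1, seed=2)
        trbv1 = out.set_index("gene").loc["TRBV1"]
        assert trbv1["mean_a"] == pytest.approx(0.8, abs=0.12)
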