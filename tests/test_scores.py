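import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from gragp.data_io import LabelVector, ValidationError
from gragp.scores import (
    ClassSummary,
    auc_score,
    bhattacharyya_score,
    entropy_score,
    raw_auc,
    score_all,
    t_score,
    wilcoxon_score,
)
from gragp.voom import TransformedMatrix


def _tm(values, sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return TransformedMatrix(
        values,
        np.ones_like(values),
        np.ones((values.shape[1], 1)),
        [f"g{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )


class TestClosedFormValues:
    def test_t_on_separated_triples(self):
        s = ClassSummary.from_samples([1, 2, 3], [4, 5, 6])
        assert t_score(s) == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)

    def test_t_zero_for_equal_means(self):
        assert t_score(ClassSummary(1.0, 1.0, 0.5, 0.7, 3, 3)) == 0.0

    def test_t_capped_on_perfect_separation(self):
        assert t_score(ClassSummary(0.0, 1.0, 0.0, 0.0, 3, 3)) == 1e8

    def test_entropy_unit_shift(self):
        assert entropy_score(ClassSummary(0.0, 1.0, 1.0, 1.0, 3, 3)) == pytest.approx(1.0, abs=1e-10)

    def test_entropy_variance_only(self):
        assert entropy_score(ClassSummary(0.0, 0.0, 2.0, 1.0, 3, 3)) == pytest.approx(1.125, abs=1e-10)

    def test_entropy_identity_case(self):
        assert entropy_score(ClassSummary(0.5, 0.5, 1.0, 1.0, 3, 3)) == 0.0

    def test_bhattacharyya_mean_shift(self):
        assert bhattacharyya_score(ClassSummary(0.0, 2.0, 1.0, 1.0, 3, 3)) == pytest.approx(0.5, abs=1e-10)

    def test_bhattacharyya_variance_only(self):
        want = 0.25 * np.log(1.5625)
        assert bhattacharyya_score(ClassSummary(0.0, 0.0, 2.0, 1.0, 3, 3)) == pytest.approx(want, abs=1e-10)

    def test_bhattacharyya_identity_case(self):
        assert bhattacharyya_score(ClassSummary(0.0, 0.0, 1.0, 1.0, 3, 3)) == pytest.approx(0.0, abs=1e-12)

    def test_wilcoxon_separated_triples(self):
        # W = 6, E[W] = 10.5, var = 3*3*7/12 = 5.25
        assert wilcoxon_score([1, 2, 3], [4, 5, 6]) == pytest.approx(4.5 / np.sqrt(5.25), abs=1e-10)

    def test_wilcoxon_interleaved_pairs(self):
        # W = 4, E[W] = 5, var = 2*2*5/12 = 5/3 per the tie-corrected formula
        assert wilcoxon_score([1, 3], [2, 4]) == pytest.approx(1.0 / np.sqrt(5.0 / 3.0), abs=1e-10)

    def test_wilcoxon_all_identical_is_zero(self):
        assert wilcoxon_score([2, 2, 2], [2, 2]) == 0.0

    def test_auc_perfect_separation(self):
        assert auc_score([1, 2], [5, 6]) == 1.0

    def test_auc_two_plus_two(self):
        assert auc_score([1, 3], [2, 4]) == pytest.approx(0.75, abs=1e-12)

    def test_auc_identical_multisets(self):
        assert auc_score([1, 2, 3], [1, 2, 3]) == 0.5

    def test_auc_folds_direction(self):
        assert auc_score([5, 6], [1, 2]) == 1.0  # raw AUC 0 folds to 1


class TestInvariances:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        # integer-valued data keeps shifts exact in floating point, so the
        # invariance can be asserted tightly
        data=st.lists(st.integers(-50, 50), min_size=4, max_size=12),
        shift=st.integers(-100, 100),
    )
    def test_label_swap_and_shift(self, data, shift):
        half = len(data) // 2
        x1 = np.array(data[:half], dtype=float)
        x2 = np.array(data[half:], dtype=float)
        if x1.size < 2 or x2.size < 2:
            return
        s12 = ClassSummary.from_samples(x1, x2)
        s21 = ClassSummary.from_samples(x2, x1)
        assert t_score(s12) == pytest.approx(t_score(s21), rel=1e-9, abs=1e-12)
        assert entropy_score(s12) == pytest.approx(entropy_score(s21), rel=1e-9, abs=1e-12)
        assert bhattacharyya_score(s12) == pytest.approx(bhattacharyya_score(s21), rel=1e-9, abs=1e-12)
        assert wilcoxon_score(x1, x2) == pytest.approx(wilcoxon_score(x2, x1), abs=1e-9)
        assert auc_score(x1, x2) == pytest.approx(auc_score(x2, x1), abs=1e-12)
        # shift invariance of the moment scores
        s_shift = ClassSummary.from_samples(x1 + shift, x2 + shift)
        assert t_score(s_shift) == pytest.approx(t_score(s12), rel=1e-6, abs=1e-8)
        assert wilcoxon_score(x1 + shift, x2 + shift) == pytest.approx(wilcoxon_score(x1, x2), abs=1e-9)

    def test_rank_scores_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        f = np.expm1  # strictly increasing
        assert wilcoxon_score(f(x1), f(x2)) == pytest.approx(wilcoxon_score(x1, x2), abs=1e-12)
        assert auc_score(f(x1), f(x2)) == pytest.approx(auc_score(x1, x2), abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_equals_mann_whitney_u(self, seed):
        """Empirical AUC must equal U / (n1*n2) from the rank-sum machinery."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, size=2)
        x1 = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        x2 = rng.integers(0, 6, size=n2).astype(float)
        u2 = mannwhitneyu(x2, x1, alternative="two-sided").statistic
        assert raw_auc(x1, x2) == pytest.approx(u2 / (n1 * n2), abs=1e-12)

    def test_raw_auc_matches_sklearn(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)
        y = np.r_[np.zeros(20), np.ones(25)]
        assert raw_auc(x1, x2) == pytest.approx(roc_auc_score(y, np.r_[x1, x2]), abs=1e-12)


class TestScoreAll:
    def test_separated_gene_beats_null_gene_everywhere(self):
        values = np.array(
            [
                [0.0, 0.5, 1.0, 5.0, 5.5, 6.0],  # separated
                [1.0, 2.0, 3.0, 1.2, 2.1, 2.9],  # overlapping
            ]
        )
        labels = LabelVector(np.repeat([0, 1], 3), ("A", "B"))
        table = score_all(_tm(values), labels)
        assert np.all(table.scores[0] > table.scores[1])

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(20, 10))
        labels = LabelVector(np.array([0, 1] * 5), ("A", "B"))
        perm = rng.permutation(10)
        t1 = score_all(_tm(values), labels)
        t2 = score_all(_tm(values[:, perm]), LabelVector(labels.labels[perm], ("A", "B")))
        assert np.allclose(t1.scores, t2.scores)

    def test_matches_scalar_recomputation_on_simulation(self, sim_study):
        cm, labels, _ = sim_study
        from gragp.voom import voom

        tm = voom(cm, labels)
        table = score_all(tm, labels)
        v1 = tm.values[:, labels.labels == 0]
        v2 = tm.values[:, labels.labels == 1]
        for g in range(0, cm.n_genes, 7):  # spot-check a spread of genes
            s = ClassSummary.from_samples(v1[g], v2[g])
            expected = [
                t_score(s),
                entropy_score(s),
                bhattacharyya_score(s),
                wilcoxon_score(v1[g], v2[g]),
                auc_score(v1[g], v2[g]),
            ]
            assert np.allclose(table.scores[g], expected, rtol=1e-9, atol=1e-9)

    def test_constant_criterion_raises_naming_it(self):
        values = np.tile(np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]), (5, 1))
        labels = LabelVector(np.repeat([0, 1], 3), ("A", "B"))
        with pytest.raises(ValidationError, match="criterion"):
            score_all(_tm(values), labels)

    def test_too_small_class_rejected(self):
        values = np.random.default_rng(0).normal(size=(12, 3))
        labels = LabelVector(np.array([0, 1, 1]), ("A", "B"))
        with pytest.raises(ValidationError):
            score_all(_tm(values), labels)
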