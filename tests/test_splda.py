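import numpy as np
import pytest

from gragp.data_io import CountMatrix, LabelVector, ValidationError
from gragp.splda import (
    SpldaModel,
    default_rho_grid,
    estimate_dkj,
    size_factors_median_ratio,
    size_factors_quantile,
    size_factors_total,
    soft_threshold_dkj,
    splda_classify,
    splda_fit,
    splda_predict,
    splda_tune_rho,
)


def _cm(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
    )


class TestSizeFactorsTotal:
    def test_direct_evaluation(self):
        cm = _cm([[1, 10, 20], [5, 14, 10]])  # totals 6, 24, 30; grand 60
        si = size_factors_total(cm)
        assert si[0] == pytest.approx(0.1)

    def test_training_factors_sum_to_one(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.integers(1, 100, size=(20, 7)))
        assert size_factors_total(cm).sum() == pytest.approx(1.0)

    def test_test_profile_equal_to_training_sample(self):
        cm = _cm([[2, 4], [6, 8]])
        si, s_star = size_factors_total(cm, cm.counts[:, 0])
        assert s_star == pytest.approx(si[0])

    def test_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            size_factors_total(_cm([[0, 1], [0, 2]]))


class TestSizeFactorsMedianRatio:
    def test_identical_samples_share_factor(self):
        cm = _cm([[3, 3], [7, 7]])
        si = size_factors_median_ratio(cm)
        assert np.allclose(si, 0.5)

    def test_doubled_sample_doubles_factor(self):
        cm = _cm([[2, 4], [10, 20]])
        si = size_factors_median_ratio(cm)
        assert si[1] / si[0] == pytest.approx(2.0)

    def test_genes_with_zero_excluded_from_reference(self):
        # gene 1 has a zero, so only gene 0 anchors the medians
        cm = _cm([[2, 4], [0, 100]])
        si = size_factors_median_ratio(cm)
        geo = np.sqrt(2.0 * 4.0)
        m = np.array([2.0 / geo, 4.0 / geo])
        assert np.allclose(si, m / m.sum())

    def test_no_all_positive_gene_rejected(self):
        with pytest.raises(ValidationError, match="total-count"):
            size_factors_median_ratio(_cm([[0, 1], [1, 0]]))


class TestSizeFactorsQuantile:
    def test_identical_samples(self):
        cm = _cm(np.tile([[1], [5], [9]], (1, 3)))
        assert np.allclose(size_factors_quantile(cm), 1.0 / 3.0)

    def test_doubling_doubles_quantile(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 50, size=(40, 1))
        cm = _cm(np.hstack([base, 2 * base]))
        si = size_factors_quantile(cm)
        assert si[1] / si[0] == pytest.approx(2.0)

    def test_percentile_convention_matches_scalar_oracle(self):
        counts = np.arange(8).reshape(-1, 1)  # {0..7}
        cm = _cm(np.hstack([counts + 1, counts + 1]))
        si, q_star = size_factors_quantile(cm, counts.ravel() + 1)
        # linear interpolation: 75th percentile of {1..8} = 6.25
        sorted_x = np.arange(1, 9, dtype=float)
        rank = 0.75 * (len(sorted_x) - 1)
        lo = int(np.floor(rank))
        expected = sorted_x[lo] + (rank - lo) * (sorted_x[lo + 1] - sorted_x[lo])
        assert q_star * (2 * expected) == pytest.approx(expected)

    def test_zero_quantile_rejected(self):
        with pytest.raises(ValidationError):
            size_factors_quantile(_cm([[0], [0], [0], [0], [1]]))


class TestEstimateDkj:
    def test_rho_zero_gives_plain_ratio(self):
        rng = np.random.default_rng(2)
        cm = _cm(rng.integers(0, 30, size=(10, 6)) + 1)
        labels = LabelVector(np.repeat([0, 1], 3), ("A", "B"))
        si = size_factors_total(cm)
        dkj = estimate_dkj(cm, labels, si, beta=1.0, rho=0.0)
        gj = cm.counts.sum(axis=1)
        for k in (0, 1):
            members = labels.labels == k
            a = cm.counts[:, members].sum(axis=1) + 1.0
            b = si[members].sum() * gj + 1.0
            assert np.allclose(dkj[k], a / b)

    @pytest.mark.parametrize(
        "a,b,rho,expected",
        [
            (2.0, 1.0, 0.5, 1.5),  # b(a/b-1)=1 > rho: shrink down by rho/b
            (1.2, 1.0, 0.5, 1.0),  # b|1-a/b|=0.2 < rho: clamp to 1
            (0.2, 1.0, 0.5, 0.7),  # b(1-a/b)=0.8 > rho: shrink up by rho/b
        ],
    )
    def test_soft_threshold_branches(self, a, b, rho, expected):
        got = soft_threshold_dkj(np.array([a]), np.array([b]), rho)[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_soft_threshold_random_grid_matches_scalar(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = rng.uniform(0.01, 5.0)
            b = rng.uniform(0.1, 5.0)
            rho = rng.uniform(0.0, 3.0)
            got = soft_threshold_dkj(np.array([a]), np.array([b]), rho)[0]
            ratio = a / b
            if b * (ratio - 1.0) > rho:
                want = ratio - rho / b
            elif b * (1.0 - ratio) > rho:
                want = ratio + rho / b
            else:
                want = 1.0
            assert got == pytest.approx(want, abs=1e-12)
            # shrinkage never crosses 1 and moves |d-1| by at most rho/b
            assert (got - 1.0) * (ratio - 1.0) >= 0.0
            assert abs(got - 1.0) <= abs(ratio - 1.0) + 1e-12


class TestClassification:
    def test_one_gene_worked_example(self):
        model = SpldaModel(
            dkj=np.array([[2.0], [0.5]]),
            gj=np.array([1.0]),
            si=np.array([1.0]),
            rho=0.0,
            beta=1.0,
            priors=np.array([0.5, 0.5]),
            size_factor_method="total",
            gene_ids=["g"],
            train_total=3.0,  # test profile sums to 3 -> s* = 1
        )
        label, scores = splda_classify(model, np.array([3.0]))
        # scores carry the constant log-prior; remove it for the worked values
        centered = scores - np.log(0.5)
        assert centered[0] == pytest.approx(3 * np.log(2.0) - 2.0, abs=1e-10)
        assert centered[1] == pytest.approx(3 * np.log(0.5) - 0.5, abs=1e-10)
        assert label == 0

    def test_all_ones_profile_ties_to_class_zero(self):
        model = SpldaModel(
            dkj=np.ones((2, 3)),
            gj=np.array([5.0, 5.0, 5.0]),
            si=np.array([0.5, 0.5]),
            rho=0.0,
            beta=1.0,
            priors=np.array([0.5, 0.5]),
            size_factor_method="total",
            gene_ids=list("abc"),
            train_total=30.0,
        )
        label, scores = splda_classify(model, np.array([1.0, 2.0, 3.0]))
        assert scores[0] == scores[1]
        assert label == 0

    def test_mirrored_profiles_give_mirrored_assignments(self):
        counts = np.array(
            [
                [20, 22, 18, 2, 3, 2],
                [2, 3, 2, 20, 22, 18],
            ]
        )
        cm = _cm(counts)
        labels = LabelVector(np.repeat([0, 1], 3), ("A", "B"))
        model = splda_fit(cm, labels, "total")
        up = splda_predict(model, np.array([[20.0], [2.0]]))
        down = splda_predict(model, np.array([[2.0], [20.0]]))
        assert up[0] == 0 and down[0] == 1

    def test_dimension_mismatch_rejected(self):
        cm = _cm(np.ones((4, 4), dtype=int))
        labels = LabelVector(np.repeat([0, 1], 2), ("A", "B"))
        model = splda_fit(cm, labels, "total")
        with pytest.raises(ValidationError):
            splda_classify(model, np.ones(3))


class TestRhoTuning:
    @pytest.fixture
    def study(self):
        rng = np.random.default_rng(4)
        n1 = n2 = 15
        base = rng.integers(5, 60, size=(30, 1)).astype(float)
        mean = np.tile(base, (1, n1 + n2))
        mean[:5, n1:] *= 4.0  # 5 informative genes
        counts = rng.poisson(mean)
        cm = _cm(counts)
        labels = LabelVector(np.repeat([0, 1], n1), ("A", "B"))
        return cm, labels

    def test_full_shrinkage_beyond_grid_max(self, study):
        cm, labels = study
        top = default_rho_grid(cm, labels)[-1]
        model = splda_fit(cm, labels, "total", rho=top * 1.001)
        assert model.involved_features() == 0

    def test_involvement_non_increasing_in_rho(self, study):
        cm, labels = study
        grid = default_rho_grid(cm, labels, n=12)
        counts = [splda_fit(cm, labels, "total", rho=r).involved_features() for r in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # brute-force recount of the involved set at one rho
        model = splda_fit(cm, labels, "total", rho=grid[3])
        manual = sum(1 for j in range(cm.n_genes) if any(model.dkj[k, j] != 1.0 for k in (0, 1)))
        assert manual == model.involved_features()

    def test_single_value_grid_returned(self, study):
        cm, labels = study
        rho, acc, involved = splda_tune_rho(cm, labels, grid=np.array([0.7]), folds=3, seed=0)
        assert rho == 0.7 and len(acc) == 1 and len(involved) == 1

    def test_ties_resolve_to_sparser_model(self, study):
        cm, labels = study
        grid = np.array([0.0, 1e-9])  # indistinguishable accuracy
        rho, acc, _ = splda_tune_rho(cm, labels, grid=grid, folds=3, seed=1)
        assert acc[0] == acc[1]
        assert rho == 1e-9

    def test_infeasible_folds_rejected(self):
        cm = _cm(np.ones((5, 4), dtype=int))
        labels = LabelVector(np.array([0, 0, 1, 1]), ("A", "B"))
        with pytest.raises(ValidationError):
            splda_tune_rho(cm, labels, folds=5)
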