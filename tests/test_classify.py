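"""ELU / cross-entropy kernels, the 1-D CNN, SVM and LR training, evaluation."""

import numpy as np
import pytest

from chrysospec import (
    DcnnConfig,
    LrConfig,
    SpectraTable,
    SvmConfig,
    WavelengthGrid,
    build_dcnn,
    cross_entropy,
    elu,
    evaluate,
    split_dataset,
    train_dcnn,
    train_lr,
    train_svm,
)
from chrysospec.exceptions import InvalidArgumentError
from chrysospec.spectra import DatasetSplit

from conftest import make_easy_table


class TestElu:
    @pytest.mark.parametrize(
        "x, alpha, expected",
        [(0.0, 1.0, 0.0), (3.0, 1.0, 3.0), (-1.0, 1.0, np.exp(-1) - 1)],
    )
    def test_reference_values(self, x, alpha, expected):
        assert elu(x, alpha) == pytest.approx(expected, abs=1e-12)

    def test_continuous_monotone_with_lower_limit(self):
        x = np.linspace(-30, 30, 10001)
        y = elu(x, alpha=2.0)
        assert np.all(np.diff(y) > 0)
        # continuity at the branch point
        assert elu(-1e-12, 2.0) == pytest.approx(0.0, abs=1e-11)
        assert elu(1e-12, 2.0) == pytest.approx(0.0, abs=1e-11)
        # the left branch saturates at -alpha
        assert y[0] > -2.0 and y[0] == pytest.approx(-2.0, abs=1e-8)

    def test_alpha_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            elu(1.0, alpha=0.0)


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        p = np.array([0, 1, 0, 0])
        assert cross_entropy(p, p) == 0.0

    def test_one_hot_vs_uniform_seven_is_ln7(self):
        p = np.zeros(7)
        p[2] = 1.0
        q = np.full(7, 1 / 7)
        assert cross_entropy(p, q) == pytest.approx(np.log(7), rel=1e-12)

    def test_clipping_floor(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])  # clipped to 1e-12
        assert cross_entropy(p, q) == pytest.approx(-np.log(1e-12), rel=1e-9)

    def test_gibbs_inequality_on_random_distributions(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert cross_entropy(p, q) >= cross_entropy(p, p) - 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cross_entropy(np.ones(3) / 3, np.ones(4) / 4)


class TestBuildDcnn:
    def test_reference_architecture_on_200_bands(self):
        net = build_dcnn(DcnnConfig(num_convs=4, num_first_kernels=32), 200, 7)
        assert net.feature_lengths == [200, 100, 50, 25, 12]
        assert net.filters == [32, 64, 128, 256]

    def test_selected_wavelength_architecture(self):
        net = build_dcnn(DcnnConfig(num_convs=3, num_first_kernels=32), 18, 7)
        assert net.feature_lengths == [18, 9, 4, 2]

    def test_forward_outputs_normalized_probabilities(self):
        net = build_dcnn(DcnnConfig(num_convs=2, num_first_kernels=4, fc_hidden=8), 40, 5)
        X = np.random.default_rng(0).uniform(0, 1, (6, 40))
        proba = net.forward(X)
        assert proba.shape == (6, 5)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_parameter_count_matches_hand_computation(self):
        # conv module m: two (in*3*f + f) convolutions + two 2f-parameter BNs
        net = build_dcnn(DcnnConfig(num_convs=4, num_first_kernels=32, fc_hidden=256),
                         200, 7)
        expected = 0
        c = 1
        length = 200
        for f in (32, 64, 128, 256):
            expected += (c * 3 * f + f) + (f * 3 * f + f) + 4 * f
            c = f
            length //= 2
        expected += c * length * 256 + 256  # first dense
        expected += 2 * 256  # its BN
        expected += 256 * 7 + 7  # output dense
        assert net.num_params() == expected == 1_182_119

    def test_sequence_collapse_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_dcnn(DcnnConfig(num_convs=5, num_first_kernels=2), 18, 3)


@pytest.fixture(scope="module")
def easy_split():
    table = make_easy_table(n_per_class=24, n_classes=4, n_bands=64, seed=2)
    return split_dataset(table, seed=3)


class TestTrainDcnn:
    CFG = DcnnConfig(num_convs=2, num_first_kernels=8, epoch=40, batch_size=24,
                     fc_hidden=32)

    def test_learns_separable_classes(self, easy_split):
        _, report = train_dcnn(easy_split, self.CFG, seed=1)
        assert report.test_accuracy >= 0.95

    def test_seeded_determinism(self, easy_split):
        _, a = train_dcnn(easy_split, self.CFG, seed=5)
        _, b = train_dcnn(easy_split, self.CFG, seed=5)
        assert a.train_accuracy == b.train_accuracy
        assert a.test_accuracy == b.test_accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_zero_epochs_is_untrained_chance_level(self, easy_split):
        cfg = DcnnConfig(num_convs=2, num_first_kernels=8, epoch=0, batch_size=24,
                         fc_hidden=32)
        _, report = train_dcnn(easy_split, cfg, seed=2)
        # binomial 99.9% envelope around 1/K for the test-set size
        n = int(report.confusion.sum())
        p = 1 / len(report.classes)
        assert abs(report.test_accuracy - p) < 3.3 * np.sqrt(p * (1 - p) / n) + 0.25

    def test_oversized_batch_shrinks_with_warning(self, easy_split):
        cfg = DcnnConfig(num_convs=2, num_first_kernels=4, epoch=1, batch_size=10_000,
                         fc_hidden=8)
        with pytest.warns(RuntimeWarning, match="batch size"):
            _, report = train_dcnn(easy_split, cfg, seed=0)
        assert report.config["batch_size"] == len(easy_split.train)


class TestTrainSvm:
    def test_separable_classes_reach_perfect_training_accuracy(self, easy_split):
        _, report = train_svm(easy_split, SvmConfig(cv_folds=3), seed=0)
        assert report.train_accuracy == 1.0
        assert report.test_accuracy >= 0.95

    def test_single_cell_grid_is_echoed(self, easy_split):
        cfg = SvmConfig(c=10.0, g=0.01)
        _, report = train_svm(easy_split, cfg)
        assert report.config["c"] == 10.0
        assert report.config["g"] == 0.01

    def test_prediction_matches_kernel_expansion_oracle(self):
        # binary problem: decision(x) = sum_i dual_i K(sv_i, x) + b
        table = make_easy_table(n_per_class=20, n_classes=2, n_bands=16, seed=4)
        split = split_dataset(table, 1)
        model, _ = train_svm(split, SvmConfig(c=10.0, g=0.1))
        svc = model.pipeline.named_steps["svc"]
        scaler = model.pipeline.named_steps["scale"]
        X5 = split.train.spectra[:5]
        Z = scaler.transform(X5)
        K = np.exp(-svc.gamma * ((Z[:, None, :] - svc.support_vectors_[None]) ** 2).sum(-1))
        decision = K @ svc.dual_coef_[0] + svc.intercept_[0]
        manual = np.where(decision > 0, svc.classes_[1], svc.classes_[0])
        assert np.array_equal(manual, model.predict(X5))

    def test_single_class_training_rejected(self):
        table = make_easy_table(n_per_class=8, n_classes=1, n_bands=16)
        split = DatasetSplit(table, table, 0)
        with pytest.raises(InvalidArgumentError):
            train_svm(split)


class TestTrainLr:
    def test_separable_classes_classified(self, easy_split):
        _, report = train_lr(easy_split, LrConfig())
        assert report.test_accuracy >= 0.95
        assert report.config["optimize_algo"] == "liblinear"

    def test_balanced_symmetric_data_has_near_zero_intercept(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-1, 0.3, (500, 3)), rng.normal(1, 0.3, (500, 3))])
        y = np.repeat([1, 2], 500)
        grid = WavelengthGrid.linspace(1000, 1200, 3)
        table = SpectraTable(X, y, grid)
        split = DatasetSplit(table, table, 0)
        model, _ = train_lr(split, LrConfig(c_prime=1.0))
        est = model.pipeline.named_steps["ovr"].estimators_[0]
        assert abs(est.intercept_[0]) < 0.3

    def test_probabilities_sum_to_one(self, easy_split):
        model, _ = train_lr(easy_split)
        proba = model.predict_proba(easy_split.test.spectra)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_one_dimensional_bayes_boundary_recovered(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = np.concatenate([rng.normal(-1, 1, n // 2), rng.normal(1, 1, n // 2)])
        y = np.repeat([1, 2], n // 2)
        # two bands so the table is valid; the second carries no signal
        X = np.column_stack([x, np.zeros(n)])
        table = SpectraTable(X, y, WavelengthGrid(np.array([1000.0, 1001.0])))
        model, _ = train_lr(DatasetSplit(table, table, 0), LrConfig(c_prime=100.0))
        est = model.pipeline.named_steps["ovr"].estimators_[0]
        scaler = model.pipeline.named_steps["scale"]
        # boundary in original units: scaler then linear model cross zero
        w = est.coef_[0][0] / scaler.scale_[0]
        b = est.intercept_[0] - est.coef_[0][0] * scaler.mean_[0] / scaler.scale_[0]
        assert abs(-b / w) < 0.1

    def test_unsupported_penalty_solver_pair_rejected(self):
        with pytest.raises(InvalidArgumentError):
            LrConfig(pi="L1", optimize_algo="lbfgs")


class _FixedPredictor:
    def __init__(self, outputs, classes):
        self.outputs = np.asarray(outputs)
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return self.outputs[: len(X)]


class TestEvaluate:
    def _table(self, labels):
        labels = np.asarray(labels)
        grid = WavelengthGrid.linspace(1000, 1100, 3)
        rng = np.random.default_rng(0)
        return SpectraTable(rng.uniform(0, 1, (len(labels), 3)), labels, grid)

    def test_perfect_predictor(self):
        labels = np.tile(np.arange(1, 8), 3)
        table = self._table(labels)
        report = evaluate(_FixedPredictor(labels, np.arange(1, 8)), table)
        assert report.test_accuracy == 1.0
        assert np.array_equal(report.confusion, np.diag(np.bincount(labels)[1:]))

    def test_constant_predictor_on_balanced_data_scores_chance(self):
        labels = np.repeat(np.arange(1, 8), 4)
        table = self._table(labels)
        report = evaluate(_FixedPredictor(np.full(28, 3), np.arange(1, 8)), table)
        assert report.test_accuracy == pytest.approx(1 / 7)

    def test_accuracy_equals_confusion_trace_over_total(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 5, 40)
        preds = rng.integers(1, 5, 40)
        table = self._table(labels)
        report = evaluate(_FixedPredictor(preds, np.arange(1, 5)), table)
        assert report.test_accuracy == np.trace(report.confusion) / report.confusion.sum()
        # rows sum to the per-class sample counts
        assert np.array_equal(report.confusion.sum(axis=1), np.bincount(labels, minlength=5)[1:])

    def test_band_mismatch_rejected(self, easy_split):
        model, _ = train_lr(easy_split)
        bad = easy_split.test.take_bands(np.arange(10))
        with pytest.raises(InvalidArgumentError):
            evaluate(model, bad)


class TestSeparationMonotonicity:
    def test_accuracy_does_not_degrade_with_higher_separation(self):
        """Parameter-recovery surrogate: wider class offsets relative to noise
        cannot hurt any of the three models (within a small CI allowance)."""
        accs = {}
        for sep in (0.004, 0.05):
            table = make_easy_table(n_per_class=24, n_classes=3, n_bands=64,
                                    seed=6, sep=sep, noise=0.004)
            split = split_dataset(table, 2)
            _, svm_rep = train_svm(split, SvmConfig(c=100.0, g=0.01))
            _, lr_rep = train_lr(split)
            _, dcnn_rep = train_dcnn(
                split,
                DcnnConfig(num_convs=2, num_first_kernels=8, epoch=30, batch_size=24,
                           fc_hidden=32),
                seed=3,
            )
            accs[sep] = (svm_rep.test_accuracy, lr_rep.test_accuracy,
                         dcnn_rep.test_accuracy)
        for low, high in zip(accs[0.004], accs[0.05]):
            assert high >= low - 0.1
        assert min(accs[0.05]) >= 0.95
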