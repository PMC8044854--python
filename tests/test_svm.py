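"""PCA-SVM baseline contracts: flattening, gamma, variance prefix, asymmetry."""

import numpy as np
import pytest

from gadnet.dataset import CellImage
from gadnet.metrics import score_predictions
from gadnet.svm import PcaSvmModel, compute_gamma, fit_pca, flatten_and_pad


def crops_from_rows(rows, labels, shape):
    """Wrap feature rows as CellImages of a given (c, h, w) shape."""
    out = []
    for i, (row, lab) in enumerate(zip(rows, labels)):
        out.append(
            CellImage(
                values=np.asarray(row, dtype=np.float32).reshape(shape),
                channels=tuple(f"ch{j}" for j in range(shape[0]))[: shape[0]],
                cell_id=i,
                label=lab,
            )
        )
    return out


class TestFlattenAndPad:
    def test_mixed_sizes_pad_to_longest(self):
        rng = np.random.default_rng(0)
        a = CellImage(rng.normal(size=(2, 4, 4)).astype(np.float32), ("x", "y"), 0, "positive")
        b = CellImage(rng.normal(size=(2, 3, 3)).astype(np.float32), ("x", "y"), 1, "negative")
        X, length = flatten_and_pad([a, b])
        assert length == 32
        assert X.shape == (2, 32)
        assert np.count_nonzero(X[1, 18:]) == 0  # 32 - 18 = 14 trailing zeros
        assert np.allclose(X[1, :18], b.values.reshape(-1))

    def test_identical_sizes_no_padding(self):
        rng = np.random.default_rng(1)
        crops = [
            CellImage(rng.normal(size=(1, 3, 3)).astype(np.float32), ("x",), i, "positive")
            for i in range(3)
        ]
        X, length = flatten_and_pad(crops)
        assert length == 9
        for i, c in enumerate(crops):
            assert np.allclose(X[i], c.values.reshape(-1))

    def test_single_crop(self):
        c = CellImage(np.ones((1, 2, 2), dtype=np.float32), ("x",), 0, "positive")
        X, _ = flatten_and_pad([c])
        assert X.shape == (1, 4)

    def test_oversize_validation_crop_truncated_with_warning(self):
        big = CellImage(np.ones((1, 5, 5), dtype=np.float32), ("x",), 0, "positive")
        with pytest.warns(UserWarning, match="truncating"):
            X, _ = flatten_and_pad([big], target_length=9)
        assert X.shape == (1, 9)


class TestGamma:
    def test_printed_formula_arithmetic(self):
        assert compute_gamma(4, 0.5) == 0.5
        assert compute_gamma(1, 1.0) == 1.0

    def test_scaling_property(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 7))
        g1 = compute_gamma(X.shape[1], float(X.var()))
        for c in (2.0, 0.5, 10.0):
            g2 = compute_gamma(X.shape[1], float((c * X).var()))
            assert g2 == pytest.approx(g1 / c**2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_gamma(0, 1.0)
        with pytest.raises(ValueError):
            compute_gamma(3, 0.0)


class TestPca:
    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(3)
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        coords = rng.normal(size=(100, 2)) * np.array([1.3, 1.0])
        X = coords @ basis.T  # exactly 2-D subspace of comparable variances
        proj = fit_pca(X)
        assert proj.n_components == 2

    def test_isotropic_3d_needs_all_three(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(600, 3))
        proj = fit_pca(X)
        assert proj.n_components == 3

    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(5)
        X = rng.normal(loc=7.0, size=(40, 6))
        proj = fit_pca(X)
        z = proj.transform(X.mean(axis=0, keepdims=True))
        assert np.allclose(z, 0.0, atol=1e-9)

    def test_retained_prefix_is_minimal(self):
        rng = np.random.default_rng(6)
        scales = np.array([10.0, 5.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.05])
        X = rng.normal(size=(300, 8)) * scales
        proj = fit_pca(X)
        ratios = np.sort(np.var(X, axis=0))[::-1] / np.var(X, axis=0).sum()
        cum = np.cumsum(ratios)
        k = proj.n_components
        assert cum[k - 1] >= 0.95
        assert k == 1 or cum[k - 2] < 0.95


class TestPcaSvmModel:
    def _blobs(self, n, seed, spread=0.5):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for i in range(n):
            pos = i % 2 == 0
            center = np.array([3.0, 3.0, 0.0, 0.0]) if pos else np.array([-3.0, -3.0, 0.0, 0.0])
            rows.append(center + rng.normal(scale=spread, size=4))
            labels.append("positive" if pos else "negative")
        return crops_from_rows(rows, labels, (1, 2, 2))

    def test_separable_blobs_high_accuracy(self):
        train = self._blobs(60, seed=1)
        val = self._blobs(40, seed=2)
        model = PcaSvmModel().fit(train)
        pred = model.predict(val)
        truth = np.array([c.label_index for c in val])
        assert (pred == truth).mean() >= 0.95
        # and on its own training set
        pred_tr = model.predict(train)
        truth_tr = np.array([c.label_index for c in train])
        assert (pred_tr == truth_tr).mean() >= 0.95

    def test_permuted_labels_score_at_chance(self):
        # structureless features: labels carry no signal, so the fitted model
        # cannot align with the validation truth beyond chance
        rng = np.random.default_rng(7)
        rows = rng.normal(size=(80, 4))
        labels = ["positive" if i % 2 == 0 else "negative" for i in range(80)]
        train = crops_from_rows(rows, labels, (1, 2, 2))
        val = crops_from_rows(rng.normal(size=(60, 4)),
                              ["positive" if i % 2 == 0 else "negative" for i in range(60)],
                              (1, 2, 2))
        model = PcaSvmModel().fit(train)
        pred = model.predict(val)
        truth = np.array([c.label_index for c in val])
        wf1 = score_predictions(pred, truth)["weighted_f1"]
        # permutation null for weighted F1 under label shuffling
        null = []
        for _ in range(200):
            perm = rng.permutation(truth)
            null.append(score_predictions(pred, perm)["weighted_f1"])
        mean, se = np.mean(null), np.std(null, ddof=1)
        assert abs(wf1 - mean) <= 3 * se

    def test_validation_rows_never_influence_fit(self):
        train = self._blobs(40, seed=5)
        model = PcaSvmModel().fit(train)
        gamma, ncomp = model.gamma_, model.projection_.n_components
        components = model.projection_.pca.components_.copy()
        model.predict(self._blobs(30, seed=6))
        assert model.gamma_ == gamma
        assert model.projection_.n_components == ncomp
        assert np.array_equal(model.projection_.pca.components_, components)

    def test_end_to_end_determinism(self):
        train = self._blobs(40, seed=8)
        val = self._blobs(20, seed=9)
        p1 = PcaSvmModel().fit(train).predict(val)
        p2 = PcaSvmModel().fit(train).predict(val)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        train = self._blobs(10, seed=10)
        for c in train:
            c.label = "positive"
        with pytest.raises(ValueError):
            PcaSvmModel().fit(train)
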