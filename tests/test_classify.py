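"""PCA reduction, LOOCV nearest-neighbour classification and summaries."""

import numpy as np
import pytest
from scipy import linalg

from wmrs.classify import (
    ConfusionMatrix,
    fit_pca,
    loocv_classify,
    matrix_summaries,
    metrics_from_confusion,
    pairwise_metrics,
    project,
)
from wmrs.extract import SpectraDataset
from wmrs.reference import THREE_SUBSET_CONFUSION
from wmrs.simulate import (
    AcquisitionConfig,
    CellClassModel,
    default_cell_classes,
    default_donors,
    generate_dataset,
)

from conftest import spectra_from_matrix


def brute_force_loocv(dataset, n_components):
    """Naive per-fold recomputation with explicit loops and an independent
    SVD route; Euclidean distances are computed element by element."""
    X = dataset.matrix()
    labels = dataset.class_labels()
    ids = dataset.cell_ids()
    n = len(labels)
    predictions = []
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        T = X[train_idx]
        mean = T.mean(axis=0)
        _, _, Vt = linalg.svd(T - mean, full_matrices=False)
        comps = Vt[:n_components]
        scores = {j: comps @ (X[j] - mean) for j in range(n)}
        best = None
        for j in train_idx:
            dist = float(np.sqrt(np.sum((scores[j] - scores[i]) ** 2)))
            key = (dist, ids[j])
            if best is None or key < best[0]:
                best = (key, labels[j])
        predictions.append(best[1])
    return predictions


class TestPCA:
    def test_two_spectra_component_parallel_to_their_difference(self, random_unit_spectra):
        spectra = random_unit_spectra(2, 40)
        model = fit_pca(SpectraDataset(spectra), n_components=1)
        diff = spectra[0].values - spectra[1].values
        diff /= np.linalg.norm(diff)
        assert min(
            np.max(np.abs(model.components[0] - diff)),
            np.max(np.abs(model.components[0] + diff)),
        ) < 1e-10

    def test_matches_independent_svd_oracle(self, random_unit_spectra):
        spectra = random_unit_spectra(20, 50, seed=7)
        ds = SpectraDataset(spectra)
        model = fit_pca(ds, n_components=5)
        assert np.allclose(model.components @ model.components.T, np.eye(5), atol=1e-8)
        X = ds.matrix()
        Xc = X - X.mean(axis=0)
        _, s, Vt = linalg.svd(Xc, full_matrices=False)
        for k in range(5):
            assert min(
                np.max(np.abs(model.components[k] - Vt[k])),
                np.max(np.abs(model.components[k] + Vt[k])),
            ) < 1e-8
        ratios = s**2 / np.sum(s**2)
        assert np.allclose(model.explained_variance_ratios, ratios[:5], atol=1e-8)

    def test_n_components_bounds(self, random_unit_spectra):
        ds = SpectraDataset(random_unit_spectra(5, 30))
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(ds, n_components=5)  # only n - 1 = 4 available

    def test_projection_consistency(self, random_unit_spectra):
        spectra = random_unit_spectra(10, 25, seed=3)
        ds = SpectraDataset(spectra)
        model = fit_pca(ds, n_components=3)
        assert np.allclose(project(model, model.mean_spectrum), 0.0, atol=1e-12)
        X = ds.matrix()
        Xc = X - X.mean(axis=0)
        fit_scores = Xc @ model.components.T
        assert np.allclose(project(model, X), fit_scores, atol=1e-10)
        other = random_unit_spectra(1, 30)[0]
        with pytest.raises(ValueError, match="axis"):
            project(model, other)


class TestLOOCV:
    def test_identical_classmates_give_diagonal_confusion(self):
        rng = np.random.default_rng(0)
        protos = rng.normal(size=(3, 40))
        rows = np.repeat(protos, 5, axis=0)  # 5 identical cells per class
        labels = [c for c in "ABC" for _ in range(5)]
        ds = SpectraDataset(spectra_from_matrix(rows, labels=labels))
        _, cm = loocv_classify(ds, n_components=2)
        assert np.array_equal(cm.counts, 5 * np.eye(3, dtype=int))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, random_unit_spectra, seed):
        labels = ["A"] * 4 + ["B"] * 4
        ds = SpectraDataset(random_unit_spectra(8, 30, seed=seed, labels=labels))
        preds, cm = loocv_classify(ds, n_components=2)
        assert preds == brute_force_loocv(ds, 2)
        assert cm.counts.sum(axis=1).tolist() == [4, 4]

    def test_single_member_class_rejected(self, random_unit_spectra):
        labels = ["A"] * 3 + ["B"]
        ds = SpectraDataset(random_unit_spectra(4, 20, labels=labels))
        with pytest.raises(ValueError, match="single member"):
            loocv_classify(ds, n_components=1)

    def test_shared_pca_mode_matches_oracle_shape(self, random_unit_spectra):
        labels = ["A"] * 5 + ["B"] * 5
        ds = SpectraDataset(random_unit_spectra(10, 30, seed=4, labels=labels))
        preds, cm = loocv_classify(ds, n_components=2, refit_per_fold=False)
        assert len(preds) == 10
        assert cm.counts.sum() == 10


class TestMetrics:
    def test_confusion_arithmetic(self):
        cm = ConfusionMatrix(("P", "N"), np.array([[9, 1], [2, 8]]))
        m = metrics_from_confusion(cm, "P")
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert (m.n_positive, m.n_negative) == (10, 10)

    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        rows = np.vstack([rng.normal(0, 0.01, (5, 30)) + 1.0,
                          rng.normal(0, 0.01, (5, 30)) - 1.0])
        labels = ["A"] * 5 + ["B"] * 5
        ds = SpectraDataset(spectra_from_matrix(rows, labels=labels))
        m = pairwise_metrics(ds, n_components=2)
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.positive_class == "A"

    def test_pairwise_requires_exactly_two_classes(self, random_unit_spectra):
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        ds = SpectraDataset(random_unit_spectra(9, 20, labels=labels))
        with pytest.raises(ValueError, match="exactly two"):
            pairwise_metrics(ds, n_components=2)

    def test_reference_table_summaries(self):
        total, accuracy, recalls = matrix_summaries(THREE_SUBSET_CONFUSION)
        assert total == 638
        assert accuracy == pytest.approx((135 + 149 + 148) / 638)
        # hand arithmetic on the printed rows
        assert recalls["CD4+"] == pytest.approx(135 / 231)
        assert recalls["CD8+"] == pytest.approx(149 / 231)
        assert recalls["CD56+"] == pytest.approx(148 / 176)

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(("A", "B"), np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            matrix_summaries(cm)

    def test_identity_matrix_accuracy(self):
        cm = ConfusionMatrix(("A", "B"), np.array([[10, 0], [0, 10]]))
        assert matrix_summaries(cm)[1] == 1.0


class TestSeparabilityProperties:
    def test_accuracy_monotone_in_effect_size(self):
        """Mean LOOCV accuracy over seeds never decreases as the
        between-class amplitude boost grows (<= 1 violation allowed)."""
        acq = AcquisitionConfig()
        donors = default_donors()
        means = []
        for effect in (0.05, 0.3, 0.8):
            accs = []
            for seed in range(10):
                classes = default_cell_classes(effect=effect)[:2]
                stacks = generate_dataset(classes, 12, donors, acq=acq, seed=seed)
                ds = SpectraDataset.from_stacks(stacks)
                _, cm = loocv_classify(ds, n_components=5)
                accs.append(matrix_summaries(cm)[1])
            means.append(np.mean(accs))
        violations = sum(means[i + 1] < means[i] for i in range(len(means) - 1))
        assert violations <= 1

    def test_donor_effects_do_not_break_classification(self):
        """Background +-30 % and gain +-20 % across donors cost < 10
        percentage points of LOOCV accuracy."""
        acq = AcquisitionConfig()
        classes = default_cell_classes()
        neutral = [d.__class__(d.donor_id) for d in default_donors()]
        accs = {}
        for name, donors in (("with", default_donors()), ("without", neutral)):
            stacks = generate_dataset(classes, 30, donors, acq=acq, seed=2)
            ds = SpectraDataset.from_stacks(stacks)
            _, cm = loocv_classify(ds, n_components=7)
            accs[name] = matrix_summaries(cm)[1]
        assert accs["without"] - accs["with"] < 0.10
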