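import numpy as np
import pytest

from svmix.haplotype_io import partition_windows
from svmix.svm_ancestry import (
    P_CEIL,
    BinaryClassifier,
    WindowClassifierEnsemble,
    classify_panel,
    classify_window,
    cross_validate_window,
    load_ensembles,
    save_ensembles,
    train_binary_svm,
    train_window_ensemble,
)


class TestTrainBinarySvm:
    @pytest.mark.parametrize("C", [1.0, 10.0, 1e5])
    def test_separable_1d(self, C):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, -1])
        w, b = train_binary_svm(X, y, C)
        assert np.sign(w @ X[0] + b) == 1
        assert np.sign(w @ X[1] + b) == -1

    def test_max_margin_ignores_uninformative_axis(self):
        # classes separate along axis 0 only; axis 1 carries no signal
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        y = np.array([1, 1, -1, -1])
        w, b = train_binary_svm(X, y, C=10.0)
        assert abs(w[1]) < 1e-6 * abs(w[0])
        # KKT margin condition on a separable problem
        margins = y * (X @ w + b)
        assert margins.min() >= 1 - 1e-6

    def test_degenerate_identical_classes(self):
        X = np.ones((6, 3))
        y = np.array([1, 1, 1, -1, -1, -1])
        w, b = train_binary_svm(X, y, C=1.0)  # must not raise
        pred = np.sign(X @ w + b)
        assert np.mean(pred == y) <= 0.5 + 1e-12

    def test_invalid_inputs(self):
        X = np.array([[1.0], [-1.0]])
        with pytest.raises(ValueError):
            train_binary_svm(X, np.array([1, 1]), C=1.0)
        with pytest.raises(ValueError):
            train_binary_svm(X, np.array([1, -1]), C=0.0)


def _make_ensemble(classifiers, k):
    return WindowClassifierEnsemble(
        classifiers=classifiers, success_rate=0.9,
        population_names=[f"P{i}" for i in range(k)], C=1.0)


class TestClassifyWindow:
    def test_two_population_case_is_sign_decision(self):
        clf = BinaryClassifier(1, 2, np.array([2.0]), -0.5)
        ens = _make_ensemble([clf], 2)
        _, label = classify_window(ens, np.array([1.0]))
        assert label == 1
        _, label = classify_window(ens, np.array([-1.0]))
        assert label == 2

    def test_strict_majority(self):
        # votes A:2 (beats B and C), B:1, C:0
        clfs = [
            BinaryClassifier(1, 2, np.array([1.0]), 0.0),   # x>0 votes A
            BinaryClassifier(1, 3, np.array([1.0]), 0.0),   # x>0 votes A
            BinaryClassifier(2, 3, np.array([1.0]), 0.0),   # x>0 votes B
        ]
        votes, label = classify_window(_make_ensemble(clfs, 3), np.array([1.0]))
        np.testing.assert_array_equal(votes, [2, 1, 0])
        assert label == 1

    def test_cyclic_tie_broken_by_summed_margin(self):
        # rock-paper-scissors: every population gets one vote; population 1
        # carries the largest summed margin in its favour (+3 - 1 = +2)
        clfs = [
            BinaryClassifier(1, 2, np.array([3.0]), 0.0),    # dec +3: votes 1
            BinaryClassifier(1, 3, np.array([-1.0]), 0.0),   # dec -1: votes 3
            BinaryClassifier(2, 3, np.array([2.0]), 0.0),    # dec +2: votes 2
        ]
        votes, label = classify_window(_make_ensemble(clfs, 3), np.array([1.0]))
        np.testing.assert_array_equal(votes, [1, 1, 1])
        assert label == 1

    def test_length_mismatch(self):
        ens = _make_ensemble([BinaryClassifier(1, 2, np.array([1.0]), 0.0)], 2)
        with pytest.raises(ValueError, match="length"):
            classify_window(ens, np.array([1.0, 2.0]))


class TestCrossValidation:
    def test_fixed_difference_gives_ceiling(self, separable_panel):
        panel, _ = separable_panel
        X = panel.alleles[:, :50].astype(float)
        p = cross_validate_window(X, panel.labels, C=1.0, seed=3)
        assert p == P_CEIL

    def test_identical_populations_near_chance(self):
        rng = np.random.default_rng(0)
        base = rng.choice([-1, 1], size=(1, 30))
        X = np.repeat(base, 12, axis=0).astype(float)
        y = np.repeat([1, 2], 6)
        ps = [cross_validate_window(X, y, C=1.0, seed=s) for s in range(40)]
        # chance level for two balanced indistinguishable populations
        assert 0.3 < np.mean(ps) < 0.7

    def test_deterministic_under_seed(self, small_panel):
        panel, _ = small_panel
        X = panel.alleles[:, :40].astype(float)
        p1 = cross_validate_window(X, panel.labels, C=1.0, seed=17)
        p2 = cross_validate_window(X, panel.labels, C=1.0, seed=17)
        assert p1 == p2

    def test_too_small_population_rejected(self):
        X = np.ones((4, 5))
        y = np.array([1, 1, 1, 2])
        with pytest.raises(ValueError, match="fewer than 3"):
            cross_validate_window(X, y, C=1.0, seed=0)


class TestTrainWindowEnsemble:
    def test_separable_panel_all_windows_ceiling(self, separable_panel):
        panel, _ = separable_panel
        part = partition_windows(panel, 20)
        ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=0)
        assert len(ensembles) == part.n_windows
        assert all(len(e.classifiers) == 1 for e in ensembles)
        assert all(e.success_rate == P_CEIL for e in ensembles)

    def test_pair_count_for_three_populations(self):
        from svmix.admixture_simulator import (SyntheticPanelSpec,
                                               generate_synthetic_panels)
        spec = SyntheticPanelSpec(n_pops=3, haplotypes_per_pop=6, n_snps=100,
                                  fst_target=0.2, seed=5)
        panel, _ = generate_synthetic_panels(spec)
        part = partition_windows(panel, 50)
        ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=0)
        assert all(len(e.classifiers) == 3 for e in ensembles)

    def test_unlabelled_panel_rejected(self, separable_panel):
        from dataclasses import replace
        panel, _ = separable_panel
        part = partition_windows(panel, 20)
        bare = replace(panel, labels=None)
        with pytest.raises(ValueError, match="labels"):
            train_window_ensemble(bare, part)


class TestClassifyPanel:
    def test_pure_ancestral_query(self, separable_panel):
        panel, _ = separable_panel
        part = partition_windows(panel, 20)
        ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=0)
        query = panel.take_rows(panel.rows_for_population("A")[:2])
        raw = classify_panel(ensembles, query, part)
        assert raw.shape == (2, part.n_windows)
        assert np.all(raw == 1)

    def test_switch_point_detected_at_junction(self, separable_panel):
        panel, _ = separable_panel
        part = partition_windows(panel, 20)
        ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=0)
        a = panel.alleles[panel.rows_for_population("A")[0]]
        b = panel.alleles[panel.rows_for_population("B")[0]]
        junction_col = 100  # boundary of window 5
        chimera = panel.take_rows([0])
        chimera.alleles = np.concatenate(
            [a[:junction_col], b[junction_col:]])[None, :]
        raw = classify_panel(ensembles, chimera, part)[0]
        expected_window = 100 // 20
        np.testing.assert_array_equal(raw[:expected_window], 1)
        np.testing.assert_array_equal(raw[expected_window:], 2)

    def test_window_independence_under_permutation(self, small_panel):
        """Each window's raw label depends only on its own columns."""
        panel, _ = small_panel
        part = partition_windows(panel, 100)
        ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=1)
        query = panel.take_rows([0, 21])
        raw = classify_panel(ensembles, query, part)
        perm = np.random.default_rng(0).permutation(part.n_windows)
        raw_perm = np.empty_like(raw)
        for new_j, old_j in enumerate(perm):
            win = part.windows[old_j]
            block = query.alleles[:, win.start:win.end].astype(float)
            for i in range(2):
                raw_perm[i, new_j] = classify_window(
                    ensembles[old_j], block[i])[1]
        np.testing.assert_array_equal(raw[:, perm], raw_perm)

    def test_penalty_insensitivity_on_separable_panel(self, small_panel):
        panel, _ = small_panel
        part = partition_windows(panel, 100)
        query = panel.take_rows(np.arange(0, 40, 7))
        raws = []
        for C in (1.0, 1e2, 1e5):
            ens = train_window_ensemble(panel, part, C=C, cv_seed=1)
            raws.append(classify_panel(ens, query, part))
        agreement = np.mean(raws[0] == raws[2])
        assert agreement > 0.99

    def test_empty_query(self, separable_panel):
        panel, _ = separable_panel
        part = partition_windows(panel, 20)
        ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=0)
        query = panel.take_rows([])
        raw = classify_panel(ensembles, query, part)
        assert raw.shape == (0, part.n_windows)


def test_ensemble_serialization_round_trip(separable_panel, tmp_path):
    panel, _ = separable_panel
    part = partition_windows(panel, 50)
    ensembles = train_window_ensemble(panel, part, C=1.0, cv_seed=0)
    path = tmp_path / "ensembles.json"
    save_ensembles(ensembles, path, window_size=50)
    back = load_ensembles(path)
    assert len(back) == len(ensembles)
    for orig, copy in zip(ensembles, back):
        assert copy.success_rate == orig.success_rate
        assert copy.population_names == orig.population_names
        for c1, c2 in zip(orig.classifiers, copy.classifiers):
            assert (c1.pop_a, c1.pop_b) == (c2.pop_a, c2.pop_b)
            np.testing.assert_allclose(c2.weights, c1.weights)
            assert c2.bias == pytest.approx(c1.bias)
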