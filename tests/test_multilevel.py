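import numpy as np
import pandas as pd
import pytest

from breathflow.multilevel import (PreprocessedMatrix, cross_validate, mpca,
                                   mplsda, multilevel_split, preprocess,
                                   select_n_components, vip_scores)


def pm_from_arrays(x, subjects, labels):
    idx = pd.RangeIndex(len(x))
    frame = pd.DataFrame(x, index=idx,
                         columns=[f"mz{i}" for i in range(x.shape[1])])
    return PreprocessedMatrix(frame, pd.Series(subjects, index=idx),
                              pd.Series(labels, index=idx))


def random_pm(seed, n_subjects=10, per_subject=3, p=8, classes=3):
    rng = np.random.default_rng(seed)
    n = n_subjects * per_subject
    x = rng.normal(size=(n, p))
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], per_subject)
    labels = np.tile([f"c{i % classes}" for i in range(per_subject)],
                     n_subjects)
    return pm_from_arrays(x - x.mean(axis=0), subjects, labels)


class TestPreprocess:
    def idx(self, n):
        return pd.RangeIndex(n)

    def test_log_center_hand_values(self):
        values = pd.DataFrame({"mzA": [1.0, np.e, np.e ** 2]})
        pm = preprocess(values, pd.Series(["a", "a", "b"]),
                        pd.Series(["x", "y", "x"]))
        assert np.allclose(pm.x["mzA"], [-1, 0, 1])

    def test_constant_column_centres_to_zero(self):
        values = pd.DataFrame({"mzA": [5.0, 5.0, 5.0]})
        pm = preprocess(values, pd.Series(list("aab")), pd.Series(list("xyx")))
        assert np.allclose(pm.x["mzA"], 0.0)

    def test_centering_idempotent(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.lognormal(size=(6, 3)),
                              columns=["mzA", "mzB", "mzC"])
        pm1 = preprocess(values, pd.Series(list("aabbcc")),
                         pd.Series(list("xyxyxy")))
        again = pm1.x - pm1.x.mean(axis=0)
        pd.testing.assert_frame_equal(pm1.x, again)

    def test_nonpositive_value_aborts_with_location(self):
        values = pd.DataFrame({"mzA": [1.0, 0.0]})
        with pytest.raises(ValueError, match="mzA"):
            preprocess(values, pd.Series(["a", "a"]), pd.Series(["x", "y"]))

    def test_drop_ions_removes_exogenous(self):
        values = pd.DataFrame({"mzA": [1.0, 2.0], "mzX": [1.0, 2.0]})
        pm = preprocess(values, pd.Series(["a", "a"]), pd.Series(["x", "y"]),
                        drop_ions=["mzX"])
        assert list(pm.x.columns) == ["mzA"]


class TestMultilevelSplit:
    def test_three_subject_oracle(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(6, 3)))
        subjects = pd.Series(["a", "a", "b", "b", "c", "c"])
        between, within = multilevel_split(x, subjects)
        for i in range(6):
            expected = x[subjects.to_numpy() == subjects[i]].mean(axis=0)
            assert np.allclose(between.iloc[i], expected)
        assert np.allclose((between + within).to_numpy(), x.to_numpy())

    def test_exact_reconstruction(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(20, 5)))
        subjects = pd.Series(np.repeat(list("abcd"), 5))
        between, within = multilevel_split(x, subjects)
        assert np.abs((between + within).to_numpy() - x.to_numpy()).max() \
            < 1e-12

    def test_within_zero_column_means_per_subject(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(9, 4)))
        subjects = pd.Series(np.repeat(list("abc"), 3))
        _, within = multilevel_split(x, subjects)
        for s in "abc":
            block = within[subjects.to_numpy() == s]
            assert np.allclose(block.mean(axis=0), 0.0, atol=1e-12)

    def test_single_sample_subject_excluded(self):
        x = pd.DataFrame(np.arange(12.0).reshape(6, 2))
        subjects = pd.Series(["a", "a", "b", "b", "c", "lone"][:6])
        _, within = multilevel_split(x, subjects)
        assert len(within) == 4  # 'c' and 'lone' are singletons here


class TestMPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(-1, 1, 8)
        x = np.outer(t, [1.0, 2.0, -1.0])
        pm = pm_from_arrays(x, np.repeat(list("abcd"), 2), list("xy") * 4)
        res = mpca(pm, n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        pm = random_pm(5, n_subjects=4, per_subject=3, p=3)
        _, within = multilevel_split(pm.x, pm.subjects)
        res = mpca(pm, n_components=3)
        cov = within.to_numpy().T @ within.to_numpy()
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ratio = eigvals / eigvals.sum()
        assert np.allclose(res.explained_variance_ratio, ratio[:3], atol=1e-10)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, within.to_numpy(), atol=1e-10)

    def test_excessive_components_rejected(self):
        pm = random_pm(6, n_subjects=3, per_subject=2, p=2)
        with pytest.raises(ValueError):
            mpca(pm, n_components=5)


def separated_pm(seed=0, sep=6.0, n_subjects=12):
    """Two classes separated by `sep` within-subject SDs on 2 ions."""
    rng = np.random.default_rng(seed)
    rows, subjects, labels = [], [], []
    for i in range(n_subjects):
        base = rng.normal(0, 2.0, size=2)
        for cls, shift in (("a", -sep / 2), ("b", sep / 2)):
            rows.append(base + [shift, 0.3 * shift] + rng.normal(0, 1, 2))
            subjects.append(f"S{i}")
            labels.append(cls)
    x = np.asarray(rows)
    return pm_from_arrays(x - x.mean(axis=0), subjects, labels)


class TestMPLSDA:
    def test_separated_classes_no_lv1_overlap(self):
        pm = separated_pm()
        model = mplsda(pm, n_components=2)
        lv1 = pd.Series(model.scores[:, 0], index=pm.labels.to_numpy())
        assert lv1["a"].max() < lv1["b"].min() or \
            lv1["b"].max() < lv1["a"].min()

    def test_informative_ion_gets_max_weight(self):
        rng = np.random.default_rng(4)
        n_subjects, p = 20, 6
        rows, subjects, labels = [], [], []
        for i in range(n_subjects):
            base = rng.normal(0, 1, p)
            for cls, shift in (("a", -2.0), ("b", 2.0)):
                row = base + rng.normal(0, 0.3, p)
                row[3] += shift          # only ion 3 carries class signal
                rows.append(row)
                subjects.append(f"S{i}")
                labels.append(cls)
        x = np.asarray(rows)
        pm = pm_from_arrays(x - x.mean(axis=0), subjects, labels)
        model = mplsda(pm, n_components=1)
        assert np.argmax(np.abs(model.weights[:, 0])) == 3
        vip = vip_scores(model)
        assert vip.idxmax() == "mz3"
        assert vip.max() == pytest.approx(np.sqrt(p), rel=0.2)

    def test_single_class_aborts(self):
        pm = random_pm(7)
        pm = PreprocessedMatrix(pm.x, pm.subjects,
                                pd.Series("only", index=pm.x.index))
        with pytest.raises(ValueError, match="classes"):
            mplsda(pm)

    def test_first_component_matches_sklearn_pls(self):
        """Dual route: first LV of NIPALS PLS2 equals sklearn's."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        pm = random_pm(8, n_subjects=12, per_subject=3, p=6, classes=3)
        model = mplsda(pm, n_components=1)
        from breathflow.multilevel import _dummy_y, multilevel_split
        y, _ = _dummy_y(pm.labels)
        _, within = multilevel_split(pm.x, pm.subjects)
        ref = sklearn.PLSRegression(n_components=1, scale=False)
        ref.fit(within.to_numpy(), y - y.mean(axis=0))
        w_ref = ref.x_weights_[:, 0]
        w = model.weights[:, 0]
        cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert cos > 1 - 1e-7

    def test_deterministic_fit(self):
        pm = random_pm(9)
        a = mplsda(pm, n_components=2)
        b = mplsda(pm, n_components=2)
        assert np.array_equal(a.scores, b.scores)


class TestVip:
    def test_sum_of_squares_identity(self):
        model = mplsda(random_pm(10), n_components=3)
        vip = vip_scores(model)
        p = len(vip)
        assert (vip ** 2).sum() == pytest.approx(p, rel=1e-10)


class TestCrossValidate:
    def test_separable_classes_near_zero_error(self):
        pm = separated_pm(seed=1, n_subjects=15)
        cv = cross_validate(pm, n_components=1, folds=5, repetitions=3, seed=0)
        assert cv.mean_error < 0.05

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(11)
        pm = random_pm(11, n_subjects=50, per_subject=2, p=5, classes=2)
        cv = cross_validate(pm, n_components=1, folds=5, repetitions=5, seed=0)
        assert abs(cv.mean_error - 0.5) < 0.15

    def test_same_seed_same_errors(self):
        pm = random_pm(12)
        a = cross_validate(pm, n_components=2, repetitions=3, seed=4)
        b = cross_validate(pm, n_components=2, repetitions=3, seed=4)
        assert a.per_repetition == b.per_repetition

    def test_more_folds_than_subjects_rejected(self):
        pm = random_pm(13, n_subjects=4)
        with pytest.raises(ValueError):
            cross_validate(pm, folds=10)

    def test_component_selection_bounded(self):
        pm = separated_pm(seed=2, n_subjects=10)
        a = select_n_components(pm, max_components=2, repetitions=2)
        assert 1 <= a <= 2
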