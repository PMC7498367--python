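import numpy as np
import pandas as pd
import pytest

from digiwest.classify import (ContingencyReport, SvmConfig, _Preprocessor,
                               _inner_splits, features_from_matrix,
                               merge_class_report, nested_cv, predict_cohort,
                               probability_by_grade, rbf_kernel, train_final,
                               tune_svm)
from sklearn.svm import SVC

SMALL = SvmConfig(C_grid=(1.0, 100.0), sigma_grid=(1e-3, 1e-1),
                  outer_repeats=2, inner_repeats=2, seed=0)


def separable_data(n_per_class=8, n_classes=4, n_features=5, seed=0):
    """Classes perfectly encoded by marker features, no noise overlap."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k in range(n_classes):
        block = rng.normal(0, 0.1, size=(n_per_class, n_features))
        block[:, k % n_features] += 10.0
        X.append(block)
        y += [f"C{k}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestRbfKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=7)
        assert rbf_kernel(x, x, sigma=0.3) == 1.0

    def test_closed_form_half(self):
        sigma = 0.7
        d = np.sqrt(np.log(2) / sigma)
        assert rbf_kernel(np.array([0.0]), np.array([d]), sigma) == \
            pytest.approx(0.5, abs=1e-12)

    def test_sigma_to_zero_limit(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert rbf_kernel(x, y, sigma=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(3), np.zeros(4), 1.0)


class TestTuneSvm:
    def test_separable_data_reaches_perfect_inner_accuracy(self):
        X, y = separable_data()
        C, sigma, acc = tune_svm(X, y, SMALL)
        assert acc == 1.0

    def test_grid_of_one_returned_unconditionally(self):
        X, y = separable_data(n_per_class=4)
        cfg = SvmConfig(C_grid=(7.0,), sigma_grid=(0.02,), inner_repeats=1)
        C, sigma, _ = tune_svm(X, y, cfg)
        assert (C, sigma) == (7.0, 0.02)

    def test_single_class_rejected(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError):
            tune_svm(X, np.array(["A"] * 6), SMALL)

    def test_selection_is_argmax_of_exhaustive_grid(self):
        """The returned pair achieves the best independently-computed inner-CV
        score, with ties broken toward smaller C then smaller sigma.  The
        published optimum (C=100, sigma=1e-4) is a member of the default grid."""
        assert 100.0 in SvmConfig().C_grid and 1e-4 in SvmConfig().sigma_grid
        rng = np.random.default_rng(4)
        X, y = separable_data(n_per_class=5, n_classes=3)
        X += rng.normal(0, 3.0, size=X.shape)  # make the grid non-trivial
        cfg = SvmConfig(C_grid=(1.0, 10.0, 100.0),
                        sigma_grid=(1e-3, 1e-2, 1e-1), inner_repeats=2, seed=9)
        C, sigma, acc = tune_svm(X, y, cfg, seed=123)
        scores = {}
        for Cg in cfg.C_grid:
            for sg in cfg.sigma_grid:
                correct = total = 0
                for tr, te in _inner_splits(y, cfg, 123):
                    pre = _Preprocessor().fit(X[tr])
                    clf = SVC(C=Cg, kernel="rbf", gamma=sg)
                    clf.fit(pre.transform(X[tr]), y[tr])
                    correct += int((clf.predict(pre.transform(X[te])) == y[te]).sum())
                    total += len(y[te])
                scores[(Cg, sg)] = correct / total
        best = max(scores.values())
        assert acc == pytest.approx(best)
        winners = sorted([k for k, v in scores.items() if v == best])
        assert (C, sigma) == winners[0]


class TestNestedCv:
    def test_separable_features_give_perfect_accuracy(self):
        X, y = separable_data(n_per_class=10, n_classes=5)
        rep = nested_cv(X, y, SMALL)
        assert rep.accuracy_mean == 100.0 and rep.accuracy_sd == 0.0

    def test_rows_sum_to_class_counts(self):
        X, y = separable_data(n_per_class=6, n_classes=4, seed=3)
        X += np.random.default_rng(0).normal(0, 5, size=X.shape)
        rep = nested_cv(X, y, SMALL)
        np.testing.assert_allclose(rep.matrix.sum(axis=1).to_numpy(), 6.0,
                                   atol=1e-9)

    def test_leakage_audit_rows_disjoint(self):
        X, y = separable_data(n_per_class=5, n_classes=3)
        audit = []
        nested_cv(X, y, SMALL, audit=audit)
        assert audit
        for rec in audit:
            assert not set(rec["train_rows"]) & set(rec["test_rows"])
            assert sorted(rec["train_rows"] + rec["test_rows"]) == list(range(len(y)))


class TestMergeClassReport:
    def ffpe_paper_matrix(self):
        """The printed FFPE contingency matrix (counts of 5 per class);
        the COAD diagonal follows from the printed 77.6% overall accuracy."""
        classes = ["HNSC", "LUSC", "LUAD", "COAD", "PAAD"]
        m = pd.DataFrame(0.0, index=classes, columns=classes)
        m.loc["HNSC", "HNSC"] = 4.9
        m.loc["HNSC", "COAD"] = 0.1
        m.loc["LUSC", "LUSC"] = 2.6
        m.loc["LUSC", "LUAD"] = 2.0
        m.loc["LUSC", "COAD"] = 0.4
        m.loc["LUAD", "LUAD"] = 2.9
        m.loc["LUAD", "LUSC"] = 0.9
        m.loc["LUAD", "COAD"] = 1.2
        m.loc["PAAD", "PAAD"] = 5.0
        coad_diag = 0.776 * 25 - (4.9 + 2.6 + 2.9 + 5.0)
        m.loc["COAD", "COAD"] = coad_diag
        m.loc["COAD", "LUAD"] = 5.0 - coad_diag
        return m

    def test_identity_merge_is_noop(self):
        rep = ContingencyReport.from_matrix(self.ffpe_paper_matrix())
        out = merge_class_report(rep, {c: c for c in rep.matrix.index})
        pd.testing.assert_frame_equal(out.matrix, rep.matrix)
        assert out.accuracy_mean == pytest.approx(rep.accuracy_mean)

    def test_lung_merge_reproduces_printed_overall(self):
        rep = ContingencyReport.from_matrix(self.ffpe_paper_matrix())
        assert rep.accuracy_mean == pytest.approx(77.6)
        merged = merge_class_report(
            rep, {"HNSC": "HNSC", "LUSC": "LUNG", "LUAD": "LUNG",
                  "COAD": "COAD", "PAAD": "PAAD"})
        assert merged.per_class["LUNG"] == pytest.approx(84.0)
        assert merged.accuracy_mean == pytest.approx(89.2)

    def test_errors_within_merged_group_become_correct(self):
        m = pd.DataFrame([[0.0, 5.0], [5.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        merged = merge_class_report(ContingencyReport.from_matrix(m),
                                    {"A": "AB", "B": "AB"})
        assert merged.accuracy_mean == pytest.approx(100.0)

    def test_incomplete_map_rejected(self):
        rep = ContingencyReport.from_matrix(self.ffpe_paper_matrix())
        with pytest.raises(ValueError):
            merge_class_report(rep, {"HNSC": "HNSC"})


class TestFinalModelAndPrediction:
    def make_model(self):
        X, y = separable_data(n_per_class=8, n_classes=3)
        Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])],
                           index=[f"s{i}" for i in range(len(y))])
        return Xdf, y, train_final(Xdf, y, SMALL)

    def test_training_points_predicted_correctly(self):
        Xdf, y, model = self.make_model()
        rec = predict_cohort(model, Xdf)
        assert (rec["predicted_type"].to_numpy() == y).all()

    def test_probabilities_sum_to_one(self):
        Xdf, _, model = self.make_model()
        rec = predict_cohort(model, Xdf)
        probs = rec[[c for c in rec.columns if c.startswith("prob_")]]
        np.testing.assert_allclose(probs.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_feature_mismatch_lists_offenders(self):
        Xdf, _, model = self.make_model()
        bad = Xdf.rename(columns={"f0": "weird"})
        with pytest.raises(ValueError, match="weird"):
            predict_cohort(model, bad)

    def test_deterministic_given_seed(self):
        X, y = separable_data(n_per_class=6, n_classes=3, seed=2)
        Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        m1 = train_final(Xdf, y, SMALL)
        m2 = train_final(Xdf, y, SMALL)
        assert (m1.C, m1.sigma) == (m2.C, m2.sigma)
        pd.testing.assert_frame_equal(predict_cohort(m1, Xdf),
                                      predict_cohort(m2, Xdf))


class TestProbabilityByGrade:
    def records(self, probs_g2, probs_g3):
        rows = []
        for i, p in enumerate(probs_g2):
            rows.append({"true_type": "A", "grade": "G2", "prob_A": p,
                         "prob_B": 1 - p})
        for i, p in enumerate(probs_g3):
            rows.append({"true_type": "A", "grade": "G3", "prob_A": p,
                         "prob_B": 1 - p})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        out = probability_by_grade(self.records([0.6, 0.4], [0.6, 0.4]))
        assert out["p"] == pytest.approx(1.0)

    def test_matches_hand_computed_t(self):
        from .oracles import pooled_ttest_formula
        g2, g3 = [0.7, 0.6, 0.8], [0.4, 0.5]
        out = probability_by_grade(self.records(g2, g3))
        t0, p0 = pooled_ttest_formula({"G2": np.array(g2), "G3": np.array(g3)},
                                      ("G2", "G3"))
        assert out["t"] == pytest.approx(t0, abs=1e-10)
        assert out["p"] == pytest.approx(p0, abs=1e-10)
        assert out["means"]["G2"] == pytest.approx(np.mean(g2))

    def test_zero_variance_equal_means_p_one(self):
        out = probability_by_grade(self.records([1.0, 1.0], [1.0, 1.0]))
        assert out["means"] == {"G2": 1.0, "G3": 1.0}
        assert out["p"] == 1.0
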