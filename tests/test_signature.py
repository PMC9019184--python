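import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regskit import SignatureModel, assign_tertiles, load_bendamustine_panel
from regskit._enet import lambda_max, lambda_path, logistic_enet_path, standardize
from regskit.signature import (
    ResistanceLabel,
    SignatureResults,
    loocv_misclassification,
    tertile_sizes,
)


class TestTertiles:
    @pytest.mark.parametrize("n,expected", [(14, (5, 4, 5)), (11, (4, 3, 4)), (3, (1, 1, 1)), (9, (3, 3, 3))])
    def test_published_panel_sizes(self, n, expected):
        assert tertile_sizes(n) == expected

    @given(st.integers(3, 200))
    @settings(max_examples=60, deadline=None)
    def test_sizes_sum_and_balance(self, n):
        lo, mid, hi = tertile_sizes(n)
        assert lo + mid + hi == n
        assert max(lo, mid, hi) - min(lo, mid, hi) <= 1

    def test_reference_panel_extreme_lines(self):
        panel = load_bendamustine_panel()
        labels = {l.cell_line: l.tertile for l in assign_tertiles(panel)}
        # least / most resistant lines of each disease land in the outer groups
        assert labels["SU-DHL-5"] == "sensitive" and labels["MOLP-2"] == "sensitive"
        assert labels["SU-DHL-10"] == "resistant" and labels["RPMI-8226"] == "resistant"

    def test_monotone_in_auc0_and_shift_invariant(self):
        df = pd.DataFrame(
            {
                "cell_line": [f"L{i}" for i in range(11)],
                "disease": ["MM"] * 11,
                "auc0": np.linspace(200, 380, 11),
            }
        )
        labels = assign_tertiles(df)
        order = {"sensitive": 0, "intermediate": 1, "resistant": 2}
        ranks = [order[l.tertile] for l in labels]  # already AUC0-sorted
        assert ranks == sorted(ranks)
        assert [l.tertile for l in labels].count("intermediate") == 3
        shifted = assign_tertiles(df.assign(auc0=df["auc0"] + 123.4))
        assert shifted == labels

    def test_too_few_lines_rejected(self):
        df = pd.DataFrame({"cell_line": ["a", "b"], "disease": ["MM", "MM"], "auc0": [1.0, 2.0]})
        with pytest.raises(ValueError):
            assign_tertiles(df)


class TestEnetSolver:
    def test_matches_sklearn_saga(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        n, p = 40, 30
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:3] = [2.0, -1.5, 1.0]
        y = (1 / (1 + np.exp(-(X @ beta))) > rng.random(n)).astype(float)
        Xs, _, _ = standardize(X)
        for alpha in (0.3, 1.0):
            lams = lambda_path(lambda_max(Xs, y, alpha), 15, 0.05)
            b0s, coefs = logistic_enet_path(Xs, y, alpha, lams)
            for li in (4, 9):
                sk = LogisticRegression(
                    solver="saga", l1_ratio=alpha, C=1.0 / (n * lams[li]),
                    max_iter=100000, tol=1e-10,
                )
                sk.fit(Xs, y)
                assert np.abs(sk.coef_[0] - coefs[li]).max() < 2e-3
                assert abs(sk.intercept_[0] - b0s[li]) < 2e-3

    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 15))
        y = (rng.random(20) > 0.5).astype(float)
        Xs, _, _ = standardize(X)
        for alpha in (0.2, 1.0):
            lmax = lambda_max(Xs, y, alpha)
            _, coefs = logistic_enet_path(Xs, y, alpha, np.array([lmax * 1.0001]))
            assert np.all(coefs[0] == 0)

    def test_intercept_only_limit_predicts_prevalence(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 10))
        y = np.array([1.0] * 10 + [0.0] * 20)
        Xs, _, _ = standardize(X)
        lmax = lambda_max(Xs, y, 0.5)
        b0s, coefs = logistic_enet_path(Xs, y, 0.5, np.array([lmax * 2]))
        assert np.all(coefs[0] == 0)
        prob = 1 / (1 + math.exp(-b0s[0]))
        assert prob == pytest.approx(y.mean(), abs=1e-9)

    def test_standardization_is_exact(self):
        rng = np.random.default_rng(5)
        X = rng.normal(3, 2, size=(25, 12))
        X[:, 0] = 7.0  # constant column
        Xs, center, scale = standardize(X)
        assert np.abs(Xs.mean(axis=0)).max() < 1e-10
        assert np.abs(Xs[:, 1:].std(axis=0) - 1).max() < 1e-10
        assert scale[0] == 1.0 and np.all(Xs[:, 0] == 0)


class TestSignatureModel:
    def test_loocv_fold_matches_manual_refit(self, trained_signature):
        expr, labels_df, results = trained_signature
        sm = SignatureModel(expr, labels_df)
        alpha = 0.5
        Xs, _, _ = standardize(sm.X_raw)
        lams = lambda_path(lambda_max(Xs, sm.y, alpha), 20, 0.05)
        mis = loocv_misclassification(sm.X_raw, sm.y, alpha, lams)
        i = 3  # recompute fold i by hand
        keep = np.arange(len(sm.y)) != i
        Xtr, c, s = standardize(sm.X_raw[keep])
        assert np.abs(Xtr.mean(axis=0)).max() < 1e-10  # left-out sample not in stats
        b0s, coefs = logistic_enet_path(Xtr, sm.y[keep], alpha, lams)
        zi = (sm.X_raw[i] - c) / s
        pred = (1 / (1 + np.exp(-(b0s + coefs @ zi))) > 0.5).astype(float)
        assert np.array_equal(mis[i], pred != sm.y[i])

    def test_perfectly_separating_gene_reaches_zero_cv_error(self):
        names = [f"L{i}" for i in range(12)]
        truth_labels = ["sensitive"] * 6 + ["resistant"] * 6
        rng = np.random.default_rng(6)
        values = rng.normal(7, 1, size=(50, 12))
        values[0] = [5.0] * 6 + [9.0] * 6  # perfect separator
        expr = pd.DataFrame(values, index=[f"G{i:03d}" for i in range(50)], columns=names)
        labels = pd.DataFrame({"cell_line": names, "disease": "DLBCL", "tertile": truth_labels})
        res = SignatureModel(expr, labels).fit(n_lambda=50)
        assert res.cv_error == 0.0
        assert "G000" in res.signature

    def test_self_prediction_separates_training_classes(self, trained_signature):
        expr, labels_df, results = trained_signature
        assert results.cv_error < 0.5
        probs = results.predict(expr).set_index("sample_id")["resistance_prob"]
        lab = labels_df.set_index("cell_line")["tertile"]
        assert probs[lab == "resistant"].mean() > probs[lab == "sensitive"].mean()

    def test_input_validation(self, trained_signature):
        expr, labels_df, _ = trained_signature
        single = labels_df.assign(tertile="resistant")
        with pytest.raises(ValueError, match="single class"):
            SignatureModel(expr, single)
        few = labels_df.iloc[:3]
        with pytest.raises(ValueError):
            SignatureModel(expr, few)
        with pytest.raises(ValueError, match="lacks samples"):
            SignatureModel(expr.drop(columns=expr.columns[:1]),
                           labels_df)


class TestPrediction:
    def test_zero_model_gives_half_everywhere(self):
        fids = ["A", "B"]
        res = SignatureResults(fids, [0.0, 0.0], [1.0, 1.0], 0.0, [0.0, 0.0], 1.0, 1.0, 0.5)
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 5)), index=fids)
        assert np.allclose(res.predict(expr)["resistance_prob"], 0.5)

    def test_positive_coefficient_monotonicity(self, toy_signature):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(len(toy_signature.feature_ids), 4)),
            index=toy_signature.feature_ids,
        )
        p0 = toy_signature.predict(expr)["resistance_prob"]
        bumped = expr.copy()
        bumped.loc["G000"] += 1.0  # coefficient +1.5
        p1 = toy_signature.predict(bumped)["resistance_prob"]
        assert (p1.to_numpy() > p0.to_numpy()).all()

    def test_feature_order_and_extra_features_irrelevant(self, toy_signature):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(len(toy_signature.feature_ids), 6)),
            index=toy_signature.feature_ids,
        )
        p0 = toy_signature.predict(expr)["resistance_prob"]
        shuffled = expr.sample(frac=1, random_state=3)
        extra = pd.concat([shuffled, pd.DataFrame(np.ones((2, 6)), index=["ZZ1", "ZZ2"])])
        p1 = toy_signature.predict(extra)["resistance_prob"]
        assert np.allclose(p0, p1)

    def test_missing_signature_features(self, toy_signature):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(len(toy_signature.feature_ids), 3)),
            index=toy_signature.feature_ids,
        )
        broken = expr.drop(index=["G000"])
        with pytest.raises(ValueError, match="signature features"):
            toy_signature.predict(broken)
        imputed = toy_signature.predict(broken, impute_missing=True)
        assert ((0 < imputed["resistance_prob"]) & (imputed["resistance_prob"] < 1)).all()


class TestSerialization:
    def test_round_trip_is_bit_exact(self, trained_signature):
        expr, _, results = trained_signature
        text = results.to_json()
        back = SignatureResults.from_json(text)
        assert back.feature_ids == results.feature_ids
        assert np.array_equal(back.coefficients, results.coefficients)
        assert np.array_equal(back.center, results.center)
        assert np.array_equal(back.scale, results.scale)
        assert back.intercept == results.intercept
        assert back.penalty_lambda == results.penalty_lambda
        p0 = results.predict(expr)["resistance_prob"]
        p1 = back.predict(expr)["resistance_prob"]
        assert np.array_equal(p0.to_numpy(), p1.to_numpy())
        # and a second round trip yields identical text
        assert back.to_json() == text

    def test_file_round_trip(self, trained_signature, tmp_path):
        _, _, results = trained_signature
        path = tmp_path / "model.json"
        results.to_json(path)
        back = SignatureResults.from_json(path)
        assert json.loads(back.to_json()) == json.loads(results.to_json())
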