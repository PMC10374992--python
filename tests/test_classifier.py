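
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from strokecohort.classifier import (
    FeatureEncoder,
    SubtypeClassifier,
    apply_to_undetermined,
    build_feature_frame,
    evaluate,
    fit_multiclass_l1,
    split_cohort,
    tune_l1_strength,
)


def toy_frame(n, rng, signal=None):
    """Minimal feature frame with one continuous and one categorical column."""
    X = pd.DataFrame({
        "age": rng.normal(60, 9, n),
        "sbp": rng.normal(140, 20, n),
        "dbp": rng.normal(81, 12, n),
        "bmi": rng.normal(24, 3, n),
        "sex": rng.choice(["male", "female"], n),
    })
    if signal is not None:
        X["any_cardioaortic_source"] = np.where(signal, "yes", "no")
    return X


class TestSplit:
    def test_sizes_at_round_numbers(self, cohort):
        y = cohort["true_subtype"].to_numpy()
        sub = cohort.iloc[:100]
        tr, te, ytr, yte = split_cohort(sub, y[:100], fraction=0.85, seed=0)
        assert (len(tr), len(te)) == (85, 15)

    def test_sizes_at_cohort_scale(self):
        # 85:15 split of 7443 cases: 6327 train / 1116 test (+-1 by rounding)
        rng = np.random.default_rng(0)
        y = rng.choice(["CE", "LAA", "SAO"], size=7443, p=[0.02, 0.32, 0.66])
        df = pd.DataFrame({"i": np.arange(7443)})
        tr, te, *_ = split_cohort(df, y, fraction=0.85, seed=1)
        assert abs(len(tr) - 6327) <= 1
        assert len(tr) + len(te) == 7443

    def test_partition_is_disjoint_exhaustive_and_reproducible(self, cohort):
        y = cohort["true_subtype"].to_numpy()
        tr1, te1, *_ = split_cohort(cohort, y, seed=7)
        tr2, te2, *_ = split_cohort(cohort, y, seed=7)
        assert tr1.index.equals(tr2.index) and te1.index.equals(te2.index)
        assert len(set(tr1.index) & set(te1.index)) == 0
        assert len(tr1) + len(te1) == len(cohort)

    def test_stratification_preserves_class_shares(self, cohort):
        y = cohort["true_subtype"].to_numpy()
        tr, te, ytr, yte = split_cohort(cohort, y, seed=3)
        for cls in ("CE", "LAA", "SAO"):
            overall = (y == cls).mean()
            assert (ytr == cls).mean() == pytest.approx(overall, abs=0.01)

    def test_missing_class_warns(self):
        # a singleton class cannot appear on both sides of the partition
        y = np.array(["LAA"] * 99 + ["CE"] * 1, dtype=object)
        df = pd.DataFrame({"i": np.arange(100)})
        with pytest.warns(UserWarning, match="absent"):
            split_cohort(df, y, fraction=0.5, seed=0)

    def test_bad_fraction_rejected(self, cohort):
        with pytest.raises(ValueError):
            split_cohort(cohort, cohort["true_subtype"], fraction=1.5)


class TestTuning:
    def test_single_point_grid_returns_it(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["LAA", "SAO"], 120)
        alpha, trace = tune_l1_strength(toy_frame(120, rng), y, [2.5], seed=0)
        assert alpha == 2.5
        assert len(trace) == 1

    def test_separable_data_selects_weakest_penalty(self):
        rng = np.random.default_rng(1)
        y = np.array(["LAA"] * 60 + ["SAO"] * 60, dtype=object)
        X = toy_frame(120, rng)
        X["age"] = np.where(y == "LAA", 40.0, 70.0) + rng.normal(0, 0.5, 120)
        alpha, trace = tune_l1_strength(X, y, [0.5, 500.0], seed=0)
        assert alpha == 0.5

    def test_pure_noise_gives_chance_auc(self):
        rng = np.random.default_rng(2)
        y = rng.choice(["LAA", "SAO"], 800)
        _, trace = tune_l1_strength(toy_frame(800, rng), y, [1.0, 10.0], seed=0)
        assert np.all(np.abs(trace["mean_cv_auc"] - 0.5) < 0.05)

    def test_empty_or_nonpositive_grid_rejected(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["LAA", "SAO"], 50)
        with pytest.raises(ValueError):
            tune_l1_strength(toy_frame(50, rng), y, [])
        with pytest.raises(ValueError):
            tune_l1_strength(toy_frame(50, rng), y, [0.0, 1.0])


class TestFit:
    def test_infinite_penalty_returns_class_frequencies(self):
        rng = np.random.default_rng(3)
        y = np.array(["CE"] * 10 + ["LAA"] * 30 + ["SAO"] * 60, dtype=object)
        model = fit_multiclass_l1(toy_frame(100, rng), y, alpha=np.inf)
        assert np.allclose(model.coef_, 0.0)
        proba = model.predict_proba(toy_frame(5, rng))
        assert np.allclose(proba, [0.1, 0.3, 0.6], atol=1e-12)
        # a huge finite penalty also zeroes every coefficient
        finite = fit_multiclass_l1(toy_frame(100, rng), y, alpha=1e6)
        assert np.allclose(finite.coef_, 0.0, atol=1e-8)

    def test_duplicated_rows_leave_solution_unchanged(self):
        # doubling every row while doubling alpha leaves the objective (hence
        # the identified fit) unchanged; one-hot blocks plus an intercept are
        # only identified up to a shift under L1, so compare predictions and
        # the continuous-feature coefficients
        rng = np.random.default_rng(4)
        X = toy_frame(80, rng)
        y = rng.choice(["LAA", "SAO"], 80)
        m1 = fit_multiclass_l1(X, y, alpha=1.0, tol=1e-10)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        m2 = SubtypeClassifier(alpha=2.0, tol=1e-10).fit(X2, y2)
        assert np.allclose(m1.coef_[:, :4], m2.coef_[:, :4], atol=1e-4)
        assert np.allclose(m1.predict_proba(X), m2.predict_proba(X), atol=1e-4)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="2 classes"):
            SubtypeClassifier().fit(toy_frame(30, rng), np.array(["SAO"] * 30))

    def test_dominant_binary_feature_gives_near_perfect_auc(self):
        # one finding present in every positive and rare among negatives
        rng = np.random.default_rng(5)
        y = np.array(["CE"] * 60 + ["SAO"] * 540, dtype=object)
        # the finding is present in all positives and exactly 8/540 negatives
        neg_signal = np.zeros(540, bool)
        neg_signal[::68] = True
        signal = np.concatenate([np.ones(60, bool), neg_signal])
        X = toy_frame(600, rng, signal=signal)
        tr = np.arange(0, 600, 2)
        te = np.arange(1, 600, 2)
        model = fit_multiclass_l1(X.iloc[tr], y[tr], alpha=0.1)
        rep = evaluate(model, X.iloc[te], y[te], n_bootstrap=0, seed=0)
        assert rep.per_class["CE"].auc >= 0.99

    def test_l1_path_sparsity_nonincreasing(self):
        rng = np.random.default_rng(6)
        n = 200
        X = toy_frame(n, rng)
        logits = 0.08 * (X["age"] - 60) - 0.03 * (X["sbp"] - 140)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-logits)), "LAA", "SAO")
        counts = []
        for alpha in (0.01, 0.1, 1.0, 10.0, 100.0):
            m = fit_multiclass_l1(X, y, alpha=alpha, tol=1e-8)
            counts.append(int(np.sum(np.abs(m.coef_) > 1e-8)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_get_set_params_roundtrip(self):
        model = SubtypeClassifier(alpha=2.0)
        model.set_params(alpha=3.0, cv=4)
        assert model.get_params()["alpha"] == 3.0
        with pytest.raises(ValueError):
            model.set_params(bogus=1)


def _oracle_penalized_fit(Z, y_idx, alpha, n_classes):
    """Independent solution of the L1-penalized multinomial objective.

    Splits W = P - N with P, N >= 0 so the objective is smooth and solvable
    by a generic box-constrained quasi-Newton method.
    """
    n, d = Z.shape
    K = n_classes

    def unpack(z):
        P = z[: K * d].reshape(K, d)
        N = z[K * d : 2 * K * d].reshape(K, d)
        return P, N, z[2 * K * d :]

    def f(z):
        P, N, b = unpack(z)
        S = Z @ (P - N).T + b
        return float(np.sum(logsumexp(S, axis=1) - S[np.arange(n), y_idx]) + alpha * np.sum(P + N))

    def g(z):
        P, N, b = unpack(z)
        S = Z @ (P - N).T + b
        pr = np.exp(S - logsumexp(S, axis=1, keepdims=True))
        Y = np.zeros((n, K))
        Y[np.arange(n), y_idx] = 1.0
        GW = (pr - Y).T @ Z
        return np.concatenate([(GW + alpha).ravel(), (-GW + alpha).ravel(), (pr - Y).sum(axis=0)])

    res = minimize(
        f, np.zeros(2 * K * d + K), jac=g, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * K * d) + [(None, None)] * K,
        options={"maxiter": 50000, "ftol": 1e-15, "gtol": 1e-12},
    )
    P, N, b = unpack(res.x)
    return P - N, b


def test_fit_matches_generic_convex_optimizer():
    """Fitted coefficients agree with an independent penalized-objective solution."""
    rng = np.random.default_rng(0)
    n, alpha = 40, 0.5
    X = pd.DataFrame({"age": rng.normal(0, 1, n), "sbp": rng.normal(0, 1, n),
                      "bmi": rng.normal(0, 1, n)})
    beta = np.array([[1.5, 0.0, 0.0], [0.0, -1.0, 0.5], [0.0, 0.0, 0.0]])
    logits = X.to_numpy() @ beta.T
    pr = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
    y_idx = np.array([rng.choice(3, p=p) for p in pr])
    y = np.array(["CE", "LAA", "SAO"], dtype=object)[y_idx]

    model = SubtypeClassifier(alpha=alpha, tol=1e-10, max_iter=500000).fit(X, y)
    Z = model.encoder_.transform(X)
    W_oracle, b_oracle = _oracle_penalized_fit(Z, y_idx, alpha, 3)
    assert np.max(np.abs(model.coef_ - W_oracle)) < 1e-4
    # intercepts are identified only up to a common shift
    assert np.max(np.abs(
        (model.intercept_ - model.intercept_.mean()) - (b_oracle - b_oracle.mean())
    )) < 1e-4


class TestEvaluate:
    @staticmethod
    def _indicator_model():
        """Scores driven solely by the source-screening indicator."""
        return SubtypeClassifier.from_dict({
            "classes": ["CE", "SAO"],
            "feature_names": ["any_cardioaortic_source=no", "any_cardioaortic_source=yes"],
            "coef": [[0.0, 4.0], [1.0, 0.0]],
            "intercept": [0.0, 0.0],
            "alpha": 1.0,
            "cv_trace": None,
            "encoder": {"continuous": [], "categorical": ["any_cardioaortic_source"],
                        "means": {}, "scales": {}, "categories": {"any_cardioaortic_source": ["no", "yes"]}},
        })

    def test_perfect_separation_scores_one(self):
        model = self._indicator_model()
        X = pd.DataFrame({"any_cardioaortic_source": ["yes"] * 20 + ["no"] * 80})
        y = np.array(["CE"] * 20 + ["SAO"] * 80, dtype=object)
        rep = evaluate(model, X, y, n_bootstrap=50, seed=0)
        assert rep.per_class["CE"].auc == 1.0
        assert rep.accuracy == 1.0

    def test_two_valued_score_auc_closed_form(self):
        # positives all score 1; fraction p of negatives ties them: AUC = 1 - p/2
        model = self._indicator_model()
        n_pos, n_neg, ties = 50, 1000, 16
        X = pd.DataFrame({"any_cardioaortic_source":
                          ["yes"] * n_pos + ["yes"] * ties + ["no"] * (n_neg - ties)})
        y = np.array(["CE"] * n_pos + ["SAO"] * n_neg, dtype=object)
        rep = evaluate(model, X, y, n_bootstrap=0, seed=0)
        assert rep.per_class["CE"].auc == pytest.approx(1 - (ties / n_neg) / 2, abs=1e-12)

    def test_majority_class_accuracy_equals_its_share(self):
        model = SubtypeClassifier.from_dict({
            "classes": ["CE", "LAA", "SAO"],
            "feature_names": ["sex=male"],
            "coef": [[0.0], [0.0], [0.0]],
            "intercept": [0.0, 0.0, 1.0],  # always predicts SAO
            "alpha": 1.0, "cv_trace": None,
            "encoder": {"continuous": [], "categorical": ["sex"], "means": {}, "scales": {},
                        "categories": {"sex": ["male"]}},
        })
        y = np.array(["CE"] * 20 + ["LAA"] * 320 + ["SAO"] * 660, dtype=object)
        X = pd.DataFrame({"sex": ["male"] * 1000})
        rep = evaluate(model, X, y, n_bootstrap=0, seed=0)
        assert rep.accuracy == pytest.approx(0.66)

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self, cohort, assignments):
        merged = cohort.merge(assignments, on="case_id")
        truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])]
        y = truth["subtype"].to_numpy()
        tr, te, ytr, yte = split_cohort(truth, y, seed=5)
        model = fit_multiclass_l1(build_feature_frame(tr), ytr, alpha=1.0)
        rep = evaluate(model, build_feature_frame(te), yte, n_bootstrap=25, seed=1)
        for m in rep.per_class.values():
            if m.defined and (m.ppv + m.sensitivity) > 0:
                assert m.f1 == pytest.approx(2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity))
        lo, hi = rep.accuracy_ci
        assert lo <= rep.accuracy <= hi

    def test_class_missing_from_test_flagged_undefined(self):
        model = self._indicator_model()
        X = pd.DataFrame({"any_cardioaortic_source": ["no"] * 30})
        y = np.array(["SAO"] * 30, dtype=object)
        rep = evaluate(model, X, y, n_bootstrap=10, seed=0)
        assert not rep.per_class["CE"].defined
        assert np.isnan(rep.per_class["CE"].auc)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(self._indicator_model(), pd.DataFrame({"any_cardioaortic_source": []}), [])


class TestApplyToUndetermined:
    def test_probabilities_form_a_simplex(self, cohort, assignments):
        merged = cohort.merge(assignments, on="case_id")
        truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])]
        model = fit_multiclass_l1(build_feature_frame(truth), truth["subtype"].to_numpy(), alpha=1.0)
        pred = apply_to_undetermined(model, cohort, assignments)
        assert len(pred) > 0
        probs = pred[["p_CE", "p_LAA", "p_SAO"]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (pred["predicted"] == np.array(["CE", "LAA", "SAO"], dtype=object)[
            np.argmax(probs, axis=1)]).all()
        # selection is exactly the incompletely investigated undetermined cases
        sel = assignments["undetermined_kind"] == "incomplete_investigation"
        assert set(pred["case_id"]) == set(assignments.loc[sel, "case_id"])

    def test_no_eligible_cases_returns_empty_with_warning(self, full_workup_cohort):
        from strokecohort import classify_cohort

        assignments, _ = classify_cohort(full_workup_cohort)
        truth_mask = assignments["confidence"].isin(["EVIDENT", "PROBABLE"])
        merged = full_workup_cohort.merge(assignments, on="case_id")
        truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])]
        model = fit_multiclass_l1(build_feature_frame(truth), truth["subtype"].to_numpy(), alpha=1.0)
        # fully investigated cohort: nothing is eligible for reclassification
        eligible = assignments["undetermined_kind"] == "incomplete_investigation"
        assert eligible.sum() == 0
        with pytest.warns(UserWarning, match="no incompletely investigated"):
            pred = apply_to_undetermined(model, full_workup_cohort, assignments)
        assert len(pred) == 0


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, tmp_path, cohort, assignments):
        merged = cohort.merge(assignments, on="case_id")
        truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])].iloc[:400]
        X = build_feature_frame(truth)
        model = fit_multiclass_l1(X, truth["subtype"].to_numpy(), alpha=1.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = SubtypeClassifier.from_json(path)
        assert np.allclose(model.predict_proba(X), restored.predict_proba(X), atol=1e-12)
        assert list(restored.classes_) == list(model.classes_)
        assert restored.feature_names_ == model.feature_names_

    def test_encoder_maps_unseen_levels_to_zero(self):
        enc = FeatureEncoder().fit(pd.DataFrame({"sex": ["male", "female"]}))
        Z = enc.transform(pd.DataFrame({"sex": ["other"]}))
        assert np.allclose(Z, 0.0)
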