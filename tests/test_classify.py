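import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cfrank import classify as clf
from cfrank.classify import _cd_fit, _standardize


def _logistic_data(n=60, p=5, d_prime=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += d_prime * y
    cols = [f"f{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)]), y


# --------------------------------------------------------------------- lasso

def test_lambda_at_or_above_max_gives_null_model():
    X, y = _logistic_data()
    lmax = clf.lambda_max(X, y)
    model = clf.fit_lasso_logistic(X, y, lmax * (1 + 1e-9))
    assert (model.coef == 0).all()
    ybar = y.mean()
    assert model.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-9)
    # just below lambda_max at least one coefficient activates
    model2 = clf.fit_lasso_logistic(X, y, lmax * 0.95)
    assert (model2.coef != 0).any()


def test_tiny_penalty_matches_unpenalized_newton_fit():
    """lambda -> 0 recovers the plain logistic MLE (statsmodels oracle)."""
    import statsmodels.api as sm

    X, y = _logistic_data(n=80, p=3, d_prime=1.0, seed=2)
    Xs, _, _ = _standardize(X)
    beta, b0 = _cd_fit(Xs.to_numpy(), y.astype(float), 1e-8)
    sm_fit = sm.Logit(y, sm.add_constant(Xs.to_numpy())).fit(disp=0, tol=1e-12)
    assert np.allclose(beta, sm_fit.params[1:], atol=1e-3)
    assert abs(b0 - sm_fit.params[0]) < 1e-3


@pytest.mark.parametrize("lam", [0.2, 0.05, 0.01, 0.001])
def test_lasso_matches_sklearn_saga_oracle(lam):
    import warnings

    from sklearn.linear_model import LogisticRegression

    X, y = _logistic_data(n=50, p=6, d_prime=1.5, seed=3)
    Xs, _, _ = _standardize(X)
    beta, b0 = _cd_fit(Xs.to_numpy(), y.astype(float), lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk = LogisticRegression(l1_ratio=1.0, solver="saga", C=1 / (len(y) * lam),
                                tol=1e-12, max_iter=200_000)
        sk.fit(Xs.to_numpy(), y)
    assert np.allclose(beta, sk.coef_[0], atol=1e-6)
    assert abs(b0 - sk.intercept_[0]) < 1e-6


@pytest.mark.parametrize("lam", [0.15, 0.02, 0.002])
def test_lasso_satisfies_kkt_conditions(lam):
    X, y = _logistic_data(n=70, p=8, d_prime=1.2, seed=4)
    Xs, _, _ = _standardize(X)
    Xv = Xs.to_numpy()
    beta, b0 = _cd_fit(Xv, y.astype(float), lam)
    mu = expit(b0 + Xv @ beta)
    g = Xv.T @ (mu - y) / len(y)
    zero, nonzero = beta == 0, beta != 0
    assert np.all(np.abs(g[zero]) <= lam + 1e-6)
    assert np.all(np.abs(g[nonzero] + lam * np.sign(beta[nonzero])) <= 1e-6)
    assert abs(mu.mean() - y.mean()) < 1e-6  # unpenalized intercept gradient


def test_duplicated_feature_preserves_predictions():
    X, y = _logistic_data(n=50, p=1, d_prime=3.0, seed=5)
    X2 = X.copy()
    X2["f0_dup"] = X["f0"]
    m1 = clf.fit_lasso_logistic(X, y, 0.02)
    m2 = clf.fit_lasso_logistic(X2, y, 0.02)
    assert np.allclose(m1.predict_proba(X), m2.predict_proba(X2), atol=1e-6)


def test_constant_labels_error():
    X, _ = _logistic_data()
    with pytest.raises(ValueError, match="constant"):
        clf.fit_lasso_logistic(X, np.ones(len(X)), 0.1)


def test_lambda_grid_spec():
    g = clf.lambda_grid()
    assert len(g) == 100
    assert g[0] == pytest.approx(1e-4)
    assert g[-1] == pytest.approx(1e1)
    assert (np.diff(np.log10(g)) > 0).all()


# ----------------------------------------------------------------------- AUC

def test_auc_separated_and_tied():
    assert clf.auc([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert clf.auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5


def test_auc_pairwise_counting_example():
    """cases {0.8, 0.3}, controls {0.1, 0.4, 0.35}: 4 of 6 pairs won."""
    scores = [0.8, 0.3, 0.1, 0.4, 0.35]
    labels = [1, 1, 0, 0, 0]
    assert clf.auc(scores, labels) == pytest.approx(4 / 6)


def test_auc_matches_brute_force_pairwise_oracle():
    rng = np.random.default_rng(6)
    for _ in range(200):
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        if labels.sum() == 0 or labels.sum() == n:
            continue
        scores = np.round(rng.normal(size=n), 1)  # provoke ties
        cases, controls = scores[labels == 1], scores[labels == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        oracle = wins / (len(cases) * len(controls))
        assert clf.auc(scores, labels) == pytest.approx(oracle, abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        clf.auc([0.1, 0.2], [1, 1])


# ------------------------------------------------------------------ AUC CI

def test_auc_ci_clips_at_one():
    lo, hi = clf.auc_ci([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert hi == 1.0
    assert 0.0 <= lo <= 1.0


def test_auc_ci_label_swap_symmetry():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=30)
    labels = (rng.random(30) < 0.5).astype(int)
    if labels.sum() < 2 or labels.sum() > 28:
        labels[:3] = [0, 1, 1]
    lo, hi = clf.auc_ci(scores, labels)
    lo2, hi2 = clf.auc_ci(scores, 1 - labels)
    assert lo2 == pytest.approx(1 - hi, abs=1e-12)
    assert hi2 == pytest.approx(1 - lo, abs=1e-12)


def test_auc_ci_covers_half_under_null():
    rng = np.random.default_rng(8)
    hits = 0
    for _ in range(200):
        scores = rng.normal(size=60)
        labels = np.repeat([0, 1], 30)
        lo, hi = clf.auc_ci(scores, labels)
        hits += lo <= 0.5 <= hi
    assert hits / 200 == pytest.approx(0.95, abs=0.05)


# ---------------------------------------------------------------- detection

def test_detection_threshold_95_specificity():
    rng = np.random.default_rng(9)
    controls = rng.uniform(size=20)
    cases = controls + 0.5
    rule, detected = clf.detection_call(pd.Series(cases), controls, spec=0.95)
    assert np.sum(controls >= rule.threshold) == 1
    assert rule.specificity == pytest.approx(0.95)


def test_detection_full_specificity_no_false_positives():
    controls = np.array([0.1, 0.4, 0.2])
    rule, _ = clf.detection_call(pd.Series([0.9]), controls, spec=1.0)
    assert np.sum(controls >= rule.threshold) == 0
    assert rule.threshold > 0.4


def test_detection_separated_cases_all_detected():
    controls = np.linspace(0, 0.3, 25)
    cases = pd.Series(np.linspace(0.5, 0.9, 10))
    _, detected = clf.detection_call(cases, controls, spec=0.95)
    assert detected.all()


def test_detection_requires_controls():
    with pytest.raises(ValueError):
        clf.detection_call(pd.Series([0.5]), np.array([]))


# -------------------------------------------------------------------- LOOCV

def test_loocv_returns_one_probability_per_sample():
    X, y = _logistic_data(n=20, p=3, d_prime=2.0, seed=10)
    res = clf.loocv_predict(X, y)
    assert len(res.oof_probability) == 20
    assert res.oof_probability.between(0, 1).all()
    assert res.ci[0] <= res.auc <= res.ci[1]


def test_loocv_perfectly_separable_cohort():
    """Two Gaussians at d' = 6: LOOCV AUC = 1."""
    X, y = _logistic_data(n=40, p=3, d_prime=6.0, seed=11)
    res = clf.loocv_predict(X, y)
    assert res.auc == 1.0


def test_loocv_standardization_no_leakage():
    """An extreme held-out value must not shift its own fold's scaling:
    the remaining folds' probabilities stay identical."""
    X, y = _logistic_data(n=20, p=2, d_prime=2.0, seed=12)
    res1 = clf.loocv_predict(X, y)
    X2 = X.copy()
    X2.iloc[0, 0] = 1e4  # corrupt one held-out sample
    res2 = clf.loocv_predict(X2, y)
    # fold 0's training set in every *other* fold changes, but fold 0's own
    # prediction is produced from a model trained without sample 0; its
    # training standardization is unchanged
    lam_idx = np.argmin(np.abs(res1.auc_by_lambda.index.to_numpy()
                               - res1.chosen_lambda))
    assert res1.chosen_lambda > 0  # smoke: selection happened
    # direct check: refit fold-0 by hand from both inputs
    from cfrank.classify import _standardize
    tr1, m1, s1 = _standardize(X.iloc[1:])
    tr2, m2, s2 = _standardize(X2.iloc[1:])
    pd.testing.assert_series_equal(m1, m2)
    pd.testing.assert_series_equal(s1, s2)


def test_loocv_requires_minimum_samples():
    X, y = _logistic_data(n=20, p=2)
    with pytest.raises(ValueError):
        clf.loocv_predict(X.iloc[:5], y[:5])
    with pytest.raises(ValueError):
        clf.loocv_predict(X.iloc[:8], np.array([1, 0, 0, 0, 0, 0, 0, 0]))


# ----------------------------------------------------------------- survival

def km_oracle(times, events):
    """Hand product-limit: S(t) after each distinct time."""
    out = {}
    s = 1.0
    at_risk = len(times)
    for t in sorted(set(times)):
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        c = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 0)
        if d:
            s *= 1 - d / at_risk
        out[t] = s
        at_risk -= d + c
    return out


def _surv_at(curves, group, t):
    sub = curves[(curves["group"] == group) & (curves["time"] <= t)]
    return sub["survival"].iloc[-1]


def test_km_two_subjects():
    """One event at t=5, one censored at 10: S = 0.5 after t=5."""
    curves, p = clf.km_logrank([5, 10], [1, 0], ["g", "g"])
    assert _surv_at(curves, "g", 5) == pytest.approx(0.5)
    assert _surv_at(curves, "g", 10) == pytest.approx(0.5)
    assert p is None  # single group -> no test


def test_km_no_events_flat_curve(caplog):
    with caplog.at_level("WARNING", logger="cfrank"):
        curves, p = clf.km_logrank([5, 10, 15, 20], [0, 0, 0, 0],
                                   ["a", "a", "b", "b"])
    assert (curves["survival"] == 1.0).all()
    assert np.isnan(p)


def test_km_identical_groups_logrank_p_one():
    times = [3, 6, 9, 3, 6, 9]
    events = [1, 0, 1, 1, 0, 1]
    groups = ["a", "a", "a", "b", "b", "b"]
    _, p = clf.km_logrank(times, events, groups)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_km_matches_product_limit_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    times = rng.integers(1, 30, n).astype(float)
    events = rng.integers(0, 2, n)
    curves, _ = clf.km_logrank(times, events, ["g"] * n)
    oracle = km_oracle(times, events)
    for t, s in oracle.items():
        assert _surv_at(curves, "g", t) == pytest.approx(s, abs=1e-12)


def test_km_administrative_censoring_at_36_months():
    curves, _ = clf.km_logrank([40.0, 50.0], [1, 1], ["g", "g"])
    assert (curves["survival"] == 1.0).all()  # events beyond 36 are censored
    assert curves["time"].max() == 36.0


def test_stratify_median_split():
    probs = pd.Series([0.1, 0.2, 0.3, 0.9], index=list("abcd"))
    groups = clf.stratify_median(probs)
    assert groups.tolist() == ["low", "low", "high", "high"]
    # exact-median score goes to "low"
    probs2 = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
    assert clf.stratify_median(probs2)["b"] == "low"


# ------------------------------------------------------------------ relapse

def test_relapse_pipeline_composition():
    rng = np.random.default_rng(13)
    n_pat = 24
    feats = [f"ct{i}" for i in range(12)]
    cohort = pd.DataFrame({
        "sample_id": [f"p{i}_{tp}" for i in range(n_pat) for tp in ("t0", "t1")],
        "patient_id": [f"p{i}" for i in range(n_pat) for _ in range(2)],
        "timepoint": ["t0", "t1"] * n_pat,
        "relapse": np.repeat(rng.integers(0, 2, n_pat), 2).astype(float),
    })
    relapse = cohort.drop_duplicates("patient_id").set_index("patient_id")["relapse"]
    rows = {}
    for i in range(n_pat):
        base = rng.normal(100, 10, len(feats))
        shift = rng.normal(0, 12, len(feats))
        if relapse[f"p{i}"] == 1:
            shift[:2] += 40.0  # injected relapse effect in two features
        rows[f"p{i}_t0"] = base
        rows[f"p{i}_t1"] = base + shift
    ranks = pd.DataFrame(rows, index=feats).T
    res, sel = clf.relapse_pipeline(ranks, cohort, "t0", "t1", k=5,
                                    eligible_features=feats)
    assert set(sel.selected) <= set(feats)
    assert len(sel.selected) == 5
    assert "ct0" in sel.selected and "ct1" in sel.selected  # largest IQR
    assert res.auc > 0.8
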