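import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from benthomap import model
from benthomap.hub import label_stations
from benthomap.model import (
    ENDO_PREDICTORS,
    EPI_PREDICTORS,
    ModelConfig,
    PredictionGrid,
    accuracy_ci,
    build_feature_matrix,
    cohens_kappa,
    confusion_matrix,
    evaluate,
    fit,
    hand_till_auc,
    predict_grid,
)

FAST = dict(n_trees_grid=(100,), mtry_offsets=(0,))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_accuracy_hand_computed():
    conf = pd.DataFrame([[40, 10], [5, 45]], index=["a", "b"], columns=["a", "b"])
    out = evaluate(conf)
    assert out["accuracy"] == pytest.approx(0.85)


def test_kappa_hand_computed():
    # p_o = 0.85; marginals (50,50) x (45,55) -> p_e = 0.5; kappa = 0.7
    conf = np.array([[40, 10], [5, 45]])
    assert cohens_kappa(conf) == pytest.approx(0.7)


def test_perfect_diagonal():
    conf = np.diag([10, 20, 30])
    out = evaluate(conf)
    assert out["accuracy"] == 1.0
    assert out["kappa"] == pytest.approx(1.0)


def test_uniform_matrix_kappa_zero():
    conf = np.full((4, 4), 7)
    assert cohens_kappa(conf) == pytest.approx(0.0)


def test_degenerate_matrix_kappa_none():
    conf = np.array([[12, 0], [0, 0]])
    assert cohens_kappa(conf) is None


def test_kappa_matches_sklearn(rng):
    y_true = rng.integers(0, 4, size=400)
    y_pred = np.where(rng.random(400) < 0.6, y_true, rng.integers(0, 4, size=400))
    conf = confusion_matrix(y_true, y_pred, classes=list(range(4)))
    assert cohens_kappa(conf) == pytest.approx(
        cohen_kappa_score(y_true, y_pred), abs=1e-12
    )


def test_ci_matches_scipy_binomtest():
    from scipy.stats import binomtest

    lo, hi = accuracy_ci(85, 100)
    ref = binomtest(85, 100).proportion_ci(confidence_level=0.95, method="exact")
    assert lo == pytest.approx(ref.low)
    assert hi == pytest.approx(ref.high)
    assert lo <= 0.85 <= hi


def test_ci_edge_cases():
    lo, hi = accuracy_ci(0, 10)
    assert lo == 0.0
    lo, hi = accuracy_ci(10, 10)
    assert hi == 1.0


def test_hand_till_matches_sklearn_ovo(rng):
    n, k = 300, 4
    y = rng.integers(0, k, size=n)
    raw = rng.random((n, k)) + np.eye(k)[y] * 0.7
    proba = raw / raw.sum(axis=1, keepdims=True)
    ours = hand_till_auc(y, proba, classes=list(range(k)))
    ref = roc_auc_score(y, proba, multi_class="ovo", average="macro")
    assert ours == pytest.approx(ref, abs=1e-10)


def test_hand_till_single_class_none():
    proba = np.array([[0.7, 0.3], [0.6, 0.4]])
    assert hand_till_auc([0, 0], proba, classes=[0, 1]) is None


def test_confusion_matrix_total():
    conf = confusion_matrix(["a", "b", "a"], ["a", "a", "b"])
    assert conf.to_numpy().sum() == 3


def test_kappa_rejects_bad_matrix():
    with pytest.raises(ValueError):
        cohens_kappa(np.array([[1, 2, 3]]))
    with pytest.raises(ValueError):
        cohens_kappa(np.array([[1, -1], [0, 1]]))


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def test_endo_features_exclude_par_and_photic():
    assert "par" not in ENDO_PREDICTORS
    assert "photic" not in ENDO_PREDICTORS
    assert "par" in EPI_PREDICTORS and "photic" in EPI_PREDICTORS


def test_feature_matrix_samples_cell_values(small_seascape):
    scape = small_seascape
    stations = label_stations(scape.stations)
    endo = stations[stations["realm"] == "endo"]
    X, y = build_feature_matrix(endo, scape.environment, scape.sediment, "endo")
    assert len(X) == len(endo)
    assert "sediment" in X.columns and "par" not in X.columns
    i = 0
    r, c = int(endo["row"].iloc[i]), int(endo["col"].iloc[i])
    assert X["salinity"].iloc[i] == scape.environment["salinity"][r, c]
    assert X["sediment"].iloc[i] == str(scape.sediment[r, c])


def test_epi_matrix_restricted_to_hard_cells(small_seascape):
    scape = small_seascape
    stations = label_stations(scape.stations)
    epi = stations[stations["realm"] == "epi"]
    X, y = build_feature_matrix(
        epi, scape.environment, scape.sediment, "epi",
        photic=scape.photic, hard=scape.hard,
    )
    rows = epi["row"].to_numpy()
    cols = epi["col"].to_numpy()
    assert len(X) == int(scape.hard[rows, cols].sum())


def test_empty_station_set():
    X, y = build_feature_matrix(
        pd.DataFrame(columns=["row", "col", "label"]), {}, np.empty((0, 0)), "endo"
    )
    assert len(X) == 0 and len(y) == 0


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def separable_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = np.where(x > 0, "pos", "neg")
    X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
    return X, pd.Series(y)


def test_separable_classes_perfect_test_metrics():
    X, y = separable_data()
    res = fit(ModelConfig(seed=0, **FAST), X, y)
    assert res.accuracy == 1.0
    assert res.kappa == pytest.approx(1.0)
    assert res.auc == pytest.approx(1.0)


def test_split_proportions_within_one_row():
    X, y = separable_data(n=1000)
    res = fit(ModelConfig(seed=3, **FAST), X, y)
    assert res.confusion.to_numpy().sum() == 300


def test_seeded_determinism():
    X, y = separable_data(n=150, seed=4)
    r1 = fit(ModelConfig(seed=9, **FAST), X, y)
    r2 = fit(ModelConfig(seed=9, **FAST), X, y)
    assert r1.accuracy == r2.accuracy
    assert r1.oob_error == r2.oob_error
    pd.testing.assert_frame_equal(r1.confusion, r2.confusion)
    pd.testing.assert_series_equal(r1.importance, r2.importance)


def test_permuted_labels_kappa_near_zero(rng):
    n = 1000
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    y = pd.Series(rng.permutation(np.repeat(["u", "v"], n // 2)))
    res = fit(ModelConfig(seed=1, **FAST), X, y)
    assert abs(res.kappa) < 0.1


def test_accuracy_inside_its_ci():
    X, y = separable_data(n=120, seed=5)
    res = fit(ModelConfig(seed=5, **FAST), X, y)
    assert res.ci_low <= res.accuracy <= res.ci_high


@pytest.mark.parametrize("strategy", ["downsample", "upsample", "balanced", "smote"])
def test_imbalance_strategies_leave_test_split_untouched(strategy):
    rng = np.random.default_rng(0)
    n = 300
    x = rng.normal(size=n)
    y = np.where(rng.random(n) < 0.85, "major", "minor")
    X = pd.DataFrame({"x": x + (y == "minor") * 2.0})
    res = fit(ModelConfig(seed=2, imbalance=strategy, **FAST), X, pd.Series(y))
    # the audited contract: the confusion matrix covers exactly the 30 % split
    assert res.confusion.to_numpy().sum() == n - int(round(n * 0.7))


def test_smote_balances_training_classes():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"x": rng.normal(size=100), "sediment_S": np.ones(100)})
    y = pd.Series(["a"] * 85 + ["b"] * 15)
    Xr, yr = model._smote(X, y, rng)
    assert (yr.value_counts() == 85).all()
    assert set(Xr["sediment_S"]) == {1.0}


def test_too_few_classes_rejected():
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        fit(ModelConfig(**FAST), X, pd.Series(["a", "a", "a"]))


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(train_fraction=1.5)
    with pytest.raises(ValueError):
        ModelConfig(imbalance="magic")
    with pytest.raises(ValueError):
        ModelConfig(n_trees_grid=())


# ---------------------------------------------------------------------------
# Grid prediction
# ---------------------------------------------------------------------------

def fitted_on_seascape(scape, seed=0):
    stations = label_stations(scape.stations)
    endo = stations[stations["realm"] == "endo"]
    X, y = build_feature_matrix(endo, scape.environment, scape.sediment, "endo")
    return fit(ModelConfig(seed=seed, **FAST), X, y)


def test_predict_grid_token_implies_probability(small_seascape):
    res = fitted_on_seascape(small_seascape)
    grid = predict_grid(res, small_seascape.environment, small_seascape.sediment, "endo")
    for idx in np.ndindex(grid.tokens.shape):
        if grid.tokens[idx] is not None:
            assert np.isfinite(grid.probability[idx])
            assert 0.0 <= grid.probability[idx] <= 1.0


def test_predict_grid_nan_predictor_gives_na(small_seascape):
    res = fitted_on_seascape(small_seascape)
    env = {k: v.copy() for k, v in small_seascape.environment.items()}
    env["salinity"][0, 0] = np.nan
    grid = predict_grid(res, env, small_seascape.sediment, "endo")
    assert grid.tokens[0, 0] is None and np.isnan(grid.probability[0, 0])


def test_predict_grid_high_confidence_on_pure_region(small_seascape):
    res = fitted_on_seascape(small_seascape)
    grid = predict_grid(res, small_seascape.environment, small_seascape.sediment, "endo")
    # deterministic rule, separable predictors: most cells confidently assigned
    assert np.nanmedian(grid.probability) > 0.67


def test_prediction_grid_invariant_enforced():
    with pytest.raises(ValueError):
        PredictionGrid(
            tokens=np.array([["x"]], dtype=object), probability=np.array([[np.nan]])
        )


def test_importance_recovers_generating_variables(small_seascape):
    res = fitted_on_seascape(small_seascape)
    top3 = list(res.importance.index[:3])
    assert {"salinity", "depth", "sediment"} & set(top3)
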