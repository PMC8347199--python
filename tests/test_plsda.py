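"""NIPALS PLS1 core, CV selection, VIP, discriminant regions, evaluation."""

import numpy as np
import pytest

from hypospec import (
    WavenumberGrid,
    classify,
    crossval_select,
    discriminant_regions,
    evaluate,
    fit_pls1,
    fit_plsda,
    predict,
    vip,
)
from hypospec.plsda import PLSDAModel


def _centered(rng, n=8, j=5):
    X = rng.normal(size=(n, j))
    y = rng.normal(size=n)
    return X - X.mean(0), y - y.mean()


def test_pls1_single_predictor_equals_ols(rng):
    x = rng.normal(size=(12, 1))
    y = 2.0 * x[:, 0] + rng.normal(0, 0.1, 12)
    xc, yc = x - x.mean(0), y - y.mean()
    *_, b = fit_pls1(xc, yc, 1)
    slope = float(xc[:, 0] @ yc / (xc[:, 0] @ xc[:, 0]))
    assert b[0] == pytest.approx(slope, abs=1e-10)


def test_pls1_full_rank_equals_least_squares(rng):
    Xc, yc = _centered(rng, 8, 5)
    *_, b = fit_pls1(Xc, yc, 5)
    fitted = Xc @ b
    oracle = Xc @ np.linalg.lstsq(Xc, yc, rcond=None)[0]
    assert np.max(np.abs(fitted - oracle)) <= 1e-8


def test_pls1_scores_mutually_orthogonal(rng):
    Xc, yc = _centered(rng, 20, 10)
    _, _, _, T, _ = fit_pls1(Xc, yc, 6)
    G = T.T @ T
    off = G - np.diag(np.diag(G))
    assert np.max(np.abs(off)) <= 1e-8


def test_pls1_training_rss_nonincreasing_in_components(rng):
    Xc, yc = _centered(rng, 25, 12)
    rss = []
    for a in range(1, 9):
        *_, b = fit_pls1(Xc, yc, a)
        rss.append(float(((yc - Xc @ b) ** 2).sum()))
    assert all(rss[i + 1] <= rss[i] + 1e-10 for i in range(len(rss) - 1))


def test_pls1_matches_sklearn_reference(rng):
    """Independent cross-check against an established PLS implementation."""
    from sklearn.cross_decomposition import PLSRegression

    X = rng.normal(size=(20, 8))
    y = rng.normal(size=20)
    Xc, yc = X - X.mean(0), y - y.mean()
    *_, b = fit_pls1(Xc, yc, 3)
    ref = PLSRegression(n_components=3, scale=False).fit(X, y)
    assert np.max(np.abs(Xc @ b - (ref.predict(X).ravel() - y.mean()))) <= 1e-8


def test_pls1_input_validation(rng):
    Xc, yc = _centered(rng, 8, 5)
    with pytest.raises(ValueError):
        fit_pls1(Xc, yc, 0)
    with pytest.raises(ValueError):
        fit_pls1(Xc, yc, 9)
    with pytest.raises(ValueError):
        fit_pls1(Xc, np.zeros(8), 1)


def _toy_model(rng, n=30, j=6, a=3):
    X = rng.normal(size=(n, j))
    labels = np.array(["CTRL", "HFD"] * (n // 2))
    X[labels == "HFD"] += 1.0
    return X, labels, fit_plsda(X, labels, a)


def test_predict_two_route_equivalence(rng):
    """Regression-vector route equals score-space accumulation."""
    X, labels, model = _toy_model(rng)
    Xc = X - model.x_mean
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    score_route = model.y_mean + (Xc @ R) @ model.y_loadings
    assert np.max(np.abs(predict(model, X) - score_route)) <= 1e-10


def test_predict_zero_row_gives_intercept(rng):
    X, labels, model = _toy_model(rng)
    yhat = predict(model, model.x_mean[None, :])
    assert yhat[0] == pytest.approx(model.y_mean, abs=1e-12)


def test_predict_channel_mismatch(rng):
    X, labels, model = _toy_model(rng)
    with pytest.raises(ValueError):
        predict(model, np.zeros((2, 4)))


def test_perfectly_collinear_training_recovers_dummies(rng):
    y_codes = np.array([0.0, 1.0] * 10)
    X = np.column_stack([y_codes, rng.normal(size=20)])
    labels = np.where(y_codes == 1, "HFD", "CTRL")
    model = fit_plsda(X, labels, 2)
    assert np.max(np.abs(predict(model, X) - y_codes)) <= 1e-10


def test_classify_threshold_strict(rng):
    X, labels, model = _toy_model(rng)
    out = classify(model, yhat=np.array([0.7, 0.3, 0.5]))
    assert list(out) == ["HFD", "CTRL", "CTRL"]  # exactly 0.5 is NOT class 1


def test_label_coding_symmetry(rng):
    X, labels, model = _toy_model(rng)
    flipped = fit_plsda(X, labels, 3, class_code={"CTRL": 1, "HFD": 0})
    yh, yh_f = predict(model, X), predict(flipped, X)
    assert np.max(np.abs(yh_f - (1.0 - yh))) <= 1e-8
    assert np.array_equal(classify(model, X), classify(flipped, X))
    # coefficients flip sign, VIP (importance) unchanged
    assert np.max(np.abs(flipped.coef + model.coef)) <= 1e-8
    assert np.max(np.abs(vip(flipped) - vip(model))) <= 1e-8


def test_crossval_separable_blobs_reaches_perfect_accuracy(rng):
    X = np.vstack([
        rng.normal(0.0, 0.3, size=(40, 4)),
        rng.normal(3.0, 0.3, size=(40, 4)),
    ])
    labels = np.array(["CTRL"] * 40 + ["HFD"] * 40)
    curve = crossval_select(X, labels, a_max=4, k=10, seed=3)
    assert curve.accuracy.max() == 1.0
    assert curve.chosen <= 2
    assert curve.chosen in curve.n_components
    again = crossval_select(X, labels, a_max=4, k=10, seed=3)
    assert np.array_equal(curve.accuracy, again.accuracy)
    assert curve.chosen == again.chosen


def test_crossval_per_class_accuracies_bounded(rng):
    X = rng.normal(size=(40, 5))
    labels = np.array(["CTRL", "HFD"] * 20)
    curve = crossval_select(X, labels, a_max=3, k=5, seed=0)
    for arr in curve.accuracy_per_class.values():
        assert np.all((0 <= arr) & (arr <= 1))


def test_crossval_errors(rng):
    X = rng.normal(size=(20, 4))
    with pytest.raises(ValueError):
        crossval_select(X, np.array(["CTRL"] * 20), a_max=2)
    with pytest.raises(ValueError):
        crossval_select(X, np.array(["CTRL", "HFD"] * 10), a_max=2, k=1)
    with pytest.raises(ValueError):
        crossval_select(X, np.array(["CTRL", "HFD"] * 10), a_max=2, k=15)


def test_crossval_group_option_keeps_groups_together(rng):
    X = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(3, 0.3, (20, 3))])
    labels = np.array(["CTRL"] * 20 + ["HFD"] * 20)
    groups = np.repeat(np.arange(8), 5)
    curve = crossval_select(X, labels, a_max=2, k=4, seed=1, groups=groups)
    assert curve.accuracy.shape == (2,)


def test_vip_mean_square_identity(rng):
    X, labels, model = _toy_model(rng, n=40, j=9, a=4)
    v = vip(model)
    assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)


def test_vip_single_component_reduction(rng):
    X, labels, model = _toy_model(rng, a=1)
    w = model.weights[:, 0]
    expected = np.sqrt(w.size) * np.abs(w) / np.linalg.norm(w)
    assert np.max(np.abs(vip(model) - expected)) <= 1e-10


def test_vip_matches_straight_loop_oracle(rng):
    X, labels, model = _toy_model(rng, n=20, j=6, a=3)
    W, T, q = model.weights, model.scores, model.y_loadings
    j = W.shape[0]
    ssy = [q[a] ** 2 * float(T[:, a] @ T[:, a]) for a in range(q.size)]
    oracle = np.zeros(j)
    for jj in range(j):
        num = sum(
            ssy[a] * (W[jj, a] / np.linalg.norm(W[:, a])) ** 2
            for a in range(q.size)
        )
        oracle[jj] = np.sqrt(j * num / sum(ssy))
    assert np.max(np.abs(vip(model) - oracle)) <= 1e-10


def test_discriminant_regions_direction_and_flip(rng):
    X, labels, model = _toy_model(rng, n=60, j=8, a=2)
    grid = WavenumberGrid.uniform(1000, 1070, 8)
    rep = discriminant_regions(model, grid)
    assert np.array_equal(rep.significant, vip(model) > 1.0)
    flipped = fit_plsda(X, labels, 2, class_code={"CTRL": 1, "HFD": 0})
    rep_f = discriminant_regions(flipped, grid)
    assert np.array_equal(rep.significant, rep_f.significant)
    # coefficient signs flip with the coding, but the class each region
    # favours is a property of the data and must not change
    for (_, r), (_, r_f) in zip(rep.regions.iterrows(), rep_f.regions.iterrows()):
        assert np.sign(r["mean_coef"]) == -np.sign(r_f["mean_coef"])
        assert r["direction"] == r_f["direction"]


def test_discriminant_regions_empty_when_vip_uniform():
    """Uniform weights make every VIP exactly 1: strictly-greater mask is empty."""
    j = 6
    w = np.full((j, 1), 1.0 / np.sqrt(j))
    model = PLSDAModel(
        weights=w,
        x_loadings=w.copy(),
        y_loadings=np.array([1.0]),
        scores=np.ones((4, 1)),
        coef=np.ones(j),
        n_components=1,
        x_mean=np.zeros(j),
        y_mean=0.5,
    )
    rep = discriminant_regions(model, WavenumberGrid.uniform(0, 50, j))
    assert not rep.significant.any()
    assert len(rep.regions) == 0


def _threshold_model():
    """One-channel identity model: yhat equals the input value."""
    return PLSDAModel(
        weights=np.ones((1, 1)),
        x_loadings=np.ones((1, 1)),
        y_loadings=np.array([1.0]),
        scores=np.ones((2, 1)),
        coef=np.array([1.0]),
        n_components=1,
        x_mean=np.zeros(1),
        y_mean=0.0,
    )


def test_evaluate_counted_confusion_fixture():
    """7/10 CTRL below threshold and 9/10 HFD above: 70% and 90%."""
    model = _threshold_model()
    x = np.array([0.2] * 7 + [0.8] * 3 + [0.9] * 9 + [0.1] * 1)[:, None]
    labels = np.array(["CTRL"] * 10 + ["HFD"] * 10)
    out = evaluate(model, x, labels)
    assert out["per_class"]["CTRL"] == pytest.approx(0.70)
    assert out["per_class"]["HFD"] == pytest.approx(0.90)
    assert out["overall"] == pytest.approx(0.80)


def test_evaluate_all_correct_and_all_wrong():
    model = _threshold_model()
    labels = np.array(["CTRL", "HFD"])
    assert evaluate(model, np.array([[0.1], [0.9]]), labels)["overall"] == 1.0
    flipped = evaluate(model, np.array([[0.9], [0.1]]), labels)
    assert flipped["per_class"]["CTRL"] == 0.0
    assert flipped["per_class"]["HFD"] == 0.0
    with pytest.raises(ValueError):
        evaluate(model, np.array([[0.1]]), np.array(["CTRL"]))
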