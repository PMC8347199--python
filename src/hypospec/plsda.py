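"""PLS-DA on a hand-implemented NIPALS PLS1 core.

Class membership is dummy-coded (HFD = 1, CTRL = 0, so that a positive
regression coefficient means "on average higher in HFD"), a PLS1 regression
is fit by NIPALS, and a sample is classified as the code-1 class when its
predicted response exceeds 0.5 (strictly).  Model complexity (number of
latent variables, LVs) is chosen by stratified 10-fold cross-validation
with per-fold recentering; ties in CV accuracy go to the smaller model.

Variable importance in projection (VIP) summarizes each channel's
contribution; channels with VIP > 1 are flagged significant, and contiguous
significant channels are merged into discriminant regions whose direction
(HFD-higher vs CTRL-higher) is the sign of the mean regression coefficient
inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .datatypes import WavenumberGrid

__all__ = [
    "PLSDAModel",
    "CvCurve",
    "DiscriminantReport",
    "DEFAULT_CLASS_CODE",
    "fit_pls1",
    "fit_plsda",
    "predict",
    "classify",
    "crossval_select",
    "vip",
    "discriminant_regions",
    "evaluate",
]

DEFAULT_CLASS_CODE = {"CTRL": 0, "HFD": 1}


def fit_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int, strict: bool = True):
    """NIPALS PLS1 on centered data.

    Per component: w = X'y / ||X'y||, t = Xw, p = X't / t't, q = y't / t't,
    then X is deflated by t p'.  The response is not deflated (for PLS1 the
    predictions are identical either way).  Returns (W, P, q, T, b) with
    the regression vector b = W (P'W)^-1 q.

    When the residual covariance X'y vanishes before ``n_components`` are
    extracted the data carry no further predictive structure; with
    ``strict`` this is an error, otherwise the model is truncated at the
    achieved number of components.
    """
    X = np.array(Xc, dtype=float)
    y = np.asarray(yc, dtype=float)
    n, j = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a vector with one entry per row of X")
    if np.allclose(y, y[0]):
        raise ValueError("response has zero variance; dummy coding degenerate")
    max_a = min(n - 1, j)
    if not (1 <= n_components <= max_a):
        raise ValueError(
            f"n_components must lie in [1, {max_a}] for a {n}x{j} matrix"
        )
    W = np.empty((j, n_components))
    P = np.empty((j, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    achieved = 0
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            if strict:
                raise ValueError(
                    f"residual covariance vanished at component {a + 1}; "
                    "reduce n_components"
                )
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        p = (X.T @ t) / tt
        W[:, a] = w
        P[:, a] = p
        T[:, a] = t
        q[a] = float(y @ t) / tt
        X -= np.outer(t, p)
        achieved = a + 1
    W, P, T, q = W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]
    b = W @ np.linalg.solve(P.T @ W, q)
    return W, P, q, T, b


@dataclass
class PLSDAModel:
    """Fitted PLS-DA state sufficient for prediction and interpretation."""

    weights: np.ndarray  # W, channels x A
    x_loadings: np.ndarray  # P, channels x A
    y_loadings: np.ndarray  # q, A
    scores: np.ndarray  # T, training rows x A
    coef: np.ndarray  # b, channels
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    class_code: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_CODE))
    threshold: float = 0.5

    @property
    def positive_class(self) -> str:
        return next(k for k, v in self.class_code.items() if v == 1)

    @property
    def negative_class(self) -> str:
        return next(k for k, v in self.class_code.items() if v == 0)

    def to_json(self, path) -> None:
        state = {
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "class_code": self.class_code,
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def from_json(cls, path) -> "PLSDAModel":
        with open(path) as fh:
            d = json.load(fh)
        W = np.array(d["weights"])
        return cls(
            weights=W,
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            scores=np.zeros((0, W.shape[1])),
            coef=np.array(d["coef"]),
            n_components=int(d["n_components"]),
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            class_code={k: int(v) for k, v in d["class_code"].items()},
            threshold=float(d["threshold"]),
        )


def _encode(labels, class_code: dict) -> np.ndarray:
    labels = np.asarray(labels).astype(str)
    unknown = set(labels) - set(class_code)
    if unknown:
        raise KeyError(f"labels {sorted(unknown)} missing from class coding")
    return np.array([class_code[lab] for lab in labels], dtype=float)


def fit_plsda(
    X: np.ndarray,
    labels,
    n_components: int,
    class_code: dict | None = None,
    strict: bool = True,
) -> PLSDAModel:
    """Dummy-code, center and fit: the user-facing fitting entry point."""
    class_code = dict(class_code or DEFAULT_CLASS_CODE)
    X = np.asarray(X, dtype=float)
    y = _encode(labels, class_code)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T, b = fit_pls1(X - x_mean, y - y_mean, n_components, strict=strict)
    return PLSDAModel(
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=b,
        n_components=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        class_code=class_code,
    )


def predict(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous predicted response on the dummy-code scale."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.size:
        raise ValueError(
            f"channel mismatch: model expects {model.coef.size}, got {X_new.shape[1]}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def classify(model: PLSDAModel, X_new=None, yhat=None) -> np.ndarray:
    """Threshold the predicted response: strictly above 0.5 -> code-1 class."""
    if yhat is None:
        if X_new is None:
            raise ValueError("provide X_new or yhat")
        yhat = predict(model, X_new)
    yhat = np.asarray(yhat, dtype=float)
    pos, neg = model.positive_class, model.negative_class
    return np.where(yhat > model.threshold, pos, neg)


@dataclass
class CvCurve:
    """Cross-validated accuracy as a function of model complexity."""

    n_components: np.ndarray
    accuracy: np.ndarray  # overall, fraction correct
    accuracy_per_class: dict  # class label -> fraction-correct array
    chosen: int

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components.tolist(),
            "accuracy": self.accuracy.tolist(),
            "accuracy_per_class": {
                k: v.tolist() for k, v in self.accuracy_per_class.items()
            },
            "chosen": self.chosen,
        }


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator):
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for pos, row in enumerate(idx):
            folds[pos % k].append(int(row))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def crossval_select(
    X: np.ndarray,
    labels,
    a_max: int = 10,
    k: int = 10,
    seed: int = 0,
    class_code: dict | None = None,
    groups=None,
) -> CvCurve:
    """Stratified k-fold CV over 1..a_max latent variables.

    Folds are built once from ``seed`` (shuffling within class, dealing
    round-robin).  Within each fold the training rows are re-centered, a
    model with ``a_max`` components is fit, and held-out predictions for
    every smaller model are read off the same fit (component truncation is
    exact for NIPALS PLS1).  The chosen complexity maximizes overall CV
    accuracy; ties go to the smallest model.  Passing ``groups`` keeps all
    rows of a group in the same fold (e.g. map-wise folds) — an option, not
    the default.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    class_code = dict(class_code or DEFAULT_CLASS_CODE)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(str)
    y = _encode(labels, class_code)
    if np.allclose(y, y[0]):
        raise ValueError("response has zero variance; dummy coding degenerate")
    rng = np.random.default_rng(seed)
    if groups is None:
        folds = _stratified_folds(labels, k, rng)
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        rng.shuffle(uniq)
        folds = [
            np.flatnonzero(np.isin(groups, uniq[i::k])) for i in range(k)
        ]
    for f in folds:
        if f.size < 2:
            raise ValueError("a fold has fewer than 2 rows; reduce k")

    classes = sorted(class_code, key=class_code.get)
    correct = np.zeros(a_max)
    correct_per_class = {c: np.zeros(a_max) for c in classes}
    n_per_class = {c: int((labels == c).sum()) for c in classes}

    for f in folds:
        test_mask = np.zeros(X.shape[0], dtype=bool)
        test_mask[f] = True
        Xtr, ytr = X[~test_mask], y[~test_mask]
        a_fold = min(a_max, Xtr.shape[0] - 1, Xtr.shape[1])
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q, T, _ = fit_pls1(Xtr - x_mean, ytr - y_mean, a_fold, strict=False)
        a_fold = W.shape[1]  # rank exhaustion may have truncated the fit
        # R maps centered X to scores even after deflation: T_new = Xc R.
        R = W @ np.linalg.inv(P.T @ W)
        t_new = (X[test_mask] - x_mean) @ R
        contrib = t_new * q  # per-component contribution to yhat
        yhat_cum = y_mean + np.cumsum(contrib, axis=1)
        truth = y[test_mask]
        for a in range(a_max):
            col = min(a, a_fold - 1)
            pred = (yhat_cum[:, col] > 0.5).astype(float)
            hits = pred == truth
            correct[a] += hits.sum()
            for c in classes:
                cmask = labels[f] == c
                correct_per_class[c][a] += hits[cmask].sum()

    accuracy = correct / X.shape[0]
    per_class = {
        c: correct_per_class[c] / max(n_per_class[c], 1) for c in classes
    }
    chosen = int(np.argmax(accuracy)) + 1  # argmax -> first max -> smallest A
    return CvCurve(
        n_components=np.arange(1, a_max + 1),
        accuracy=accuracy,
        accuracy_per_class=per_class,
        chosen=chosen,
    )


def vip(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( J * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a' t_a.  The squared scores average to 1 over channels.
    """
    W = model.weights
    T = model.scores
    q = model.y_loadings
    if T.shape[0] == 0:
        raise ValueError("model carries no training scores; refit to compute VIP")
    j = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = np.einsum("ja,ja->a", W, W)
    return np.sqrt(j * (W**2 / wnorm2) @ ssy / ssy.sum())


@dataclass
class DiscriminantReport:
    """Per-channel VIP/coefficient map plus merged significant regions."""

    wavenumbers: np.ndarray
    vip: np.ndarray
    coef: np.ndarray
    significant: np.ndarray  # VIP > 1
    regions: pd.DataFrame  # lo_cm1, hi_cm1, n_channels, mean_coef, direction

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber_cm1": self.wavenumbers,
                "vip": self.vip,
                "coef": self.coef,
                "significant": self.significant,
            }
        )


def discriminant_regions(model: PLSDAModel, grid: WavenumberGrid) -> DiscriminantReport:
    """VIP > 1 channels merged into contiguous regions with class direction."""
    scores = vip(model)
    if scores.size != len(grid):
        raise ValueError("model channel count does not match grid")
    mask = scores > 1.0
    pos, neg = model.positive_class, model.negative_class
    rows = []
    in_run = False
    start = 0
    for i, flag in enumerate(np.append(mask, False)):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            in_run = False
            mean_coef = float(model.coef[start:i].mean())
            rows.append(
                {
                    "lo_cm1": float(grid.values[start]),
                    "hi_cm1": float(grid.values[i - 1]),
                    "n_channels": i - start,
                    "mean_coef": mean_coef,
                    "direction": f"{pos}-higher" if mean_coef > 0 else f"{neg}-higher",
                }
            )
    regions = pd.DataFrame(
        rows, columns=["lo_cm1", "hi_cm1", "n_channels", "mean_coef", "direction"]
    )
    return DiscriminantReport(
        wavenumbers=grid.values.copy(),
        vip=scores,
        coef=model.coef.copy(),
        significant=mask,
        regions=regions,
    )


def evaluate(model: PLSDAModel, X_test: np.ndarray, labels_test) -> dict:
    """Per-class and overall fraction of correctly classified samples."""
    labels_test = np.asarray(labels_test).astype(str)
    pred = classify(model, X_test)
    out: dict = {"per_class": {}}
    for cls in model.class_code:
        mask = labels_test == cls
        if not mask.any():
            raise ValueError(f"no test samples of class {cls!r}")
        out["per_class"][cls] = float((pred[mask] == cls).mean())
    out["overall"] = float((pred == labels_test).mean())
    return out
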