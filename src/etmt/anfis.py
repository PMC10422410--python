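"""Overall cognitive-impairment scoring with a Takagi–Sugeno ANFIS.

With no clinician-assigned labels available, targets are produced by k-means
(k = 3) on the standardized 13-feature vectors; clusters are ordered by how
slow and error-prone they are (ascending mean of standardized completion time
plus error count) and labeled 0 / 0.5 / 1 for low / medium / high impairment.

The network is the classic five-layer Takagi–Sugeno system with first-order
consequents: Gaussian memberships per input per rule (fuzzification), product
firing strengths, normalization, rule-wise linear outputs, and a weighted
sum.  Rules are scatter-partitioned — one rule per cluster — rather than
grid-partitioned: a full 3-per-input grid over 13 inputs would enumerate
3^13 ≈ 1.6 million rules, so "three membership functions" is realized as
three rule-wise Gaussian sets on every input.

Training is the standard hybrid scheme: each epoch solves all consequent
coefficients globally by (ridge-regularized) least squares with the premises
held fixed, then takes one full-batch gradient step on the premise centers
and widths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .features import FEATURE_NAMES, FeatureVector

LABELS = (0.0, 0.5, 1.0)
SIGMA_FLOOR = 0.1
RIDGE = 1e-8
PREMISE_LR = 0.01
DEFAULT_EPOCHS = 30
DEFAULT_TRAIN_FRAC = 0.75


class AnfisError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Standardized feature matrix with impairment targets in {0, 0.5, 1}."""

    X: np.ndarray                 # (n, d) standardized
    y: np.ndarray                 # (n,) labels
    mean: np.ndarray              # (d,) standardization mean
    std: np.ndarray               # (d,) standardization sd (zero-variance -> 1)
    participant_ids: list[str] = field(default_factory=list)

    def standardize(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.mean) / self.std


@dataclass
class AnfisModel:
    centers: np.ndarray           # (r, d) premise Gaussians, standardized space
    sigmas: np.ndarray            # (r, d), floored at SIGMA_FLOOR
    coeffs: np.ndarray            # (r, d) linear consequent weights
    intercepts: np.ndarray        # (r,)
    mean: np.ndarray              # standardization parameters carried with the model
    std: np.ndarray
    trained: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]


@dataclass(frozen=True)
class ErrorStats:
    """RMSE, mean error, and sample (n-1) standard deviation of the errors
    e = actual - predicted."""

    rmse: float
    error_mean: float
    error_std: float


def error_stats(predicted: Sequence[float], actual: Sequence[float]) -> ErrorStats:
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1 or p.size == 0:
        raise AnfisError("predicted and actual must be equal-length non-empty vectors")
    e = a - p
    return ErrorStats(
        rmse=float(np.sqrt(np.mean(e ** 2))),
        error_mean=float(np.mean(e)),
        error_std=float(np.std(e, ddof=1)) if e.size > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Labeling

def feature_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    return np.array([v.as_array() for v in vectors], dtype=float)


def kmeans_label(vectors: Sequence[FeatureVector], k: int = 3,
                 seed: int = 0) -> LabeledDataset:
    """Standardize, cluster with seeded k-means++ (10 restarts), and label.

    Clusters are ranked by the ascending mean of standardized FH2 + FH3
    (slower and more error-prone ⇒ more impaired) and assigned 0, 0.5, 1.
    """
    X_raw = feature_matrix(vectors)
    if len({tuple(row) for row in X_raw}) < k:
        raise AnfisError(f"need at least {k} distinct feature vectors")
    mean = X_raw.mean(axis=0)
    std = X_raw.std(axis=0)
    std[std == 0] = 1.0
    X = (X_raw - mean) / std

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    assignment = km.fit_predict(X)

    i_fh2 = FEATURE_NAMES.index("FH2")
    i_fh3 = FEATURE_NAMES.index("FH3")
    severity = [X[assignment == c][:, [i_fh2, i_fh3]].sum(axis=1).mean()
                for c in range(k)]
    order = np.argsort(severity)                       # ascending severity
    label_values = np.linspace(0.0, 1.0, k)
    label_of = {int(c): float(label_values[rank]) for rank, c in enumerate(order)}
    y = np.array([label_of[int(c)] for c in assignment])
    return LabeledDataset(X=X, y=y, mean=mean, std=std,
                          participant_ids=[v.participant_id for v in vectors])


# ---------------------------------------------------------------------------
# Model construction and forward pass

def anfis_init(dataset: LabeledDataset) -> AnfisModel:
    """One rule per label cluster: centers at cluster means, widths at cluster
    sds (floored), zero consequent weights with intercept = cluster label."""
    labels = sorted(set(dataset.y.tolist()))
    centers, sigmas, intercepts = [], [], []
    for lab in labels:
        members = dataset.X[dataset.y == lab]
        if members.size == 0:
            raise AnfisError(f"empty cluster for label {lab}")
        centers.append(members.mean(axis=0))
        sigmas.append(np.maximum(members.std(axis=0), SIGMA_FLOOR))
        intercepts.append(lab)
    d = dataset.X.shape[1]
    return AnfisModel(
        centers=np.array(centers), sigmas=np.array(sigmas),
        coeffs=np.zeros((len(labels), d)), intercepts=np.array(intercepts),
        mean=dataset.mean.copy(), std=dataset.std.copy(),
        meta={"labels": labels})


def _firing(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Normalized firing strengths, (n, r); underflow falls back to the
    nearest-center rule with weight 1."""
    z = (X[:, None, :] - model.centers[None, :, :]) / model.sigmas[None, :, :]
    logw = -0.5 * np.sum(z ** 2, axis=2)              # (n, r)
    w = np.exp(logw)
    total = w.sum(axis=1)
    wbar = np.zeros_like(w)
    ok = total > 0
    wbar[ok] = w[ok] / total[ok, None]
    if np.any(~ok):
        nearest = np.argmax(logw[~ok], axis=1)
        wbar[np.flatnonzero(~ok), nearest] = 1.0
    return wbar


def anfis_forward(model: AnfisModel, x: np.ndarray) -> float | np.ndarray:
    """Network output Σ_r w̄_r (a_r · x + b_r) for standardized input(s)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.n_inputs:
        raise AnfisError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    wbar = _firing(model, X)                           # (n, r)
    f = X @ model.coeffs.T + model.intercepts[None, :]  # (n, r)
    out = np.sum(wbar * f, axis=1)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Hybrid training

def stratified_split(y: np.ndarray, train_frac: float, seed: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified train/test index split; every label contributes at
    least one sample to each partition.  Continuous targets (any singleton
    label value) fall back to a plain shuffled split."""
    rng = np.random.default_rng(seed)
    labels = sorted(set(y.tolist()))
    counts = [int(np.sum(y == lab)) for lab in labels]
    if min(counts) < 2:
        idx = rng.permutation(len(y))
        n_train = min(max(int(round(train_frac * len(y))), 1), len(y) - 1)
        return np.sort(idx[:n_train]), np.sort(idx[n_train:])
    train_idx, test_idx = [], []
    for lab in labels:
        idx = np.flatnonzero(y == lab)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    if not train_idx or not test_idx:
        raise AnfisError("degenerate train/test split")
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _solve_consequents(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> None:
    """Global least squares for all rule consequents with premises fixed.

    Design matrix columns are w̄_r * [x, 1] for each rule; a small ridge term
    keeps the normal equations well-posed when some rule rarely fires.
    """
    n, d = X.shape
    r = model.n_rules
    wbar = _firing(model, X)
    design = np.empty((n, r * (d + 1)))
    for j in range(r):
        design[:, j * (d + 1): j * (d + 1) + d] = wbar[:, j, None] * X
        design[:, j * (d + 1) + d] = wbar[:, j]
    A = design.T @ design + RIDGE * np.eye(r * (d + 1))
    theta = np.linalg.solve(A, design.T @ y)
    for j in range(r):
        model.coeffs[j] = theta[j * (d + 1): j * (d + 1) + d]
        model.intercepts[j] = theta[j * (d + 1) + d]


def _premise_gradient_step(model: AnfisModel, X: np.ndarray, y: np.ndarray,
                           lr: float) -> None:
    """One full-batch gradient-descent step on centers and widths for the
    mean squared error; widths stay above SIGMA_FLOOR."""
    n, d = X.shape
    wbar = _firing(model, X)                            # (n, r)
    f = X @ model.coeffs.T + model.intercepts[None, :]   # (n, r)
    yhat = np.sum(wbar * f, axis=1)
    e = yhat - y                                        # (n,)
    # dyhat/dw_r = (f_r - yhat) / S with S = Σ w; fold S into wbar:
    # dyhat/dlogw_r = wbar_r (f_r - yhat)
    dl_dlogw = (2.0 / n) * e[:, None] * wbar * (f - yhat[:, None])   # (n, r)
    z = (X[:, None, :] - model.centers[None, :, :])                  # (n, r, d)
    dlogw_dc = z / model.sigmas[None, :, :] ** 2
    dlogw_ds = z ** 2 / model.sigmas[None, :, :] ** 3
    grad_c = np.sum(dl_dlogw[:, :, None] * dlogw_dc, axis=0)
    grad_s = np.sum(dl_dlogw[:, :, None] * dlogw_ds, axis=0)
    model.centers -= lr * grad_c
    model.sigmas = np.maximum(model.sigmas - lr * grad_s, SIGMA_FLOOR)


def anfis_train(model: AnfisModel, dataset: LabeledDataset,
                epochs: int = DEFAULT_EPOCHS,
                train_frac: float = DEFAULT_TRAIN_FRAC, seed: int = 0,
                lr: float = PREMISE_LR
                ) -> tuple[AnfisModel, dict[str, ErrorStats]]:
    """Hybrid least-squares + gradient training on a stratified split.

    Returns the trained model (the input model is not mutated) and error
    statistics on both partitions.  ``epochs=0`` returns an untouched copy.
    """
    if not 0 < train_frac < 1:
        raise AnfisError("train_frac must be in (0, 1)")
    if dataset.X.shape[0] < 8:
        raise AnfisError("need at least 8 samples to train")
    model = AnfisModel(
        centers=model.centers.copy(), sigmas=model.sigmas.copy(),
        coeffs=model.coeffs.copy(), intercepts=model.intercepts.copy(),
        mean=model.mean.copy(), std=model.std.copy(),
        trained=model.trained, meta=dict(model.meta))
    tr, te = stratified_split(dataset.y, train_frac, seed)
    Xtr, ytr = dataset.X[tr], dataset.y[tr]
    Xte, yte = dataset.X[te], dataset.y[te]
    for _ in range(epochs):
        _solve_consequents(model, Xtr, ytr)
        _premise_gradient_step(model, Xtr, ytr, lr)
    if epochs > 0:
        # final LSE so reported errors reflect optimal consequents for the
        # final premises
        _solve_consequents(model, Xtr, ytr)
        model.trained = True
    model.meta.update({"epochs": epochs, "train_frac": train_frac, "seed": seed,
                       "n_train": int(len(tr)), "n_test": int(len(te))})
    stats = {
        "train": error_stats(anfis_forward(model, Xtr), ytr),
        "test": error_stats(anfis_forward(model, Xte), yte),
    }
    return model, stats


def score_participant(model: AnfisModel, features: FeatureVector
                      ) -> tuple[float, str]:
    """Cognitive-impairment score in [0, 1] plus its low/medium/high band."""
    if not model.trained:
        raise AnfisError("model is not trained")
    raw = np.asarray(features.as_array(), dtype=float)
    x = (raw - model.mean) / model.std
    score = float(np.clip(anfis_forward(model, x), 0.0, 1.0))
    band = "low" if score < 1 / 3 else ("medium" if score < 2 / 3 else "high")
    return score, band


# ---------------------------------------------------------------------------
# Persistence (bit-exact reload via repr-precision floats)

def save_model(model: AnfisModel, path: str | Path) -> None:
    doc = {
        "centers": model.centers.tolist(),
        "sigmas": model.sigmas.tolist(),
        "coeffs": model.coeffs.tolist(),
        "intercepts": model.intercepts.tolist(),
        "mean": model.mean.tolist(),
        "std": model.std.tolist(),
        "trained": model.trained,
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> AnfisModel:
    with open(path) as fh:
        doc = json.load(fh)
    return AnfisModel(
        centers=np.array(doc["centers"]), sigmas=np.array(doc["sigmas"]),
        coeffs=np.array(doc["coeffs"]), intercepts=np.array(doc["intercepts"]),
        mean=np.array(doc["mean"]), std=np.array(doc["std"]),
        trained=bool(doc["trained"]), meta=dict(doc.get("meta", {})))
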