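"""Classifiers for the nodule/non-nodule decision.

The multilayer perceptron is written out explicitly: logistic activations,
per-pattern (online) back-propagation of the squared error, and a momentum
term, i.e. weight updates

    dw(t) = eta * lambda(t) * y(t) + alpha * dw(t-1)

with the output-layer local gradient lambda = (d - y) * phi'(u).  The
ensemble wrappers implement bootstrap aggregation (bagging, majority vote)
and the AdaBoost.M1 reweighting schedule (beta_t = eps_t / (1 - eps_t),
member vote weight log(1/beta_t), rounds with eps_t >= 0.5 discarded).
The random-forest backend delegates to scikit-learn's implementation of
Breiman's algorithm behind the same fit/predict surface.

All training is deterministic under a fixed seed.  Continuous scores for
the positive (nodule) class are in [0, 1]; hard labels threshold at 0.5.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    e = np.exp(u[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class MlpClassifier:
    """Feed-forward network trained by momentum back-propagation.

    Parameters
    ----------
    hidden_layer_sizes : sizes of the hidden layers (default one layer of 10).
    learning_rate : eta in (0, 1).
    momentum : alpha in [0, 1).
    epochs : full passes over the training patterns.
    seed : weight-initialization seed; training is bitwise reproducible.

    Inputs are expected standardized (zero mean, unit variance on the
    training split).  The single logistic output neuron is the positive-class
    score.
    """

    supports_sample_weight = False

    def __init__(
        self,
        hidden_layer_sizes: Sequence[int] = (10,),
        learning_rate: float = 0.1,
        momentum: float = 0.9,
        epochs: int = 500,
        seed: int = 0,
    ) -> None:
        if not 0 < learning_rate < 1:
            raise ValueError("learning_rate must be in (0, 1)")
        if not 0 <= momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        self.hidden_layer_sizes = tuple(int(h) for h in hidden_layer_sizes)
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.weights_: list[np.ndarray] | None = None  # (fan_in + 1, fan_out), bias row last
        self.loss_curve_: list[float] = []

    def _init_weights(self, n_features: int) -> list[np.ndarray]:
        rng = np.random.default_rng(self.seed)
        sizes = (n_features, *self.hidden_layer_sizes, 1)
        return [
            rng.uniform(-0.5, 0.5, size=(fan_in + 1, fan_out)) / np.sqrt(fan_in)
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        activations = [x]
        for w in self.weights_:
            u = activations[-1] @ w[:-1] + w[-1]
            activations.append(_sigmoid(u))
        return activations

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MlpClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are single-class")
        self.weights_ = self._init_weights(X.shape[1])
        velocity = [np.zeros_like(w) for w in self.weights_]
        eta, alpha = self.learning_rate, self.momentum
        self.loss_curve_ = []
        for _ in range(self.epochs):
            sq_err = 0.0
            for i in range(len(X)):
                acts = self._forward(X[i : i + 1])
                out = acts[-1]
                err = y[i] - out  # d_j(t) - y_j(t)
                sq_err += float(err[0, 0] ** 2)
                # local gradients, output layer first: lambda = e * phi'(u)
                lam = err * out * (1.0 - out)
                for layer in range(len(self.weights_) - 1, -1, -1):
                    w = self.weights_[layer]
                    grad = np.vstack([acts[layer].T @ lam, lam])
                    if layer > 0:
                        a = acts[layer]
                        lam = (lam @ w[:-1].T) * a * (1.0 - a)
                    velocity[layer] = eta * grad + alpha * velocity[layer]
                    self.weights_[layer] = w + velocity[layer]
            self.loss_curve_.append(sq_err / len(X))
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] + 1 != self.weights_[0].shape[0]:
            raise ValueError("feature count differs from training")
        return self._forward(X)[-1].reshape(-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)

    def to_json(self) -> dict:
        return {
            "model": "mlp",
            "hidden_layer_sizes": list(self.hidden_layer_sizes),
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "epochs": self.epochs,
            "seed": self.seed,
            "weights": [w.tolist() for w in self.weights_ or []],
        }

    @classmethod
    def from_json(cls, payload: dict) -> "MlpClassifier":
        model = cls(
            hidden_layer_sizes=payload["hidden_layer_sizes"],
            learning_rate=payload["learning_rate"],
            momentum=payload["momentum"],
            epochs=payload["epochs"],
            seed=payload["seed"],
        )
        if payload.get("weights"):
            model.weights_ = [np.asarray(w) for w in payload["weights"]]
        return model


class TreeClassifier:
    """CART decision tree (scikit-learn backend); supports instance weights."""

    supports_sample_weight = True

    def __init__(self, seed: int = 0, max_depth: int | None = None) -> None:
        self.seed = int(seed)
        self.max_depth = max_depth
        self._tree: DecisionTreeClassifier | None = None

    def fit(self, X, y, sample_weight=None) -> "TreeClassifier":
        self._tree = DecisionTreeClassifier(
            random_state=self.seed, max_depth=self.max_depth
        )
        self._tree.fit(X, y, sample_weight=sample_weight)
        return self

    def scores(self, X) -> np.ndarray:
        proba = self._tree.predict_proba(X)
        if proba.shape[1] == 1:
            return np.full(len(X), float(self._tree.classes_[0]))
        return proba[:, list(self._tree.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


class ForestClassifier:
    """Random forest: bagged CART trees with sqrt(p) random feature subsets."""

    supports_sample_weight = True

    def __init__(
        self,
        n_trees: int = 100,
        seed: int = 0,
        max_features: str | int | None = "sqrt",
        bootstrap: bool = True,
    ) -> None:
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.max_features = max_features
        self.bootstrap = bootstrap
        self._forest: RandomForestClassifier | None = None

    def fit(self, X, y, sample_weight=None) -> "ForestClassifier":
        self._forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            bootstrap=self.bootstrap,
            random_state=self.seed,
        )
        self._forest.fit(X, y, sample_weight=sample_weight)
        return self

    def scores(self, X) -> np.ndarray:
        proba = self._forest.predict_proba(X)
        if proba.shape[1] == 1:
            return np.full(len(X), float(self._forest.classes_[0]))
        return proba[:, list(self._forest.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


def train_random_forest(X, y, n_trees: int = 100, seed: int = 0) -> ForestClassifier:
    return ForestClassifier(n_trees=n_trees, seed=seed).fit(X, y)


@dataclasses.dataclass
class BaggingEnsemble:
    """Bootstrap-aggregated ensemble; score = positive-vote fraction."""

    members: list
    seed: int

    def scores(self, X) -> np.ndarray:
        votes = np.stack([m.predict(X) for m in self.members])
        return votes.mean(axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


def train_bagging(
    base_factory: Callable[[int], object],
    X: np.ndarray,
    y: np.ndarray,
    n_members: int = 10,
    seed: int = 0,
    resample: bool = True,
) -> BaggingEnsemble:
    """Train ``n_members`` base models on uniform bootstrap resamples.

    ``base_factory(member_seed)`` must return an unfitted model with
    ``fit``/``predict``.  With ``resample=False`` every member sees the full
    training set (useful to recover the single base learner at T = 1).
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    members = []
    for t in range(n_members):
        member_seed = int(rng.integers(0, 2**31 - 1))
        idx = (
            rng.integers(0, len(X), size=len(X))
            if resample
            else np.arange(len(X))
        )
        members.append(base_factory(member_seed).fit(X[idx], y[idx]))
    return BaggingEnsemble(members=members, seed=seed)


@dataclasses.dataclass
class AdaBoostEnsemble:
    """Weighted-vote ensemble from the AdaBoost.M1 schedule.

    ``round_errors`` holds the weighted error of each accepted round and
    ``weight_history`` the renormalized pattern weights after each round,
    for diagnostics.
    """

    members: list
    member_weights: list[float]
    seed: int
    round_errors: list[float] = dataclasses.field(default_factory=list)
    weight_history: list[np.ndarray] = dataclasses.field(default_factory=list)

    def scores(self, X) -> np.ndarray:
        w = np.asarray(self.member_weights)
        votes = np.stack([m.predict(X) for m in self.members])
        return (w[:, None] * votes).sum(axis=0) / w.sum()

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


_BETA_FLOOR = 1e-10  # beta cap when a round is error-free


def train_adaboost_m1(
    base_factory: Callable[[int], object],
    X: np.ndarray,
    y: np.ndarray,
    n_rounds: int = 10,
    seed: int = 0,
) -> AdaBoostEnsemble:
    """AdaBoost.M1 on a binary problem.

    Pattern weights start uniform; after each round t with weighted error
    eps_t < 0.5, correctly classified patterns are down-weighted by
    beta_t = eps_t / (1 - eps_t) and weights renormalized; the member votes
    with weight log(1 / beta_t).  A round with eps_t >= 0.5 is discarded and
    boosting stops (the first member is kept regardless so the ensemble is
    usable).  Bases that cannot take instance weights are trained on a
    weighted bootstrap resample instead.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(X)
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    members: list = []
    alphas: list[float] = []
    errors: list[float] = []
    history: list[np.ndarray] = []
    for t in range(n_rounds):
        member_seed = int(rng.integers(0, 2**31 - 1))
        model = base_factory(member_seed)
        if getattr(model, "supports_sample_weight", False):
            model.fit(X, y, sample_weight=w * n)
        else:
            idx = rng.choice(n, size=n, replace=True, p=w)
            model.fit(X[idx], y[idx])
        pred = model.predict(X)
        miss = pred != y
        eps = float(w[miss].sum())
        if eps >= 0.5:
            if not members:  # degenerate data: keep one member anyway
                members.append(model)
                alphas.append(1.0)
                errors.append(eps)
            break
        beta = max(eps / (1.0 - eps), _BETA_FLOOR)
        members.append(model)
        alphas.append(float(np.log(1.0 / beta)))
        errors.append(eps)
        if eps == 0.0:
            history.append(w.copy())
            break
        w[~miss] *= beta
        w /= w.sum()
        history.append(w.copy())
    return AdaBoostEnsemble(
        members=members,
        member_weights=alphas,
        seed=seed,
        round_errors=errors,
        weight_history=history,
    )


# --- name-based construction used by the pipeline and CLI -------------------

CLASSIFIER_NAMES = ("ann", "rf", "bag-ann", "bag-rf", "ada-ann", "ada-rf")


class _EnsembleTrainer:
    """Deferred ensemble construction so every classifier exposes fit/predict."""

    def __init__(self, kind: str, base: str, seed: int, hyper: dict) -> None:
        self.kind, self.base, self.seed, self.hyper = kind, base, seed, hyper
        self._model = None

    def _base_factory(self) -> Callable[[int], object]:
        hyper = self.hyper
        if self.base == "ann":
            return lambda s: MlpClassifier(
                hidden_layer_sizes=hyper.get("hidden_layer_sizes", (10,)),
                learning_rate=hyper.get("learning_rate", 0.1),
                momentum=hyper.get("momentum", 0.9),
                epochs=hyper.get("epochs", 500),
                seed=s,
            )
        return lambda s: ForestClassifier(
            n_trees=hyper.get("n_trees", 50), seed=s
        )

    def fit(self, X, y):
        n_members = self.hyper.get("n_members", 10)
        if self.kind == "bag":
            self._model = train_bagging(
                self._base_factory(), X, y, n_members=n_members, seed=self.seed
            )
        else:
            self._model = train_adaboost_m1(
                self._base_factory(), X, y, n_rounds=n_members, seed=self.seed
            )
        return self

    def scores(self, X):
        return self._model.scores(X)

    def predict(self, X):
        return self._model.predict(X)


def make_classifier(name: str, seed: int = 0, **hyper):
    """Build a classifier by its pipeline name.

    Names: ``ann`` (MLP), ``rf`` (random forest), ``bag-ann``/``bag-rf``
    (bagging of the base), ``ada-ann``/``ada-rf`` (AdaBoost.M1 of the base).
    """
    if name == "ann":
        return MlpClassifier(
            hidden_layer_sizes=hyper.get("hidden_layer_sizes", (10,)),
            learning_rate=hyper.get("learning_rate", 0.1),
            momentum=hyper.get("momentum", 0.9),
            epochs=hyper.get("epochs", 500),
            seed=seed,
        )
    if name == "rf":
        return ForestClassifier(n_trees=hyper.get("n_trees", 100), seed=seed)
    if name in ("bag-ann", "bag-rf", "ada-ann", "ada-rf"):
        kind, base = name.split("-")
        return _EnsembleTrainer(kind, base, seed, hyper)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def save_model_json(model, path: str | Path) -> None:
    """Serialize a model (MLP, or ensembles of MLPs) to a JSON container."""
    path = Path(path)
    if isinstance(model, MlpClassifier):
        payload = model.to_json()
    elif isinstance(model, (BaggingEnsemble, AdaBoostEnsemble)) and all(
        isinstance(m, MlpClassifier) for m in model.members
    ):
        payload = {
            "model": "bagging" if isinstance(model, BaggingEnsemble) else "adaboost",
            "seed": model.seed,
            "members": [m.to_json() for m in model.members],
        }
        if isinstance(model, AdaBoostEnsemble):
            payload["member_weights"] = model.member_weights
    else:
        raise ValueError("only MLP-based models serialize to JSON")
    path.write_text(json.dumps(payload))


def load_model_json(path: str | Path):
    payload = json.loads(Path(path).read_text())
    if payload["model"] == "mlp":
        return MlpClassifier.from_json(payload)
    members = [MlpClassifier.from_json(m) for m in payload["members"]]
    if payload["model"] == "bagging":
        return BaggingEnsemble(members=members, seed=payload["seed"])
    return AdaBoostEnsemble(
        members=members,
        member_weights=payload["member_weights"],
        seed=payload["seed"],
    )
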