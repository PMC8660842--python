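"""Classifiers for the UV-Vis spectrum class: random forests (primary),
classification trees, and optional SVM / multilayer-perceptron plug-ins,
together with importance-based feature selection and Y-scrambling validation.

Random forests are ensembles of unpruned classification trees grown on
bootstrap samples, with mtry features available per split, validated
internally by the out-of-bag (OOB) estimate. Every prediction carries a
probability equal to the vote fraction of the predicted class (ties break
POS: in photosafety screening sensitivity outranks specificity). Descriptor
importance is the classic per-tree OOB permutation score (mean decrease in
accuracy), with Gini-based scores recorded alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .labeling import NEG, POS

_MTRY = {"sqrt": "sqrt", "third": 1.0 / 3.0}


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters: 500-1000 unpruned trees and mtry equal
    to the square root (default) or one third of the descriptor count."""

    n_trees: int = 500
    mtry: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry not in _MTRY:
            raise ValueError("mtry must be 'sqrt' or 'third'")


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    config: dict
    feature_names: list[str]
    oob_accuracy: float | None = None
    importances_gini: np.ndarray | None = None
    importances_mda: np.ndarray | None = None

    @property
    def importances(self) -> np.ndarray:
        """Accuracy-based permutation importances when computed, else Gini."""
        if self.importances_mda is not None:
            return self.importances_mda
        if self.importances_gini is not None:
            return self.importances_gini
        raise ValueError("model carries no importances")

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, f"{prefix}.joblib")
        manifest = {
            "algorithm": self.algorithm,
            "config": self.config,
            "n_features": len(self.feature_names),
            "oob_accuracy": self.oob_accuracy,
        }
        Path(f"{prefix}.json").write_text(json.dumps(manifest, indent=2))

    @staticmethod
    def load(prefix: str | Path) -> "TrainedModel":
        return joblib.load(f"{prefix}.joblib")


@dataclass(frozen=True)
class Prediction:
    mol_id: str
    predicted: str
    probability: float  # vote fraction for the predicted class, in [0.5, 1]


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return X, y


def _feature_names(X, n: int) -> list[str]:
    names = getattr(X, "columns", None)
    return list(names) if names is not None else [f"f{i}" for i in range(n)]


def _values(X) -> np.ndarray:
    return X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)


def train_rf(X, y, cfg: RFConfig | None = None, compute_mda: bool = False) -> TrainedModel:
    """Grow a random forest with OOB validation.

    ``compute_mda`` also runs the per-tree OOB permutation importance, which
    costs one extra pass over trees per descriptor; Gini importances are
    always recorded.
    """
    cfg = cfg or RFConfig()
    names = _feature_names(X, np.shape(X)[1])
    Xv, y = _check_xy(_values(X), y)
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=_MTRY[cfg.mtry],
        oob_score=True,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(Xv, y)
    model = TrainedModel(
        algorithm="rf",
        estimator=rf,
        config={"n_trees": cfg.n_trees, "mtry": cfg.mtry, "seed": cfg.seed},
        feature_names=names,
        oob_accuracy=float(rf.oob_score_),
        importances_gini=rf.feature_importances_.copy(),
    )
    if compute_mda:
        model.importances_mda = oob_permutation_importance(model, Xv, y, seed=cfg.seed)
    return model


def oob_permutation_importance(
    model: TrainedModel, X, y, seed: int = 0
) -> np.ndarray:
    """Mean decrease in accuracy when a descriptor's values are permuted,
    evaluated per tree on that tree's out-of-bag samples (one permutation per
    tree, the classic scheme) and averaged over the forest."""
    if model.algorithm != "rf":
        raise ValueError("OOB permutation importance is defined for random forests")
    rf: RandomForestClassifier = model.estimator
    Xv = np.asarray(_values(X), dtype=float)
    # trees inside a fitted forest predict encoded class indices, not labels
    y_enc = np.searchsorted(rf.classes_, np.asarray(y)).astype(float)
    n_samples, n_features = Xv.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(n_features)
    n_used = 0
    for tree, sample_idx in zip(rf.estimators_, rf.estimators_samples_):
        oob_mask = np.ones(n_samples, dtype=bool)
        oob_mask[sample_idx] = False
        if not oob_mask.any():
            continue
        Xo, yo = Xv[oob_mask], y_enc[oob_mask]
        base = np.mean(tree.predict(Xo) == yo)
        perm = rng.permutation(len(yo))
        Xp = Xo.copy()
        for j in range(n_features):
            saved = Xp[:, j].copy()
            Xp[:, j] = Xo[perm, j]
            drops[j] += base - np.mean(tree.predict(Xp) == yo)
            Xp[:, j] = saved
        n_used += 1
    if n_used == 0:
        raise ValueError("no tree had out-of-bag samples; grow more trees")
    return drops / n_used


def predict(model: TrainedModel, X, mol_ids: Sequence[str] | None = None) -> list[Prediction]:
    """Majority-vote predictions with the vote fraction of the predicted
    class as probability; exact ties (vote fraction 0.5) go POS."""
    names = getattr(X, "columns", None)
    if names is not None and list(names) != model.feature_names:
        raise ValueError("feature columns do not match the training provenance")
    Xv = _values(X)
    if Xv.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {Xv.shape[1]}"
        )
    est = model.estimator
    proba = est.predict_proba(np.asarray(Xv, dtype=float))
    classes = list(est.classes_)
    p_pos = proba[:, classes.index(POS)] if POS in classes else np.zeros(len(Xv))
    if mol_ids is None:
        index = getattr(X, "index", None)
        mol_ids = [str(i) for i in index] if index is not None else [str(i) for i in range(len(Xv))]
    out = []
    for mol_id, p in zip(mol_ids, p_pos):
        label = POS if p >= 0.5 else NEG
        out.append(Prediction(str(mol_id), label, float(max(p, 1.0 - p))))
    return out


def select_top_k(model: TrainedModel, k: int) -> list[int]:
    """Indices of the k most important descriptors (accuracy-based when
    available), ties broken deterministically by lower column index."""
    if k <= 0:
        raise ValueError("k must be positive")
    imp = model.importances
    if k > len(imp):
        raise ValueError(f"k={k} exceeds the {len(imp)} available descriptors")
    order = np.argsort(-imp, kind="stable")
    return sorted(int(i) for i in order[:k])


def train_cart(X, y, cp: float = 0.01, seed: int = 0) -> TrainedModel:
    """Classification tree with cost-complexity pruning.

    ``cp`` follows the rpart convention (minimum relative improvement per
    split); it is mapped to sklearn's ccp_alpha by scaling with the root
    misclassification risk. A single-class y yields a trivial one-leaf tree.
    """
    Xv = _values(X)
    names = _feature_names(X, np.shape(Xv)[1])
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        import warnings

        warnings.warn("single-class labels: returning a trivial one-leaf tree")
        tree = DecisionTreeClassifier(random_state=seed).fit(np.asarray(Xv[:1], dtype=float), y[:1])
        return TrainedModel("cart", tree, {"cp": cp, "seed": seed, "degenerate": True}, names)
    root_risk = 1.0 - counts.max() / counts.sum()
    tree = DecisionTreeClassifier(random_state=seed, ccp_alpha=cp * root_risk)
    tree.fit(np.asarray(Xv, dtype=float), y)
    return TrainedModel(
        "cart",
        tree,
        {"cp": cp, "ccp_alpha": cp * root_risk, "seed": seed},
        names,
        importances_gini=tree.feature_importances_.copy(),
    )


@dataclass(frozen=True)
class TreeRule:
    """One root-to-leaf path: ordered (feature, op, threshold) tests and the
    class the leaf predicts."""

    conditions: tuple[tuple[str, str, float], ...]
    predicted: str
    n_samples: int


def extract_rules(model: TrainedModel) -> list[TreeRule]:
    """Human-readable root-to-leaf rules from a classification tree."""
    if model.algorithm != "cart":
        raise ValueError("rule extraction applies to classification trees")
    t = model.estimator.tree_
    classes = model.estimator.classes_
    rules: list[TreeRule] = []

    def walk(node: int, conds: tuple) -> None:
        if t.children_left[node] == -1:
            predicted = str(classes[int(np.argmax(t.value[node]))])
            rules.append(TreeRule(conds, predicted, int(t.n_node_samples[node])))
            return
        name = model.feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + ((name, "<=", thr),))
        walk(t.children_right[node], conds + ((name, ">", thr),))

    walk(0, ())
    return rules


def y_scramble(
    X, y, cfg: RFConfig | None = None, n_rounds: int = 5, seed: int = 0
) -> list[float]:
    """Retrain on uniformly permuted labels ``n_rounds`` times and report the
    internal (OOB) accuracy of each round; a valid model collapses to chance."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    cfg = cfg or RFConfig()
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    accs = []
    for r in range(n_rounds):
        y_perm = y[rng.permutation(len(y))]
        round_cfg = RFConfig(cfg.n_trees, cfg.mtry, seed=int(rng.integers(2**31 - 1)))
        accs.append(train_rf(X, y_perm, round_cfg).oob_accuracy)
    return accs


def train_svm(X, y, C: float = 500.0, gamma: float = 0.004, seed: int = 0) -> TrainedModel:
    """C-SVM with an RBF kernel (class output only, no probability
    calibration); the defaults are the tuned working values."""
    Xv, y = _check_xy(_values(X), y)
    names = _feature_names(X, Xv.shape[1])
    svm = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed).fit(Xv, y)
    return TrainedModel("svm", svm, {"C": C, "gamma": gamma, "kernel": "rbf", "seed": seed}, names)


#: Architecture of the deep multilayer-perceptron plug-in: four hidden layers
#: (250, 250, 8, 4) with relu, a single sigmoid output unit, adam with
#: learning rate 0.001, batch size 36, binary cross-entropy, 100 epochs.
MLP_ARCHITECTURE = {
    "initializer": "random_normal",
    "hidden_layers": (250, 250, 8, 4),
    "output_units": 1,
    "hidden_activation": "relu",
    "output_activation": "sigmoid",
    "batch_size": 36,
    "optimizer": "adam",
    "loss": "binary_crossentropy",
    "epochs": 100,
    "learning_rate": 0.001,
    "decay": 1e-6,
}


def train_mlp(X, y, seed: int = 0, epochs: int | None = None) -> TrainedModel:
    """Deep MLP plug-in mirroring :data:`MLP_ARCHITECTURE`; binary class
    output is thresholded at 0.5 on the sigmoid unit."""
    Xv, y = _check_xy(_values(X), y)
    names = _feature_names(X, Xv.shape[1])
    arch = dict(MLP_ARCHITECTURE)
    if epochs is not None:
        arch["epochs"] = epochs
    mlp = MLPClassifier(
        hidden_layer_sizes=arch["hidden_layers"],
        activation="relu",
        solver="adam",
        batch_size=arch["batch_size"],
        learning_rate_init=arch["learning_rate"],
        max_iter=arch["epochs"],
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at fixed epoch budget
        mlp.fit(Xv, y)
    return TrainedModel("mlp", mlp, {**arch, "seed": seed}, names)
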