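"""Binary scoliosis-risk classifier on the (6,16,16) DCR tensor.

The network applies two rounds of convolution (kernel (1,3,3), padding
(0,1,1), stride (1,1,1)) each followed by (1,2,2) average pooling,
growing channels 1 -> 4 -> 8, so the feature map flattens to
8 * 6 * 4 * 4 = 768 units; the classifier head maps 768 -> 192 -> 2 and
a softmax turns the two logits into class probabilities (label 1 = high
risk, label 0 = low risk).  Training uses cross-entropy loss and Adam.

Two entry points:

* the statsmodels-style pair :class:`DCRClassifier` /
  :class:`DCRClassifierResults` — build the model from features and
  labels, call ``fit()``, inspect ``summary()``;
* the functional layer (:func:`balance_downsample`, :func:`build_model`,
  :func:`train`, :func:`evaluate`, :func:`fc_layer_pca_test`) used by
  the CLI and available for scripted pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve, auc as _sk_auc
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _nn

LABEL_MAP = {1: "high risk", 0: "low risk"}


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    The channel plan (1, 4, 8) is pinned by the flattened dimension:
    after two (1,2,2) poolings the spatial grid is (6, 4, 4), and
    8 * 6 * 4 * 4 = 768 is the only plan reaching the 768-unit
    fully connected input.
    """

    channels: tuple[int, int, int] = (1, 4, 8)
    hidden_dim: int = 192
    n_classes: int = 2
    epochs: int = 100
    learning_rate: float = 0.005
    batch_size: int = 20
    validation_split: float = 0.2
    folds: int = 5
    seed: int = 0
    input_shape: tuple[int, int, int] = (6, 16, 16)
    #: input rescaling applied before the first convolution; raw DCR
    #: block frequencies are ~1/256 on a baseline shared by every
    #: sample, which leaves the network poorly conditioned.
    #: "center" (default) subtracts the training-set mean tensor and
    #: divides by the global standard deviation of the centred training
    #: features, exposing each variant's compositional deviation at
    #: unit scale; "minmax" rescales each sample's vector to [0, 1];
    #: "none" feeds raw frequencies.
    input_normalization: str = "center"

    @property
    def flat_dim(self) -> int:
        d, h, w = self.input_shape
        return self.channels[-1] * d * (h // 4) * (w // 4)

    def __post_init__(self) -> None:
        if self.flat_dim != 768:
            raise ConfigurationError(
                f"channel plan {self.channels} gives flattened dimension "
                f"{self.flat_dim}, expected 768")


class CNN:
    """The network itself: forward pass, probabilities, activations."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c1, c2, c3 = config.channels
        self.net = _nn.Sequential([
            _nn.Conv3d1x3x3(c1, c2, rng), _nn.ReLU(), _nn.AvgPool1x2x2(),
            _nn.Conv3d1x3x3(c2, c3, rng), _nn.ReLU(), _nn.AvgPool1x2x2(),
            _nn.Flatten(),
            _nn.Linear(config.flat_dim, config.hidden_dim, rng), _nn.ReLU(),
            _nn.Linear(config.hidden_dim, config.n_classes, rng),
        ])
        self._flatten_index = 7  # layers [:7] end at the 768-d activation
        # centering statistics, fitted on the training set by train()
        self.center_mu_: np.ndarray | None = None
        self.center_scale_: float | None = None

    def fit_normalization(self, X: np.ndarray) -> None:
        """Fit the "center" input statistics on training tensors."""
        X = self._raw_tensors(X)
        self.center_mu_ = X.mean(axis=0)
        scale = float((X - self.center_mu_).std())
        self.center_scale_ = scale if scale > 0 else 1.0

    @staticmethod
    def _raw_tensors(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1536:
            X = X.reshape(-1, 6, 16, 16)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[1:] != (6, 16, 16):
            raise ValueError(f"expected (n, 6, 16, 16) tensors, got "
                             f"{X.shape}")
        return X

    def _as_input(self, X: np.ndarray) -> np.ndarray:
        X = self._raw_tensors(X)
        mode = self.config.input_normalization
        if mode == "center":
            if self.center_mu_ is None:
                raise ConfigurationError(
                    "centering statistics not fitted; train the model or "
                    "call fit_normalization() first")
            X = (X - self.center_mu_) / self.center_scale_
        elif mode == "minmax":
            flat = X.reshape(len(X), -1)
            lo = flat.min(axis=1, keepdims=True)
            hi = flat.max(axis=1, keepdims=True)
            span = np.where(hi > lo, hi - lo, 1.0)
            X = ((flat - lo) / span).reshape(X.shape)
        elif mode != "none":
            raise ConfigurationError(
                f"unknown input_normalization {mode!r}")
        return X[:, None]  # add channel axis

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(self._as_input(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax probability pairs (p0, p1); rows sum to 1."""
        return _nn.softmax(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax decision; an exact 0.5/0.5 tie resolves to label 0
        (conservative toward low risk)."""
        proba = self.predict_proba(X)
        return (proba[:, 1] > proba[:, 0]).astype(int)

    def fc_activations(self, X: np.ndarray) -> np.ndarray:
        """The 768-dimension flattened convolutional feature map."""
        return self.net.forward(self._as_input(X), upto=self._flatten_index)

    def shape_trace(self, n: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """Static shape trace of one forward pass, for architecture
        verification: (layer name, output shape without batch axis)."""
        x = np.zeros((n, 1, *self.config.input_shape))
        trace = [("input", x.shape[1:])]
        for layer in self.net.layers:
            x = layer.forward(x)
            trace.append((type(layer).__name__, x.shape[1:]))
        return trace

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params)}
        if self.center_mu_ is not None:
            arrays["center_mu"] = self.center_mu_
            arrays["center_scale"] = np.array(self.center_scale_)
        np.savez(directory / "weights.npz", **arrays)
        cfg = asdict(self.config)
        cfg["label_map"] = {str(k): v for k, v in LABEL_MAP.items()}
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CNN":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        cfg.pop("label_map", None)
        cfg["channels"] = tuple(cfg["channels"])
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = cls(ModelConfig(**cfg), np.random.default_rng(0))
        with np.load(directory / "weights.npz") as data:
            for i, p in enumerate(model.net.params):
                p[...] = data[f"p{i}"]
            if "center_mu" in data:
                model.center_mu_ = data["center_mu"]
                model.center_scale_ = float(data["center_scale"])
        return model


@dataclass
class EvalReport:
    """ROC sweep, AUC, confusion matrix and per-class accuracy on one
    evaluation set."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float | None
    confusion: np.ndarray           # rows: true 0/1, cols: predicted 0/1
    per_class_accuracy: dict[int, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})


def balance_downsample(X: np.ndarray, y: np.ndarray, seed: int,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random downsampling of the majority class to the minority count.

    Returns the balanced features, labels and the selected indices into
    the original arrays (sorted, so already-balanced input comes back in
    its original order).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return np.asarray(X)[keep], y[keep], keep


def build_model(config: ModelConfig | None = None) -> CNN:
    """Construct an untrained network from a configuration."""
    config = config or ModelConfig()
    return CNN(config, np.random.default_rng(config.seed))


def train(model: CNN, X: np.ndarray, y: np.ndarray,
          config: ModelConfig | None = None,
          rng: np.random.Generator | None = None) -> list[list[float]]:
    """Train in place with Adam + cross-entropy; returns the per-epoch
    lists of batch losses (the raw material of a loss boxplot)."""
    config = config or model.config
    rng = rng or np.random.default_rng(config.seed + 1)
    if config.input_normalization == "center" and model.center_mu_ is None:
        model.fit_normalization(X)
    Xt = model._as_input(X)
    y = np.asarray(y, dtype=int)
    opt = _nn.Adam(model.net.params, lr=config.learning_rate)
    history: list[list[float]] = []
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = model.net.forward(Xt[sel])
            loss, dlogits = _nn.cross_entropy(logits, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss ({loss}) at step "
                    f"{opt.t + 1}; lower the learning rate")
            model.net.backward(dlogits)
            opt.step(model.net.grads)
            epoch_losses.append(loss)
        history.append(epoch_losses)
    return history


def evaluate(model: CNN, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """ROC/AUC (trapezoidal over the full threshold sweep) and the
    confusion matrix at the argmax decision.

    A single-class evaluation set leaves ``auc`` as ``None`` (the
    confusion matrix is still emitted).
    """
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(X)
    pred = model.predict(X)
    conf = _sk_confusion(y, pred, labels=[0, 1])
    per_class = {}
    for cls in (0, 1):
        total = conf[cls].sum()
        per_class[cls] = float(conf[cls, cls] / total) if total else float("nan")
    if len(np.unique(y)) < 2:
        fpr = tpr = thr = np.array([])
        auc_value = None
    else:
        fpr, tpr, thr = roc_curve(y, proba[:, 1])
        auc_value = float(_sk_auc(fpr, tpr))
    return EvalReport(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc_value,
                      confusion=conf, per_class_accuracy=per_class,
                      n=len(y))


def fc_layer_pca_test(model: CNN, X: np.ndarray, y: np.ndarray,
                      seed: int = 0) -> dict:
    """Reduce the 768-d fully connected input with PCA to 2 components
    and compare the groups on each component.

    Groups are truncated to equal size by seeded subsampling so a paired
    t-test can be formed; Welch's unequal-variance test is reported
    alongside for transparency.
    """
    y = np.asarray(y, dtype=int)
    acts = model.fc_activations(X)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("each group needs at least 3 samples")
    coords = PCA(n_components=2, random_state=seed).fit_transform(acts)
    rng = np.random.default_rng(seed)
    k = min(len(pos), len(neg))
    pos = np.sort(rng.choice(pos, size=k, replace=False))
    neg = np.sort(rng.choice(neg, size=k, replace=False))
    out = {"coordinates": coords, "labels": y, "n_per_group": k}
    for comp in (0, 1):
        a, b = coords[pos, comp], coords[neg, comp]
        if np.allclose(a, b):
            t_p, p_p = 0.0, 1.0
        else:
            t_p, p_p = stats.ttest_rel(a, b)
        t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
        out[f"pca{comp + 1}"] = {
            "t_paired": float(t_p), "p_paired": float(p_p),
            "t_welch": float(t_w), "p_welch": float(p_w),
            "mean_high": float(a.mean()), "mean_low": float(b.mean()),
        }
    return out


@dataclass
class DCRClassifierResults:
    """Fitted-model results: trained network, loss history, held-out
    evaluation, cross-validation metrics."""

    model: CNN
    config: ModelConfig
    loss_history: list[list[float]]
    eval_report: EvalReport
    cv_reports: list[EvalReport] = field(default_factory=list)
    label_map: dict[int, str] = field(default_factory=lambda: dict(LABEL_MAP))
    n_train: int = 0

    @property
    def auc(self) -> float | None:
        return self.eval_report.auc

    @property
    def cv_aucs(self) -> list[float]:
        return [r.auc for r in self.cv_reports if r.auc is not None]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def summary(self) -> str:
        conf = self.eval_report.confusion
        lines = [
            "DCR 3D-CNN classifier results",
            "=" * 46,
            f"training samples            {self.n_train}",
            f"held-out samples            {self.eval_report.n}",
            f"epochs / lr / batch         {self.config.epochs} / "
            f"{self.config.learning_rate} / {self.config.batch_size}",
            f"final mean epoch loss       "
            f"{np.mean(self.loss_history[-1]):.4f}",
            f"held-out AUC                "
            + (f"{self.auc:.4f}" if self.auc is not None else "undefined"),
            f"accuracy low risk (0)       "
            f"{self.eval_report.per_class_accuracy[0]:.4f}",
            f"accuracy high risk (1)      "
            f"{self.eval_report.per_class_accuracy[1]:.4f}",
            "confusion matrix (rows true 0/1, cols predicted 0/1)",
            f"    {conf[0, 0]:6d} {conf[0, 1]:6d}",
            f"    {conf[1, 0]:6d} {conf[1, 1]:6d}",
        ]
        if self.cv_aucs:
            aucs = ", ".join(f"{a:.3f}" for a in self.cv_aucs)
            lines.append(f"5-fold CV AUCs              {aucs}")
        return "\n".join(lines)


class DCRClassifier:
    """DCR-tensor scoliosis-risk model in the model/results idiom.

    Parameters
    ----------
    features
        ``(n, 1536)`` DCR vectors or ``(n, 6, 16, 16)`` tensors.
    labels
        Binary labels; 1 = high risk (Pathogenic), 0 = low risk
        (Benign / Benignlikely).
    config
        Architecture and training settings; defaults follow the study
        protocol (100 epochs, learning rate 0.005, batch size 20,
        validation split 0.2, 5 folds).
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       config: ModelConfig | None = None) -> "DCRClassifier":
        """Build from a wide feature table with one label column; all
        remaining numeric columns are the 1536 DCR features."""
        labels = df[label_column].to_numpy()
        feats = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(feats, labels, config=config)

    def fit(self, balance: bool = True,
            cross_validate: bool = False) -> DCRClassifierResults:
        """Balance classes, hold out the validation split, train the
        final model, and (optionally) run stratified k-fold
        cross-validation for model assessment."""
        cfg = self.config
        X, y = self.features, self.labels
        if balance:
            X, y, _ = balance_downsample(X, y, seed=cfg.seed)
        idx_train, idx_val = train_test_split(
            np.arange(len(y)), test_size=cfg.validation_split,
            random_state=cfg.seed, stratify=y)
        model = build_model(cfg)
        history = train(model, X[idx_train], y[idx_train], cfg)
        report = evaluate(model, X[idx_val], y[idx_val])

        cv_reports = []
        if cross_validate:
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                                  random_state=cfg.seed)
            for tr, va in skf.split(X, y):
                fold_model = build_model(cfg)
                train(fold_model, X[tr], y[tr], cfg)
                cv_reports.append(evaluate(fold_model, X[va], y[va]))

        return DCRClassifierResults(
            model=model, config=cfg, loss_history=history,
            eval_report=report, cv_reports=cv_reports,
            n_train=len(idx_train))
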