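"""CNN training/calibration and the ABC rejection step.

The classifier maps SNP images to scenario logits; after training, its
probabilities are calibrated by temperature scaling (a single scalar T > 0
dividing the logits, fitted by minimizing validation negative
log-likelihood — argmax-preserving by construction).  The calibrated
probability vectors of the observed dataset and of an independent set of
simulations are then used as ABC summary statistics: plain rejection on
Euclidean distance yields scenario posterior probabilities, and — for the
chosen scenario — a CNN regressor's predicted parameter vectors play the
same role for parameter posteriors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import nn
from .demography import MIGRATION_PARAMS, SIZE_PARAMS, TIME_PARAMS
from .simulate import ReferenceTable
from .timescale import hpd_interval

__all__ = [
    "TrainingSpec",
    "ClassifierModel",
    "RegressorModel",
    "CalibrationResult",
    "ModelSelectionResult",
    "ParameterPosterior",
    "train_classifier",
    "calibrate_temperature",
    "predict_probabilities",
    "evaluate_classifier",
    "EvaluationResult",
    "abc_select_model",
    "train_regressor",
    "abc_estimate_parameters",
]


@dataclass(frozen=True)
class TrainingSpec:
    """Hyperparameters of the default CNN and its optimizer."""

    epochs: int = 25
    batch_size: int = 64
    learning_rate: float = 5e-4
    conv_channels: tuple[int, ...] = (32, 32, 32)
    kernels: tuple[int, ...] = (2, 5, 10)
    head: str = "gap"
    hidden: int = 0
    weight_decay: float = 1e-4
    restore_best: bool = True  # rewind to the best-validation epoch


@dataclass
class ClassifierModel:
    """A trained scenario classifier plus its training metadata."""

    net: nn.Sequential
    input_shape: tuple[int, int]
    n_classes: int
    spec: TrainingSpec
    seed: int
    history: pd.DataFrame

    def logits(self, images: np.ndarray) -> np.ndarray:
        x = _as_batch(images, self.input_shape)
        return self.net.forward(x, train=False)

    def weights_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.net.state_bytes()).hexdigest()


@dataclass
class RegressorModel:
    """Multi-output CNN regressor over transformed demographic parameters."""

    net: nn.Sequential
    input_shape: tuple[int, int]
    param_names: list[str]
    target_mean: np.ndarray
    target_sd: np.ndarray
    scenario: int
    spec: TrainingSpec
    seed: int
    history: pd.DataFrame

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predictions on the transformed (log10 / logit) parameter scale."""
        x = _as_batch(images, self.input_shape)
        out = self.net.forward(x, train=False)
        return out * self.target_sd + self.target_mean


@dataclass(frozen=True)
class CalibrationResult:
    temperature: float
    loss_before: float
    loss_after: float


@dataclass(frozen=True)
class ModelSelectionResult:
    pp: np.ndarray
    retained: np.ndarray
    tolerance: float


@dataclass(frozen=True)
class ParameterPosterior:
    """Accepted parameter samples with per-parameter median and 95% HPD."""

    samples: pd.DataFrame
    summary: pd.DataFrame  # index: parameter; columns: median, hpd_low, hpd_high


@dataclass(frozen=True)
class EvaluationResult:
    confusion: np.ndarray  # true scenario x predicted scenario
    accuracy: float
    per_class_accuracy: np.ndarray


def _as_batch(images: np.ndarray, input_shape: tuple[int, int]) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != tuple(input_shape):
        raise ValueError(f"image shape {x.shape[1:]} does not match model input {input_shape}")
    return x


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_classifier(
    train: ReferenceTable,
    val: ReferenceTable,
    hyper: TrainingSpec | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Train the scenario classifier; deterministic for a given seed and spec."""
    hyper = hyper or TrainingSpec()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty reference table")
    if train.image_shape != val.image_shape:
        raise ValueError("train and validation images must share a shape")
    classes = np.union1d(np.unique(train.labels), np.unique(val.labels))
    n_classes = int(classes.max()) + 1
    rng = np.random.default_rng(seed)
    net = nn.build_cnn(train.image_shape[0], n_classes, rng,
                       conv_channels=hyper.conv_channels, kernels=hyper.kernels,
                       head=hyper.head, width=train.image_shape[1], hidden=hyper.hidden)
    opt = nn.Adam(net.params(), lr=hyper.learning_rate, weight_decay=hyper.weight_decay)
    x_train = train.images.astype(np.float64)
    y_train = train.labels.astype(np.int64)
    x_val = val.images.astype(np.float64)
    y_val = val.labels.astype(np.int64)
    hist = []
    best_acc, best_state = -np.inf, None
    for epoch in range(hyper.epochs):
        losses = []
        for idx in _epoch_batches(len(train), hyper.batch_size, rng):
            net.zero_grad()
            logits = net.forward(x_train[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y_train[idx])
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_logits = net.forward(x_val, train=False)
        val_loss, _ = nn.softmax_cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        hist.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_accuracy": val_acc})
        # select by validation accuracy (confidence is recalibrated later by
        # temperature scaling, so accuracy is the relevant criterion here)
        if hyper.restore_best and val_acc > best_acc:
            best_acc, best_state = val_acc, net.get_state()
    if hyper.restore_best and best_state is not None:
        net.set_state(best_state)
    return ClassifierModel(
        net=net,
        input_shape=train.image_shape,
        n_classes=n_classes,
        spec=hyper,
        seed=seed,
        history=pd.DataFrame(hist),
    )


def _nll(logits: np.ndarray, labels: np.ndarray, temperature: float) -> float:
    loss, _ = nn.softmax_cross_entropy(logits / temperature, labels)
    return loss


def calibrate_temperature(model: ClassifierModel, val: ReferenceTable) -> CalibrationResult:
    """Fit the temperature on a validation set by bounded 1-D NLL minimization.

    T = 1 is always a feasible fallback, so the calibrated loss never exceeds
    the uncalibrated one, and dividing logits by a positive scalar never
    changes any argmax.
    """
    if len(val) == 0:
        raise ValueError("empty calibration set")
    if np.unique(val.labels).size < 2:
        raise ValueError("calibration set must contain more than one class")
    logits = model.logits(val.images)
    labels = val.labels.astype(np.int64)
    loss_before = _nll(logits, labels, 1.0)
    res = minimize_scalar(
        lambda t: _nll(logits, labels, t), bounds=(0.05, 20.0), method="bounded"
    )
    temperature = float(res.x)
    loss_after = _nll(logits, labels, temperature)
    if loss_after > loss_before:
        temperature, loss_after = 1.0, loss_before
    return CalibrationResult(temperature=temperature, loss_before=loss_before, loss_after=loss_after)


def predict_probabilities(
    model: ClassifierModel, temperature: float, images: np.ndarray
) -> np.ndarray:
    """Calibrated class probabilities softmax(logits / T), one row per image."""
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    return nn.softmax(model.logits(images) / temperature)


def evaluate_classifier(
    model: ClassifierModel, temperature: float, test: ReferenceTable
) -> EvaluationResult:
    probs = predict_probabilities(model, temperature, test.images)
    pred = probs.argmax(axis=1)
    k = model.n_classes
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(test.labels, pred):
        confusion[int(t), int(p)] += 1
    totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(totals > 0, confusion.diagonal() / totals, np.nan)
    accuracy = float(confusion.trace() / max(confusion.sum(), 1))
    return EvaluationResult(confusion=confusion, accuracy=accuracy, per_class_accuracy=per_class)


def _retain_count(tolerance: float, n: int) -> int:
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    k = int(round(tolerance * n))
    if k < 1:
        raise ValueError("tolerance * reference size must be >= 1")
    return k


def abc_select_model(
    obs_vec: np.ndarray,
    ref_vecs: np.ndarray,
    ref_labels: np.ndarray,
    tolerance: float,
) -> ModelSelectionResult:
    """Rejection ABC on probability vectors: retain the closest fraction and
    read scenario posterior probabilities off the retained labels."""
    ref_vecs = np.asarray(ref_vecs, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if ref_vecs.ndim != 2 or ref_vecs.shape[0] == 0:
        raise ValueError("reference set must be a non-empty 2-D array")
    counts = np.bincount(ref_labels.astype(np.int64))
    if counts[counts > 0].min() != counts.max():
        warnings.warn("reference set is not balanced across scenarios", stacklevel=2)
    k = _retain_count(tolerance, ref_vecs.shape[0])
    d = np.linalg.norm(ref_vecs - np.asarray(obs_vec, dtype=float)[None, :], axis=1)
    retained = np.argsort(d, kind="stable")[:k]  # stable: ties broken by record id
    n_classes = int(ref_labels.max()) + 1
    pp = np.bincount(ref_labels[retained].astype(np.int64), minlength=n_classes) / k
    return ModelSelectionResult(pp=pp, retained=retained, tolerance=tolerance)


_LOG10_PARAMS = TIME_PARAMS + SIZE_PARAMS


def transform_params(params: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Map parameters to regression scale: log10 for times/sizes, logit for
    migrant fractions."""
    cols = []
    for name in names:
        x = params[name].to_numpy(dtype=float)
        if name in _LOG10_PARAMS:
            cols.append(np.log10(x))
        elif name in MIGRATION_PARAMS:
            cols.append(np.log(x / (1.0 - x)))
        else:
            raise KeyError(f"unknown parameter {name!r}")
    return np.stack(cols, axis=1)


def free_param_names(scenario: int) -> list[str]:
    """Parameters that vary under a scenario (constrained copies excluded)."""
    from .demography import ScenarioId

    scen = ScenarioId(scenario)
    names = list(TIME_PARAMS) + ["n_anc", "n_ez_pre", "n_z_pre"]
    if scen.ez_expands:
        names += ["n_ez_lgp", "n_ez_post"]
    if scen.z_expands:
        names += ["n_z_lgp", "n_z_post"]
    names += list(MIGRATION_PARAMS)
    return names


def train_regressor(
    train: ReferenceTable,
    hyper: TrainingSpec | None = None,
    seed: int = 0,
    param_names: list[str] | None = None,
    val_fraction: float = 0.1,
) -> RegressorModel:
    """Train the parameter regressor on a single-scenario reference table."""
    hyper = hyper or TrainingSpec()
    if len(train) == 0:
        raise ValueError("empty reference table")
    scenarios = np.unique(train.labels)
    if scenarios.size != 1:
        raise ValueError("train_regressor requires records from a single scenario")
    scenario = int(scenarios[0])
    param_names = param_names or free_param_names(scenario)
    y_raw = transform_params(train.params, param_names)
    target_mean = y_raw.mean(axis=0)
    target_sd = y_raw.std(axis=0)
    target_sd[target_sd == 0] = 1.0
    y = (y_raw - target_mean) / target_sd
    rng = np.random.default_rng(seed)
    n = len(train)
    n_val = max(1, int(round(val_fraction * n))) if n > 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    net = nn.build_cnn(train.image_shape[0], len(param_names), rng,
                       conv_channels=hyper.conv_channels, kernels=hyper.kernels,
                       head=hyper.head, width=train.image_shape[1], hidden=hyper.hidden)
    opt = nn.Adam(net.params(), lr=hyper.learning_rate, weight_decay=hyper.weight_decay)
    x = train.images.astype(np.float64)
    hist = []
    best_loss, best_state = np.inf, None
    for epoch in range(hyper.epochs):
        losses = []
        for bidx in _epoch_batches(len(train_idx), hyper.batch_size, rng):
            idx = train_idx[bidx]
            net.zero_grad()
            pred = net.forward(x[idx], train=True)
            loss, grad = nn.mse_loss(pred, y[idx])
            net.backward(grad)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if n_val:
            vpred = net.forward(x[val_idx], train=False)
            row["val_loss"] = nn.mse_loss(vpred, y[val_idx])[0]
            if hyper.restore_best and row["val_loss"] < best_loss:
                best_loss, best_state = row["val_loss"], net.get_state()
        hist.append(row)
    if hyper.restore_best and best_state is not None:
        net.set_state(best_state)
    return RegressorModel(
        net=net,
        input_shape=train.image_shape,
        param_names=list(param_names),
        target_mean=target_mean,
        target_sd=target_sd,
        scenario=scenario,
        spec=hyper,
        seed=seed,
        history=pd.DataFrame(hist),
    )


def abc_estimate_parameters(
    obs_pred: np.ndarray,
    ref_preds: np.ndarray,
    ref_params: pd.DataFrame,
    tolerance: float,
    param_names: list[str] | None = None,
) -> ParameterPosterior:
    """Rejection ABC in predicted-parameter space.

    Distances are Euclidean after standardizing each dimension by the
    reference standard deviation (zero-variance dimensions are dropped with
    a warning); the posterior is the set of true parameters of the retained
    records, summarized by median and 95% HPD.
    """
    ref_preds = np.asarray(ref_preds, dtype=float)
    obs_pred = np.asarray(obs_pred, dtype=float).ravel()
    if ref_preds.ndim != 2 or ref_preds.shape[0] == 0:
        raise ValueError("reference predictions must be a non-empty 2-D array")
    if len(ref_params) != ref_preds.shape[0]:
        raise ValueError("ref_params and ref_preds must align")
    sd = ref_preds.std(axis=0)
    scale = np.maximum(1.0, np.abs(ref_preds).max(axis=0))
    keep = sd > 1e-12 * scale  # constant dimensions up to float rounding
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance dimension(s) from the ABC distance",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all summary dimensions have zero variance")
    d = np.linalg.norm((ref_preds[:, keep] - obs_pred[keep]) / sd[keep], axis=1)
    k = _retain_count(tolerance, ref_preds.shape[0])
    retained = np.argsort(d, kind="stable")[:k]
    if param_names is None:
        param_names = [c for c in ref_params.columns if c not in ("scenario", "seed")]
    samples = ref_params.iloc[retained][param_names].reset_index(drop=True)
    rows = {}
    for name in param_names:
        vals = samples[name].to_numpy(dtype=float)
        if k >= 20:
            low, high = hpd_interval(vals, 0.95)
        else:  # too few samples for an HPD: fall back to min/max
            low, high = float(vals.min()), float(vals.max())
        rows[name] = {"median": float(np.median(vals)), "hpd_low": low, "hpd_high": high}
    summary = pd.DataFrame(rows).T[["median", "hpd_low", "hpd_high"]]
    return ParameterPosterior(samples=samples, summary=summary)
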