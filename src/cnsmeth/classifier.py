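"""Masked-feature neural network for sparse binary methylation profiles.

Low-pass nanopore runs observe only a small, run-dependent subset of the
atlas CpGs, while the reference cohort is fully observed. To make a
network robust to that missingness, every training sample is presented
each epoch with a random fraction of its features masked out (the
fraction drawn uniformly from a configured range spanning realistic
sparsity). Missing and masked features share one encoding: the value
channel is zeroed and a parallel binary "observed" indicator channel is
zeroed, so "unmethylated" and "unobserved" remain distinguishable.

Raw outputs are converted to classification scores by temperature
scaling (fit on a held-out split) followed by a softmax, giving a
probability that measures confidence in the tumor class assignment.
Family-level scores are the exact sums of member class scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .features import BinaryFeatureVector, ReferenceAtlas

__all__ = [
    "MaskedNetConfig",
    "MaskedNetModel",
    "ClassScores",
    "FamilyScores",
    "TopCall",
    "TrainingError",
    "ConvergenceWarning",
    "train",
    "predict",
    "aggregate_families",
    "top_call",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class TrainingError(RuntimeError):
    """Raised when optimization diverges (e.g. NaN loss)."""


class ConvergenceWarning(UserWarning):
    """Held-out accuracy below the configured target after training."""


@dataclass(frozen=True)
class MaskedNetConfig:
    """Training hyperparameters.

    ``mask_rate_range`` defaults to (0.3, 0.99): the fraction of features
    hidden per presentation, spanning roughly the sparsity seen in
    low-pass runs (from under 1% to ~80% of atlas sites observed).
    """

    hidden_size: int = 256
    mask_rate_range: tuple[float, float] = (0.3, 0.99)
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    val_fraction: float = 0.2
    min_val_accuracy: float = 0.9
    temperature_bounds: tuple[float, float] = (0.05, 20.0)

    def __post_init__(self) -> None:
        lo, hi = self.mask_rate_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("mask_rate_range must satisfy 0 <= lo <= hi <= 1")
        if self.hidden_size < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("hidden_size, epochs and batch_size must be positive")


@dataclass
class ClassScores:
    """Softmax probability per methylation class; sums to 1."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class scores sum to {total}, expected 1")
        for label, s in self.scores.items():
            if not -1e-9 <= s <= 1.0 + 1e-9:
                raise ValueError(f"score for {label} outside [0, 1]: {s}")

    def __getitem__(self, label: str) -> float:
        return self.scores[label]

    def items(self):
        return self.scores.items()


@dataclass
class FamilyScores:
    """Per-family scores: exact sums of member class scores."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"family scores sum to {total}, expected 1")

    def __getitem__(self, label: str) -> float:
        return self.scores[label]

    def items(self):
        return self.scores.items()


@dataclass
class TopCall:
    label: str
    score: float
    tie: bool = False


@dataclass
class MaskedNetModel:
    """A trained single-hidden-layer network with fixed class order.

    The class order is serialized with the model; the output dimension
    equals the number of classes.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    class_order: list[str]
    hierarchy: dict[str, str]
    temperature: float
    config: MaskedNetConfig
    seed: int
    heldout_accuracy: float = float("nan")

    @property
    def n_sites(self) -> int:
        return self.w1.shape[0] // 2

    @property
    def n_classes(self) -> int:
        return self.w2.shape[1]

    def _encode(self, values: np.ndarray) -> np.ndarray:
        """Stack (value, observed) channels; NaN means missing."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.n_sites:
            raise ValueError(
                f"feature vector length {values.shape[1]} != model input "
                f"dimension {self.n_sites}"
            )
        obs = (~np.isnan(values)).astype(float)
        vals = np.where(np.isnan(values), 0.0, values)
        return np.hstack([vals, obs])

    def logits(self, values: np.ndarray) -> np.ndarray:
        x = self._encode(values)
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        return h @ self.w2 + self.b2

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(values) / self.temperature)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def apply_mask(
    values: np.ndarray, observed: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out a random per-row fraction of features in both channels.

    A rate of 0 leaves the row untouched, so a (0, 0) mask-rate range
    reduces training to standard supervised training.
    """
    rates = np.asarray(rates, dtype=float)[:, None]
    drop = rng.random(values.shape) < rates
    return np.where(drop, 0.0, values), np.where(drop, 0.0, observed)


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        if len(idx) > 1:
            n_val = min(max(n_val, 1), len(idx) - 1)
        else:
            n_val = 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train(
    atlas: ReferenceAtlas,
    config: MaskedNetConfig | None = None,
    seed: int = 0,
) -> MaskedNetModel:
    """Train the masked-feature network on a filtered reference atlas.

    Deterministic under ``seed``. Requires at least two classes and two
    samples per class; warns (ConvergenceWarning) if held-out accuracy
    ends below ``config.min_val_accuracy``.
    """
    config = config or MaskedNetConfig()
    classes = atlas.classes
    if len(classes) < 2:
        raise ValueError("training requires at least two methylation classes")
    counts = {c: int((atlas.labels == c).sum()) for c in classes}
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes with fewer than 2 samples: {thin}")

    rng = np.random.default_rng(seed)
    X = atlas.matrix.astype(float)
    y = np.array([classes.index(label) for label in atlas.labels])
    n, s = X.shape
    k = len(classes)

    tr, va = _stratified_split(atlas.labels, config.val_fraction, rng)
    obs_full = np.ones_like(X)

    h = config.hidden_size
    w1 = rng.normal(0.0, np.sqrt(2.0 / (2 * s)), size=(2 * s, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, k))
    b2 = np.zeros(k)
    params = [w1, b1, w2, b2]
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    lo, hi = config.mask_rate_range
    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            rates = rng.uniform(lo, hi, size=len(batch))
            vals, obs = apply_mask(X[batch], obs_full[batch], rates, rng)
            xb = np.hstack([vals, obs])
            yb = y[batch]

            z1 = xb @ params[0] + params[1]
            a1 = np.maximum(z1, 0.0)
            logits = a1 @ params[2] + params[3]
            probs = _softmax(logits)
            ll = -np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None))
            loss = ll.mean()
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, step {step}: loss={loss}; "
                    f"|w1|max={np.abs(params[0]).max():.3g}, lr={config.learning_rate}"
                )

            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            g2 = a1.T @ dlogits + config.weight_decay * params[2]
            gb2 = dlogits.sum(axis=0)
            da1 = dlogits @ params[2].T
            dz1 = da1 * (z1 > 0)
            g1 = xb.T @ dz1 + config.weight_decay * params[0]
            gb1 = dz1.sum(axis=0)

            step += 1
            for p, g, ms, vs in zip(params, [g1, gb1, g2, gb2], m_state, v_state):
                ms *= beta1
                ms += (1 - beta1) * g
                vs *= beta2
                vs += (1 - beta2) * g * g
                m_hat = ms / (1 - beta1**step)
                v_hat = vs / (1 - beta2**step)
                p -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    model = MaskedNetModel(
        w1=params[0], b1=params[1], w2=params[2], b2=params[3],
        class_order=classes, hierarchy=dict(atlas.hierarchy),
        temperature=1.0, config=config, seed=seed,
    )

    if len(va) > 0:
        val_logits = model.logits(X[va])
        val_acc = float((val_logits.argmax(axis=1) == y[va]).mean())
        model.temperature = _fit_temperature(
            model, X[va], y[va], config, rng
        )
    else:
        val_acc = float("nan")
    model.heldout_accuracy = val_acc
    if np.isfinite(val_acc) and val_acc < config.min_val_accuracy:
        warnings.warn(
            f"held-out accuracy {val_acc:.3f} below target "
            f"{config.min_val_accuracy:.3f}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return model


def _fit_temperature(
    model: MaskedNetModel,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: MaskedNetConfig,
    rng: np.random.Generator,
    n_masked_copies: int = 5,
) -> float:
    """Choose the softmax temperature minimizing held-out NLL.

    The validation samples are replicated under the training-time masking
    distribution so the calibration matches deployment sparsity.
    """
    lo, hi = config.mask_rate_range
    xs, ys = [x_val], [y_val]
    obs = np.ones_like(x_val)
    for _ in range(n_masked_copies):
        rates = rng.uniform(lo, hi, size=len(x_val))
        vals, ob = apply_mask(x_val, obs, rates, rng)
        vals = vals.copy()
        vals[ob == 0] = np.nan
        xs.append(vals)
        ys.append(y_val)
    values = np.vstack(xs)
    y = np.concatenate(ys)
    logits = model.logits(values)

    def nll(t: float) -> float:
        p = _softmax(logits / t)
        return float(-np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean())

    res = minimize_scalar(nll, bounds=config.temperature_bounds, method="bounded")
    return float(res.x)


def predict(model: MaskedNetModel, vector: BinaryFeatureVector | np.ndarray) -> ClassScores:
    """Score one case: missing features receive the training-time masked
    encoding; output is a temperature-scaled softmax over classes."""
    values = vector.values if isinstance(vector, BinaryFeatureVector) else np.asarray(vector)
    probs = model.predict_proba(values)[0]
    probs = probs / probs.sum()
    return ClassScores({c: float(p) for c, p in zip(model.class_order, probs)})


def aggregate_families(
    scores: ClassScores, hierarchy: dict[str, str]
) -> FamilyScores:
    """Sum class scores within each methylation class family."""
    out: dict[str, float] = {}
    for cls, score in scores.items():
        if cls not in hierarchy:
            raise KeyError(f"class {cls!r} missing from class->family hierarchy")
        fam = hierarchy[cls]
        out[fam] = out.get(fam, 0.0) + score
    return FamilyScores(out)


def top_call(scores: ClassScores | FamilyScores | dict[str, float]) -> TopCall:
    """Best-scoring label; ties break lexicographically and are flagged."""
    items = scores.items() if not isinstance(scores, dict) else scores.items()
    items = list(items)
    if not items:
        raise ValueError("empty score map")
    best_score = max(s for _, s in items)
    tied = sorted(label for label, s in items if s == best_score)
    return TopCall(label=tied[0], score=best_score, tie=len(tied) > 1)


def save_model(model: MaskedNetModel, path: str | Path) -> None:
    """Serialize to a single versioned .npz with class order and hierarchy
    embedded."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "class_order": model.class_order,
        "hierarchy": model.hierarchy,
        "temperature": model.temperature,
        "seed": model.seed,
        "heldout_accuracy": model.heldout_accuracy,
        "config": {
            "hidden_size": model.config.hidden_size,
            "mask_rate_range": list(model.config.mask_rate_range),
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "learning_rate": model.config.learning_rate,
            "weight_decay": model.config.weight_decay,
            "val_fraction": model.config.val_fraction,
            "min_val_accuracy": model.config.min_val_accuracy,
        },
    }
    np.savez(
        path,
        w1=model.w1, b1=model.b1, w2=model.w2, b2=model.b2,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> MaskedNetModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']}")
        cfg = meta["config"]
        config = MaskedNetConfig(
            hidden_size=cfg["hidden_size"],
            mask_rate_range=tuple(cfg["mask_rate_range"]),
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            learning_rate=cfg["learning_rate"],
            weight_decay=cfg["weight_decay"],
            val_fraction=cfg["val_fraction"],
            min_val_accuracy=cfg["min_val_accuracy"],
        )
        return MaskedNetModel(
            w1=data["w1"], b1=data["b1"], w2=data["w2"], b2=data["b2"],
            class_order=list(meta["class_order"]),
            hierarchy=dict(meta["hierarchy"]),
            temperature=float(meta["temperature"]),
            config=config,
            seed=int(meta["seed"]),
            heldout_accuracy=float(meta["heldout_accuracy"]),
        )
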