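"""The neural classifier and its calibration.

The identifier is a small feed-forward network: feature vector in [0,1]^N in,
probability vector over the M classes out.  Architecture follows a fixed
rule — one or two hidden layers, each of dimension max(N, M), ReLU or Mish
activations, softmax output so every prediction is a proper probability
vector.  Calibration minimizes the *sum* of cross-entropy losses over the
training set by full-batch gradient descent under one of five optimizers
(SGD, Adam, AdamW, and the AMSGrad variants of the latter two), for at most
1000 epochs per learning rate; a grid of learning rates is searched and the
best-scoring calibration kept.  All randomness is seeded: the same
configuration yields byte-identical weights.

Everything here is plain numpy; networks of this size (tens of inputs,
about a hundred classes, a few thousand training rows) train in seconds
with full-batch steps, which also removes mini-batch nondeterminism.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from . import metrics as _metrics
from .dataset import (
    augment_training_missing,
    eligible,
    split_by_class,
    train_fraction_count,
)
from .encoding import (
    CharacterGroup,
    ContinuousCharacterDef,
    DiscreteCharacterDef,
    EmpiricalDistribution,
    encode_records,
    fit_group_distributions,
)

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import CollectionRecord, DatasetSplit
    from .taxonomy import TaxonomyTable

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "CalibratedIdentifier",
    "cross_entropy_loss",
    "total_loss",
    "train_network",
    "grid_search",
    "fit_identifier",
    "FitResult",
]

PROB_FLOOR = 1e-12

ADAM_RATES = (0.0001, 0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05)
SGD_RATES = (0.05, 0.1, 0.2)


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of the classifier network.

    The hidden dimension is not free: it equals max(input_dim, output_dim).
    ``activation`` may be a single name or one name per hidden layer
    (e.g. ``("relu", "mish")``).
    """

    input_dim: int
    output_dim: int
    n_hidden_layers: int = 1
    activation: str | tuple[str, ...] = "relu"

    def __post_init__(self) -> None:
        if self.n_hidden_layers not in (1, 2):
            raise ValueError("n_hidden_layers must be 1 or 2")
        for a in self.activations:
            if a not in ("relu", "mish"):
                raise ValueError(f"unknown activation {a!r}")

    @property
    def activations(self) -> tuple[str, ...]:
        if isinstance(self.activation, str):
            return (self.activation,) * self.n_hidden_layers
        if len(self.activation) != self.n_hidden_layers:
            raise ValueError("one activation per hidden layer required")
        return tuple(self.activation)

    @property
    def hidden_dim(self) -> int:
        return max(self.input_dim, self.output_dim)


@dataclass
class TrainingConfig:
    """Hyperparameters of one calibration run.

    ``learning_rates`` defaults to the standard grid for the chosen
    optimizer: nine rates from 1e-4 to 5e-2 for Adam/AdamW, {0.05, 0.1, 0.2}
    for SGD.  ``select_on='validation'`` picks the winning rate by MRR on a
    15% carve-out of the training set (no test leakage); ``'train'`` picks by
    final training loss.
    """

    optimizer: str = "adamw"
    amsgrad: bool = False
    learning_rates: tuple[float, ...] | None = None
    max_epochs: int = 1000
    seed: int = 0
    weight_decay: float | None = None  # None -> 0.01 for adamw, else 0
    plateau_patience: int = 50
    plateau_tol: float = 1e-9
    validation_fraction: float = 0.15
    select_on: str = "validation"

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.optimizer == "sgd" and self.amsgrad:
            raise ValueError("amsgrad applies only to adam/adamw")
        if self.select_on not in ("validation", "train"):
            raise ValueError("select_on must be 'validation' or 'train'")

    @property
    def rates(self) -> tuple[float, ...]:
        if self.learning_rates is not None:
            return tuple(self.learning_rates)
        return SGD_RATES if self.optimizer == "sgd" else ADAM_RATES

    @property
    def effective_weight_decay(self) -> float:
        if self.weight_decay is not None:
            return self.weight_decay
        return 0.01 if self.optimizer == "adamw" else 0.0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --- activations -----------------------------------------------------------

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0).astype(float)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _mish(x: np.ndarray) -> np.ndarray:
    return x * np.tanh(_softplus(x))


def _mish_grad(x: np.ndarray) -> np.ndarray:
    sp = _softplus(x)
    t = np.tanh(sp)
    sig = 1.0 / (1.0 + np.exp(-x))
    return t + x * (1.0 - t * t) * sig


_ACT = {"relu": (_relu, _relu_grad), "mish": (_mish, _mish_grad)}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --- losses ---------------------------------------------------------------

def cross_entropy_loss(prob_vector: Sequence[float], true_class_index: int) -> float:
    """-log p(true class), natural log; p = 0 is floored with a warning."""
    p = np.asarray(prob_vector, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    pt = p[true_class_index]
    if pt < PROB_FLOOR:
        warnings.warn(
            f"true-class probability {pt} floored at {PROB_FLOOR} in loss"
        )
        pt = PROB_FLOOR
    return float(-np.log(pt))


def _sum_ce(probs: np.ndarray, y: np.ndarray) -> float:
    pt = np.clip(probs[np.arange(len(y)), y], PROB_FLOOR, None)
    return float(-np.log(pt).sum())


# --- the network ----------------------------------------------------------

class _Network:
    """Weights + forward/backward for the fixed architecture."""

    def __init__(self, spec: NetworkSpec, seed: int) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim] + [spec.hidden_dim] * spec.n_hidden_layers + [spec.output_dim]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            k = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-k, k, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-k, k, size=fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = self.spec.activations
        pre: list[np.ndarray] = []
        a = X
        for i in range(len(self.W) - 1):
            z = a @ self.W[i] + self.b[i]
            pre.append(z)
            a = _ACT[acts[i]][0](z)
            pre.append(a)
        logits = a @ self.W[-1] + self.b[-1]
        return _softmax(logits), pre

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, dtype=float))[0]

    def gradients(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        """Loss (sum of cross-entropies) and gradients w.r.t. all params."""
        probs, pre = self.forward(X)
        loss = _sum_ce(probs, y)
        n_layers = len(self.W)
        acts = self.spec.activations
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(y)), y] = 1.0
        delta = probs - onehot  # d(sum CE)/d logits
        gW: list[np.ndarray] = [np.empty(0)] * n_layers
        gb: list[np.ndarray] = [np.empty(0)] * n_layers
        for i in range(n_layers - 1, -1, -1):
            a_prev = X if i == 0 else pre[2 * i - 1]
            gW[i] = a_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                z_prev = pre[2 * (i - 1)]
                delta = (delta @ self.W[i].T) * _ACT[acts[i - 1]][1](z_prev)
        return loss, gW + gb


class _Optimizer:
    def __init__(self, config: TrainingConfig, lr: float, params: list[np.ndarray]):
        self.kind = config.optimizer
        self.lr = lr
        self.amsgrad = config.amsgrad
        self.wd = config.effective_weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.vmax = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.kind == "sgd":
            for p, g in zip(params, grads):
                p -= self.lr * g
            return
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.kind == "adam" and self.wd:
                g = g + self.wd * p  # coupled L2
            if self.kind == "adamw" and self.wd:
                p -= self.lr * self.wd * p  # decoupled decay
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            if self.amsgrad:
                np.maximum(self.vmax[i], self.v[i], out=self.vmax[i])
                vhat = self.vmax[i] / (1 - self.beta2**self.t)
            else:
                vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class CalibratedIdentifier:
    """A frozen, deployable identifier.

    Bundles the character group with its fitted encoding distributions, the
    network weights, the ordered class list and the provenance of the run.
    ``group`` is None for identifiers trained directly on feature matrices.
    """

    network: _Network
    classes: list[str]
    mode: str = "species"
    group: CharacterGroup | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def spec(self) -> NetworkSpec:
        return self.network.spec

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability matrix for pre-encoded feature rows."""
        return self.network.predict_proba(X)

    # -- archive ------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the identifier archive (versioned JSON; floats round-trip
        bit-exactly via their shortest-repr decimal form)."""
        members = []
        if self.group is not None:
            for m in self.group.members:
                if isinstance(m, ContinuousCharacterDef):
                    if m.distribution is None:
                        raise ValueError(f"member {m.name!r} has no fitted distribution")
                    members.append(
                        {
                            "kind": "continuous",
                            "name": m.name,
                            "units": m.units,
                            "knots": m.distribution.knots.tolist(),
                            "probs": m.distribution.probs.tolist(),
                        }
                    )
                else:
                    members.append(
                        {"kind": "discrete", "name": m.name, "states": list(m.states)}
                    )
        doc = {
            "format": "morphoident-identifier",
            "version": 1,
            "mode": self.mode,
            "classes": self.classes,
            "spec": {
                "input_dim": self.spec.input_dim,
                "output_dim": self.spec.output_dim,
                "n_hidden_layers": self.spec.n_hidden_layers,
                "activation": list(self.spec.activations),
            },
            "weights": {
                "W": [w.tolist() for w in self.network.W],
                "b": [b.tolist() for b in self.network.b],
            },
            "group": None
            if self.group is None
            else {
                "id": self.group.id,
                "filter_only": list(self.group.filter_only),
                "members": members,
            },
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CalibratedIdentifier":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format") != "morphoident-identifier":
            raise ValueError(f"{path}: not an identifier archive")
        spec = NetworkSpec(
            input_dim=doc["spec"]["input_dim"],
            output_dim=doc["spec"]["output_dim"],
            n_hidden_layers=doc["spec"]["n_hidden_layers"],
            activation=tuple(doc["spec"]["activation"]),
        )
        net = _Network(spec, seed=0)
        net.W = [np.array(w, dtype=float) for w in doc["weights"]["W"]]
        net.b = [np.array(b, dtype=float) for b in doc["weights"]["b"]]
        group = None
        if doc["group"] is not None:
            members = []
            for m in doc["group"]["members"]:
                if m["kind"] == "continuous":
                    members.append(
                        ContinuousCharacterDef(
                            m["name"],
                            m.get("units", ""),
                            EmpiricalDistribution(
                                np.array(m["knots"], dtype=float),
                                np.array(m["probs"], dtype=float),
                            ),
                        )
                    )
                else:
                    members.append(DiscreteCharacterDef(m["name"], tuple(m["states"])))
            group = CharacterGroup(
                doc["group"]["id"], members, list(doc["group"]["filter_only"])
            )
        return cls(
            network=net,
            classes=list(doc["classes"]),
            mode=doc["mode"],
            group=group,
            provenance=doc.get("provenance", {}),
        )


def total_loss(identifier: CalibratedIdentifier, X: np.ndarray, y: Sequence[int]) -> float:
    """Sum (not mean) of cross-entropy losses over the given records."""
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty record set")
    return _sum_ce(identifier.predict_proba(np.asarray(X, dtype=float)), y)


def train_network(
    features: np.ndarray,
    labels: Sequence[int],
    spec: NetworkSpec,
    config: TrainingConfig,
    learning_rate: float | None = None,
    classes: Sequence[str] | None = None,
) -> CalibratedIdentifier:
    """Calibrate one network at one learning rate.

    Runs full-batch gradient steps for at most ``config.max_epochs`` epochs,
    stopping early once the loss has improved by less than ``plateau_tol``
    for ``plateau_patience`` consecutive epochs.  Deterministic given
    ``config.seed`` (which fixes the weight initialization).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, dims) with one label per row")
    if len(y) == 0:
        raise ValueError("empty training set")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN; records must be complete")
    if y.min() < 0 or y.max() >= spec.output_dim:
        raise ValueError("label index outside [0, output_dim)")
    lr = float(learning_rate if learning_rate is not None else config.rates[0])
    net = _Network(spec, seed=config.seed)
    opt = _Optimizer(config, lr, net.params)
    initial_loss = None
    best = np.inf
    best_params = [p.copy() for p in net.params]
    stall = 0
    epochs_run = 0
    for epoch in range(config.max_epochs):
        loss, grads = net.gradients(X, y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"loss diverged to {loss} at epoch {epoch} (lr={lr}, "
                f"optimizer={config.optimizer})"
            )
        if initial_loss is None:
            initial_loss = loss
        if loss < best - config.plateau_tol:
            best = loss
            best_params = [p.copy() for p in net.params]
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                break
        opt.step(net.params, grads)
        epochs_run = epoch + 1
    tail_loss, _ = net.gradients(X, y)
    if np.isfinite(tail_loss) and tail_loss < best:
        best = tail_loss
        best_params = [p.copy() for p in net.params]
    # keep the best parameters seen, so the final loss never exceeds the
    # initial one even if the last steps overshot
    for p, bp in zip(net.params, best_params):
        p[...] = bp
    final_loss = float(best)
    initial_loss = float(initial_loss)
    class_list = list(classes) if classes is not None else [str(i) for i in range(spec.output_dim)]
    return CalibratedIdentifier(
        network=net,
        classes=class_list,
        provenance={
            "seed": config.seed,
            "learning_rate": lr,
            "optimizer": config.optimizer,
            "amsgrad": config.amsgrad,
            "epochs_run": epochs_run,
            "initial_loss": initial_loss,
            "final_loss": final_loss,
            "config_digest": config.digest(),
        },
    )


def _carve_validation(
    y: np.ndarray, config: TrainingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class validation carve-out indices (train_idx, val_idx)."""
    rng = np.random.default_rng(config.seed + 1)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(len(idx))
        k = train_fraction_count(len(idx), 1.0 - config.validation_fraction)
        train_idx.extend(idx[perm[:k]])
        val_idx.extend(idx[perm[k:]])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def grid_search(
    features: np.ndarray,
    labels: Sequence[int],
    spec: NetworkSpec,
    config: TrainingConfig,
    classes: Sequence[str] | None = None,
) -> tuple[CalibratedIdentifier, list[dict]]:
    """Calibrate one identifier per learning rate and keep the best.

    Selection uses MRR on a per-class 15% validation carve-out of the
    training data (``select_on='validation'``) or final training loss
    (``select_on='train'``).  After selection the winner is retrained on the
    full training data at the winning rate.  Returns the winner and the
    per-rate score table.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not config.rates:
        raise ValueError("empty learning-rate grid")
    use_val = config.select_on == "validation" and len(y) >= 8 and len(np.unique(y)) >= 2
    if use_val:
        tr, va = _carve_validation(y, config)
        if len(va) == 0:
            use_val = False
    table: list[dict] = []
    failures: list[str] = []
    best_score, best_lr = -np.inf, None
    for lr in config.rates:
        try:
            if use_val:
                cand = train_network(X[tr], y[tr], spec, config, lr, classes)
                probs = cand.predict_proba(X[va])
                score = _metrics.mrr_from_probs(probs, y[va])
            else:
                cand = train_network(X, y, spec, config, lr, classes)
                score = -cand.provenance["final_loss"]
        except RuntimeError as e:
            failures.append(f"lr={lr}: {e}")
            table.append({"learning_rate": lr, "score": None, "error": str(e)})
            continue
        table.append(
            {
                "learning_rate": lr,
                "score": score,
                "final_loss": cand.provenance["final_loss"],
                "epochs_run": cand.provenance["epochs_run"],
            }
        )
        if score > best_score:
            best_score, best_lr = score, lr
    if best_lr is None:
        raise RuntimeError("all learning rates diverged: " + "; ".join(failures))
    winner = train_network(X, y, spec, config, best_lr, classes)
    winner.provenance["grid"] = table
    winner.provenance["selected_learning_rate"] = best_lr
    return winner, table


@dataclass
class FitResult:
    """Outcome of an end-to-end calibration on collection records."""

    identifier: CalibratedIdentifier
    split: "DatasetSplit"
    test_records: list  # complete test-set records for this group
    grid_table: list[dict]


def fit_identifier(
    records: Sequence["CollectionRecord"],
    group: CharacterGroup,
    mode: str = "species",
    taxonomy: "TaxonomyTable | None" = None,
    config: TrainingConfig | None = None,
    spec: NetworkSpec | None = None,
    n_hidden_layers: int = 1,
    activation: str | tuple[str, ...] = "relu",
    allow_one_missing: bool = True,
    fraction: float = 0.7,
) -> FitResult:
    """Full calibration pipeline on raw collection records.

    Filters to group-eligible records, splits 70/30 per class, augments
    single-missing training records with species training averages, fits the
    per-character encoding distributions on the training set only, encodes,
    and grid-searches the network.  Test records that are incomplete for the
    group are excluded (imputation at test time would need the label).
    """
    if config is None:
        config = TrainingConfig()
    if mode not in ("species", "section"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "section" and taxonomy is None:
        raise ValueError("section mode requires a taxonomy table")

    def label_of(r: "CollectionRecord") -> str:
        if r.species is None:
            raise ValueError(f"collection {r.collection_id!r} has no species label")
        if taxonomy is not None and mode == "section":
            return taxonomy.section_of(r.species)
        return r.species

    pool = [r for r in records if eligible(r, group, allow_one_missing)]
    if not pool:
        raise ValueError(f"no records eligible for group {group.id}")
    labels_by_id = {r.collection_id: label_of(r) for r in pool}
    split = split_by_class(pool, labels_by_id, fraction=fraction, seed=config.seed)
    train = split.subset(pool, "train")
    test = [r for r in split.subset(pool, "test") if eligible(r, group, False)]

    train = augment_training_missing(train, group)
    if not train:
        raise ValueError("no training records left after augmentation")
    fitted = fit_group_distributions(group, train)

    if taxonomy is not None:
        classes = [
            c for c in taxonomy.class_list(mode)
            if c in {labels_by_id[r.collection_id] for r in train}
        ]
    else:
        classes = sorted({labels_by_id[r.collection_id] for r in train})
    class_index = {c: i for i, c in enumerate(classes)}

    X = encode_records(train, fitted)
    y = np.array([class_index[labels_by_id[r.collection_id]] for r in train])
    net_spec = spec or NetworkSpec(
        input_dim=fitted.total_dims,
        output_dim=len(classes),
        n_hidden_layers=n_hidden_layers,
        activation=activation,
    )
    if net_spec.input_dim != fitted.total_dims or net_spec.output_dim != len(classes):
        raise ValueError("network spec dims do not match group/classes")
    ident, table = grid_search(X, y, net_spec, config, classes)
    ident.mode = mode
    ident.group = fitted
    return FitResult(identifier=ident, split=split, test_records=test, grid_table=table)
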