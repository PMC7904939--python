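"""The 2D CNN affinity regressor and its scikit-learn estimator wrapper.

Architecture (single-channel n_d x n_t input):

    conv(32 filters, 5x5, valid) -> maxpool(2x2, stride 1)
    -> conv(18 filters, 3x3, valid) -> maxpool(2x2, stride 1)
    -> flatten -> dropout(0.1) -> dense(128, ReLU) -> dense(1, linear)

trained with Adam (lr 0.001), mean-squared-error loss, batch size 32,
20 epochs, examples reshuffled each epoch under the run seed.  Both
convolutions are unpadded and the poolings overlap, so the smallest legal
input is 9 x 9 with the default kernels.

:class:`SimCNNRegressor` is the estimator (fit/predict/get_params);
:class:`TrainedModel` couples a fitted estimator with the drug and target
rosters its similarity vectors are defined against, which is what
persistence and candidate ranking need.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .core import Drug, Target
from .features import (
    PairInput,
    outer_product,
    similarity_vector_for_drug,
    similarity_vector_for_target,
)

__all__ = [
    "ModelConfig",
    "SimCNNRegressor",
    "TrainedModel",
    "layer_output_shapes",
    "min_input_size",
    "build_model",
    "train",
    "predict",
    "rank_candidates",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters (defaults as published)."""

    conv_filters: tuple = (32, 18)
    conv_kernels: tuple = ((5, 5), (3, 3))
    pool_size: int = 2
    pool_stride: int = 1
    dropout_rate: float = 0.1
    fc_width: int = 128
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "conv_filters", tuple(self.conv_filters))
        object.__setattr__(
            self, "conv_kernels", tuple(tuple(k) for k in self.conv_kernels)
        )
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels lengths differ")
        if any(f <= 0 for f in self.conv_filters):
            raise ValueError("filter counts must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.fc_width, self.batch_size, self.pool_size) <= 0:
            raise ValueError("fc_width, batch_size and pool_size must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.pool_size != 2 or self.pool_stride != 1:
            raise ValueError(
                "only 2x2 max-pooling with stride 1 is supported"
            )


def layer_output_shapes(n_d: int, n_t: int, cfg: ModelConfig | None = None):
    """Per-layer spatial shapes and the flatten length, by valid-conv/pool
    arithmetic.  Raises with the minimum size if the input is too small."""
    cfg = cfg or ModelConfig()
    h, w = n_d, n_t
    shapes = [("input", (1, h, w))]
    for (f, (kh, kw)) in zip(cfg.conv_filters, cfg.conv_kernels):
        h, w = h - kh + 1, w - kw + 1
        if h <= 0 or w <= 0:
            raise ValueError(_too_small_msg(n_d, n_t, cfg))
        shapes.append((f"conv{f}", (f, h, w)))
        h, w = h - 1, w - 1
        if h <= 0 or w <= 0:
            raise ValueError(_too_small_msg(n_d, n_t, cfg))
        shapes.append(("pool", (f, h, w)))
    flat = cfg.conv_filters[-1] * h * w
    shapes.append(("flatten", (flat,)))
    shapes.append(("dense", (cfg.fc_width,)))
    shapes.append(("output", (1,)))
    return shapes


def min_input_size(cfg: ModelConfig | None = None) -> int:
    """Smallest spatial extent that survives all convolutions and poolings."""
    cfg = cfg or ModelConfig()
    # each conv removes k-1, each 2x2/stride-1 pool removes 1; need >= 1 left
    return 1 + sum(k[0] - 1 + 1 for k in cfg.conv_kernels)


def _too_small_msg(n_d, n_t, cfg):
    m = min_input_size(cfg)
    return (
        f"input {n_d} x {n_t} too small for the receptive field; both "
        f"dimensions must be at least {m}"
    )


class SimCNNRegressor(BaseEstimator, RegressorMixin):
    """2D CNN regressor over similarity outer-product grids.

    Parameters mirror :class:`ModelConfig`.  ``fit`` expects ``X`` of shape
    (n_samples, n_d, n_t) — one outer-product grid per drug–target pair —
    and continuous affinities ``y``.

    Attributes (after fit)
    ----------------------
    layers_ : list
        The layer stack holding the fitted weights.
    input_shape_ : tuple
        (n_d, n_t) the network was built for.
    loss_history_ : list of float
        Mean training MSE per epoch.
    """

    def __init__(self, conv_filters=(32, 18), conv_kernels=((5, 5), (3, 3)),
                 pool_size=2, pool_stride=1, dropout_rate=0.1, fc_width=128,
                 learning_rate=0.001, batch_size=32, epochs=20, seed=0):
        self.conv_filters = conv_filters
        self.conv_kernels = conv_kernels
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.dropout_rate = dropout_rate
        self.fc_width = fc_width
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _config(self) -> ModelConfig:
        return ModelConfig(
            conv_filters=self.conv_filters, conv_kernels=self.conv_kernels,
            pool_size=self.pool_size, pool_stride=self.pool_stride,
            dropout_rate=self.dropout_rate, fc_width=self.fc_width,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.seed,
        )

    def _build_layers(self, n_d, n_t, cfg, rng):
        layer_output_shapes(n_d, n_t, cfg)  # validates size
        layers = []
        in_ch = 1
        h, w = n_d, n_t
        for f, kern in zip(cfg.conv_filters, cfg.conv_kernels):
            conv = nn.Conv2D(in_ch, f, kern, rng)
            layers.append(conv)
            h, w = conv.out_shape(h, w)
            pool = nn.MaxPool2x2()
            layers.append(pool)
            h, w = pool.out_shape(h, w)
            in_ch = f
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(cfg.dropout_rate, rng))
        layers.append(nn.Dense(in_ch * h * w, cfg.fc_width, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dense(cfg.fc_width, 1, rng))
        return layers

    def _forward(self, x, train):
        for layer in self.layers_:
            x = layer.forward(x, train=train)
        return x

    def _backward(self, dout):
        for layer in reversed(self.layers_):
            dout = layer.backward(dout)

    @staticmethod
    def _validate_X(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must have shape (n_samples, n_d, n_t); got {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("need at least one training example")
        cfg = self._config()
        n_d, n_t = X.shape[1], X.shape[2]
        rng = np.random.default_rng(cfg.seed)
        self.layers_ = self._build_layers(n_d, n_t, cfg, rng)
        # start the regression head at the target mean so optimization spends
        # its steps on structure rather than on the affinity offset
        self.layers_[-1].b[...] = y.mean()
        self.input_shape_ = (n_d, n_t)
        self.loss_history_ = []
        params = [p for layer in self.layers_ for p in layer.params]
        opt = nn.Adam(params, lr=cfg.learning_rate)
        n = len(X)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_sse = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = X[idx][:, None, :, :]
                yb = y[idx]
                pred = self._forward(xb, train=True).ravel()
                resid = pred - yb
                epoch_sse += float((resid ** 2).sum())
                dpred = (2.0 / len(idx)) * resid
                self._backward(dpred[:, None])
                opt.step([g for layer in self.layers_ for g in layer.grads])
            self.loss_history_.append(epoch_sse / n)
        return self

    def predict(self, X, batch_size: int = 256):
        check_is_fitted(self, "layers_")
        X = self._validate_X(X)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"grid shape {X.shape[1:]} does not match the fitted "
                f"input shape {self.input_shape_}"
            )
        out = np.empty(len(X))
        for start in range(0, len(X), batch_size):
            xb = X[start:start + batch_size][:, None, :, :]
            out[start:start + batch_size] = self._forward(xb, train=False).ravel()
        return out

    # --- weight persistence helpers -----------------------------------
    def get_weights(self) -> dict:
        check_is_fitted(self, "layers_")
        weights = {}
        for li, layer in enumerate(self.layers_):
            for pi, p in enumerate(layer.params):
                weights[f"layer{li}_p{pi}"] = p.copy()
        return weights

    def set_weights(self, weights: dict) -> None:
        check_is_fitted(self, "layers_")
        for li, layer in enumerate(self.layers_):
            for pi, p in enumerate(layer.params):
                key = f"layer{li}_p{pi}"
                if key not in weights or weights[key].shape != p.shape:
                    raise ValueError(f"weight blob missing or mismatched at {key}")
                p[...] = weights[key]


@dataclass(frozen=True)
class TrainedModel:
    """A fitted regressor plus the rosters its inputs are defined against."""

    estimator: SimCNNRegressor
    drug_roster_ids: tuple
    target_roster_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "drug_roster_ids", tuple(self.drug_roster_ids))
        object.__setattr__(self, "target_roster_ids", tuple(self.target_roster_ids))
        shape = (len(self.drug_roster_ids), len(self.target_roster_ids))
        if self.estimator.input_shape_ != shape:
            raise ValueError("roster lengths do not match the fitted input shape")

    @property
    def config(self) -> ModelConfig:
        return self.estimator._config()

    @property
    def input_shape(self) -> tuple:
        return self.estimator.input_shape_


def build_model(n_d: int, n_t: int, cfg: ModelConfig | None = None) -> SimCNNRegressor:
    """Construct (and size-validate) an untrained estimator for an
    n_d x n_t input grid."""
    cfg = cfg or ModelConfig()
    layer_output_shapes(n_d, n_t, cfg)
    return SimCNNRegressor(**asdict(cfg))


def train(
    examples: list[tuple[PairInput, float]], cfg: ModelConfig | None = None
) -> TrainedModel:
    """Fit the CNN on (grid, affinity) examples."""
    cfg = cfg or ModelConfig()
    if not examples:
        raise ValueError("need at least one training example")
    first = examples[0][0]
    for pair, _ in examples:
        if pair.grid.shape != first.grid.shape:
            raise ValueError("all example grids must share one shape")
    X = np.stack([pair.grid for pair, _ in examples])
    y = np.array([aff for _, aff in examples])
    est = SimCNNRegressor(**asdict(cfg)).fit(X, y)
    return TrainedModel(est, first.drug_roster_ids, first.target_roster_ids)


def predict(model: TrainedModel, pairs: list[PairInput]) -> np.ndarray:
    """Affinity predictions, one per pair, in input order."""
    if not pairs:
        return np.empty(0)
    X = np.stack([p.grid for p in pairs])
    return model.estimator.predict(X)


def rank_candidates(
    model: TrainedModel,
    candidate_drugs: list[Drug],
    target: Target,
    scoring=None,
    n_bits: int = 2048,
) -> list[tuple[str, float, int]]:
    """Rank candidate compounds against one target by predicted affinity.

    Each candidate's similarity vector is computed against the model's
    training drug roster, the target's against the training target roster;
    the outer-product grids are scored and sorted descending (rank 1 =
    strongest predicted binding).  Ties keep input order; candidates whose
    SMILES fail to parse are skipped with a warning.
    """
    if not candidate_drugs:
        raise ValueError("need at least one candidate drug")
    roster_drugs = _roster_drugs(model)
    tv = similarity_vector_for_target(target, _roster_targets(model), scoring)
    kept_ids, grids = [], []
    for d in candidate_drugs:
        try:
            dv = similarity_vector_for_drug(d, roster_drugs, n_bits=n_bits)
        except ValueError as exc:
            warnings.warn(f"skipping candidate {d.drug_id!r}: {exc}", stacklevel=2)
            continue
        kept_ids.append(d.drug_id)
        grids.append(outer_product(dv, tv).grid)
    if not grids:
        raise ValueError("no candidate produced a valid similarity vector")
    preds = model.estimator.predict(np.stack(grids))
    order = np.argsort(-preds, kind="stable")
    return [
        (kept_ids[i], float(preds[i]), rank)
        for rank, i in enumerate(order, start=1)
    ]


def save_model(model: TrainedModel, path) -> None:
    """Persist as a directory: plain-text manifest + weights blob."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "config": asdict(model.config),
        "drug_roster_ids": list(model.drug_roster_ids),
        "target_roster_ids": list(model.target_roster_ids),
        "input_shape": list(model.input_shape),
        "drug_roster_smiles": list(getattr(model, "_drug_smiles", []) or []),
        "target_roster_sequences": list(getattr(model, "_target_sequences", []) or []),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    np.savez(out / "weights.npz", **model.estimator.get_weights())


def load_model(path) -> TrainedModel:
    p = Path(path)
    manifest_path = p / "manifest.json"
    weights_path = p / "weights.npz"
    if not manifest_path.exists() or not weights_path.exists():
        raise FileNotFoundError(f"{path}: not a saved model directory")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version "
            f"{manifest.get('format_version')!r}"
        )
    cfg = ModelConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["config"].items()
    })
    est = SimCNNRegressor(**asdict(cfg))
    n_d = len(manifest["drug_roster_ids"])
    n_t = len(manifest["target_roster_ids"])
    rng = np.random.default_rng(cfg.seed)
    est.layers_ = est._build_layers(n_d, n_t, cfg, rng)
    est.input_shape_ = (n_d, n_t)
    est.loss_history_ = []
    with np.load(weights_path) as blob:
        est.set_weights({k: blob[k] for k in blob.files})
    model = TrainedModel(
        est, tuple(manifest["drug_roster_ids"]), tuple(manifest["target_roster_ids"])
    )
    smiles = manifest.get("drug_roster_smiles") or []
    seqs = manifest.get("target_roster_sequences") or []
    if smiles:
        object.__setattr__(model, "_drug_smiles", tuple(smiles))
    if seqs:
        object.__setattr__(model, "_target_sequences", tuple(seqs))
    return model


def attach_rosters(model: TrainedModel, drugs: list[Drug], targets: list[Target]):
    """Attach the roster entities (SMILES, sequences) needed to embed
    *unseen* candidates; required before :func:`rank_candidates` on a model
    whose manifest lacks them."""
    if tuple(d.drug_id for d in drugs) != model.drug_roster_ids:
        raise ValueError("drug roster mismatch")
    if tuple(t.target_id for t in targets) != model.target_roster_ids:
        raise ValueError("target roster mismatch")
    object.__setattr__(model, "_drug_smiles", tuple(d.smiles for d in drugs))
    object.__setattr__(model, "_target_sequences", tuple(t.sequence for t in targets))
    return model


def _roster_drugs(model: TrainedModel) -> list[Drug]:
    smiles = getattr(model, "_drug_smiles", None)
    if not smiles:
        raise ValueError(
            "model has no drug roster SMILES attached; call attach_rosters"
        )
    return [Drug(i, s) for i, s in zip(model.drug_roster_ids, smiles)]


def _roster_targets(model: TrainedModel) -> list[Target]:
    seqs = getattr(model, "_target_sequences", None)
    if not seqs:
        raise ValueError(
            "model has no target roster sequences attached; call attach_rosters"
        )
    return [Target(i, s) for i, s in zip(model.target_roster_ids, seqs)]
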