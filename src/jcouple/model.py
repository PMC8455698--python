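"""Scikit-learn style estimator wrapping the angle-attention network.

:class:`ScalarCouplingRegressor` follows the sklearn contract — constructor
stores hyperparameters untouched, :meth:`fit` learns and sets trailing-
underscore attributes, :meth:`predict` maps a dataset's coupling records to
SCCs in Hz.  One model serves all eight coupling types; the type enters via
the coupling-edge one-hot.  Validation is split by molecule, never by
record, so coupling pairs of one molecule cannot leak across the split.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import features as F
from . import nn
from .autodiff import Tensor
from .io import COUPLING_TYPES, Dataset
from .metrics import MetricReport, grouped_log_mae


class _Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: dict[str, Tensor], clip_norm: float = 5.0):
        self.params = params
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0
        self.clip_norm = clip_norm
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, lr: float) -> None:
        self.t += 1
        grads = {
            k: (p.grad if p.grad is not None else np.zeros_like(p.data))
            for k, p in self.params.items()
        }
        gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, self.clip_norm / (gnorm + 1e-12))
        for k, p in self.params.items():
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def one_cycle_lr(step: int, total_steps: int, max_lr: float, warmup_frac: float) -> float:
    """One-cycle schedule: linear warm-up, cosine anneal to ~0."""
    warm = max(1, int(warmup_frac * total_steps))
    if step < warm:
        return max_lr * (0.04 + 0.96 * step / warm)
    frac = (step - warm) / max(1, total_steps - warm)
    return max_lr * (1e-4 + (1 - 1e-4) * 0.5 * (1 + np.cos(np.pi * frac)))


class ScalarCouplingRegressor(BaseEstimator, RegressorMixin):
    """Graph network with bond-angle attention for SCC regression.

    Parameters
    ----------
    d_model : hidden node-state width (even, divisible by ``n_heads``).
    n_heads : self-attention heads.
    n_passes : T, number of (bond MP, coupling MP) iterations.
    hidden_sizes : decoder MLP hidden widths.
    use_angle_attention / use_angle_features : the two ablation toggles
        (Karplus-form bond attention; angle cosines in the coupling block).
    attention_scale : ``"d_model"`` or ``"d_head"`` softmax scaling.
    loss : ``"grouped_log_mae"`` (default) or ``"mae"``.
    epochs, batch_size, max_lr, warmup_frac : one-cycle Adam training.
    validation_fraction : molecule-level fraction held out during fit to
        select the best epoch (set 0 to disable and keep the last epoch).
    bond_scale : covalent-radius multiplier for bond perception.
    random_state : seed for initialisation, splitting and batching.

    Attributes (after fit)
    ----------------------
    params_ : dict of trained tensors.
    history_ : per-epoch DataFrame (train loss, validation score, lr).
    best_epoch_, n_epochs_ : epoch bookkeeping.
    feature_stats_ : normalisation statistics (training set).
    layout_hash_ : feature-layout fingerprint checked on load.
    attention_coeffs_ : fitted (A', B', C').
    """

    def __init__(
        self,
        d_model: int = 128,
        n_heads: int = 8,
        n_passes: int = 2,
        hidden_sizes: tuple[int, ...] = (256, 128),
        use_angle_attention: bool = True,
        use_angle_features: bool = True,
        attention_scale: str = "d_model",
        loss: str = "grouped_log_mae",
        log_mae_floor: float = 1e-9,
        epochs: int = 144,
        batch_size: int = 16,
        max_lr: float = 3e-3,
        warmup_frac: float = 0.3,
        validation_fraction: float = 0.2,
        normalize: bool = True,
        standardize_targets: bool = True,
        bond_scale: float = 1.3,
        dtype: str = "float64",
        warm_start: bool = False,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_passes = n_passes
        self.hidden_sizes = hidden_sizes
        self.use_angle_attention = use_angle_attention
        self.use_angle_features = use_angle_features
        self.attention_scale = attention_scale
        self.loss = loss
        self.log_mae_floor = log_mae_floor
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.warmup_frac = warmup_frac
        self.validation_fraction = validation_fraction
        self.normalize = normalize
        self.standardize_targets = standardize_targets
        self.bond_scale = bond_scale
        self.dtype = dtype
        self.warm_start = warm_start
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _model_config(self) -> nn.ModelConfig:
        return nn.ModelConfig(
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_passes=self.n_passes,
            hidden_sizes=tuple(self.hidden_sizes),
            attention_scale=self.attention_scale,
            use_angle_attention=self.use_angle_attention,
            use_angle_features=self.use_angle_features,
            log_mae_floor=self.log_mae_floor,
        )

    def _feature_config(self) -> F.FeatureConfig:
        return F.FeatureConfig(
            normalize=self.normalize,
            use_angle_features=self.use_angle_features,
            bond_scale=self.bond_scale,
        )

    def _featurize(self, dataset: Dataset, fit_stats: bool) -> list[F.MolFeatures]:
        mols = F.featurize(dataset, self._feature_config())
        mols = [m for m in mols if len(m.rec_type)]
        if self.normalize:
            if fit_stats:
                self.feature_stats_ = F.FeatureStats.fit(mols)
            self.feature_stats_.apply(mols)
        return mols

    def _np_dtype(self):
        return np.dtype(self.dtype)

    def _collate(self, mols) -> F.Batch:
        batch = F.collate(mols)
        dt = self._np_dtype()
        if dt != np.float64:
            for name in ("atom_x", "bond_x", "cpl_x", "mol_x", "angle_cos", "y"):
                v = getattr(batch, name)
                if v is not None:
                    setattr(batch, name, v.astype(dt))
        return batch

    def _loss(self, pred: Tensor, batch: F.Batch) -> Tensor:
        mu, sd = self.target_stats_
        y_std = (batch.y - mu) / sd
        if self.loss == "mae":
            return nn.loss_mae(pred, y_std)
        if self.loss == "grouped_log_mae":
            return nn.loss_grouped_log_mae(
                pred, y_std, batch.rec_type, floor=self.log_mae_floor
            )
        raise ValueError(f"unknown loss {self.loss!r}")

    # ------------------------------------------------------------------
    def fit(self, dataset: Dataset, y=None) -> "ScalarCouplingRegressor":
        """Train on a labelled :class:`Dataset` (labels live in the records)."""
        if not dataset.records:
            raise ValueError("empty training set")
        if any(r.scc is None for r in dataset.records):
            raise ValueError("fit requires labelled records")
        rng = np.random.default_rng(self.random_state)
        config = self._model_config()
        mols = self._featurize(dataset, fit_stats=True)
        if not mols:
            raise ValueError("no molecules with records to train on")
        manifest = F.layout_manifest()
        self.layout_hash_ = manifest["hash"]

        order = rng.permutation(len(mols))
        n_val = int(round(self.validation_fraction * len(mols)))
        val_mols = [mols[i] for i in order[:n_val]]
        train_mols = [mols[i] for i in order[n_val:]]
        if not train_mols:
            raise ValueError("validation fraction leaves no training molecules")
        val_batch = self._collate(val_mols) if val_mols else None

        widths = manifest["widths"]
        ys = np.array([r.scc for r in dataset.records], dtype=float)
        # train on z-scored labels by default: Adam's per-step update is
        # bounded by the learning rate, so raw Hz targets spanning ~200 Hz
        # would need tens of thousands of steps just to move the output bias
        if self.standardize_targets:
            self.target_stats_ = (float(ys.mean()), float(ys.std() or 1.0))
        else:
            self.target_stats_ = (0.0, 1.0)
        if self.warm_start and hasattr(self, "params_"):
            pass  # continue from the existing parameters
        else:
            self.params_ = nn.init_params(
            rng,
            widths["atom"],
            widths["bond"],
            widths["coupling"],
            widths["molecule"],
                config,
            )
        dt = self._np_dtype()
        if dt != np.float64:
            for p in self.params_.values():
                p.data = p.data.astype(dt)
        opt = _Adam(self.params_)
        n_batches = max(1, int(np.ceil(len(train_mols) / self.batch_size)))
        total_steps = self.epochs * n_batches
        history = []
        best_score = np.inf
        best_params = None
        step = 0
        for epoch in range(self.epochs):
            perm = rng.permutation(len(train_mols))
            epoch_losses = []
            for b in range(n_batches):
                idx = perm[b * self.batch_size : (b + 1) * self.batch_size]
                if len(idx) == 0:
                    continue
                batch = self._collate([train_mols[i] for i in idx])
                opt.zero_grad()
                pred = nn.forward(batch, self.params_, config)
                loss = self._loss(pred, batch)
                loss.backward()
                lr = one_cycle_lr(step, total_steps, self.max_lr, self.warmup_frac)
                opt.step(lr)
                step += 1
                epoch_losses.append(loss.item())
            row = {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "lr": one_cycle_lr(step - 1, total_steps, self.max_lr, self.warmup_frac),
            }
            if val_batch is not None:
                report = self._evaluate_batch(val_batch, config)
                row["val_score"] = report.score
                row["val_mae"] = float(np.mean(list(report.per_type_mae.values())))
                if report.score < best_score:
                    best_score = report.score
                    best_params = {k: p.data.copy() for k, p in self.params_.items()}
            history.append(row)
            if self.verbose:
                print(f"[epoch {epoch:3d}] " + " ".join(f"{k}={v:.4g}" for k, v in row.items() if k != "epoch"))
        if best_params is not None:
            for k, p in self.params_.items():
                p.data = best_params[k]
            self.best_epoch_ = int(
                min(range(len(history)), key=lambda i: history[i].get("val_score", np.inf))
            )
        else:
            self.best_epoch_ = self.epochs - 1
        self.n_epochs_ = self.epochs
        self.history_ = pd.DataFrame(history)
        self.attention_coeffs_ = tuple(self.params_["attn_coeffs"].data.tolist())
        return self

    # ------------------------------------------------------------------
    def _evaluate_batch(self, batch: F.Batch, config: nn.ModelConfig) -> MetricReport:
        mu, sd = self.target_stats_
        pred = nn.forward(batch, self.params_, config).data * sd + mu
        types = np.array([COUPLING_TYPES[t] for t in batch.rec_type])
        return grouped_log_mae(batch.y, pred, types, floor=self.log_mae_floor)

    def _predict_batch(self, dataset: Dataset) -> tuple[F.Batch, np.ndarray]:
        self._check_fitted()
        mols = self._featurize(dataset, fit_stats=False)
        batch = self._collate(mols)
        mu, sd = self.target_stats_
        pred = nn.forward(batch, self.params_, self._model_config()).data * sd + mu
        return batch, pred

    def predict(self, dataset: Dataset) -> np.ndarray:
        """Predicted SCC (Hz) for every record, in dataset record order."""
        batch, pred = self._predict_batch(dataset)
        out = np.empty(len(dataset.records))
        out[batch.rec_pos] = pred
        return out

    def evaluate(self, dataset: Dataset) -> MetricReport:
        """Per-type MAE and grouped log(MAE) against the dataset's labels."""
        batch, pred = self._predict_batch(dataset)
        types = np.array([COUPLING_TYPES[t] for t in batch.rec_type])
        return grouped_log_mae(batch.y, pred, types, floor=self.log_mae_floor)

    def transform(self, dataset: Dataset) -> np.ndarray:
        """Per-record embedding f_atom0 ⊕ f_atom1 ⊕ f_mol (for e.g. PCA)."""
        self._check_fitted()
        mols = self._featurize(dataset, fit_stats=False)
        batch = self._collate(mols)
        _, aux = nn.forward(
            batch, self.params_, self._model_config(), return_embeddings=True
        )
        emb = aux["record_embedding"].data
        out = np.empty((len(dataset.records), emb.shape[1]))
        out[batch.rec_pos] = emb
        return out

    def score(self, dataset: Dataset, y=None) -> float:
        """Negative grouped log(MAE) (higher is better, sklearn convention)."""
        return -self.evaluate(dataset).score

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a self-describing checkpoint (.npz + embedded JSON)."""
        self._check_fitted()
        meta = {
            "config": self.get_params(),
            "layout_hash": self.layout_hash_,
            "feature_stats": self.feature_stats_.to_dict()
            if self.normalize
            else None,
            "target_stats": list(self.target_stats_),
            "best_epoch": self.best_epoch_,
        }
        arrays = {f"param_{k}": p.data for k, p in self.params_.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ScalarCouplingRegressor":
        """Load a checkpoint; verifies the feature-layout hash."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]))
            params = {
                k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
            }
        config = meta["config"]
        config["hidden_sizes"] = tuple(config["hidden_sizes"])
        est = cls(**config)
        current = F.layout_manifest()["hash"]
        if meta["layout_hash"] != current:
            raise ValueError(
                "checkpoint feature layout does not match this version "
                f"({meta['layout_hash']} != {current})"
            )
        est.layout_hash_ = meta["layout_hash"]
        est.params_ = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
        if meta["feature_stats"] is not None:
            est.feature_stats_ = F.FeatureStats.from_dict(meta["feature_stats"])
        est.target_stats_ = tuple(meta["target_stats"])
        est.best_epoch_ = meta["best_epoch"]
        est.history_ = pd.DataFrame()
        est.attention_coeffs_ = tuple(est.params_["attn_coeffs"].data.tolist())
        return est


def constant_mean_baseline(train: Dataset, test: Dataset) -> np.ndarray:
    """Per-type constant-mean predictor: the natural no-structure baseline."""
    means: dict[str, float] = {}
    vals: dict[str, list[float]] = {}
    for r in train.records:
        vals.setdefault(r.ctype, []).append(float(r.scc))
    for t, v in vals.items():
        means[t] = float(np.mean(v))
    overall = float(np.mean([float(r.scc) for r in train.records]))
    return np.array([means.get(r.ctype, overall) for r in test.records])


def train(dataset: Dataset, **params) -> ScalarCouplingRegressor:
    """Functional wrapper: fit a :class:`ScalarCouplingRegressor` on a dataset."""
    return ScalarCouplingRegressor(**params).fit(dataset)
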