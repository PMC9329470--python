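"""Multi-task silhouette regressor under nested cross-validation.

The cohort is split into ``k_outer`` non-overlapping partitions. Outer model
``m`` trains on partitions ``{m, ..., m+k-3}`` (three of five by default),
uses partition ``m+k-2`` for model selection and collects unbiased predictions
on partition ``m+k-1``; rotating ``m`` tiles the validation partitions over
the whole cohort, so every participant receives exactly one out-of-fold
prediction. Within each outer training split an inner cross-validation trains
``inner_k`` nets whose mean-ensemble is the fold's predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._net import Adam, MultiTaskNet, NetSpec, OptimizerConfig, train_net

__all__ = [
    "TARGET_COLUMNS",
    "FoldAssignment",
    "InnerEnsemble",
    "CVConfig",
    "assign_folds",
    "train_fold",
    "ensemble_predict",
    "run_nested_cv",
    "audit_leakage",
    "NetSpec",
    "OptimizerConfig",
]

#: regression targets, in head order
TARGET_COLUMNS = ("vat_l", "asat_l", "gfat_l", "ratio")


@dataclass(frozen=True)
class FoldAssignment:
    """Rotation-scheme nested-CV partitioning."""

    ids: tuple
    partition: np.ndarray  # participant index -> outer partition in {0..k-1}
    k_outer: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.partition, minlength=self.k_outer)
        if counts.max() - counts.min() > 1:
            raise ValueError("partition sizes must differ by at most 1")

    def partition_of(self, pid) -> int:
        return int(self.partition[self.ids.index(pid)])

    def train_partitions(self, m: int) -> tuple:
        return tuple((m + j) % self.k_outer for j in range(self.k_outer - 2))

    def test_partition(self, m: int) -> int:
        return (m + self.k_outer - 2) % self.k_outer

    def validation_partition(self, m: int) -> int:
        return (m + self.k_outer - 1) % self.k_outer

    def indices_in(self, partitions) -> np.ndarray:
        if np.isscalar(partitions):
            partitions = (partitions,)
        return np.flatnonzero(np.isin(self.partition, list(partitions)))


def assign_folds(ids, k_outer: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic shuffled split of ids into ``k_outer`` near-equal partitions."""
    ids = list(ids)
    if k_outer < 2:
        raise ValueError("k_outer must be >= 2")
    if k_outer < 3:
        raise ValueError("the rotation scheme needs k_outer >= 3 "
                         "(train k-2, test 1, validation 1)")
    if len(ids) < k_outer:
        raise ValueError("need at least k_outer participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    partition = np.empty(len(ids), dtype=np.int64)
    for p, chunk in enumerate(np.array_split(order, k_outer)):
        partition[chunk] = p
    return FoldAssignment(ids=tuple(ids), partition=partition, k_outer=k_outer)


@dataclass
class InnerEnsemble:
    """Inner-CV models of one outer fold plus the train-split target scaling."""

    models: list
    target_mean: np.ndarray
    target_sd: np.ndarray

    def __post_init__(self) -> None:
        if len(self.models) == 0:
            raise ValueError("empty model list")


def train_fold(X_train, y_train, spec: NetSpec | None = None,
               opt: OptimizerConfig | None = None, inner_k: int = 3,
               seed: int = 0, in_shape=(237, 256)) -> InnerEnsemble:
    """Inner cross-validation on one outer training split.

    Targets are standardized per task using train-split statistics only; each
    of the ``inner_k`` nets trains on ``inner_k - 1`` inner folds with early
    stopping on its held-out inner fold.
    """
    if inner_k < 2:
        raise ValueError("inner_k must be >= 2")
    spec = spec or NetSpec()
    opt = opt or OptimizerConfig()
    y = np.asarray(y_train, dtype=np.float64)
    mean = y.mean(axis=0)
    sd = y.std(axis=0)
    sd[sd == 0] = 1.0
    yz = ((y - mean) / sd).astype(np.float32)

    rng = np.random.default_rng(seed)
    order = rng.permutation(y.shape[0])
    inner_folds = np.array_split(order, inner_k)
    models = []
    for j in range(inner_k):
        val_idx = inner_folds[j]
        tr_idx = np.concatenate([inner_folds[i] for i in range(inner_k) if i != j])
        net, _ = train_net(X_train[tr_idx], yz[tr_idx], X_train[val_idx], yz[val_idx],
                           spec, opt, seed=seed + 1000 * (j + 1), in_shape=in_shape)
        models.append(net)
    return InnerEnsemble(models=models, target_mean=mean, target_sd=sd)


def ensemble_predict(ensemble: InnerEnsemble, X) -> np.ndarray:
    """Mean-ensemble of the inner models, de-standardized to physical units."""
    if len(ensemble.models) == 0:
        raise ValueError("empty model list")
    preds = np.mean([m.predict(X) for m in ensemble.models], axis=0)
    return preds * ensemble.target_sd + ensemble.target_mean


@dataclass(frozen=True)
class CVConfig:
    k_outer: int = 5
    inner_k: int = 3
    net: NetSpec = field(default_factory=NetSpec)
    opt: OptimizerConfig = field(default_factory=OptimizerConfig)
    derive_ratio: bool = False  # predict ratio as VAT_hat / ASAT_hat instead of its own head
    seed: int = 0


def run_nested_cv(silhouettes: np.ndarray, targets: pd.DataFrame,
                  config: CVConfig | None = None,
                  folds: FoldAssignment | None = None):
    """Full nested cross-validation producing one out-of-fold prediction per id.

    ``silhouettes``: array (n, 237, 256) aligned with ``targets`` rows;
    ``targets``: DataFrame with an ``id`` column and the four target columns.
    Returns ``(prediction_table, folds, ensembles)``; the prediction table has
    fold provenance columns for leakage auditing.
    """
    config = config or CVConfig()
    ids = list(targets["id"])
    missing = [pid for pid, ok in zip(ids, np.arange(len(ids)) < silhouettes.shape[0])
               if not ok]
    if silhouettes.shape[0] != len(ids):
        raise ValueError(f"missing silhouettes for {len(ids) - silhouettes.shape[0]} "
                         f"participants (e.g. {missing[:5]})")
    y = targets.loc[:, list(TARGET_COLUMNS)].to_numpy(dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("non-finite targets")
    folds = folds or assign_folds(ids, k_outer=config.k_outer, seed=config.seed)
    X = np.asarray(silhouettes, dtype=np.float32)
    in_shape = X.shape[1:]

    n = len(ids)
    pred = np.full((n, len(TARGET_COLUMNS)), np.nan)
    outer_model = np.full(n, -1, dtype=int)
    ensembles = []
    for m in range(config.k_outer):
        tr = folds.indices_in(folds.train_partitions(m))
        val = folds.indices_in(folds.validation_partition(m))
        ens = train_fold(X[tr], y[tr], spec=config.net, opt=config.opt,
                         inner_k=config.inner_k, seed=config.seed + 77 * (m + 1),
                         in_shape=in_shape)
        p = ensemble_predict(ens, X[val])
        if config.derive_ratio:
            ratio_col = TARGET_COLUMNS.index("ratio")
            vat_col = TARGET_COLUMNS.index("vat_l")
            asat_col = TARGET_COLUMNS.index("asat_l")
            p[:, ratio_col] = p[:, vat_col] / np.maximum(p[:, asat_col], 1e-6)
        pred[val] = p
        outer_model[val] = m
        ensembles.append(ens)

    table = pd.DataFrame({"id": ids})
    for j, col in enumerate(TARGET_COLUMNS):
        table[f"{col}_pred"] = pred[:, j]
    table["outer_partition"] = folds.partition
    table["outer_model"] = outer_model
    table["train_partitions"] = [
        ",".join(map(str, folds.train_partitions(m))) for m in outer_model]
    table["inner_k"] = config.inner_k
    if table.filter(like="_pred").isna().any().any():
        raise RuntimeError("validation partitions failed to tile the cohort")
    return table, folds, ensembles


def audit_leakage(prediction_table: pd.DataFrame, folds: FoldAssignment) -> bool:
    """True iff no participant was predicted by a model trained on them."""
    for _, row in prediction_table.iterrows():
        trained_on = {int(p) for p in str(row["train_partitions"]).split(",")}
        own = folds.partition_of(row["id"])
        if own in trained_on:
            return False
        if folds.validation_partition(int(row["outer_model"])) != own:
            return False
    return True
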