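"""Sex-stratified linear comparator models and R²/MAE benchmarking.

Named comparators mirror the standard anthropometric baselines:

- ``BMI``:        age + BMI
- ``Waist``:      age + waist circumference
- ``WHR``:        age + waist-to-hip ratio
- ``Anthro``:     age + weight + height + BMI + waist + hip + WHR + 5 impedances
- ``Silhouette``: age + the silhouette-CNN prediction of the target
- ``custom``:     any user-supplied covariate list

All comparators are ordinary least squares fit per sex stratum on the nested-CV
training partitions and evaluated on the validation partitions, so their
out-of-fold discipline matches the silhouette model exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .predictor import FoldAssignment

__all__ = [
    "NAMED_COMPARATORS",
    "ComparatorSpec",
    "ModelMetrics",
    "fit_comparator",
    "r2_mae",
    "bootstrap_ci",
    "compare_models",
    "evaluate_models",
]

_ANTHRO = ["age_years", "weight_kg", "height_cm", "bmi", "waist_cm", "hip_cm", "whr",
           "impedance_1", "impedance_2", "impedance_3", "impedance_4", "impedance_5"]

NAMED_COMPARATORS = {
    "BMI": ["age_years", "bmi"],
    "Waist": ["age_years", "waist_cm"],
    "WHR": ["age_years", "whr"],
    "Anthro": _ANTHRO,
}


@dataclass(frozen=True)
class ComparatorSpec:
    """A named or custom linear comparator."""

    name: str
    covariates: tuple = ()
    prediction_column: str | None = None  # for the Silhouette comparator

    def resolve(self, target: str) -> list:
        if self.name in NAMED_COMPARATORS:
            return list(NAMED_COMPARATORS[self.name])
        if self.name == "Silhouette":
            col = self.prediction_column or f"{target}_pred"
            return ["age_years", col]
        if self.name == "custom":
            if not self.covariates:
                raise ValueError("custom spec needs covariates")
            return list(self.covariates)
        raise ValueError(f"unknown comparator {self.name!r}")


@dataclass(frozen=True)
class ModelMetrics:
    r2: float
    mae: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int


def _check_design(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by greedy QR elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_comparator(cohort: pd.DataFrame, spec: ComparatorSpec, target: str,
                   folds: FoldAssignment) -> pd.Series:
    """Out-of-fold OLS predictions of ``target`` for every participant.

    Models are fit separately within each sex stratum on the outer training
    partitions of each fold rotation and applied to the validation partition.
    """
    if list(cohort["id"]) != list(folds.ids):
        raise ValueError("cohort ids do not match the fold assignment")
    covs = spec.resolve(target)
    missing = [c for c in covs + [target] if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if cohort[covs].isna().any().any():
        raise ValueError("covariates contain missing values")
    pred = pd.Series(np.nan, index=cohort.index, name=f"{target}_{spec.name}")
    part = pd.Series(folds.partition, index=cohort.index)
    for sex in cohort["sex"].unique():
        in_sex = cohort["sex"] == sex
        for m in range(folds.k_outer):
            tr = in_sex & part.isin(folds.train_partitions(m))
            va = in_sex & (part == folds.validation_partition(m))
            Xtr = np.column_stack([np.ones(tr.sum()), cohort.loc[tr, covs].to_numpy(float)])
            _check_design(Xtr, ["intercept"] + covs)
            beta, *_ = np.linalg.lstsq(Xtr, cohort.loc[tr, target].to_numpy(float), rcond=None)
            Xva = np.column_stack([np.ones(va.sum()), cohort.loc[va, covs].to_numpy(float)])
            pred.loc[va] = Xva @ beta
    return pred


def r2_mae(y, y_hat) -> tuple:
    """Coefficient of determination (1 - SSres/SStot) and mean absolute error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if not (np.isfinite(y).all() and np.isfinite(y_hat).all()):
        raise ValueError("non-finite values")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero variance in y")
    r2 = 1.0 - np.sum((y - y_hat) ** 2) / ss_tot
    mae = float(np.mean(np.abs(y - y_hat)))
    return float(r2), mae


def _boot_r2(y, y_hat, B, seed):
    """Vectorized bootstrap distribution of R² over paired resamples."""
    rng = np.random.default_rng(seed)
    n = y.size
    idx = rng.integers(0, n, size=(B, n))
    yb = y[idx]
    pb = y_hat[idx]
    mb = yb.mean(axis=1, keepdims=True)
    ss_tot = np.sum((yb - mb) ** 2, axis=1)
    ss_res = np.sum((yb - pb) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)


def bootstrap_ci(y, y_hat, B: int = 1000, seed: int = 0) -> tuple:
    """Percentile 95% bootstrap confidence interval for R²."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 10:
        raise ValueError("need n >= 10 for a bootstrap interval")
    if B < 100:
        warnings.warn(f"B={B} resamples is too few for stable percentiles", stacklevel=2)
    r2s = _boot_r2(y, y_hat, B, seed)
    lo, hi = np.nanpercentile(r2s, [2.5, 97.5])
    return float(lo), float(hi)


def compare_models(y, y_hat_a, y_hat_b, B: int = 1000, seed: int = 0) -> dict:
    """ΔR² (model a minus model b) with a paired-bootstrap 95% CI.

    The same resample indices are used for both models, so the interval
    reflects the paired difference, not two independent uncertainties.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(y_hat_a, dtype=float)
    b = np.asarray(y_hat_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("mismatched participants between models")
    r2a, _ = r2_mae(y, a)
    r2b, _ = r2_mae(y, b)
    diff = _boot_r2(y, a, B, seed) - _boot_r2(y, b, B, seed)  # same seed -> same indices
    lo, hi = np.nanpercentile(diff, [2.5, 97.5])
    return {"delta_r2": r2a - r2b, "ci_low": float(lo), "ci_high": float(hi), "n_boot": B}


def evaluate_models(cohort: pd.DataFrame, predictions: pd.DataFrame,
                    folds: FoldAssignment, targets=("vat_l", "asat_l", "gfat_l", "ratio"),
                    comparators=("BMI", "Waist", "Anthro", "Silhouette"),
                    B: int = 1000, seed: int = 0, pooled: bool = True) -> pd.DataFrame:
    """Benchmark table: model x target x stratum with R², bootstrap CI, MAE.

    ``pooled`` additionally reports sexes-combined rows (both reporting modes
    are of interest; per-stratum rows are always present).
    """
    df = cohort.merge(predictions, on="id", validate="one_to_one")
    rows = []
    for target in targets:
        for name in comparators:
            spec = ComparatorSpec(name=name)
            pred = fit_comparator(df, spec, target, folds)
            strata = [(s, df["sex"] == s) for s in sorted(df["sex"].unique())]
            if pooled:
                strata.append(("pooled", pd.Series(True, index=df.index)))
            for stratum, sel in strata:
                y = df.loc[sel, target].to_numpy(float)
                p = pred[sel].to_numpy(float)
                r2, mae = r2_mae(y, p)
                lo, hi = bootstrap_ci(y, p, B=B, seed=seed)
                rows.append(dict(target=target, model=name, stratum=stratum,
                                 r2=r2, ci_low=lo, ci_high=hi, mae=mae,
                                 n=int(sel.sum()), n_boot=B))
    return pd.DataFrame(rows)
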