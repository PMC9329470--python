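"""Cardiometabolic disease association layer.

Sex-stratified logistic models (odds ratio per SD of exposure), Cox
proportional-hazards models for incident events (hazard ratio per SD),
quintile grouping of an exposure, and marginally standardized prevalence
(g-computation) within BMI-category x waist-category cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

__all__ = [
    "AssociationResult",
    "ADJUSTMENT_SETS",
    "BMI_CATEGORY_EDGES",
    "WAIST_CUTOFFS_CM",
    "standardize_exposure",
    "fit_prevalent",
    "fit_incident",
    "quintile_groups",
    "bmi_category",
    "waist_category",
    "standardized_prevalence",
    "association_table",
]

#: adjustment sets; "base" is age + imaging-center indicators
ADJUSTMENT_SETS = {
    "base": ["age_years"],
    "bmi": ["age_years", "bmi"],
    "bmi_waist": ["age_years", "bmi", "waist_cm"],
}

#: WHO BMI category edges: normal / overweight / obese / severely obese
BMI_CATEGORY_EDGES = (18.5, 25.0, 30.0, 40.0)
BMI_CATEGORY_LABELS = ("normal", "overweight", "obese", "severely_obese")

#: default sex-specific elevated-waist cutoffs (cm); per-BMI-subgroup overrides allowed
WAIST_CUTOFFS_CM = {"male": 102.0, "female": 88.0}


@dataclass(frozen=True)
class AssociationResult:
    disease: str
    exposure: str
    stratum: str
    adjustment: str
    effect_per_sd: float  # OR or HR
    ci_low: float
    ci_high: float
    n: int
    events: int
    kind: str  # "OR" or "HR"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.effect_per_sd <= self.ci_high):
            raise ValueError("CI must contain the point estimate")
        if self.effect_per_sd <= 0:
            raise ValueError("effect must be positive")


def standardize_exposure(values, stratum) -> pd.Series:
    """(x - mean)/SD computed within each stratum (typically sex)."""
    values = pd.Series(values).astype(float)
    stratum = pd.Series(stratum, index=values.index)
    out = values.copy()
    for _, grp in values.groupby(stratum):
        sd = grp.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero SD within stratum")
        out.loc[grp.index] = (grp - grp.mean()) / sd
    return out


def _design(df: pd.DataFrame, exposure_z: pd.Series, adjustment: str) -> pd.DataFrame:
    covs = ADJUSTMENT_SETS[adjustment]
    X = pd.DataFrame({"exposure": exposure_z})
    for c in covs:
        X[c] = df[c].astype(float)
    if "center" in df.columns and df["center"].nunique() > 1:
        X = pd.concat([X, pd.get_dummies(df["center"], prefix="center",
                                         drop_first=True, dtype=float)], axis=1)
    return X


def fit_prevalent(cohort: pd.DataFrame, disease: str, exposure: str,
                  adjustment: str = "bmi_waist", min_cases: int = 20) -> list:
    """Sex-stratified logistic regression; OR per SD of exposure with Wald 95% CI."""
    results = []
    ycol = f"{disease}_prevalent"
    for sex, df in cohort.groupby("sex"):
        y = df[ycol].astype(int)
        if y.sum() < min_cases:
            import warnings

            warnings.warn(f"{disease}/{sex}: only {int(y.sum())} cases (low power)",
                          stacklevel=2)
        z = standardize_exposure(df[exposure], df["sex"])
        X = sm.add_constant(_design(df, z, adjustment))
        try:
            fit = sm.Logit(y.to_numpy(), X.to_numpy(float)).fit(disp=0)
        except Exception as exc:  # separation and friends
            raise RuntimeError(f"logistic fit failed for {disease}/{sex}: {exc}") from exc
        j = list(X.columns).index("exposure")
        beta, se = fit.params[j], fit.bse[j]
        results.append(AssociationResult(
            disease=disease, exposure=exposure, stratum=str(sex), adjustment=adjustment,
            effect_per_sd=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959964 * se)),
            ci_high=float(np.exp(beta + 1.959964 * se)),
            n=len(df), events=int(y.sum()), kind="OR"))
    return results


def fit_incident(cohort: pd.DataFrame, disease: str, exposure: str,
                 adjustment: str = "bmi_waist", min_events: int = 10) -> list:
    """Sex-stratified Cox model on incident events (prevalent cases excluded).

    Efron tie handling; HR per SD of exposure with 95% CI.
    """
    results = []
    for sex, df in cohort.groupby("sex"):
        df = df[df[f"{disease}_prevalent"] == 0].copy()
        events = int(df[f"{disease}_incident"].sum())
        if events == 0:
            raise ValueError(f"zero incident {disease} events in {sex} stratum")
        if events < min_events:
            import warnings

            warnings.warn(f"{disease}/{sex}: only {events} events (low power)", stacklevel=2)
        z = standardize_exposure(df[exposure], df["sex"])
        X = _design(df, z, adjustment)
        data = X.copy()
        data["T"] = df[f"{disease}_follow_up_years"].to_numpy(float)
        data["E"] = df[f"{disease}_incident"].to_numpy(int)
        data = data[data["T"] > 0]
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col="T", event_col="E")
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed for {disease}/{sex}: {exc}") from exc
        beta = float(cph.params_["exposure"])
        se = float(cph.standard_errors_["exposure"])
        results.append(AssociationResult(
            disease=disease, exposure=exposure, stratum=str(sex), adjustment=adjustment,
            effect_per_sd=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959964 * se)),
            ci_high=float(np.exp(beta + 1.959964 * se)),
            n=len(data), events=events, kind="HR"))
    return results


def quintile_groups(exposure, stratum) -> pd.Series:
    """Sex-stratified {Q1, Q2-4, Q5} labels from empirical quintiles.

    Ties are broken by stable (ordinal) rank so group sizes stay within a
    tie-run length of the nominal 20/60/20 split.
    """
    exposure = pd.Series(exposure).astype(float)
    stratum = pd.Series(stratum, index=exposure.index)
    out = pd.Series(index=exposure.index, dtype=object)
    for _, grp in exposure.groupby(stratum):
        n = len(grp)
        if n < 5:
            raise ValueError("need at least 5 per stratum for quintiles")
        ranks = grp.rank(method="first").to_numpy()  # stable ordinal ranks
        q = np.ceil(5.0 * ranks / n).astype(int)
        lab = np.where(q <= 1, "Q1", np.where(q >= 5, "Q5", "Q2-4"))
        out.loc[grp.index] = lab
    return out


def bmi_category(bmi, edges=BMI_CATEGORY_EDGES) -> pd.Series:
    bins = [-np.inf, *edges, np.inf]
    labels = ["underweight", *BMI_CATEGORY_LABELS]
    return pd.cut(pd.Series(bmi).astype(float), bins=bins, labels=labels, right=False)


def waist_category(waist_cm, sex, cutoffs=None, bmi_cat=None) -> pd.Series:
    """'normal' vs 'elevated' waist per sex (optionally per sex x BMI subgroup).

    ``cutoffs`` maps sex -> cutoff cm, or sex -> {bmi_category -> cutoff}.
    """
    cutoffs = cutoffs or WAIST_CUTOFFS_CM
    waist = pd.Series(waist_cm).astype(float)
    sex = pd.Series(sex, index=waist.index)
    out = pd.Series(index=waist.index, dtype=object)
    for i in waist.index:
        cut = cutoffs[sex[i]]
        if isinstance(cut, dict):
            cut = cut[str(bmi_cat[i])]
        out[i] = "elevated" if waist[i] >= cut else "normal"
    return out


def standardized_prevalence(cohort: pd.DataFrame, disease: str, exposure: str,
                            adjustment: str | None = "base",
                            waist_cutoffs=None, B: int = 200, seed: int = 0) -> pd.DataFrame:
    """Marginally standardized prevalence in sex x BMI x waist x quintile-group cells.

    For each sex stratum an adjusted logistic model with cell indicators is
    fit; every participant's outcome probability is predicted under
    counterfactual membership of each cell and averaged (g-computation).
    With ``adjustment=None`` no covariate model is used and the result equals
    the raw cell prevalence. 95% CIs by bootstrap over participants.
    """
    ycol = f"{disease}_prevalent"
    df = cohort.copy()
    df["bmi_cat"] = bmi_category(df["bmi"]).astype(str)
    df["waist_cat"] = waist_category(df["waist_cm"], df["sex"], cutoffs=waist_cutoffs,
                                     bmi_cat=df["bmi_cat"])
    df["qgroup"] = quintile_groups(df[exposure], df["sex"])
    df["cell"] = df["bmi_cat"] + "/" + df["waist_cat"] + "/" + df["qgroup"].astype(str)

    rows = []
    rng = np.random.default_rng(seed)
    for sex, d in df.groupby("sex"):
        cells = sorted(d["cell"].unique())
        ests = _g_computation(d, ycol, cells, adjustment)
        boots = {c: [] for c in cells}
        for _ in range(B):
            idx = rng.integers(0, len(d), size=len(d))
            db = d.iloc[idx]
            try:
                eb = _g_computation(db, ycol, cells, adjustment)
            except (RuntimeError, np.linalg.LinAlgError):
                continue
            for c in cells:
                if c in eb and np.isfinite(eb[c]):
                    boots[c].append(eb[c])
        for c in cells:
            bmi_cat, waist_cat, qgroup = c.split("/")
            bs = np.asarray(boots[c])
            lo, hi = (np.percentile(bs, [2.5, 97.5]) if bs.size >= max(20, B // 4)
                      else (np.nan, np.nan))
            rows.append(dict(sex=sex, bmi_cat=bmi_cat, waist_cat=waist_cat, qgroup=qgroup,
                             prevalence=ests.get(c, np.nan), ci_low=lo, ci_high=hi,
                             n=int((d["cell"] == c).sum())))
    return pd.DataFrame(rows)


def _g_computation(d: pd.DataFrame, ycol: str, cells: list, adjustment: str | None) -> dict:
    """Standardized prevalence per cell within one stratum."""
    present = [c for c in cells if (d["cell"] == c).any()]
    if adjustment is None:
        return {c: float(d.loc[d["cell"] == c, ycol].mean()) for c in present}
    cell_idx = pd.Categorical(d["cell"], categories=present)
    C = pd.get_dummies(cell_idx, drop_first=True, dtype=float)
    covs = d[ADJUSTMENT_SETS[adjustment]].astype(float).reset_index(drop=True)
    X = pd.concat([C.reset_index(drop=True), covs], axis=1)
    X.insert(0, "const", 1.0)
    y = d[ycol].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        return {c: float(y.mean()) for c in present}
    try:
        fit = sm.Logit(y, X.to_numpy(float)).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise RuntimeError(f"standardization model failed: {exc}") from exc
    out = {}
    for c in present:
        Xc = X.copy()
        dummies = [col for col in C.columns]
        for col in dummies:
            Xc[col] = 1.0 if col == c else 0.0
        out[c] = float(fit.predict(Xc.to_numpy(float)).mean())
    return out


def association_table(cohort: pd.DataFrame, exposure: str,
                      diseases=("t2d", "cad", "htn", "chol"),
                      adjustments=("base", "bmi", "bmi_waist"),
                      incident_for=("t2d", "cad")) -> pd.DataFrame:
    """Tidy table of OR/SD and HR/SD association results."""
    import warnings

    rows = []
    for disease in diseases:
        for adj in adjustments:
            try:
                for res in fit_prevalent(cohort, disease, exposure, adjustment=adj):
                    rows.append(res.__dict__)
            except RuntimeError as exc:  # separation / singular fits at small n
                warnings.warn(f"skipping prevalent {disease}/{adj}: {exc}", stacklevel=2)
        if disease in incident_for:
            try:
                for res in fit_incident(cohort, disease, exposure, adjustment="bmi_waist"):
                    rows.append(res.__dict__)
            except (ValueError, RuntimeError) as exc:  # zero events / non-convergence
                warnings.warn(f"skipping incident {disease}: {exc}", stacklevel=2)
    return pd.DataFrame(rows)
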