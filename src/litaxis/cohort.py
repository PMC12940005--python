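"""Synthetic salivary neuroimmune cohort and illustrative ECC risk modelling.

The generator draws two latent axes per subject — a neuroendocrine stress
axis S and an inflammation axis I, both standard normal — and builds eight
salivary markers (IL-6, TNF, cortisol, DHEA, NPY, TAC, GPx, SOD) as
range-anchored linear combinations of the latents plus independent noise.
ECC status is Bernoulli with logit equal to an intercept plus a configurable
log-odds effect vector on the standardised markers; the intercept is solved
numerically so the expected prevalence matches the configuration.  All values
are fully synthetic (no real patient data) and the downstream classifier and
permutation-importance analysis are methodological illustrations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

MARKERS = ("il6", "tnf", "cortisol", "dhea", "npy", "tac", "gpx", "sod")

MARKER_COLUMNS = {
    "il6": "il6_pg_ml",
    "tnf": "tnf_pg_ml",
    "cortisol": "cortisol_nmol_l",
    "dhea": "dhea_nmol_l",
    "npy": "npy_pg_ml",
    "tac": "tac_mmol_l",
    "gpx": "gpx_u_ml",
    "sod": "sod_u_ml",
}

#: plausible salivary ranges in conventional units (editable configuration)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "il6": (0.0, 50.0),      # pg/mL
    "tnf": (0.0, 40.0),      # pg/mL
    "cortisol": (1.0, 30.0), # nmol/L
    "dhea": (0.1, 10.0),     # nmol/L
    "npy": (10.0, 200.0),    # pg/mL
    "tac": (0.2, 2.0),       # mmol/L
    "gpx": (10.0, 120.0),    # U/mL
    "sod": (5.0, 80.0),      # U/mL
}

#: per-marker log-odds effects on ECC (per SD of the marker)
DEFAULT_EFFECTS: dict[str, float] = {
    "il6": 1.0, "tnf": 0.5, "cortisol": 0.6, "dhea": 0.0,
    "npy": 0.0, "tac": -0.6, "gpx": -0.5, "sod": -0.4,
}

#: (stress loading, inflammation loading) per marker; redox markers load
#: negatively on inflammation, stress markers on the neuroendocrine axis
DEFAULT_COUPLING: dict[str, tuple[float, float]] = {
    "il6": (0.4, 0.5),
    "tnf": (0.3, 0.5),
    "cortisol": (0.7, 0.0),
    "dhea": (0.5, 0.0),
    "npy": (0.4, 0.0),
    "tac": (0.0, -0.5),
    "gpx": (0.0, -0.5),
    "sod": (0.0, -0.4),
}


@dataclass
class CohortConfig:
    n_subjects: int = 500
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    coupling: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    prevalence: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0


@dataclass
class RiskFit:
    model: Pipeline
    feature_names: list[str]
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    y_pred: np.ndarray
    y_prob: np.ndarray


@dataclass
class RiskReport:
    confusion: tuple[int, int, int, int]  # TN, FP, FN, TP on the held-out split
    importances: pd.DataFrame  # marker, importance_mean, importance_sd
    auc: float


def _validate(config: CohortConfig) -> None:
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not 0.0 < config.prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    for m in MARKERS:
        lo, hi = config.ranges[m]
        if not lo < hi:
            raise ValueError(f"marker {m}: range low must be < high")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")


def simulate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate the synthetic cohort table, deterministically per seed.

    Marker values are centred at each range midpoint with the latent+noise
    z-scaled so that three standard deviations span the half-range (clipping
    therefore alters well under 1% of values).
    """
    if config is None:
        config = CohortConfig()
    _validate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    stress = rng.standard_normal(n)
    inflammation = rng.standard_normal(n)

    data = {}
    for m in MARKERS:
        a, b = config.coupling.get(m, (0.0, 0.0))
        z = a * stress + b * inflammation + config.noise_sd * rng.standard_normal(n)
        total_sd = np.sqrt(a ** 2 + b ** 2 + config.noise_sd ** 2)
        lo, hi = config.ranges[m]
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        values = mid + z / (3.0 * total_sd) * half
        data[MARKER_COLUMNS[m]] = np.clip(values, lo, hi)

    X = np.column_stack([data[MARKER_COLUMNS[m]] for m in MARKERS])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X_std = (X - X.mean(axis=0)) / sd
    beta = np.array([config.effects.get(m, 0.0) for m in MARKERS])
    eta = X_std @ beta

    def gap(b0: float) -> float:
        return float(expit(b0 + eta).mean() - config.prevalence)

    try:
        intercept = brentq(gap, -30.0, 30.0)
    except ValueError as exc:
        raise ValueError(
            "prevalence unattainable for the configured effects"
        ) from exc
    p = expit(intercept + eta)
    ecc = (rng.random(n) < p).astype(int)

    table = pd.DataFrame(data)
    table.insert(0, "subject_id", [f"SUBJ{i:05d}" for i in range(n)])
    table["ecc_status"] = ecc
    table.attrs["intercept"] = float(intercept)
    return table


def _default_model(seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("logistic", LogisticRegression(max_iter=1000, random_state=seed)),
        ]
    )


def fit_risk_model(
    table: pd.DataFrame,
    model: Pipeline | None = None,
    split_fraction: float = 0.3,
    seed: int = 0,
) -> RiskFit:
    """Stratified train/test split and fit of the risk classifier.

    The default model is a standardised, L2-regularised logistic regression;
    any sklearn-style classifier with fit/predict_proba can be plugged in.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    feature_cols = [MARKER_COLUMNS[m] for m in MARKERS]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["ecc_status"].to_numpy(dtype=int)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=split_fraction, stratify=y, random_state=seed
    )
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    clf = model if model is not None else _default_model(seed)
    clf.fit(X_train, y_train)
    return RiskFit(
        model=clf,
        feature_names=list(MARKERS),
        X_train=X_train,
        y_train=y_train,
        X_test=X_test,
        y_test=y_test,
        y_pred=clf.predict(X_test),
        y_prob=clf.predict_proba(X_test)[:, 1],
    )


def permutation_importances(
    fit: RiskFit, repeats: int = 10, seed: int = 0, scoring: str = "roc_auc"
) -> pd.DataFrame:
    """Held-out permutation importance per marker (mean score drop +/- sd)."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    result = _sk_permutation_importance(
        fit.model,
        fit.X_test,
        fit.y_test,
        scoring=scoring,
        n_repeats=repeats,
        random_state=seed,
    )
    return pd.DataFrame(
        {
            "marker": fit.feature_names,
            "importance_mean": result.importances_mean,
            "importance_sd": result.importances_std,
        }
    )


def confusion_counts(
    labels: Sequence[int], preds: Sequence[int]
) -> tuple[int, int, int, int]:
    """(TN, FP, FN, TP) tally for binary labels/predictions."""
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    if labels.shape != preds.shape:
        raise ValueError("labels and predictions must have equal length")
    tn, fp, fn, tp = _sk_confusion_matrix(labels, preds, labels=[0, 1]).ravel()
    return int(tn), int(fp), int(fn), int(tp)


def coefficient_signs(table: pd.DataFrame, seed: int = 0) -> dict[str, float]:
    """Full-data standardised logistic coefficients per marker (for recovery checks)."""
    feature_cols = [MARKER_COLUMNS[m] for m in MARKERS]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["ecc_status"].to_numpy(dtype=int)
    clf = _default_model(seed)
    clf.fit(X, y)
    coefs = clf.named_steps["logistic"].coef_[0]
    return dict(zip(MARKERS, coefs))


def risk_report(
    table: pd.DataFrame,
    model: Pipeline | None = None,
    split_fraction: float = 0.3,
    repeats: int = 10,
    seed: int = 0,
) -> RiskReport:
    """Fit, held-out confusion matrix, AUC, and permutation importances."""
    fit = fit_risk_model(table, model=model, split_fraction=split_fraction, seed=seed)
    importances = permutation_importances(fit, repeats=repeats, seed=seed)
    return RiskReport(
        confusion=confusion_counts(fit.y_test, fit.y_pred),
        importances=importances,
        auc=float(roc_auc_score(fit.y_test, fit.y_prob)),
    )
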