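"""ROC evaluation: AUC, covariate-adjusted AUC, bootstrap CIs, operating points.

AUC is the Mann-Whitney concordance probability (ties count one half), equal
to the trapezoidal area under the empirical ROC curve.  Covariate adjustment
fits a logistic model ``label ~ marker + covariates`` by iteratively
reweighted least squares and evaluates the AUC of the fitted linear
predictor.  Confidence intervals are percentile intervals of the AUC over
class-stratified bootstrap resamples (default 2000 replications); the
operating point maximizes Youden's J = sensitivity + specificity - 1 over
all score midpoints, ties resolved toward higher specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import ConfigurationError, DesignError
from . import dmp


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    threshold: float
    sensitivity: float
    specificity: float
    adjusted: bool
    covariates: tuple = ()
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_boot": self.n_boot, "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "adjusted": self.adjusted, "covariates": list(self.covariates),
            "notes": list(self.notes),
        }


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DesignError(f"need both classes present, got {classes.size}")
    return (labels == classes.max()).astype(int)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, float)
    y = _check_labels(labels)
    return float(roc_auc_score(y, scores))


def adjusted_auc(marker, labels, covariates: pd.DataFrame | None = None,
                 n_boot: int = 2000, level: float = 0.95,
                 seed: int | None = None) -> RocSummary:
    """AUC of the logistic linear predictor ``label ~ marker + covariates``.

    On detected separation (diverging IRLS coefficients) the summary falls
    back to the unadjusted marker AUC, with a note recorded.  Categorical
    covariates (e.g. sex) are factor-coded.
    """
    marker = np.asarray(marker, float)
    y = _check_labels(labels)
    notes = []
    cov_names = tuple(covariates.columns) if covariates is not None else ()

    cols = [marker]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object:
                col = pd.factorize(col, sort=True)[0]
            col = np.asarray(col, float)
            if np.ptp(col) == 0:      # absorbed by the intercept
                notes.append(f"dropped constant covariate {c!r}")
                continue
            cols.append(col)
    x = sm.add_constant(np.column_stack(cols), has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("adjustment design matrix is rank deficient")

    score = marker
    adjusted = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            raise np.linalg.LinAlgError("perfect separation")
        if np.any(~np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
            raise np.linalg.LinAlgError("diverging coefficients")
        score = x @ fit.params
        adjusted = True
    except Exception as exc:
        notes.append(f"separation detected ({exc}); falling back to unadjusted marker AUC")

    auc = roc_auc(score, y)
    ci_low, ci_high = bootstrap_ci(score, y, n_boot=n_boot, level=level, seed=seed)
    threshold, sens, spec = operating_point(score, y)
    return RocSummary(auc=auc, ci_low=ci_low, ci_high=ci_high, n_boot=n_boot,
                      threshold=threshold, sensitivity=sens, specificity=spec,
                      adjusted=adjusted, covariates=cov_names, notes=notes)


def fit_logistic(y, x_with_const: np.ndarray, tol: float = 1e-8, maxiter: int = 100):
    """IRLS logistic fit (statsmodels GLM); exposed for oracle comparisons."""
    fit = sm.GLM(np.asarray(y), x_with_const, family=sm.families.Binomial()).fit(
        maxiter=maxiter, tol=tol)
    return np.asarray(fit.params)


def bootstrap_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                 seed: int | None = None) -> tuple[float, float]:
    """Percentile CI of the AUC over class-stratified bootstrap resamples."""
    scores = np.asarray(scores, float)
    y = _check_labels(labels)
    if not 0.0 < level < 1.0:
        raise ConfigurationError("level must lie in (0, 1)")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    redrawn = 0
    for i in range(n_boot):
        while True:
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            idx = np.concatenate([bp, bn])
            if len(np.unique(y[idx])) == 2:
                break
            redrawn += 1  # unreachable under stratified draws; kept as a guard
        aucs[i] = roc_auc(scores[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J (ties -> higher specificity).

    A sample is called positive when its score is >= the threshold;
    candidate thresholds are midpoints between consecutive sorted unique
    scores plus open boundaries on each side.
    """
    scores = np.asarray(scores, float)
    y = _check_labels(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    n1 = int(y.sum())
    n0 = y.size - n1
    best = (-np.inf, -np.inf, -np.inf)  # (J, specificity, threshold)
    for thr in candidates:
        pred = scores >= thr
        sens = float((pred & (y == 1)).sum()) / n1
        spec = float((~pred & (y == 0)).sum()) / n0
        j = sens + spec - 1.0
        if (j, spec, thr) > best:
            best = (j, spec, thr)
    j, spec, thr = best
    sens = j + 1.0 - spec
    return float(thr), float(sens), float(spec)


def correlate_clinical(marker, clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p of a marker against each clinical scale column."""
    rows = []
    for col in clinical.columns:
        r, p = dmp.pearson(marker, clinical[col].to_numpy())
        rows.append({"scale": col, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("scale")
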