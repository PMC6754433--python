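"""Probe-wise differential methylation with moderated t-statistics.

Per probe, an ordinary least-squares model of beta on group (plus optional
covariates) yields a group coefficient and residual variance; residual
variances are then shrunk toward a common prior by empirical Bayes.  The
prior (d0 degrees of freedom, s0^2 scale) is estimated by moment-matching
the marginal distribution of log residual variances against a scaled-F
model, and the moderated t-statistic

    t = coef / (se_unscaled * sqrt((d0*s0^2 + d*s^2) / (d0 + d)))

is referred to a t distribution on d0 + d degrees of freedom.  Modelling is
on beta values directly, so effect sizes stay in beta units and the raw
case-minus-control mean difference (delta_beta) is carried alongside the
adjusted coefficient.  Benjamini-Hochberg adjustment and the 0.1 / 0.1
FDR / |delta-beta| screening rule complete the DMP call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DesignError


@dataclass
class DesignSpec:
    """Response group column plus optional numeric/binary covariate columns."""

    group_col: str = "group"
    covariates: tuple = ()


@dataclass
class ModerationFit:
    d0: float                        # prior degrees of freedom (math.inf allowed)
    s0_sq: float                     # prior variance
    post_var: np.ndarray             # per-probe posterior (moderated) variance


def build_design(samples: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, np.ndarray, list]:
    """Design matrix [intercept, group, covariates...]; returns (X, case_mask, names)."""
    if design.group_col not in samples.columns:
        raise DesignError(f"group column {design.group_col!r} not in sample sheet")
    groups = samples[design.group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise DesignError(f"group column must have exactly 2 levels, got {levels}")
    case_level = "case" if "case" in levels else levels[0]
    case = (groups == case_level).to_numpy().astype(float)

    columns = [np.ones(len(samples)), case]
    names = ["intercept", "group"]
    for cov in design.covariates:
        if cov not in samples.columns:
            raise DesignError(f"covariate {cov!r} not in sample sheet")
        col = samples[cov]
        if col.dtype == object:
            codes, _ = pd.factorize(col, sort=True)
            col = codes.astype(float)
        columns.append(np.asarray(col, float))
        names.append(cov)
    x = np.column_stack(columns)

    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the first column that adds no rank
        culprit = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                culprit.append(names[j])
        raise DesignError(f"design matrix is rank deficient; collinear column(s): {culprit}")
    return x, case.astype(bool), names


def fit_probe_models(beta: pd.DataFrame, samples: pd.DataFrame,
                     design: DesignSpec | None = None) -> pd.DataFrame:
    """Per-probe OLS of beta on the design; vectorized across probes.

    Returns a frame indexed by probe_id with columns ``coefficient`` (group
    effect adjusted for covariates), ``s2`` (residual variance), ``df``
    (residual degrees of freedom) and ``delta_beta`` (raw unadjusted group
    mean difference, case minus control).
    """
    design = design or DesignSpec()
    x, case, _ = build_design(samples.loc[beta.columns], design)
    n, k = x.shape
    if n <= k:
        raise DesignError(f"need more samples ({n}) than design columns ({k})")

    y = beta.to_numpy()                                   # probes x samples
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = y @ x @ xtx_inv.T                             # probes x k
    resid = y - coefs @ x.T
    df = n - k
    s2 = (resid ** 2).sum(axis=1) / df
    delta = y[:, case].mean(axis=1) - y[:, ~case].mean(axis=1)

    return pd.DataFrame(
        {
            "coefficient": coefs[:, 1],
            "s2": s2,
            "df": float(df),
            "delta_beta": delta,
            "stdev_unscaled": math.sqrt(xtx_inv[1, 1]),
        },
        index=beta.index,
    )


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return x


def moderate_variances(s2, d, coefficients=None, stdev_unscaled=None,
                       d0_override: float | None = None):
    """Empirical-Bayes shrinkage of residual variances; optionally moderated t and p.

    Returns ``ModerationFit`` alone, or ``(fit, t, p)`` when ``coefficients``
    and ``stdev_unscaled`` are supplied.  ``d0_override`` forces the prior
    degrees of freedom (0 recovers the ordinary t; ``math.inf`` pools fully).
    """
    s2 = np.asarray(s2, float)
    if s2.size < 10:
        raise ConfigurationError(f"need at least 10 probes to moderate, got {s2.size}")
    d = float(d)
    s2_safe = np.maximum(s2, 1e-12)

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            s0_sq = float(np.exp(np.mean(np.log(s2_safe))))  # irrelevant at d0=0
        elif math.isinf(d0):
            z = np.log(s2_safe)
            e = z - special.digamma(d / 2) + math.log(d / 2)
            s0_sq = float(np.exp(np.mean(e)))
        else:
            s0_sq = _fit_s0(s2_safe, d, d0)
    else:
        z = np.log(s2_safe)
        e = z - special.digamma(d / 2) + math.log(d / 2)
        evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - math.log(d0 / 2)))
        else:
            d0 = math.inf
            s0_sq = float(np.exp(np.mean(e)))

    if math.isinf(d0):
        post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post = s2_safe.copy()
    else:
        post = (d0 * s0_sq + d * s2_safe) / (d0 + d)
    fit = ModerationFit(d0=d0, s0_sq=s0_sq, post_var=post)

    if coefficients is None:
        return fit
    coefficients = np.asarray(coefficients, float)
    se = np.asarray(stdev_unscaled, float) * np.sqrt(post)
    t = coefficients / se
    df_total = min(d0 + d, 1e9)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return fit, t, p


def _fit_s0(s2: np.ndarray, d: float, d0: float) -> float:
    e = np.log(s2) - special.digamma(d / 2) + math.log(d / 2)
    return float(np.exp(np.mean(e) + special.digamma(d0 / 2) - math.log(d0 / 2)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving on input indexing."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dmp_table(beta: pd.DataFrame, samples: pd.DataFrame,
              design: DesignSpec | None = None,
              fdr_max: float = 0.1, delta_min: float = 0.1) -> pd.DataFrame:
    """Full DMP call: per-probe OLS, variance moderation, BH-FDR, pass flags."""
    fits = fit_probe_models(beta, samples, design)
    mod, t, p = moderate_variances(
        fits["s2"].to_numpy(), fits["df"].iloc[0],
        coefficients=fits["coefficient"].to_numpy(),
        stdev_unscaled=fits["stdev_unscaled"].to_numpy(),
    )
    table = fits.drop(columns="stdev_unscaled").copy()
    table["post_var"] = mod.post_var
    table["t"] = t
    table["df_total"] = mod.d0 + fits["df"].iloc[0] if not math.isinf(mod.d0) else math.inf
    table["p"] = p
    table["fdr"] = bh_adjust(p)
    table["pass_fdr"] = table["fdr"] <= fdr_max
    table["pass_delta"] = table["delta_beta"].abs() >= delta_min
    return table


def select_dmps(table: pd.DataFrame, fdr_max: float = 0.1, delta_min: float = 0.1) -> pd.DataFrame:
    """Rows with fdr <= fdr_max and |delta_beta| >= delta_min, sorted by
    (fdr ascending, |delta_beta| descending, probe_id)."""
    if table.empty:
        raise ConfigurationError("DMP table is empty")
    keep = (table["fdr"] <= fdr_max) & (table["delta_beta"].abs() >= delta_min)
    sub = table.loc[keep].copy()
    sub["_absd"] = sub["delta_beta"].abs()
    sub["_pid"] = sub.index.astype(str)
    sub = sub.sort_values(["fdr", "_absd", "_pid"], ascending=[True, False, True],
                          kind="mergesort")
    return sub.drop(columns=["_absd", "_pid"])


def two_group_test(x_case, x_control) -> tuple[float, float, float]:
    """Student's t-test with pooled variance; returns (t, df, p)."""
    a = np.asarray(x_case, float)
    b = np.asarray(x_control, float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(a.size + b.size - 2), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with t-based two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("pearson needs paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DesignError("pearson correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
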