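"""Probe-level QC, BMIQ probe-type normalization, and batch adjustment.

The three preprocessing stages mirror standard 450K practice:

* **filter_probes** removes probes that fail detection in any sample, have low
  bead counts in too many samples, sit on sex chromosomes, overlap SNPs, or
  bind non-specifically (cross-reactive).
* **bmiq_normalize** fits, per sample, three-state beta mixtures (unmethylated
  U, hemimethylated H, methylated M) to type-I and type-II probes separately
  and maps the type-II U/M components onto the type-I ones by quantile
  matching, with the intermediate H stratum rescaled between the transformed
  boundaries (beta-mixture quantile dilation).
* **batch_adjust** is a parametric empirical-Bayes location/scale adjustment
  on logit(beta): per-batch probe-wise means and variances are shrunk toward
  moment-matched normal / inverse-gamma priors while the case/control effect
  is protected, one batch variable at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .errors import ConfigurationError, DegenerateDataError, DesignError, NoProbesRetainedError
from .synthetic import EPS_BETA, MethylationDataset

# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

FILTER_RULES = ("detection", "beads", "sex_chr", "snp", "cross_reactive")


@dataclass
class FilterThresholds:
    """QC thresholds; defaults follow common 450K practice.

    A probe is dropped when it fails detection (p > ``detection_p_max``) in one
    or more samples, or when the fraction of samples with fewer than
    ``min_bead_count`` beads is strictly greater than ``max_low_bead_fraction``.
    """

    detection_p_max: float = 0.01
    min_bead_count: int = 3
    max_low_bead_fraction: float = 0.05
    drop_sex_chromosomes: bool = True
    drop_snp_probes: bool = True
    drop_cross_reactive: bool = True

    def validate(self) -> None:
        if not 0.0 < self.detection_p_max < 1.0:
            raise ConfigurationError("detection_p_max must lie in (0, 1)")
        if not 0.0 <= self.max_low_bead_fraction <= 1.0:
            raise ConfigurationError("max_low_bead_fraction must lie in [0, 1]")
        if self.min_bead_count < 0:
            raise ConfigurationError("min_bead_count must be >= 0")


@dataclass
class FilterReport:
    removed: dict                    # rule -> count (first-triggering rule wins)
    retained: int
    total: int
    log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"removed": dict(self.removed), "retained": self.retained, "total": self.total,
                "log": list(self.log)}

    def to_text(self) -> str:
        lines = [f"probes in: {self.total}"]
        for rule in FILTER_RULES:
            lines.append(f"removed by {rule}: {self.removed.get(rule, 0)}")
        lines.append(f"retained: {self.retained}")
        lines.extend(self.log)
        return "\n".join(lines) + "\n"


def filter_probes(dataset: MethylationDataset,
                  thresholds: FilterThresholds | None = None) -> tuple[MethylationDataset, FilterReport]:
    """Apply the QC rules in order; each removal is attributed to the first rule that fires."""
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    dataset.validate()

    masks = {}
    masks["detection"] = (dataset.detection_p.to_numpy() > thresholds.detection_p_max).any(axis=1)
    low_bead_frac = (dataset.bead_count.to_numpy() < thresholds.min_bead_count).mean(axis=1)
    masks["beads"] = low_bead_frac > thresholds.max_low_bead_fraction
    chrom = dataset.annotation["chromosome"].astype(str).to_numpy()
    n = dataset.n_probes
    masks["sex_chr"] = np.isin(chrom, ["X", "Y"]) if thresholds.drop_sex_chromosomes else np.zeros(n, bool)
    masks["snp"] = (dataset.annotation["snp_flag"].to_numpy().astype(int) == 1
                    if thresholds.drop_snp_probes else np.zeros(n, bool))
    masks["cross_reactive"] = (dataset.annotation["cross_reactive_flag"].to_numpy().astype(int) == 1
                               if thresholds.drop_cross_reactive else np.zeros(n, bool))

    removed = {}
    already = np.zeros(n, dtype=bool)
    for rule in FILTER_RULES:
        fires = masks[rule] & ~already
        removed[rule] = int(fires.sum())
        already |= masks[rule]
    keep = ~already
    if not keep.any():
        raise NoProbesRetainedError("no probes retained after filtering")

    out = MethylationDataset(
        beta=dataset.beta.loc[keep],
        detection_p=dataset.detection_p.loc[keep],
        bead_count=dataset.bead_count.loc[keep],
        annotation=dataset.annotation.loc[keep],
        samples=dataset.samples,
    )
    report = FilterReport(
        removed=removed, retained=int(keep.sum()), total=n,
        log=[f"rule order: {' -> '.join(FILTER_RULES)}"],
    )
    return out, report


# ---------------------------------------------------------------------------
# Three-state beta mixture (EM)
# ---------------------------------------------------------------------------

STATE_LABELS = ("U", "H", "M")


@dataclass
class BetaMixtureFit:
    """Three-component beta mixture, components ordered by increasing mean."""

    weights: np.ndarray              # (3,)
    a: np.ndarray                    # (3,) first shape parameter
    b: np.ndarray                    # (3,) second shape parameter
    log_likelihood: float
    n_iter: int
    labels: tuple = STATE_LABELS

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def responsibilities(self, values: np.ndarray) -> np.ndarray:
        """Posterior component probabilities for each observation (rows sum to 1)."""
        x = np.clip(np.asarray(values, float), EPS_BETA, 1 - EPS_BETA)
        logp = np.stack(
            [np.log(self.weights[k]) + beta_dist.logpdf(x, self.a[k], self.b[k]) for k in range(3)],
            axis=1,
        )
        logp -= logp.max(axis=1, keepdims=True)
        r = np.exp(logp)
        return r / r.sum(axis=1, keepdims=True)

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Hard state assignment: index into (U, H, M) by maximum responsibility."""
        return self.responsibilities(values).argmax(axis=1)


def _weighted_beta_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Method-of-moments beta shape parameters under weights ``w``."""
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-4), 1 - 1e-4)
    v = max(v, 1e-8)
    common = max(m * (1 - m) / v - 1.0, 1e-3)
    a = max(m * common, 1e-3)
    b = max((1 - m) * common, 1e-3)
    return a, b


def fit_beta_mixture(values, n_states: int = 3, tol: float = 1e-4,
                     max_iter: int = 100, seed: int | None = None) -> BetaMixtureFit:
    """EM fit of a 3-state beta mixture; components reported in increasing-mean order.

    The M-step matches each component's weighted mean and variance (method of
    moments), which is fast and numerically stable on near-boundary betas.
    Initialization splits the data at the 0.25 / 0.75 state boundaries, so a
    single dominant state keeps nearly all of the mixture weight.
    """
    if n_states != 3:
        raise ConfigurationError("n_states must be 3")
    x = np.clip(np.asarray(values, float), EPS_BETA, 1 - EPS_BETA)
    if x.size < 50:
        raise ConfigurationError(f"need at least 50 values to fit, got {x.size}")
    if np.ptp(x) < 1e-8:
        raise DegenerateDataError("all values identical; beta mixture undefined")

    # seed the U/H/M strata at the canonical methylation-state boundaries;
    # a nearly empty stratum starts with a vague default so EM can keep its
    # weight small when a single state dominates the data
    assign = np.digitize(x, [0.25, 0.75])
    default_shapes = ((2.0, 18.0), (10.0, 10.0), (18.0, 2.0))
    weights = np.empty(3)
    a = np.empty(3)
    b = np.empty(3)
    for k in range(3):
        mask = assign == k
        if mask.sum() < 5:
            weights[k] = 1e-3
            a[k], b[k] = default_shapes[k]
        else:
            weights[k] = mask.mean()
            a[k], b[k] = _weighted_beta_moments(x[mask], np.ones(int(mask.sum())))
    weights /= weights.sum()

    loglik = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(weights[k]) + beta_dist.logpdf(x, a[k], b[k]) for k in range(3)], axis=1
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        new_loglik = float(lse.sum())
        r = np.exp(logp - lse[:, None])
        for k in range(3):
            wk = r[:, k] + 1e-12
            weights[k] = wk.mean()
            a[k], b[k] = _weighted_beta_moments(x, wk)
        weights /= weights.sum()
        if new_loglik - loglik < tol and n_iter > 1:
            loglik = new_loglik
            break
        loglik = new_loglik

    means = a / (a + b)
    order = np.lexsort((weights, means))  # by mean, ties broken by weight
    return BetaMixtureFit(weights=weights[order], a=a[order], b=b[order],
                          log_likelihood=loglik, n_iter=n_iter)


# ---------------------------------------------------------------------------
# BMIQ
# ---------------------------------------------------------------------------


def _bmiq_map_sample(t1: np.ndarray, t2: np.ndarray, tol: float, max_iter: int,
                     seed: int | None) -> np.ndarray:
    fit1 = fit_beta_mixture(t1, tol=tol, max_iter=max_iter, seed=seed)
    fit2 = fit_beta_mixture(t2, tol=tol, max_iter=max_iter, seed=seed)
    x = np.clip(t2, EPS_BETA, 1 - EPS_BETA)
    states = fit2.classify(x)
    out = x.copy()

    u_mask, h_mask, m_mask = states == 0, states == 1, states == 2
    # quantile-match the U stratum onto the type-I U component (lower tail)
    if u_mask.any():
        q = beta_dist.cdf(x[u_mask], fit2.a[0], fit2.b[0])
        out[u_mask] = beta_dist.ppf(q, fit1.a[0], fit1.b[0])
    # quantile-match the M stratum onto the type-I M component (upper tail)
    if m_mask.any():
        q = beta_dist.sf(x[m_mask], fit2.a[2], fit2.b[2])
        out[m_mask] = beta_dist.isf(q, fit1.a[2], fit1.b[2])
    # dilate the H stratum linearly between the transformed U/M boundaries
    if h_mask.any():
        lo2 = x[u_mask].max() if u_mask.any() else x[h_mask].min()
        hi2 = x[m_mask].min() if m_mask.any() else x[h_mask].max()
        lo_t = beta_dist.ppf(beta_dist.cdf(lo2, fit2.a[0], fit2.b[0]), fit1.a[0], fit1.b[0])
        hi_t = beta_dist.isf(beta_dist.sf(hi2, fit2.a[2], fit2.b[2]), fit1.a[2], fit1.b[2])
        if not np.isfinite(lo_t):
            lo_t = lo2
        if not np.isfinite(hi_t):
            hi_t = hi2
        if hi_t <= lo_t or hi2 <= lo2:
            shift = 0.5 * ((lo_t if np.isfinite(lo_t) else 0) + (hi_t if np.isfinite(hi_t) else 1)) \
                - 0.5 * (lo2 + hi2)
            out[h_mask] = x[h_mask] + shift
        else:
            out[h_mask] = lo_t + (x[h_mask] - lo2) * (hi_t - lo_t) / (hi2 - lo2)

    # enforce rank preservation across strata and clamp into [0, 1]
    order = np.argsort(x, kind="mergesort")
    out[order] = np.maximum.accumulate(out[order])
    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(dataset: MethylationDataset, tol: float = 1e-4,
                   max_iter: int = 100, seed: int | None = None) -> MethylationDataset:
    """Per-sample BMIQ: map type-II probe betas onto the type-I distribution.

    Type-I values are returned bit-identical; within each sample the rank
    order of type-II probes is preserved.
    """
    design = dataset.annotation["design_type"].astype(str).to_numpy()
    is2 = design == "II"
    if (~is2).sum() < 50 or is2.sum() < 50:
        raise ConfigurationError("need at least 50 probes of each design type for BMIQ")

    beta = dataset.beta.to_numpy().copy()
    for j, sample_id in enumerate(dataset.beta.columns):
        try:
            beta[is2, j] = _bmiq_map_sample(beta[~is2, j], beta[is2, j], tol, max_iter, seed)
        except (DegenerateDataError, ConfigurationError) as exc:
            raise DegenerateDataError(f"BMIQ mixture fit failed for sample {sample_id}: {exc}") from exc

    out = dataset.copy()
    out.beta = pd.DataFrame(beta, index=dataset.beta.index, columns=dataset.beta.columns)
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment (logit scale)
# ---------------------------------------------------------------------------


def _eb_iterate(sdat: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
                gamma_bar: float, t2: float, a_prior: float, b_prior: float,
                conv: float = 1e-4, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the EB posterior for one batch (probes in rows)."""
    n_b = sdat.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * t2 * gamma_hat + d_old * gamma_bar) / (n_b * t2 + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _adjust_one_variable(m: np.ndarray, batch: np.ndarray, protect: np.ndarray) -> np.ndarray:
    """Parametric ComBat-style adjustment of one batch variable on matrix ``m``
    (probes x samples), protecting the design columns in ``protect``."""
    levels, batch_codes = np.unique(batch, return_inverse=True)
    counts = np.bincount(batch_codes)
    if (counts < 2).any():
        bad = levels[counts < 2][0]
        raise DesignError(f"batch level {bad!r} has fewer than 2 samples")
    if len(levels) == 1:
        return m.copy()

    n = m.shape[1]
    onehot = np.zeros((n, len(levels)))
    onehot[np.arange(n), batch_codes] = 1.0
    design = np.hstack([onehot, protect])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("batch variable is perfectly confounded with the protected group")

    b_hat, *_ = np.linalg.lstsq(design, m.T, rcond=None)       # (n_lev + k) x probes
    grand_mean = (counts / n) @ b_hat[: len(levels)]           # probes
    fitted = (design @ b_hat).T
    var_pooled = ((m - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = grand_mean[:, None] + (protect @ b_hat[len(levels):]).T
    sdat = (m - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = sdat.copy()
    for lev in range(len(levels)):
        cols = batch_codes == lev
        sb = sdat[:, cols]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_bar = float(gamma_hat.mean())
        t2 = float(gamma_hat.var(ddof=1))
        dm, dv = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
        if dv <= 0:
            dv = 1e-12
        a_prior = (2 * dv + dm ** 2) / dv
        b_prior = (dm * dv + dm ** 3) / dv
        if t2 <= 0:
            gamma_star, delta_star = np.full_like(gamma_hat, gamma_bar), delta_hat
        else:
            gamma_star, delta_star = _eb_iterate(sb, gamma_hat, delta_hat,
                                                 gamma_bar, t2, a_prior, b_prior)
        adjusted[:, cols] = (sb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    return adjusted * np.sqrt(var_pooled)[:, None] + stand_mean


def batch_adjust(dataset: MethylationDataset,
                 batch_variables=("sex", "batch_id"),
                 protect: str = "group") -> MethylationDataset:
    """Sequentially remove location/scale batch effects on logit(beta).

    Each variable in ``batch_variables`` is adjusted in turn while the
    ``protect`` group contrast is retained in the standardization design.
    A variable with a single level is a no-op.
    """
    samples = dataset.samples
    for col in tuple(batch_variables) + (protect,):
        if col not in samples.columns:
            raise DesignError(f"column {col!r} not found in sample sheet")
    groups = pd.get_dummies(samples[protect], drop_first=True).to_numpy(float)

    m = logit(np.clip(dataset.beta.to_numpy(), EPS_BETA, 1 - EPS_BETA))
    for col in batch_variables:
        batch = samples[col].astype(str).to_numpy()
        m = _adjust_one_variable(m, batch, groups)

    out = dataset.copy()
    out.beta = pd.DataFrame(np.clip(expit(m), 0.0, 1.0),
                            index=dataset.beta.index, columns=dataset.beta.columns)
    return out
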