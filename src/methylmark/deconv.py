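"""Reference-based leukocyte deconvolution (constrained projection).

Each blood sample's methylation profile over a panel of cell-type
discriminating probes is modelled as a nonnegative mixture of six reference
profiles (B, CD8T, CD4T, NK, monocytes, granulocytes).  Proportions are the
nonnegative least-squares projection of the sample onto the reference matrix,
renormalized to sum to one; the raw residual norm is retained so the
projection quality is not hidden by the renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_ind

from .errors import DesignError, FormatError
from .synthetic import CELL_TYPES, MethylationDataset


@dataclass
class CellTypeReference:
    """Reference mean betas: discriminating probes x 6 cell types."""

    profiles: pd.DataFrame

    def __post_init__(self):
        if self.profiles.shape[1] != 6:
            raise FormatError(f"reference must have 6 cell-type columns, got {self.profiles.shape[1]}")
        if not self.profiles.index.is_unique:
            raise FormatError("reference probe_ids are not unique")
        vals = self.profiles.to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise FormatError("reference betas must lie in [0, 1]")

    @property
    def cell_types(self) -> list:
        return list(self.profiles.columns)

    @classmethod
    def from_tsv(cls, path) -> "CellTypeReference":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", float_format="%.6f")


@dataclass
class CellProportions:
    """Estimated mixing fractions per sample (rows sum to 1) plus fit residuals."""

    fractions: pd.DataFrame          # samples x cell types
    residual_norm: pd.Series         # per-sample ||y - R w|| before renormalization
    warnings: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["residual_norm"] = self.residual_norm
        out.to_csv(path, sep="\t", float_format="%.6f")


def estimate_proportions(dataset: MethylationDataset,
                         reference: CellTypeReference) -> CellProportions:
    """Nonnegative projection of each sample onto the reference profiles.

    Requires at least 50% of the reference probes to be present in the
    dataset; the intersection is used.  Deterministic (no randomness).
    """
    common = reference.profiles.index.intersection(dataset.beta.index)
    overlap = len(common) / len(reference.profiles.index)
    if overlap < 0.5:
        raise DesignError(
            f"only {len(common)}/{len(reference.profiles.index)} reference probes "
            f"({overlap:.1%}) present in dataset; need >= 50%"
        )
    r = reference.profiles.loc[common].to_numpy()
    recorded = []
    cond = np.linalg.cond(r)
    if cond > 1e6:
        msg = f"reference matrix poorly conditioned (cond = {cond:.3g})"
        recorded.append(msg)
        warnings.warn(msg)

    y = dataset.beta.loc[common].to_numpy()
    fracs = np.empty((dataset.n_samples, 6))
    resid = np.empty(dataset.n_samples)
    for j in range(dataset.n_samples):
        w, rnorm = nnls(r, y[:, j])
        resid[j] = rnorm
        total = w.sum()
        fracs[j] = w / total if total > 0 else np.full(6, 1 / 6)

    return CellProportions(
        fractions=pd.DataFrame(fracs, index=dataset.beta.columns, columns=reference.cell_types),
        residual_norm=pd.Series(resid, index=dataset.beta.columns, name="residual_norm"),
        warnings=recorded,
    )


def compare_composition(props: CellProportions, samples: pd.DataFrame,
                        group_col: str = "group") -> pd.DataFrame:
    """Per-cell-type two-sample Student's t-test of estimated proportions."""
    groups = samples.loc[props.fractions.index, group_col]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise DesignError(f"need exactly 2 groups, got {list(labels)}")
    a_mask = (groups == "case").to_numpy() if "case" in labels else (groups == labels[0]).to_numpy()
    if a_mask.sum() < 2 or (~a_mask).sum() < 2:
        raise DesignError("each group needs at least 2 samples")

    rows = []
    for ct in props.fractions.columns:
        x = props.fractions[ct].to_numpy()
        xa, xb = x[a_mask], x[~a_mask]
        if np.ptp(x) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = ttest_ind(xa, xb, equal_var=True)
        rows.append({"cell_type": ct, "mean_case": xa.mean(), "mean_control": xb.mean(),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("cell_type")


def reference_from_truth(truth) -> CellTypeReference:
    """Build a reference object from a generator truth record (fixture path)."""
    return CellTypeReference(truth.cell_reference[list(CELL_TYPES)])
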