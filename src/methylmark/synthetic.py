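"""Synthetic 450K-style methylation datasets with known ground truth.

The generator emulates the structure a blood-based EWAS pipeline has to cope
with: two diagnostic groups with a small set of planted differentially
methylated positions (DMPs), per-sample leukocyte mixtures over six reference
cell types, chip/batch location-scale effects, the two Infinium probe
chemistries (type II compressed toward 0.5), detection/bead-count failures,
and clinical severity scores (ADOS, ASSQ-R, IQ) separated by group.

Beta values are built in the logit domain (Gaussian probe noise and batch
shifts, then inverse-logit), which keeps them inside (0, 1) and makes the
logit-scale batch adjustment exactly invertible for recovery tests.  Planted
case/control means are placed symmetrically around 0.5 so the configured
effect size survives the logit round trip in expectation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import ConfigurationError, FormatError

CELL_TYPES = ("B", "CD8T", "CD4T", "NK", "Mono", "Gran")

#: Mean whole-blood composition (granulocyte-dominated) scaled to a Dirichlet
#: concentration of 30, i.e. moderate person-to-person variability.
DEFAULT_DIRICHLET_ALPHA = (1.5, 2.4, 4.5, 1.5, 2.1, 18.0)

#: Case/control means of the clinical scores the cohort is characterised by.
DEFAULT_CLINICAL_MEANS = {
    "ados_total": (7.0, 1.5),
    "assq_total": (28.6, 6.1),
    "iq": (110.0, 112.0),
}

_CLINICAL_SD = {"ados_total": 2.5, "assq_total": 7.0, "iq": 10.0}
_CLINICAL_BOUNDS = {"ados_total": (0.0, 26.0), "assq_total": (0.0, 54.0), "iq": (80.0, 145.0)}

SAMPLE_COLUMNS = ["group", "age", "sex", "batch_id", "iq", "ados_total", "assq_total"]
ANNOTATION_COLUMNS = ["chromosome", "design_type", "snp_flag", "cross_reactive_flag", "gene_symbol"]

EPS_BETA = 1e-6


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    ``noise_sd``, ``batch_shift_sd`` and ``batch_scale_sd`` act on the logit
    scale; ``delta_beta`` is the planted case-minus-control difference in beta
    units.  ``type2_attenuation`` < 1 compresses type-II probes toward 0.5
    (multiplicatively on the logit scale), giving BMIQ a real distortion to
    correct.
    """

    n_probes: int = 2000
    n_case: int = 30
    n_control: int = 30
    planted_dmp_count: int = 10
    delta_beta: float = 0.10
    noise_sd: float = 0.25
    dirichlet_alpha: tuple = DEFAULT_DIRICHLET_ALPHA
    batch_count: int = 2
    batch_shift_sd: float = 0.2
    batch_scale_sd: float = 0.1
    failure_rate_detection: float = 0.0005
    failure_rate_beads: float = 0.001
    clinical_means: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_MEANS))
    sex_probe_fraction: float = 0.03
    snp_probe_fraction: float = 0.02
    cross_reactive_fraction: float = 0.02
    type2_fraction: float = 0.72
    type2_attenuation: float = 0.8
    n_reference_probes: int = 120
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_probes", "n_case", "n_control", "batch_count"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.planted_dmp_count < 0:
            raise ConfigurationError("planted_dmp_count must be >= 0")
        if self.planted_dmp_count > self.n_probes:
            raise ConfigurationError("planted_dmp_count exceeds n_probes")
        if not 0.0 <= self.delta_beta <= 1.0:
            raise ConfigurationError(f"delta_beta must lie in [0, 1], got {self.delta_beta}")
        for name in (
            "failure_rate_detection",
            "failure_rate_beads",
            "sex_probe_fraction",
            "snp_probe_fraction",
            "cross_reactive_fraction",
            "type2_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if alpha.shape != (6,) or np.any(alpha <= 0):
            raise ConfigurationError("dirichlet_alpha must be a strictly positive 6-vector")
        for name in ("noise_sd", "batch_shift_sd", "batch_scale_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 < self.type2_attenuation <= 1.0:
            raise ConfigurationError("type2_attenuation must lie in (0, 1]")
        for key in ("ados_total", "assq_total", "iq"):
            if key not in self.clinical_means or len(self.clinical_means[key]) != 2:
                raise ConfigurationError(f"clinical_means must map {key!r} to (case, control) means")


@dataclass
class SampleRecord:
    """One row of the sample sheet; ``true_cell_props`` is generator-only ground truth."""

    sample_id: str
    group: str
    age: float
    sex: str
    batch_id: str
    iq: float
    ados_total: float
    assq_total: float
    true_cell_props: tuple | None = None

    def validate(self) -> None:
        if not self.group:
            raise FormatError(f"sample {self.sample_id}: empty group")
        if self.true_cell_props is not None:
            total = float(np.sum(self.true_cell_props))
            if abs(total - 1.0) > 1e-9 or np.any(np.asarray(self.true_cell_props) < 0):
                raise FormatError(
                    f"sample {self.sample_id}: cell proportions must be nonnegative and sum to 1"
                )


@dataclass
class MethylationDataset:
    """Beta matrix plus QC channels, probe annotation and sample sheet.

    ``beta``, ``detection_p`` and ``bead_count`` are probes x samples frames
    sharing index (probe_id) and columns (sample_id); ``annotation`` is indexed
    by probe_id and ``samples`` by sample_id.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def group_mask(self, group: str = "case") -> np.ndarray:
        return (self.samples["group"] == group).to_numpy()

    def sample_records(self, truth: "TruthRecord | None" = None) -> list:
        records = []
        for sid, row in self.samples.iterrows():
            props = None
            if truth is not None and sid in truth.cell_props.index:
                props = tuple(truth.cell_props.loc[sid])
            rec = SampleRecord(sample_id=str(sid), group=str(row["group"]),
                               age=float(row["age"]), sex=str(row["sex"]),
                               batch_id=str(row["batch_id"]), iq=float(row["iq"]),
                               ados_total=float(row["ados_total"]),
                               assq_total=float(row["assq_total"]),
                               true_cell_props=props)
            rec.validate()
            records.append(rec)
        return records

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            self.beta.copy(), self.detection_p.copy(), self.bead_count.copy(),
            self.annotation.copy(), self.samples.copy(),
        )

    def validate(self) -> None:
        if not self.beta.index.is_unique:
            raise FormatError("probe_ids are not unique")
        if not self.beta.columns.is_unique:
            raise FormatError("sample_ids are not unique")
        for name, frame in (("detection_p", self.detection_p), ("bead_count", self.bead_count)):
            if frame.shape != self.beta.shape:
                raise FormatError(f"{name} shape {frame.shape} does not match beta {self.beta.shape}")
            if not frame.index.equals(self.beta.index) or not frame.columns.equals(self.beta.columns):
                raise FormatError(f"{name} index/columns do not match beta")
        if not self.annotation.index.equals(self.beta.index):
            raise FormatError("annotation probe_ids do not match beta")
        if not self.samples.index.equals(self.beta.columns):
            raise FormatError("sample sheet sample_ids do not match beta columns")
        vals = self.beta.to_numpy()
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            i, j = np.argwhere((vals < 0) | (vals > 1))[0]
            raise FormatError(
                f"beta value {vals[i, j]} outside [0, 1] at probe {self.beta.index[i]}, "
                f"sample {self.beta.columns[j]}"
            )


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset (generator only)."""

    planted_probe_ids: list
    delta_beta: dict                 # probe_id -> true case-minus-control beta difference
    batch_shift: dict                # batch_id -> logit-scale location shift
    batch_scale: dict                # batch_id -> noise scale multiplier
    cell_props: pd.DataFrame         # samples x 6 true mixing proportions
    cell_reference: pd.DataFrame     # reference probes x 6 cell-type mean betas


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_dataset(config: GeneratorConfig) -> tuple[MethylationDataset, TruthRecord]:
    """Generate a dataset with planted effects; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p, nc, nt = config.n_probes, config.n_case, config.n_control
    n = nc + nt

    probe_ids = np.array([f"cg{i:08d}" for i in range(p)])
    sample_ids = np.array([f"CASE{i:03d}" for i in range(nc)] + [f"CTRL{i:03d}" for i in range(nt)])
    group = np.array(["case"] * nc + ["control"] * nt)

    # --- annotation -------------------------------------------------------
    chromosome = rng.integers(1, 23, size=p).astype(str)
    sex_mask = rng.random(p) < config.sex_probe_fraction
    chromosome[sex_mask] = rng.choice(["X", "Y"], size=int(sex_mask.sum()), p=[0.75, 0.25])
    design_type = np.where(rng.random(p) < config.type2_fraction, "II", "I")
    snp_flag = (rng.random(p) < config.snp_probe_fraction).astype(int)
    cross_flag = (rng.random(p) < config.cross_reactive_fraction).astype(int)
    gene_symbol = np.where(rng.random(p) < 0.6,
                           np.array([f"GENE{i % 997:04d}" for i in range(p)]), "")

    # --- baseline methylation states (trimodal, as on real arrays) --------
    state = rng.choice(3, size=p, p=[0.35, 0.30, 0.35])
    mu = np.empty(p)
    mu[state == 0] = rng.normal(-2.2, 0.5, size=int((state == 0).sum()))
    mu[state == 1] = rng.normal(0.0, 0.6, size=int((state == 1).sum()))
    mu[state == 2] = rng.normal(2.2, 0.5, size=int((state == 2).sum()))

    clean = (~sex_mask) & (snp_flag == 0) & (cross_flag == 0)

    # planted DMPs: clean mid-methylation probes so +delta stays in range
    planted_pool = np.flatnonzero(clean & (state == 1))
    if planted_pool.size < config.planted_dmp_count:
        planted_pool = np.flatnonzero(clean)
    if planted_pool.size < config.planted_dmp_count:
        raise ConfigurationError("planted_dmp_count: not enough clean probes to plant effects in")
    planted = np.sort(rng.choice(planted_pool, size=config.planted_dmp_count, replace=False))

    # cell-type discriminating probes: clean type-I probes, not planted
    ref_pool = np.flatnonzero(clean & (design_type == "I"))
    ref_pool = np.setdiff1d(ref_pool, planted)
    n_ref = min(config.n_reference_probes, ref_pool.size)
    ref_idx = np.sort(rng.choice(ref_pool, size=n_ref, replace=False))

    c_logit = np.tile(mu[ref_idx][:, None], (1, 6))
    for r in range(n_ref):
        k = r % 6
        sign = 1.0 if (r // 6) % 2 == 0 else -1.0
        c_logit[r, k] = mu[ref_idx[r]] + sign * 2.5
    reference_beta = expit(c_logit)

    # --- per-sample means: mix cell profiles in beta space ----------------
    weights = rng.dirichlet(np.asarray(config.dirichlet_alpha, float), size=n)  # n x 6
    mean_beta = np.tile(expit(mu)[:, None], (1, n))
    mean_beta[ref_idx, :] = reference_beta @ weights.T

    x = logit(np.clip(mean_beta, EPS_BETA, 1 - EPS_BETA))
    x[design_type == "II", :] *= config.type2_attenuation

    # planted effects, symmetric around 0.5 (overwrites after attenuation)
    if planted.size:
        x[np.ix_(planted, group == "case")] = logit(0.5 + config.delta_beta / 2)
        x[np.ix_(planted, group == "control")] = logit(0.5 - config.delta_beta / 2)

    # --- batch structure (balanced within group) and noise ----------------
    batch_ids = np.array([f"B{1 + (i % config.batch_count)}" for i in range(n)])
    batch_names = [f"B{b + 1}" for b in range(config.batch_count)]
    shift = {b: float(s) for b, s in zip(batch_names, rng.normal(0, config.batch_shift_sd, config.batch_count))}
    scale = {b: float(np.exp(s)) for b, s in zip(batch_names, rng.normal(0, config.batch_scale_sd, config.batch_count))}
    if config.batch_count == 1:
        shift = {batch_names[0]: 0.0}
        scale = {batch_names[0]: 1.0}

    shift_vec = np.array([shift[b] for b in batch_ids])
    scale_vec = np.array([scale[b] for b in batch_ids])
    eps = rng.standard_normal((p, n))
    beta = expit(x + shift_vec[None, :] + config.noise_sd * scale_vec[None, :] * eps)
    beta = np.clip(beta, EPS_BETA, 1 - EPS_BETA)

    # --- QC channels ------------------------------------------------------
    detection_p = rng.uniform(0.0, 0.005, size=(p, n))
    fail_det = rng.random((p, n)) < config.failure_rate_detection
    detection_p[fail_det] = rng.uniform(0.011, 0.8, size=int(fail_det.sum()))
    bead_count = rng.poisson(12, size=(p, n)) + 4
    fail_bead = rng.random((p, n)) < config.failure_rate_beads
    bead_count[fail_bead] = rng.integers(0, 3, size=int(fail_bead.sum()))

    # --- sample sheet -----------------------------------------------------
    age = np.round(_truncnorm(rng, 26.0, 6.0, 18.0, 55.0, n), 1)
    sex = np.where(rng.random(n) < 0.65, "M", "F")
    clinical = {}
    for key in ("iq", "ados_total", "assq_total"):
        case_mean, control_mean = config.clinical_means[key]
        sd = _CLINICAL_SD[key]
        lo, hi = _CLINICAL_BOUNDS[key]
        vals = np.empty(n)
        vals[group == "case"] = _truncnorm(rng, case_mean, sd, lo, hi, nc)
        vals[group == "control"] = _truncnorm(rng, control_mean, sd, lo, hi, nt)
        clinical[key] = np.round(vals, 1)

    samples = pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": sex,
            "batch_id": batch_ids,
            "iq": clinical["iq"],
            "ados_total": clinical["ados_total"],
            "assq_total": clinical["assq_total"],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    annotation = pd.DataFrame(
        {
            "chromosome": chromosome,
            "design_type": design_type,
            "snp_flag": snp_flag,
            "cross_reactive_flag": cross_flag,
            "gene_symbol": gene_symbol,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    index = annotation.index
    cols = samples.index
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=index, columns=cols),
        detection_p=pd.DataFrame(detection_p, index=index, columns=cols),
        bead_count=pd.DataFrame(bead_count.astype(int), index=index, columns=cols),
        annotation=annotation,
        samples=samples,
    )
    dataset.validate()

    truth = TruthRecord(
        planted_probe_ids=[str(q) for q in probe_ids[planted]],
        delta_beta={str(q): float(config.delta_beta) for q in probe_ids[planted]},
        batch_shift=shift,
        batch_scale=scale,
        cell_props=pd.DataFrame(weights, index=samples.index, columns=list(CELL_TYPES)),
        cell_reference=pd.DataFrame(
            reference_beta, index=pd.Index(probe_ids[ref_idx], name="probe_id"), columns=list(CELL_TYPES)
        ),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Tab-separated on-disk format
# ---------------------------------------------------------------------------

_MATRIX_FILES = ("beta.tsv", "detection_p.tsv", "bead_count.tsv")


def write_dataset(dataset: MethylationDataset, directory, truth: Optional[TruthRecord] = None) -> None:
    """Write the TSV file set (and optional truth sidecar) to ``directory``."""
    os.makedirs(directory, exist_ok=True)
    d = str(directory)
    dataset.beta.to_csv(os.path.join(d, "beta.tsv"), sep="\t", float_format="%.6f")
    dataset.detection_p.to_csv(os.path.join(d, "detection_p.tsv"), sep="\t", float_format="%.6f")
    dataset.bead_count.to_csv(os.path.join(d, "bead_count.tsv"), sep="\t")
    dataset.annotation.to_csv(os.path.join(d, "annotation.tsv"), sep="\t")
    dataset.samples.to_csv(os.path.join(d, "samples.tsv"), sep="\t", float_format="%.4f")
    if truth is not None:
        write_truth(truth, directory)


def write_truth(truth: TruthRecord, directory) -> None:
    payload = {
        "planted_probe_ids": list(truth.planted_probe_ids),
        "delta_beta": truth.delta_beta,
        "batch_shift": truth.batch_shift,
        "batch_scale": truth.batch_scale,
        "cell_props": truth.cell_props.round(9).to_dict(orient="index"),
        "cell_reference": truth.cell_reference.round(9).to_dict(orient="index"),
    }
    with open(os.path.join(str(directory), "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(directory) -> TruthRecord:
    path = os.path.join(str(directory), "truth.json")
    if not os.path.exists(path):
        raise FormatError(f"missing file: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    cell_props = pd.DataFrame.from_dict(payload["cell_props"], orient="index")[list(CELL_TYPES)]
    cell_props.index.name = "sample_id"
    reference = pd.DataFrame.from_dict(payload["cell_reference"], orient="index")[list(CELL_TYPES)]
    reference.index.name = "probe_id"
    return TruthRecord(
        planted_probe_ids=payload["planted_probe_ids"],
        delta_beta=payload["delta_beta"],
        batch_shift=payload["batch_shift"],
        batch_scale=payload["batch_scale"],
        cell_props=cell_props,
        cell_reference=reference,
    )


def _read_matrix(path: str, name: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"missing file: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header or ragged rows
        raise FormatError(f"{name}: malformed table ({exc})") from exc
    if frame.index.name != "probe_id":
        raise FormatError(f"{name}: first column must be 'probe_id', got {frame.index.name!r}")
    frame.columns.name = "sample_id"
    return frame


def read_dataset(directory) -> MethylationDataset:
    """Read the TSV file set written by :func:`write_dataset`, with validation."""
    d = str(directory)
    beta = _read_matrix(os.path.join(d, "beta.tsv"), "beta.tsv")
    detection_p = _read_matrix(os.path.join(d, "detection_p.tsv"), "detection_p.tsv")
    bead_count = _read_matrix(os.path.join(d, "bead_count.tsv"), "bead_count.tsv")

    vals = beta.to_numpy()
    bad = np.argwhere(~((vals >= 0.0) & (vals <= 1.0)))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"beta.tsv: value {vals[i, j]!r} outside [0, 1] at row {i + 2} "
            f"(probe {beta.index[i]}), column {j + 2} (sample {beta.columns[j]})"
        )

    ann_path = os.path.join(d, "annotation.tsv")
    if not os.path.exists(ann_path):
        raise FormatError(f"missing file: {ann_path}")
    annotation = pd.read_csv(ann_path, sep="\t", index_col=0, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise FormatError(f"annotation.tsv: missing column(s) {missing}")

    samp_path = os.path.join(d, "samples.tsv")
    if not os.path.exists(samp_path):
        raise FormatError(f"missing file: {samp_path}")
    samples = pd.read_csv(samp_path, sep="\t", index_col=0)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"samples.tsv: missing column(s) {missing}")

    dataset = MethylationDataset(
        beta=beta, detection_p=detection_p, bead_count=bead_count.astype(int),
        annotation=annotation, samples=samples,
    )
    dataset.validate()
    return dataset
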