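"""End-to-end discovery pipeline: QC -> BMIQ -> batch -> deconvolution ->
DMP calling -> random-forest + CALF marker selection -> consensus -> ROC.

Every stage derives its own seed deterministically from the global seed
(CRC32 of the stage name XORed into it), so a rerun with the same
configuration produces byte-identical output files; all report files are
written with fixed numeric formatting and no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import os
import sys
import zlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import calf as calf_mod
from . import deconv as deconv_mod
from . import dmp as dmp_mod
from . import evaluate as eval_mod
from . import forest as forest_mod
from . import preprocess as prep_mod
from .errors import ConfigurationError, StageError
from .forest import ForestConfig
from .preprocess import FilterThresholds
from .synthetic import (GeneratorConfig, MethylationDataset, TruthRecord,
                        generate_dataset, read_dataset, read_truth, write_dataset)

STAGES = ("generate", "qc", "bmiq", "batch", "deconv", "dmp", "forest", "calf", "evaluate")


@dataclass
class PipelineConfig:
    """All knobs of the discovery workflow, with the study defaults."""

    input_dir: str | None = None                 # read a dataset instead of generating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    run_bmiq: bool = True
    batch_variables: tuple = ("sex", "batch_id")
    run_deconv: bool = True
    reference_path: str | None = None            # defaults to the generator's reference
    fdr_max: float = 0.1
    delta_min: float = 0.1
    max_candidates: int = 50
    calf_limit: int = 10
    calf_metric: str = "pearson"
    n_perm: int = 2000
    n_trials: int = 2000
    subsample_fraction: float = 0.8
    min_count: int = 750
    ntree: int = 500
    mtry: int | str = "tune"
    cv_repeats: int = 3
    n_boot: int = 2000
    covariates: tuple = ("age", "sex")
    seed: int = 0
    output_dir: str = "methylmark_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "generator" in raw:
            g = dict(raw.pop("generator"))
            if "clinical_means" in g:
                g["clinical_means"] = {k: tuple(v) for k, v in g["clinical_means"].items()}
            if "dirichlet_alpha" in g:
                g["dirichlet_alpha"] = tuple(g["dirichlet_alpha"])
            kwargs["generator"] = GeneratorConfig(**g)
        if "thresholds" in raw:
            kwargs["thresholds"] = FilterThresholds(**raw.pop("thresholds"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("batch_variables", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: CRC32 of the stage name folded into the global seed."""
    return (zlib.crc32(stage.encode("utf-8")) ^ int(global_seed)) % (2 ** 31)


class _Log:
    def __init__(self, echo: bool = True):
        self.lines = []
        self.echo = echo

    def info(self, msg: str) -> None:
        self.lines.append(msg)
        if self.echo:
            print(msg, file=sys.stderr)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig, echo: bool = True) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a dict with in-memory results and the paths written.  Any stage
    failure raises :class:`StageError` after leaving a ``FAILED_<stage>``
    marker next to the partial outputs.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    log = _Log(echo=echo)
    report: dict = {"output_dir": out}
    stage = "generate"
    try:
        # ------------------------------------------------------------ input
        truth: TruthRecord | None = None
        if config.input_dir:
            dataset = read_dataset(config.input_dir)
            if os.path.exists(os.path.join(config.input_dir, "truth.json")):
                truth = read_truth(config.input_dir)
            log.info(f"[generate] read dataset from {config.input_dir}: "
                     f"{dataset.n_probes} probes x {dataset.n_samples} samples")
        else:
            gen = dataclasses.replace(config.generator,
                                      seed=stage_seed(config.seed, "generate") ^ config.generator.seed)
            dataset, truth = generate_dataset(gen)
            log.info(f"[generate] synthetic dataset: {dataset.n_probes} probes x "
                     f"{dataset.n_samples} samples, seed {gen.seed}")

        # ---------------------------------------------------------------- qc
        stage = "qc"
        dataset, filter_report = prep_mod.filter_probes(dataset, config.thresholds)
        with open(os.path.join(out, "filter_report.txt"), "w") as fh:
            fh.write(filter_report.to_text())
        with open(os.path.join(out, "filter_report.json"), "w") as fh:
            json.dump(filter_report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.info(f"[qc] retained {filter_report.retained}/{filter_report.total} probes")
        report["filter_report"] = filter_report

        # -------------------------------------------------------------- bmiq
        stage = "bmiq"
        if config.run_bmiq:
            dataset = prep_mod.bmiq_normalize(dataset, seed=stage_seed(config.seed, "bmiq"))
            log.info("[bmiq] type-II probes mapped onto type-I distribution")
        else:
            log.info("[bmiq] skipped")

        # ------------------------------------------------------------- batch
        stage = "batch"
        if config.batch_variables:
            dataset = prep_mod.batch_adjust(dataset, config.batch_variables)
            log.info(f"[batch] adjusted for {list(config.batch_variables)}")
        else:
            log.info("[batch] skipped")

        # ------------------------------------------------------------ deconv
        stage = "deconv"
        if config.run_deconv:
            reference = None
            if config.reference_path:
                reference = deconv_mod.CellTypeReference.from_tsv(config.reference_path)
            elif truth is not None:
                reference = deconv_mod.reference_from_truth(truth)
            if reference is None:
                log.info("[deconv] skipped: no reference available")
            else:
                props = deconv_mod.estimate_proportions(dataset, reference)
                props.to_tsv(os.path.join(out, "cell_props.tsv"))
                comp = deconv_mod.compare_composition(props, dataset.samples)
                comp.to_csv(os.path.join(out, "composition_tests.tsv"), sep="\t",
                            float_format="%.6g")
                log.info(f"[deconv] min composition p-value: {comp['p'].min():.3g}")
                report["cell_props"] = props
                report["composition_tests"] = comp
        else:
            log.info("[deconv] skipped")

        # --------------------------------------------------------------- dmp
        stage = "dmp"
        table = dmp_mod.dmp_table(dataset.beta, dataset.samples,
                                  fdr_max=config.fdr_max, delta_min=config.delta_min)
        table.to_csv(os.path.join(out, "dmp_table.tsv"), sep="\t", float_format="%.6g")
        selected = dmp_mod.select_dmps(table, config.fdr_max, config.delta_min)
        if len(selected) < 2:
            selected = table.assign(_pid=table.index.astype(str)).sort_values(
                ["fdr", "_pid"], kind="mergesort").drop(columns="_pid").head(20)
            log.info("[dmp] fewer than 2 probes passed thresholds; "
                     "falling back to the 20 smallest-FDR probes as candidates")
        candidates = list(selected.index[: config.max_candidates])
        log.info(f"[dmp] {int((table['pass_fdr'] & table['pass_delta']).sum())} DMPs pass "
                 f"FDR<={config.fdr_max} and |delta_beta|>={config.delta_min}; "
                 f"{len(candidates)} candidates carried forward")
        report["dmp_table"] = table
        report["candidates"] = candidates

        x_df = dataset.beta.loc[candidates].T       # samples x candidate probes
        y = (dataset.samples["group"] == "case").astype(int).to_numpy()

        # ------------------------------------------------------------ forest
        stage = "forest"
        fconfig = ForestConfig(ntree=config.ntree, mtry=config.mtry,
                               cv_repeats=config.cv_repeats,
                               seed=stage_seed(config.seed, "forest"))
        _, importance = forest_mod.grow_forest(x_df, y, fconfig)
        ranking = forest_mod.rank_importance(importance, top_k=len(candidates))
        ranking.to_csv(os.path.join(out, "mdg_ranking.tsv"), sep="\t", index=False,
                       float_format="%.6g")
        log.info(f"[forest] mtry={importance.mtry}, OOB error {importance.oob_error:.3f}, "
                 f"top MDG probe {ranking['probe_id'].iloc[0]}")
        report["forest_importance"] = importance
        report["mdg_ranking"] = ranking

        # -------------------------------------------------------------- calf
        stage = "calf"
        model = calf_mod.greedy_fit(x_df, y, limit=config.calf_limit, metric=config.calf_metric)
        perm = calf_mod.permutation_test(x_df, y, limit=config.calf_limit,
                                         metric=config.calf_metric, n_perm=config.n_perm,
                                         seed=stage_seed(config.seed, "calf-perm"))
        stability = calf_mod.stability_selection(
            x_df, y, limit=config.calf_limit, metric=config.calf_metric,
            n_trials=config.n_trials, fraction=config.subsample_fraction,
            seed=stage_seed(config.seed, "calf-stability"), min_count=config.min_count)
        consensus = calf_mod.consensus_markers(model, stability, config.min_count)
        payload = model.to_dict()
        payload["empirical_p"] = perm.p
        payload["n_perm"] = perm.n_perm
        with open(os.path.join(out, "calf_model.json"), "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        stability.counts.rename_axis("probe_id").rename("count").to_csv(
            os.path.join(out, "stability_counts.tsv"), sep="\t")
        pd.Series(consensus, name="probe_id").to_csv(
            os.path.join(out, "consensus.tsv"), sep="\t", index=False)
        log.info(f"[calf] {len(model.features)} features, metric {model.final_metric:.4f}, "
                 f"empirical p {perm.p:.2e}; {len(consensus)} consensus markers")
        report["calf_model"] = model
        report["permutation"] = perm
        report["stability"] = stability
        report["consensus"] = consensus

        # ---------------------------------------------------------- evaluate
        stage = "evaluate"
        top_marker = consensus[0] if consensus else (model.features[0][0]
                                                     if model.features else candidates[0])
        cov_df = dataset.samples[list(config.covariates)] if config.covariates else None
        eval_seed = stage_seed(config.seed, "evaluate")
        rows = []
        scores = {
            top_marker: dataset.beta.loc[top_marker].to_numpy(),
            "calf_score": model.score(x_df),
        }
        summaries = {}
        for name, score in scores.items():
            summary = eval_mod.adjusted_auc(score, y, covariates=cov_df,
                                            n_boot=config.n_boot, seed=eval_seed)
            summaries[name] = summary
            rows.append({"marker": name, **summary.to_dict()})
        roc_report = pd.DataFrame(rows).drop(columns=["notes"])
        roc_report.to_csv(os.path.join(out, "roc_report.tsv"), sep="\t", index=False,
                          float_format="%.6g")
        clinical = eval_mod.correlate_clinical(
            dataset.beta.loc[top_marker].to_numpy(),
            dataset.samples[["assq_total", "ados_total", "iq"]])
        clinical.to_csv(os.path.join(out, "clinical_correlations.tsv"), sep="\t",
                        float_format="%.6g")
        log.info(f"[evaluate] top consensus marker {top_marker}: adjusted AUC "
                 f"{summaries[top_marker].auc:.3f} "
                 f"[{summaries[top_marker].ci_low:.3f}, {summaries[top_marker].ci_high:.3f}]")
        report["roc_report"] = roc_report
        report["roc_summaries"] = summaries
        report["clinical_correlations"] = clinical
        report["top_marker"] = top_marker

        # ----------------------------------------------------------- summary
        summary_payload = {
            "top_consensus_marker": top_marker,
            "n_candidates": len(candidates),
            "n_consensus": len(consensus),
            "calf_final_metric": round(model.final_metric, 6),
            "calf_empirical_p": perm.p,
            "forest_top_probe": str(ranking["probe_id"].iloc[0]),
            "adjusted_auc": round(summaries[top_marker].auc, 6),
            "auc_ci": [round(summaries[top_marker].ci_low, 6),
                       round(summaries[top_marker].ci_high, 6)],
            "sensitivity": round(summaries[top_marker].sensitivity, 6),
            "specificity": round(summaries[top_marker].specificity, 6),
        }
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary_payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.write(os.path.join(out, "pipeline_log.txt"))
        report["summary"] = summary_payload
        return report
    except Exception as exc:
        with open(os.path.join(out, f"FAILED_{stage}"), "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        log.write(os.path.join(out, "pipeline_log.txt"))
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc


def generate_to_dir(config: GeneratorConfig, directory) -> tuple[MethylationDataset, TruthRecord]:
    """Generate a dataset and write it (with truth sidecar) to ``directory``."""
    dataset, truth = generate_dataset(config)
    write_dataset(dataset, directory, truth=truth)
    return dataset, truth
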