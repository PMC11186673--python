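"""End-to-end orchestration: simulate (optional) -> preprocess -> train ->
evaluate -> interpret, with a validated YAML config, per-stage seed fan-out,
a content-hash manifest for exact re-runs, and resumable partial state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as anno
from . import cascade, interpret, metrics, preprocess, synthdata

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "evaluate", "interpret")


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.  Unknown keys are rejected before any
    computation."""

    out_dir: str
    task: str = "multiclass"                  # binary | multiclass
    seed: int = 0
    log_level: str = "INFO"
    # input paths; when beta_path is None the simulate stage runs instead
    beta_path: str | None = None
    metadata_path: str | None = None
    blacklist_path: str | None = None
    probe_bed_path: str | None = None
    gene_tsv_path: str | None = None
    sim: dict = field(default_factory=dict)   # SimConfig overrides
    boost: dict = field(default_factory=dict)  # BoostConfig overrides
    dnn: dict = field(default_factory=dict)   # DNNConfig overrides
    test_fraction: float = 0.25
    max_missing_fraction: float = preprocess.DEFAULT_MAX_MISSING_FRACTION
    dm_alpha: float = interpret.DEFAULT_DM_ALPHA
    dm_min_abs_diff: float = interpret.DEFAULT_DM_MIN_ABS_DIFF
    promoter_bp: int = interpret.DEFAULT_PROMOTER_BP

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass"):
            raise ConfigError(f"task must be binary or multiclass, got {self.task!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must lie in (0, 1)")
        for name in ("sim", "boost", "dnn"):
            block = getattr(self, name)
            if not isinstance(block, dict):
                raise ConfigError(f"{name} block must be a mapping")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        for block, target in (("sim", synthdata.SimConfig),
                              ("boost", cascade.BoostConfig),
                              ("dnn", cascade.DNNConfig)):
            if block in raw and raw[block]:
                valid = {f.name for f in dataclasses.fields(target)}
                bad = set(raw[block]) - valid
                if bad:
                    raise ConfigError(
                        f"unknown keys in {block!r} block: {sorted(bad)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration must be a YAML mapping")
        return cls.from_dict(raw)


def _stage_seed(global_seed: int, stage: str) -> int:
    import zlib
    return int(np.random.SeedSequence(
        [int(global_seed) % 2**31, zlib.crc32(stage.encode())]).generate_state(1)[0]
    ) % 2**31


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute the workflow; returns the run directory.

    Stage outputs are persisted as they complete; on failure the exception
    names the stage and completed outputs stay on disk, so a re-run with
    ``resume=True`` continues from the first incomplete stage.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    state_path = run_dir / "state.json"
    state = {"completed": []}
    if resume and state_path.exists():
        with open(state_path) as fh:
            state = json.load(fh)

    ctx: dict = {}
    for stage in STAGES:
        if stage in state["completed"]:
            logger.info("stage %s already complete; reloading outputs", stage)
            _reload_stage(stage, config, run_dir, ctx)
            continue
        try:
            _run_stage(stage, config, run_dir, ctx)
        except Exception as err:  # noqa: BLE001 - re-raised with stage context
            _write_json({**state, "failed_stage": stage}, state_path)
            raise PipelineStageError(stage, err) from err
        state["completed"].append(stage)
        _write_json(state, state_path)

    manifest = {
        "config": {**dataclasses.asdict(config)},
        "seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "outputs": {str(p.relative_to(run_dir)): _sha256(p)
                    for p in sorted(run_dir.rglob("*"))
                    if p.is_file() and p.name != "manifest.json"},
    }
    _write_json(manifest, run_dir / "manifest.json")
    return run_dir


def _run_stage(stage: str, config: RunConfig, run_dir: Path, ctx: dict) -> None:
    seed = _stage_seed(config.seed, stage)
    if stage == "simulate":
        if config.beta_path is not None:
            ctx["beta"] = preprocess.read_beta_tsv(config.beta_path)
            ctx["metadata"] = pd.read_csv(config.metadata_path, sep="\t",
                                          index_col="sample_id")
            if config.probe_bed_path:
                probes = anno.read_probe_bed(config.probe_bed_path)
                genes = (anno.read_gene_tsv(config.gene_tsv_path)
                         if config.gene_tsv_path else None)
                ctx["annotation"] = anno.GenomicAnnotation(
                    probes=probes,
                    genes=genes if genes is not None else
                    pd.DataFrame(columns=anno.GENE_COLUMNS))
            return
        sim_config = synthdata.SimConfig(**{"seed": seed, **config.sim})
        cohort = synthdata.simulate_cohort(sim_config)
        annotation, truth = synthdata.simulate_annotation(sim_config)
        data_dir = run_dir / "data"
        synthdata.write_cohort(cohort, data_dir)
        anno.write_probe_bed(annotation.probes, data_dir / "probes.bed")
        anno.write_gene_tsv(annotation.genes, data_dir / "genes.tsv")
        truth.to_csv(data_dir / "probe_gene_truth.tsv", sep="\t", index=False)
        ctx.update(beta=cohort.beta, metadata=cohort.metadata,
                   annotation=annotation, cohort=cohort)
    elif stage == "preprocess":
        blacklist = (preprocess.read_blacklist(config.blacklist_path)
                     if config.blacklist_path else set())
        filtered, report = preprocess.filter_probes(
            ctx["beta"], blacklist, ctx.get("annotation"),
            max_missing_fraction=config.max_missing_fraction)
        if filtered.isna().to_numpy().any():
            filtered = preprocess.impute_knn(filtered)
        m = preprocess.beta_to_m(filtered)
        preprocess.write_matrix_tsv(m, run_dir / "m_values.tsv")
        _write_json(report.to_dict(), run_dir / "filter_report.json")
        ctx["m_values"] = m
    elif stage == "train":
        labels = cascade.labels_for_task(ctx["metadata"], config.task)
        dataset = cascade.LabeledDataset(ctx["m_values"], labels)
        dataset = cascade.split_train_test(dataset, config.test_fraction, seed)
        default = (cascade.BoostConfig.binary_default if config.task == "binary"
                   else cascade.BoostConfig.multiclass_default)(seed)
        boost_config = dataclasses.replace(default, **config.boost)
        dnn_config = cascade.DNNConfig(**{"seed": seed, **config.dnn})
        model = cascade.train_cascade(dataset, boost_config, dnn_config)
        cascade.save_model(model, run_dir / "model")
        dataset.split.to_csv(run_dir / "split_assignment.tsv", sep="\t",
                             header=["split"], index_label="sample_id")
        ctx.update(dataset=dataset, model=model)
    elif stage == "evaluate":
        report = metrics.evaluate(ctx["model"], ctx["dataset"])
        report.to_json(run_dir / "report.json")
        boost_report = metrics.evaluate(ctx["model"].boost_stage, ctx["dataset"])
        boost_report.to_json(run_dir / "boost_report.json")
        ctx["report"] = report
    elif stage == "interpret":
        model = ctx["model"]
        ranked = interpret.rank_importances(model.selected)
        ranked.to_csv(run_dir / "importances.tsv", sep="\t", index=False)
        annotation = ctx.get("annotation")
        if annotation is not None and len(annotation.genes):
            pg = interpret.map_probes_to_genes(model.selected.probe_ids,
                                               annotation,
                                               promoter_bp=config.promoter_bp)
            pg.table.to_csv(run_dir / "probe_gene_map.tsv", sep="\t", index=False)
        condition = ctx["metadata"]["condition"]
        if {"cancer", "normal"} <= set(condition):
            dm = interpret.differential_methylation(
                ctx["m_values"], condition, alpha=config.dm_alpha,
                min_abs_diff=config.dm_min_abs_diff)
            dm.table.to_csv(run_dir / "differential_methylation.tsv", sep="\t",
                            index_label="probe_id")
    else:  # pragma: no cover
        raise ConfigError(f"unknown stage {stage}")


def _reload_stage(stage: str, config: RunConfig, run_dir: Path, ctx: dict) -> None:
    """Rebuild in-memory context from a completed stage's persisted outputs."""
    if stage == "simulate":
        data_dir = run_dir / "data"
        if config.beta_path is not None:
            _run_stage("simulate", config, run_dir, ctx)  # pure input loading
            return
        ctx["beta"] = preprocess.read_beta_tsv(data_dir / "beta.tsv")
        ctx["metadata"] = pd.read_csv(data_dir / "metadata.tsv", sep="\t",
                                      index_col="sample_id")
        ctx["annotation"] = anno.GenomicAnnotation(
            probes=anno.read_probe_bed(data_dir / "probes.bed"),
            genes=anno.read_gene_tsv(data_dir / "genes.tsv"))
    elif stage == "preprocess":
        ctx["m_values"] = preprocess.read_beta_tsv(run_dir / "m_values.tsv")
    elif stage == "train":
        ctx["model"] = cascade.load_model(run_dir / "model")
        split = pd.read_csv(run_dir / "split_assignment.tsv", sep="\t",
                            index_col="sample_id")["split"]
        labels = cascade.labels_for_task(ctx["metadata"], config.task)
        ctx["dataset"] = cascade.LabeledDataset(ctx["m_values"], labels, split)
    # evaluate / interpret write files only; nothing to reload
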