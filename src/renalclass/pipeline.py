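"""End-to-end pipeline: wire the stages together with one config and seed.

Stage order: simulate (or load) -> filter -> cluster / sam / nsc / cgma on
expression; cn-call -> cna on copy number; enrich on the SAM-called genes;
fisher on the marker tables. Each stage writes its outputs under
``out_dir`` and registers them (with SHA-256 hashes and row counts) in a
run manifest, so a rerun with the same config and seed is byte-identical
apart from nothing: no timestamps are written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cgma import cohort_bias_summary, regional_bias, relative_expression
from .cnv import call_cn_segments, cna_regions, cnv_cohort_profile
from .enrichment import enrich_collection, default_universe
from .exact_tests import IHC_MARKER_TABLES, ihc_batch
from .io import (
    ContingencyTable2x2,
    read_cn_matrix,
    read_expression_matrix,
    read_gene_sets_gmt,
    read_probe_annotation,
    read_snp_annotation,
    write_cn_calls_bed,
    write_cn_matrix,
    write_expression_matrix,
    write_probe_annotation,
    write_snp_annotation,
)
from .nsc import nsc_cross_validate, nsc_select_threshold, nsc_train
from .preprocess import FilterSpec, cut_tree, filter_probes, hierarchical_cluster
from .sam import fold_changes, sam_call, sam_fit
from .simulate import SimulationConfig, simulate_cn, simulate_expression

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "cluster", "sam", "nsc", "cgma", "cnv", "enrich", "fisher")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    stages: tuple = ("simulate", "filter", "cluster", "sam", "nsc", "cgma", "cnv", "fisher")
    # inputs (ignored for stages fed by `simulate`)
    expression_path: str | None = None
    labels_path: str | None = None
    normals_path: str | None = None
    annotation_path: str | None = None
    cn_path: str | None = None
    cohorts_path: str | None = None
    snp_annotation_path: str | None = None
    gmt_path: str | None = None
    relations_path: str | None = None
    fisher_tables_path: str | None = None
    # stage parameters
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    cluster_metric: str = "correlation"
    sam_n_perm: int = 200
    sam_delta: float = 1.4
    nsc_folds: int = 10
    nsc_thresholds: int = 100
    nsc_offset_percentile: float = 30.0
    nsc_max_error: float = 0.10
    cgma_z_threshold: float = 1.96
    cgma_min_genes: int = 10
    cnv_loss_cut: float = 1.6
    cnv_gain_cut: float = 3.5
    cnv_min_run: int = 4
    cnv_min_fraction: float = 0.30
    enrich_p_threshold: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if "filter_spec" in raw:
            raw["filter_spec"] = FilterSpec(**raw["filter_spec"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needs_expression = {"filter", "cluster", "sam", "nsc", "cgma"} & set(self.stages)
        if needs_expression and "simulate" not in self.stages:
            for p in (self.expression_path, self.labels_path, self.annotation_path):
                if p is None:
                    raise ValueError("expression stages enabled without simulate: "
                                     "expression_path, labels_path and annotation_path required")
            for p in (self.expression_path, self.labels_path, self.annotation_path):
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        if "cnv" in self.stages and "simulate" not in self.stages:
            for p in (self.cn_path, self.snp_annotation_path):
                if p is None or not Path(p).exists():
                    raise ValueError("cnv stage requires existing cn_path and snp_annotation_path")
        if "enrich" in self.stages:
            if self.gmt_path is None or not Path(self.gmt_path).exists():
                raise ValueError("enrich stage requires an existing gmt_path")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict (also written
    to ``out_dir/manifest.json``). Any stage failure raises
    :class:`PipelineError` naming the stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {},
    }

    def register(name: str, path: Path, n_rows: int | None = None) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
            **({"n_rows": n_rows} if n_rows is not None else {}),
        }

    tumors = normals = annotation = None
    cn = snp_annotation = None
    truth = None

    def stage(name):
        return name in config.stages

    try:
        if stage("simulate"):
            tumors, normals, annotation, truth = simulate_expression(config.simulation, config.seed)
            cn, snp_annotation, cn_truth = simulate_cn(config.simulation, config.seed)
            truth.cn_segments = cn_truth.cn_segments
            write_expression_matrix(tumors, out / "expression.tsv", out / "labels.tsv")
            write_expression_matrix(normals, out / "normals.tsv")
            write_probe_annotation(annotation, out / "probe_annotation.tsv")
            write_cn_matrix(cn, out / "cn_matrix.tsv", out / "cn_cohorts.tsv")
            write_snp_annotation(snp_annotation, out / "snp_annotation.tsv")
            truth.to_json(out / "truth_ledger.json")
            register("expression", out / "expression.tsv", tumors.n_probes)
            register("normals", out / "normals.tsv", normals.n_probes)
            register("probe_annotation", out / "probe_annotation.tsv", len(annotation.table))
            register("cn_matrix", out / "cn_matrix.tsv", len(cn.values))
            register("snp_annotation", out / "snp_annotation.tsv", len(snp_annotation.table))
            register("truth_ledger", out / "truth_ledger.json")
        else:
            if config.expression_path:
                tumors = read_expression_matrix(config.expression_path, config.labels_path)
            if config.normals_path:
                normals = read_expression_matrix(config.normals_path)
            if config.annotation_path:
                annotation = read_probe_annotation(config.annotation_path)
            if config.cn_path:
                cn = read_cn_matrix(config.cn_path, config.cohorts_path)
            if config.snp_annotation_path:
                snp_annotation = read_snp_annotation(config.snp_annotation_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    filtered = tumors
    if stage("filter"):
        try:
            filtered = filter_probes(tumors, config.filter_spec)
            write_expression_matrix(filtered, out / "filtered.tsv")
            register("filtered", out / "filtered.tsv", filtered.n_probes)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("filter", e) from e

    if stage("cluster"):
        try:
            dend = hierarchical_cluster(filtered, metric=config.cluster_metric)
            clusters = cut_tree(dend, k=2)
            (out / "dendrogram.json").write_text(
                json.dumps(
                    {
                        "merges": dend.merges.tolist(),
                        "heights": dend.heights.tolist(),
                        "leaf_order": dend.leaf_order.tolist(),
                        "samples": dend.sample_ids,
                    },
                    indent=2,
                )
            )
            (out / "dendrogram.newick").write_text(dend.to_newick() + "\n")
            clusters.to_csv(out / "clusters.tsv", sep="\t", header=False)
            register("dendrogram", out / "dendrogram.json")
            register("newick", out / "dendrogram.newick")
            register("clusters", out / "clusters.tsv", len(clusters))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cluster", e) from e

    sam_result = None
    if stage("sam"):
        try:
            fit = sam_fit(tumors, n_perm=config.sam_n_perm, seed=config.seed)
            call = sam_call(fit, config.sam_delta)
            fc = fold_changes(tumors)
            called_set = set(call.called_ids)
            table = pd.DataFrame(
                {
                    "probe_id": fit.probe_ids,
                    "d": fit.d,
                    "s": fit.s,
                    "fold_change": fc.to_numpy(),
                    "called": [p in called_set for p in fit.probe_ids],
                    "direction": ["up" if x > 0 else "down" for x in fit.d],
                }
            )
            table.to_csv(out / "sam.tsv", sep="\t", index=False)
            summary = {
                "delta": call.delta,
                "n_called": call.n_called,
                "false_calls": call.false_calls,
                "fdr": call.fdr,
                "s0": fit.s0,
                "n_perm": fit.n_perm,
            }
            (out / "sam_summary.json").write_text(json.dumps(summary, indent=2))
            register("sam", out / "sam.tsv", len(table))
            register("sam_summary", out / "sam_summary.json")
            sam_result = (fit, call, table)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("sam", e) from e

    if stage("nsc"):
        try:
            model = nsc_train(tumors, s0_percentile=config.nsc_offset_percentile,
                              n_thresholds=config.nsc_thresholds)
            curve = nsc_cross_validate(
                tumors,
                n_folds=config.nsc_folds,
                n_thresholds=config.nsc_thresholds,
                seed=config.seed,
                s0_percentile=config.nsc_offset_percentile,
            )
            threshold, size = nsc_select_threshold(curve, config.nsc_max_error)
            survivors = model.survivors(threshold)
            predictor = [p for p, s in zip(model.probe_ids_, survivors) if s]
            payload = {
                "threshold": threshold,
                "expected_size": size,
                "predictor_probes": predictor,
                "s0": model.s0_,
                "cv_errors": curve.errors.tolist(),
                "cv_thresholds": curve.thresholds.tolist(),
                "cv_mean_survivors": curve.mean_survivors.tolist(),
                "folds": curve.fold_assignment.to_dict(),
            }
            (out / "nsc_model.json").write_text(json.dumps(payload, indent=2))
            register("nsc_model", out / "nsc_model.json")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("nsc", e) from e

    if stage("cgma"):
        try:
            R = relative_expression(tumors, normals)
            bias = regional_bias(R, annotation, config.cgma_z_threshold, config.cgma_min_genes)
            summary = cohort_bias_summary(bias, tumors.labels)
            bias.to_csv(out / "cgma_bias.tsv", sep="\t", index=False)
            summary.to_csv(out / "cgma_summary.tsv", sep="\t", index=False)
            register("cgma_bias", out / "cgma_bias.tsv", len(bias))
            register("cgma_summary", out / "cgma_summary.tsv", len(summary))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cgma", e) from e

    if stage("cnv"):
        try:
            calls = call_cn_segments(cn, snp_annotation, config.cnv_loss_cut,
                                     config.cnv_gain_cut, config.cnv_min_run)
            write_cn_calls_bed(calls, out / "cn_calls.bed")
            region_rows = []
            for cohort in sorted(cn.cohorts.unique()):
                samples = list(cn.cohorts.index[cn.cohorts == cohort])
                regions = cna_regions(calls, samples, snp_annotation,
                                      config.cnv_min_fraction, config.cnv_min_run, cohort)
                region_rows.extend(dataclasses.asdict(r) for r in regions)
            pd.DataFrame(region_rows).to_csv(out / "cna_regions.tsv", sep="\t", index=False)
            register("cn_calls", out / "cn_calls.bed", len(calls))
            register("cna_regions", out / "cna_regions.tsv", len(region_rows))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cnv", e) from e

    if stage("enrich"):
        try:
            collection = read_gene_sets_gmt(config.gmt_path, config.relations_path)
            if sam_result is None:
                raise ValueError("enrich stage requires the sam stage")
            _, call, table = sam_result
            probe2gene = annotation.table.set_index("probe_id")["gene_symbol"]
            array_genes = set(probe2gene)
            universe = default_universe(collection, array_genes)
            called_genes = {probe2gene[p] for p in call.called_ids if p in probe2gene.index}
            selected = called_genes & universe
            result = enrich_collection(selected, collection, universe, config.enrich_p_threshold)
            result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            register("enrichment", out / "enrichment.tsv", len(result))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("enrich", e) from e

    if stage("fisher"):
        try:
            if config.fisher_tables_path:
                raw = pd.read_csv(config.fisher_tables_path, sep="\t")
                tables = {
                    row["marker"]: ContingencyTable2x2(row["a"], row["b"], row["c"], row["d"])
                    for _, row in raw.iterrows()
                }
            else:
                tables = IHC_MARKER_TABLES
            result = ihc_batch(tables)
            result.to_csv(out / "fisher.tsv", sep="\t", index=False)
            register("fisher", out / "fisher.tsv", len(result))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("fisher", e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
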