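"""End-to-end orchestration: ingest/simulate -> normalize -> signatures ->
classical-vs-variant contrast -> fold-change correlation -> clustering ->
optional enrichment, with a manifest recording provenance of every output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import heatmap_export, hierarchical_cluster
from .deconv_de import (DEError, FilterCriteria, compare_chcl_vhcl,
                        derive_signatures, fold_change_correlation)
from .enrichment import hypergeometric_enrich, read_gmt
from .normalization import NormalizationConfig, normalize_pipeline
from .panel_io import read_count_table, read_sample_metadata, write_results
from .synthetic_data import (ExperimentDesign, simulate_experiment,
                             truth_recovery_report, write_simulation)

logger = logging.getLogger("hclsig")

#: Fixed per-stage seed offsets: adding a stage never perturbs earlier stages.
STAGE_SEED_OFFSETS = {"simulate": 0, "gsea": 1000}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full-run configuration; exactly one of counts-path or simulation set."""

    counts_path: str | None = None
    metadata_path: str | None = None
    counts_dialect: str = "tsv_matrix"
    simulation: ExperimentDesign | None = None
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    under_reference: str = "nB"
    cluster_genes: str = "all"  # all | bcell | signature
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    gmt_path: str | None = None
    out_dir: str = "hclsig_out"
    seed: int = 0
    make_heatmap: bool = True

    def __post_init__(self) -> None:
        has_real = self.counts_path is not None
        has_sim = self.simulation is not None
        if has_real == has_sim:
            raise ValueError(
                "config must set exactly one of counts_path or simulation"
            )
        if has_real and self.metadata_path is None:
            raise ValueError("real input needs a metadata_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            raw["simulation"] = ExperimentDesign(**sim) if isinstance(sim, dict) \
                else ExperimentDesign()
        if "normalization" in raw:
            nc = dict(raw["normalization"])
            if "housekeeping_genes" in nc:
                nc["housekeeping_genes"] = tuple(nc["housekeeping_genes"])
            raw["normalization"] = NormalizationConfig(**nc)
        if "criteria" in raw:
            raw["criteria"] = FilterCriteria(**raw["criteria"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output dir excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute the whole pipeline; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        start = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - start, 4), **info}
        return done

    def record(paths):
        for p in (paths.values() if isinstance(paths, dict) else [paths]):
            manifest["outputs"].append(str(Path(p).relative_to(out_dir)))

    truth = None
    try:
        done = stage("input")
        if config.simulation is not None:
            design = dataclasses.replace(
                config.simulation,
                seed=config.seed + STAGE_SEED_OFFSETS["simulate"])
            cm, truth = simulate_experiment(design)
            record(write_simulation(cm, truth, out_dir / "simulated"))
            done(mode="simulated", lanes=len(cm.lanes))
        else:
            cm = read_count_table(config.counts_path, config.counts_dialect)
            meta = read_sample_metadata(config.metadata_path, lanes=cm.lanes)
            cm.attach_metadata(meta)
            done(mode="real", lanes=len(cm.lanes))
    except Exception as e:  # noqa: BLE001 - abort with stage name
        raise PipelineError("input", e) from e

    try:
        done = stage("normalize")
        norm, factors = normalize_pipeline(cm, config.normalization)
        record(write_results({"normalized_counts": norm}, out_dir))
        factors.table.to_csv(out_dir / "lane_factors.tsv", sep="\t",
                             float_format="%.17g")
        record(out_dir / "lane_factors.tsv")
        done()
    except Exception as e:
        raise PipelineError("normalize", e) from e

    try:
        done = stage("signatures")
        sets = derive_signatures(norm, config.criteria,
                                 under_reference=config.under_reference)
        record(write_results({"signatures": sets}, out_dir))
        venn = sets.venn_counts()
        (out_dir / "venn_counts.json").write_text(
            json.dumps(venn, indent=2, sort_keys=True) + "\n")
        record(out_dir / "venn_counts.json")
        done(**venn)
        manifest["venn_counts"] = venn
    except Exception as e:
        raise PipelineError("signatures", e) from e

    try:
        done = stage("chcl_vhcl")
        result, over, under = compare_chcl_vhcl(norm, config.criteria)
        record(write_results({"chcl_vs_vhcl": result}, out_dir))
        done(n_chcl_over=len(over), n_vhcl_over=len(under))
    except DEError as e:
        logger.warning("cHCL/vHCL stage skipped: %s", e)
        manifest["stages"]["chcl_vhcl"] = {"skipped": str(e)}
    except Exception as e:
        raise PipelineError("chcl_vhcl", e) from e

    try:
        done = stage("fc_correlation")
        corr = fold_change_correlation(norm, "cHCL", "vHCL", "nB", config.criteria)
        (out_dir / "fc_correlation.json").write_text(
            json.dumps(corr, indent=2, sort_keys=True) + "\n")
        record(out_dir / "fc_correlation.json")
        done(**corr)
        manifest["fc_correlation"] = corr
    except DEError as e:
        logger.warning("fold-change correlation skipped: %s", e)
        manifest["stages"]["fc_correlation"] = {"skipped": str(e)}
    except Exception as e:
        raise PipelineError("fc_correlation", e) from e

    try:
        done = stage("clustering")
        subset = None
        if config.cluster_genes == "bcell":
            subset = sets.bcell_specific or None
        elif config.cluster_genes == "signature":
            subset = sets.hcl_signature or None
        cres = hierarchical_cluster(norm, subset, config.cluster_distance,
                                    config.cluster_linkage)
        if config.make_heatmap:
            img, tsv = heatmap_export(norm, cres, out_dir / "heatmap.png")
            record(img), record(tsv)
        done(group_purity=cres.group_purity)
        manifest["group_purity"] = cres.group_purity
    except Exception as e:
        raise PipelineError("clustering", e) from e

    if config.gmt_path:
        try:
            done = stage("enrichment")
            coll = read_gmt(config.gmt_path)
            universe = set(norm.panel.table.loc[norm.panel.endogenous,
                                                "gene_symbol"].str.upper())
            query = {g.upper() for g in sets.hcl_signature} or None
            if query:
                enr = hypergeometric_enrich(query, coll, universe)
                enr.to_csv(out_dir / "enrichment.tsv", sep="\t",
                           float_format="%.6g")
                record(out_dir / "enrichment.tsv")
                done(n_terms=len(enr))
            else:
                done(skipped="empty signature")
        except Exception as e:
            raise PipelineError("enrichment", e) from e

    if truth is not None:
        recovery = truth_recovery_report(truth, sets)
        manifest["recovery"] = recovery

    manifest_path = out_dir / "manifest.json"
    manifest["outputs"].append("manifest.json")
    manifest["outputs"] = sorted(set(manifest["outputs"]))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
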