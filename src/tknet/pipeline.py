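"""End-to-end orchestration: simulate -> diff -> concord -> mediate -> network -> rank.

A run is driven by a YAML config (all keys optional except where noted;
unknown keys are rejected and every validation problem is reported at once,
not first-failure). Stage outputs are written as TSV under the output
directory, and a machine-readable JSON run report records stage timings,
SHA-256 digests of every written file, stage counts, the top candidates,
and the resolved configuration — rerunning the same config reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import abundance, mediators, network, ranking, simulate, tables
from .errors import ConfigError

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


class Thresholds(BaseModel):
    """Decision thresholds, defaulting to the pipeline's standard values."""

    model_config = ConfigDict(extra="forbid")

    fdr: float = Field(default=0.1, gt=0.0, lt=1.0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    p_ind: float = Field(default=0.3, gt=0.0, lt=1.0)
    p_comb: float = Field(default=0.01, gt=0.0, lt=1.0)
    min_abund: float = Field(default=0.01, ge=0.0, lt=1.0)


class SimulationSection(BaseModel):
    """Overrides for :class:`tknet.simulate.SimulationConfig` (seed comes
    from the top level)."""

    model_config = ConfigDict(extra="forbid")

    n_taxa: int = Field(default=200, ge=2)
    n_samples_per_group: int = Field(default=10, ge=2)
    n_regulated_taxa: int = Field(default=20, ge=1)
    regulation_fold: float = Field(default=5.0, ge=1.0)
    mediator_baseline: float = Field(default=0.10, gt=0.0, lt=1.0)
    mediator_effect: float = -50.0
    phenotype_baseline: float = 100.0
    phenotype_noise: float = Field(default=5.0, gt=0.0)
    auc_scale: float = Field(default=300.0, gt=0.0)
    taxon_dispersion: float = Field(default=0.7, gt=0.0)
    mediator_dispersion: float = Field(default=0.7, gt=0.0)
    library_size: int = Field(default=50_000, ge=1)
    n_genes: int = Field(default=200, ge=2)
    regulator_microbe_coupling: float = Field(default=-0.8, gt=-1.0, lt=0.0)
    regulator_module_loading: float = Field(default=0.82, gt=0.0, lt=1.0)


class PipelineConfig(BaseModel):
    """Validated top-level run configuration."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    method: str = "spearman"  # mediator-screen correlation method
    thresholds: Thresholds = Field(default_factory=Thresholds)
    simulation: SimulationSection = Field(default_factory=SimulationSection)

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(seed=self.seed, **self.simulation.model_dump())


def validate_config(config_path) -> PipelineConfig:
    """Load and validate a YAML config.

    An empty file yields the all-defaults configuration. Unknown keys, type
    mismatches and out-of-range thresholds are collected exhaustively into a
    single :class:`ConfigError`.
    """
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(x) for x in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _truth_frame(truth: simulate.GroundTruth) -> pd.DataFrame:
    rows = [
        {"kind": "mediator_taxon", "id": truth.mediator_taxon, "value": ""},
        {"kind": "regulator_gene", "id": truth.regulator_gene, "value": ""},
    ]
    for taxon, direction in sorted((truth.regulated_taxa or {}).items()):
        rows.append({"kind": "regulated_taxon", "id": taxon, "value": str(direction)})
    for name, members in sorted((truth.module_members or {}).items()):
        for gene in members:
            rows.append({"kind": name, "id": gene, "value": ""})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | str | Path, outdir) -> dict:
    """Execute every stage on a synthetic dataset and write all artifacts.

    Returns the run report (also serialized to ``report.json`` in
    ``outdir``).
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    cfg = config.simulation_config()
    report: dict = {
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
        "files": {},
        "counts": {},
    }

    def _stage(name):
        report["stages"][name] = {"started": time.time()}

    def _done(name):
        st = report["stages"][name]
        st["seconds"] = round(time.time() - st.pop("started"), 4)

    def _write_table(name, ft):
        path = outdir / name
        tables.write_feature_table(ft, path)
        report["files"][name] = _sha256(path)

    def _write_records(name, df):
        path = outdir / name
        tables.write_records(df, path)
        report["files"][name] = _sha256(path)

    # -- simulate ---------------------------------------------------------
    _stage("simulate")
    counts_a, counts_b, meta, truth_mb = simulate.simulate_microbiome_experiments(cfg)
    expr_groups, microbe_by_group, lfc, truth = simulate.simulate_expression_groups(
        cfg, truth_mb
    )
    _write_table("exp_a_counts.tsv", counts_a)
    _write_table("exp_b_counts.tsv", counts_b)
    _write_records("metadata.tsv", meta.reset_index())
    for i, eg in enumerate(expr_groups):
        _write_records(f"expr_strain_{i + 1}.tsv", eg.reset_index())
    _write_records(
        "microbe_abundance.tsv",
        pd.concat(microbe_by_group).rename_axis("sample_id").reset_index(),
    )
    _write_records("fold_changes.tsv", lfc.reset_index())
    _write_records("truth.tsv", _truth_frame(truth))
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True)
    )
    report["files"]["config_resolved.yaml"] = _sha256(outdir / "config_resolved.yaml")
    _done("simulate")

    # -- differential abundance ------------------------------------------
    _stage("diff")
    rel_a = abundance.to_relative_abundance(counts_a)
    rel_b = abundance.to_relative_abundance(counts_b)
    diff_a = abundance.differential_features(rel_a, meta, "perturbed", "control")
    diff_b = abundance.differential_features(rel_b, meta, "perturbed", "control")
    _write_records("diff_exp_a.tsv", diff_a)
    _write_records("diff_exp_b.tsv", diff_b)
    report["counts"]["features_tested"] = int(diff_a["testable"].sum())
    _done("diff")

    # -- concordance ------------------------------------------------------
    _stage("concord")
    concord = abundance.concordant_features(diff_a, diff_b, fdr=th.fdr)
    _write_records("concordant.tsv", concord)
    report["counts"]["concordant_features"] = int(concord["concordant"].sum())
    _done("concord")

    # -- mediator screen --------------------------------------------------
    _stage("mediate")
    pert_meta = meta[meta["group"] == "perturbed"]
    pert_rel = pd.concat(
        [rel_a.values[[s for s in rel_a.sample_ids if s in pert_meta.index]],
         rel_b.values[[s for s in rel_b.sample_ids if s in pert_meta.index]]],
        axis=1,
    )
    pooled = tables.FeatureTable(values=pert_rel, kind="relative")
    candidates_in = concord.loc[concord["concordant"], "feature_id"].tolist()
    corr = mediators.phenotype_correlations(
        pooled,
        pert_meta,
        candidates_in,
        ["fasting_glucose", "auc_gtt"],
        method=config.method,
        forbid_groups=("control",),
    )
    nominated = mediators.nominate_mediators(concord, corr, alpha=th.alpha)
    _write_records("phenotype_correlations.tsv", corr)
    _write_records("mediator_candidates.tsv", nominated)
    n_cand = (
        int((nominated["classification"] != "not_candidate").sum())
        if len(nominated)
        else 0
    )
    report["counts"]["mediator_candidates"] = n_cand
    report["top_mediators"] = (
        nominated.loc[
            nominated["classification"] != "not_candidate", "feature_id"
        ]
        .head(5)
        .tolist()
        if len(nominated)
        else []
    )
    _done("mediate")

    # -- gene network -----------------------------------------------------
    _stage("network")
    g, net_summary = network.build_network(
        expr_groups, lfc, p_ind=th.p_ind, p_comb=th.p_comb
    )
    _write_records("network_nodes.tsv", network.node_table(g))
    _write_records("network_edges.tsv", network.edge_table(g))
    report["counts"].update(
        {
            "network_members": net_summary["n_members"],
            "network_edges": net_summary["n_edges"],
        }
    )
    report["network_membership_fraction"] = round(
        net_summary["membership_fraction"], 4
    )
    _done("network")

    # -- regulator ranking ------------------------------------------------
    _stage("rank")
    ranked = ranking.prioritize_regulators(
        g, expr_groups, [m.to_numpy() for m in microbe_by_group], lfc
    )
    _write_records("regulator_ranking.tsv", ranked)
    report["counts"]["genes_ranked"] = len(ranked)
    report["top_regulators"] = ranked["gene_id"].head(5).tolist()
    _done("rank")

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
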