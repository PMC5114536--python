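"""Synthetic coupled microbiome / phenotype / expression data with planted truth.

The generator emulates the two study designs the pipeline analyses, at desk
scale, with every causal ingredient planted and recorded so each inference
stage has a recoverable answer:

* **Two two-group microbiome perturbation experiments** sharing one taxon
  pool. Counts follow a logistic-normal–multinomial composition model:
  per-sample log abundances are the log baseline plus taxon-specific
  Gaussian noise, closed to proportions, then multinomially sampled at a
  fixed library size. A set of regulated taxa has its baseline multiplied by
  ``regulation_fold`` (per-taxon direction) in the perturbed group of *both*
  experiments. One regulated taxon — the planted mediator, emulating an
  abundant mucin-degrading species that blooms when the factor is removed —
  causally drives the phenotypes: for every perturbed-group sample,
  fasting glucose = beta0 + beta1 * (mediator proportion) + N(0, sigma),
  and AUC-GTT is the same construction on its own scale. Phenotypes exist
  only for perturbed-group samples, matching the within-knockout
  correlation design.

* **k expression groups** (different genetic backgrounds) with a modular
  log-scale latent-factor structure: genes of a module load on a shared
  per-group factor, giving sign-consistent within-module correlation across
  groups. A planted regulator gene belongs to exactly one module, is coupled
  to the per-sample microbe abundance with a negative target correlation
  (``rho_target``), carries the largest |log10 fold change|, and — because
  its module loading is weaker than its peers' — sits peripherally in the
  reconstructed network. Fold changes are assigned per module sign so that
  planted edges satisfy the fold-change consistency rule.

Randomness: one independent RNG stream per logical component (taxa,
phenotype, expression), each keyed by (master seed, component name), so the
streams never interleave and adding a component cannot perturb existing
draws. The ground truth is returned as a separate artifact and never leaks
into the data tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables import FeatureTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_microbiome_experiments",
    "simulate_expression_groups",
]


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one logical component."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf-8"))])


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults defining the
    reference conditions used throughout the test-suite.

    Microbiome side: ``n_taxa`` taxa, ``n_samples_per_group`` mice per group
    per experiment, ``n_regulated_taxa`` planted responders whose baseline is
    multiplied by ``regulation_fold`` in the perturbed group,
    ``mediator_effect`` (beta1, phenotype units per unit relative abundance)
    with noise ``phenotype_noise`` (sigma) around ``phenotype_baseline``
    (beta0); AUC-GTT uses the same structure scaled by ``auc_scale``.
    ``taxon_dispersion`` / ``mediator_dispersion`` are log-scale biological
    standard deviations; ``library_size`` is reads per sample.

    Expression side: ``n_genes`` signature genes, modules of
    ``module_sizes`` genes loading 0.9 on per-group latent factors,
    per-group sample sizes ``n_expr_samples``; the planted regulator is
    coupled to the microbe at ``regulator_microbe_coupling`` (target Pearson,
    must lie in (-1, 0) for the inhibitor scenario) and carries
    |log10 FC| = ``regulator_lfc``.
    """

    seed: int
    # microbiome experiments
    n_taxa: int = 200
    n_samples_per_group: int = 10
    n_regulated_taxa: int = 20
    regulation_fold: float = 5.0
    mediator_baseline: float = 0.10
    mediator_effect: float = -50.0
    phenotype_baseline: float = 100.0
    phenotype_noise: float = 5.0
    auc_scale: float = 300.0
    taxon_dispersion: float = 0.7
    mediator_dispersion: float = 0.7
    library_size: int = 50_000
    # expression groups
    n_genes: int = 200
    module_sizes: tuple = (30, 30, 25, 25, 20)
    module_loading: float = 0.9
    n_expr_samples: tuple = (8, 7, 9, 10)
    regulator_microbe_coupling: float = -0.8
    regulator_module_loading: float = 0.82
    regulator_lfc: float = 1.2
    microbe_log_mean: float = -3.0
    microbe_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        errors = []
        if self.n_taxa < 2:
            errors.append("n_taxa must be >= 2")
        if self.n_samples_per_group < 2:
            errors.append("n_samples_per_group must be >= 2")
        if not 0 < self.n_regulated_taxa <= self.n_taxa:
            errors.append("n_regulated_taxa must lie in [1, n_taxa]")
        if self.regulation_fold < 1.0:
            errors.append("regulation_fold must be >= 1")
        if not 0 < self.mediator_baseline < 1:
            errors.append("mediator_baseline must lie in (0, 1)")
        if self.phenotype_noise <= 0 or self.taxon_dispersion <= 0:
            errors.append("noise/dispersion parameters must be positive")
        if self.library_size < 1:
            errors.append("library_size must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            errors.append("module_sizes must sum to at most n_genes")
        if any(n < 3 for n in self.n_expr_samples):
            errors.append("each expression group needs >= 3 samples")
        if not -1.0 < self.regulator_microbe_coupling < 0.0:
            errors.append(
                "regulator_microbe_coupling must lie in (-1, 0) "
                "(inhibitor scenario)"
            )
        if not 0.0 < self.regulator_module_loading < 1.0:
            errors.append("regulator_module_loading must lie in (0, 1)")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class GroundTruth:
    """Planted answers, kept separate from the data tables."""

    regulated_taxa: dict = field(default_factory=dict)  # taxon id -> direction
    mediator_taxon: str | None = None
    beta0: float | None = None
    beta1: float | None = None
    sigma: float | None = None
    module_members: dict = field(default_factory=dict)  # module name -> gene ids
    module_signs: dict = field(default_factory=dict)  # module name -> +/-1
    regulator_gene: str | None = None
    coupling_sign: int | None = None


def _taxon_ids(n: int) -> list[str]:
    return [f"taxon_{i:04d}" for i in range(1, n + 1)]


def _softmax_rows(log_p: np.ndarray) -> np.ndarray:
    z = log_p - log_p.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def simulate_microbiome_experiments(
    cfg: SimulationConfig,
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame, GroundTruth]:
    """Generate the two perturbation experiments plus phenotype metadata.

    Returns ``(counts_a, counts_b, metadata, truth)``. Metadata holds the
    group/experiment labels and the two phenotype columns
    (``fasting_glucose``, ``auc_gtt``); phenotype cells of control samples
    are NaN. Fully reproducible from ``cfg.seed``.
    """
    rng_taxa = component_rng(cfg.seed, "taxa")
    rng_phen = component_rng(cfg.seed, "phenotype")
    taxa = _taxon_ids(cfg.n_taxa)

    base = rng_taxa.lognormal(mean=0.0, sigma=1.0, size=cfg.n_taxa)
    base /= base.sum()
    regulated_idx = rng_taxa.choice(cfg.n_taxa, size=cfg.n_regulated_taxa, replace=False)
    mediator_idx = int(regulated_idx[0])
    # pin the mediator's baseline proportion, rescaling the rest
    base *= (1.0 - cfg.mediator_baseline) / (1.0 - base[mediator_idx])
    base[mediator_idx] = cfg.mediator_baseline

    directions = rng_taxa.choice([-1, 1], size=cfg.n_regulated_taxa)
    directions[0] = 1  # mediator is enriched in the perturbed (factor-free) group
    enriched = regulated_idx[directions > 0]
    if (base[enriched] * cfg.regulation_fold >= 1.0).any():
        raise ConfigError(
            "regulation_fold pushes a baseline proportion to >= 1; "
            "infeasible composition"
        )

    dispersion = np.full(cfg.n_taxa, cfg.taxon_dispersion)
    dispersion[mediator_idx] = cfg.mediator_dispersion
    mult = np.ones(cfg.n_taxa)
    mult[regulated_idx] = cfg.regulation_fold ** directions.astype(float)

    truth = GroundTruth(
        regulated_taxa={taxa[i]: int(d) for i, d in zip(regulated_idx, directions)},
        mediator_taxon=taxa[mediator_idx],
        beta0=cfg.phenotype_baseline,
        beta1=cfg.mediator_effect,
        sigma=cfg.phenotype_noise,
    )

    n = cfg.n_samples_per_group
    tables = {}
    meta_rows = []
    for exp in ("exp_a", "exp_b"):
        columns = {}
        for group, m in (("perturbed", mult), ("control", np.ones(cfg.n_taxa))):
            z = rng_taxa.standard_normal((n, cfg.n_taxa))
            log_p = np.log(base * m) + dispersion * z
            props = _softmax_rows(log_p)
            counts = np.vstack(
                [rng_taxa.multinomial(cfg.library_size, p) for p in props]
            )
            for j in range(n):
                sid = f"{exp}_{group}_{j + 1:02d}"
                columns[sid] = counts[j]
                row = {
                    "sample_id": sid,
                    "group": group,
                    "experiment": exp,
                    "strain_or_cohort": "mouse",
                    "fasting_glucose": np.nan,
                    "auc_gtt": np.nan,
                }
                if group == "perturbed":
                    med = props[j, mediator_idx]
                    mu = cfg.phenotype_baseline + cfg.mediator_effect * med
                    row["fasting_glucose"] = mu + rng_phen.normal(
                        0.0, cfg.phenotype_noise
                    )
                    row["auc_gtt"] = cfg.auc_scale * mu + rng_phen.normal(
                        0.0, cfg.auc_scale * cfg.phenotype_noise
                    )
                meta_rows.append(row)
        tables[exp] = FeatureTable(
            values=pd.DataFrame(columns, index=pd.Index(taxa, name="feature_id")),
            kind="counts",
        )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return tables["exp_a"], tables["exp_b"], meta, truth


def _gene_ids(n: int) -> list[str]:
    return [f"gene_{i:04d}" for i in range(1, n + 1)]


def simulate_expression_groups(
    cfg: SimulationConfig, microbiome_truth: GroundTruth | None = None
) -> tuple[list, list, pd.Series, GroundTruth]:
    """Generate k expression matrices, per-sample microbe abundances and
    per-gene log10 fold changes, with one planted regulator.

    Returns ``(expr_groups, microbe_by_group, fold_changes, truth)`` where
    ``expr_groups`` is a list of genes x samples DataFrames (one per group),
    ``microbe_by_group`` a parallel list of per-sample microbe abundance
    Series, and ``fold_changes`` the signed log10 fold changes. When
    ``microbiome_truth`` is given its taxa-side fields are merged into the
    returned truth.
    """
    rng = component_rng(cfg.seed, "expression")
    genes = _gene_ids(cfg.n_genes)

    module_members: dict[str, list[str]] = {}
    module_signs: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(cfg.module_sizes):
        name = f"module_{m + 1}"
        module_members[name] = genes[pos : pos + size]
        module_signs[name] = -1 if m % 2 == 0 else 1
        pos += size
    background = genes[pos:]
    # no modules configured -> a pure-noise signature without a planted
    # regulator (the null scenario for edge-calibration studies)
    regulator = module_members["module_1"][0] if module_members else None

    # signed log10 fold changes: module genes share their module's sign,
    # background genes hover near zero, the regulator carries the largest
    # magnitude so the fold-change source ranks it on top.
    lfc = pd.Series(0.0, index=pd.Index(genes, name="gene_id"))
    for name, members in module_members.items():
        lfc.loc[members] = module_signs[name] * rng.uniform(0.3, 0.9, len(members))
    lfc.loc[background] = rng.uniform(-0.1, 0.1, len(background))
    if regulator is not None:
        lfc.loc[regulator] = module_signs["module_1"] * cfg.regulator_lfc

    rho = cfg.regulator_microbe_coupling
    lam = cfg.regulator_module_loading
    load = cfg.module_loading
    gene_noise = float(np.sqrt(1.0 - load**2))
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)

    expr_groups = []
    microbe_by_group = []
    for gi, n_g in enumerate(cfg.n_expr_samples):
        group = f"strain_{gi + 1}"
        sample_ids = [f"{group}_s{j + 1:02d}" for j in range(n_g)]

        factors = {name: rng.standard_normal(n_g) for name in module_members}
        X = rng.standard_normal((cfg.n_genes, n_g))  # unit-variance residuals
        gene_index = {gene: i for i, gene in enumerate(genes)}
        for name, members in module_members.items():
            idx = [gene_index[gname] for gname in members]
            X[idx] = gene_noise * X[idx] + load * factors[name]
        if regulator is not None:
            ri = gene_index[regulator]
            # the regulator loads weakly on its module (peripheral placement)
            x_reg = lam * factors["module_1"] + np.sqrt(1.0 - lam**2) * (
                rng.standard_normal(n_g)
            )
            X[ri] = x_reg
            # ... and the microbe sits causally downstream of it: log
            # abundance mixes the (standardized) regulator signal at the
            # target coupling with independent environmental noise.
            reg_std = (x_reg - x_reg.mean()) / x_reg.std()
            m_log = rho * reg_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(
                n_g
            )
        else:
            m_log = rng.standard_normal(n_g)
        microbe = np.exp(cfg.microbe_log_mean + cfg.microbe_log_sigma * m_log)
        X += baseline[:, None]
        expr_groups.append(
            pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
        )
        microbe_by_group.append(pd.Series(microbe, index=sample_ids, name="microbe"))

    truth = GroundTruth(
        module_members=module_members,
        module_signs=module_signs,
        regulator_gene=regulator,
        coupling_sign=int(np.sign(rho)) if regulator is not None else None,
    )
    if microbiome_truth is not None:
        truth = replace(
            truth,
            regulated_taxa=microbiome_truth.regulated_taxa,
            mediator_taxon=microbiome_truth.mediator_taxon,
            beta0=microbiome_truth.beta0,
            beta1=microbiome_truth.beta1,
            sigma=microbiome_truth.sigma,
        )
    return expr_groups, microbe_by_group, lfc, truth
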