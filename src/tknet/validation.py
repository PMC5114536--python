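"""Planted-truth recovery experiments and null calibrations.

Single-replicate building blocks for the package's self-validation studies:
each function runs the relevant pipeline stages on one synthetic dataset and
reports whether the planted answer was recovered, or how many false
discoveries a null configuration produced. The test-suite and the
reproduction script aggregate these over many seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import abundance, mediators, network, ranking, simulate, tables

__all__ = [
    "mediator_trial",
    "regulator_trial",
    "null_concordant_count",
    "noise_edge_tally",
]


def mediator_trial(seed: int, **overrides) -> dict:
    """Run the exploratory phase plus mediator screen on one synthetic
    dataset.

    Returns a dict with the concordant-feature count, whether the planted
    mediator was concordant, its classification, and whether it attained
    the smallest min-p among all classified candidates.
    """
    cfg = simulate.SimulationConfig(seed=seed, **overrides)
    counts_a, counts_b, meta, truth = simulate.simulate_microbiome_experiments(cfg)
    rel_a = abundance.to_relative_abundance(counts_a)
    rel_b = abundance.to_relative_abundance(counts_b)
    diff_a = abundance.differential_features(rel_a, meta, "perturbed", "control")
    diff_b = abundance.differential_features(rel_b, meta, "perturbed", "control")
    concord = abundance.concordant_features(diff_a, diff_b, fdr=0.1)
    m = truth.mediator_taxon
    out = {
        "n_concordant": int(concord["concordant"].sum()),
        "mediator_concordant": bool(
            concord.set_index("feature_id").loc[m, "concordant"]
        ),
        "classification": "not_concordant",
        "mediator_best": False,
    }
    if not out["mediator_concordant"]:
        return out
    pert_meta = meta[meta["group"] == "perturbed"]
    pooled = tables.FeatureTable(
        values=pd.concat(
            [
                rel_a.values[[s for s in rel_a.sample_ids if s in pert_meta.index]],
                rel_b.values[[s for s in rel_b.sample_ids if s in pert_meta.index]],
            ],
            axis=1,
        ),
        kind="relative",
    )
    features = concord.loc[concord["concordant"], "feature_id"].tolist()
    corr = mediators.phenotype_correlations(
        pooled,
        pert_meta,
        features,
        ["fasting_glucose", "auc_gtt"],
        method="spearman",
        forbid_groups=("control",),
    )
    nominated = mediators.nominate_mediators(concord, corr, alpha=0.05)
    by_id = nominated.set_index("feature_id")
    out["classification"] = str(by_id.loc[m, "classification"])
    candidates = nominated[nominated["classification"] != "not_candidate"]
    out["mediator_best"] = bool(
        len(candidates) and candidates.iloc[0]["feature_id"] == m
    )
    return out


def regulator_trial(seed: int, **overrides) -> dict:
    """Network reconstruction plus regulator ranking on one synthetic
    dataset; reports network membership and the planted regulator's rank."""
    cfg = simulate.SimulationConfig(seed=seed, **overrides)
    expr_groups, microbe, lfc, truth = simulate.simulate_expression_groups(cfg)
    g, summary = network.build_network(expr_groups, lfc)
    out = {
        "member": truth.regulator_gene in g,
        "final_rank": None,
        "membership_fraction": summary["membership_fraction"],
    }
    if not out["member"]:
        return out
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranked = ranking.prioritize_regulators(
            g, expr_groups, [m.to_numpy() for m in microbe], lfc
        )
    out["final_rank"] = int(
        ranked.set_index("gene_id").loc[truth.regulator_gene, "final_rank"]
    )
    return out


def null_concordant_count(seed: int, n_taxa: int = 200, **overrides) -> int:
    """Concordant-feature count under the global null (no planted effects)."""
    cfg = simulate.SimulationConfig(
        seed=seed,
        n_taxa=n_taxa,
        regulation_fold=1.0,
        mediator_effect=0.0,
        **overrides,
    )
    counts_a, counts_b, meta, _ = simulate.simulate_microbiome_experiments(cfg)
    diff_a = abundance.differential_features(
        abundance.to_relative_abundance(counts_a), meta, "perturbed", "control"
    )
    diff_b = abundance.differential_features(
        abundance.to_relative_abundance(counts_b), meta, "perturbed", "control"
    )
    concord = abundance.concordant_features(diff_a, diff_b, fdr=0.1)
    return int(concord["concordant"].sum())


def noise_edge_tally(seed: int, n_genes: int = 40) -> tuple[int, int]:
    """(admissible edges, evaluated pairs) among pure-noise gene pairs."""
    cfg = simulate.SimulationConfig(seed=seed, n_genes=n_genes, module_sizes=())
    expr_groups, _, _, _ = simulate.simulate_expression_groups(cfg)
    rng = np.random.default_rng(seed + 977)
    lfc = pd.Series(
        rng.choice([-1.0, 1.0], n_genes) * rng.uniform(0.2, 1.0, n_genes),
        index=expr_groups[0].index,
    )
    g, _ = network.build_network(expr_groups, lfc)
    return g.number_of_edges(), n_genes * (n_genes - 1) // 2
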