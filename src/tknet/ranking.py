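"""Four-source rank-sum prioritization of host genes as microbe regulators.

For every gene that is a member of the reconstructed network, four evidence
sources are collected:

* ``s1`` — absolute value of the average per-group correlation between the
  gene's expression and the target microbe's abundance;
* ``s2`` — the gene's average shortest path length in the gene network
  (larger = more peripheral; upstream regulators of an external target tend
  to sit at the network edge rather than its core);
* ``s3`` — absolute log10 fold change of the gene (perturbed vs control);
* ``s4`` — the signed version of ``s1``: positive when the per-group
  correlation signs agree across all groups, negative otherwise, so that
  sign-consistent genes outrank sign-inconsistent ones of equal magnitude.

Each source is ranked ascending with average ties, the four ranks are
summed, and the gene with the *largest* total is ranked first (longer path
lengths and stronger correlations yield higher scores). A shared negative
correlation sign labels the gene a putative inhibitor of the microbe, a
shared positive sign a putative enhancer; the label is reported alongside
the rank but does not enter the score.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .network import avg_shortest_path_lengths
from .stats import rank_ascending

__all__ = [
    "signed_abs_avg_correlation",
    "aggregate_ranks",
    "prioritize_regulators",
]


def signed_abs_avg_correlation(rhos) -> tuple[float, float, str]:
    """Collapse per-group correlations into (s1, s4, direction_class).

    ``s1 = |mean(rhos)|``; ``s4 = +s1`` when every group shares a strict
    sign, else ``-s1``. The shared sign gives the direction class
    (negative -> ``putative_inhibitor``, positive -> ``putative_enhancer``);
    any zero or sign disagreement yields ``inconsistent``.
    """
    rhos = np.asarray(rhos, dtype=float).ravel()
    if rhos.size < 2:
        raise ValueError("at least two per-group correlations are required")
    if np.isnan(rhos).any() or (np.abs(rhos) > 1).any():
        raise ValueError("correlations must lie in [-1, 1] with no missing values")
    s1 = float(abs(rhos.mean()))
    if (rhos < 0).all():
        return s1, s1, "putative_inhibitor"
    if (rhos > 0).all():
        return s1, s1, "putative_enhancer"
    return s1, -s1, "inconsistent"


def aggregate_ranks(sources: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum aggregation over source columns.

    ``sources`` is indexed by gene id with one column per evidence source.
    Every column is ranked ascending with average ties; ranks are summed
    into ``total_score``; ``final_rank`` 1 goes to the largest total, with a
    lexicographic gene-id tiebreak.
    """
    if sources.isna().to_numpy().any():
        raise DataError("rank sources contain missing values")
    out = sources.copy()
    for i, col in enumerate(sources.columns, start=1):
        out[f"r{i}"] = rank_ascending(sources[col].to_numpy(dtype=float))
    rank_cols = [f"r{i}" for i in range(1, len(sources.columns) + 1)]
    out["total_score"] = out[rank_cols].sum(axis=1)
    order = np.lexsort(
        (out.index.astype(str).to_numpy(), -out["total_score"].to_numpy())
    )
    out = out.iloc[order]
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def _corr_rows_with_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / denom
    return np.clip(r, -1.0, 1.0)


def prioritize_regulators(
    g: nx.Graph,
    expr_groups,
    microbe_by_group,
    fold_changes_log10: pd.Series,
) -> pd.DataFrame:
    """Rank network genes as candidate regulators of the target microbe.

    ``expr_groups`` and ``microbe_by_group`` are parallel sequences: one
    genes x samples expression matrix and one per-sample microbe abundance
    vector per group, sharing sample order within each group.
    ``fold_changes_log10`` maps gene id to a signed log10 fold change.

    Genes absent from the network (no admissible edge) are excluded with a
    warning — only networked genes carry a defined path length. Returns one
    record per ranked gene, sorted by ``final_rank``.
    """
    expr_groups = list(expr_groups)
    microbe_by_group = [np.asarray(m, dtype=float) for m in microbe_by_group]
    if len(expr_groups) != len(microbe_by_group):
        raise DataError("one microbe abundance vector per expression group required")
    for eg, m in zip(expr_groups, microbe_by_group):
        if eg.shape[1] != m.size:
            raise DataError(
                "microbe abundance and expression must share samples within a group"
            )
    network_genes = sorted(g.nodes)
    signature = [str(x) for x in expr_groups[0].index]
    dropped = sorted(set(signature) - set(network_genes))
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} gene(s) not in the network "
            f"(no admissible edge): {dropped[:5]} ...",
            stacklevel=2,
        )
    missing = set(network_genes) - set(signature)
    if missing:
        raise DataError(f"network gene(s) absent from expression: {sorted(missing)[:5]}")

    rhos = np.column_stack(
        [
            _corr_rows_with_vector(
                eg.loc[network_genes].to_numpy(dtype=float), m
            )
            for eg, m in zip(expr_groups, microbe_by_group)
        ]
    )
    if np.isnan(rhos).any():
        bad = network_genes[int(np.nonzero(np.isnan(rhos).any(axis=1))[0][0])]
        raise DataError(f"correlation undefined (constant vector) for gene {bad!r}")
    aspl = avg_shortest_path_lengths(g)

    s1 = np.empty(len(network_genes))
    s4 = np.empty(len(network_genes))
    direction = []
    for i in range(len(network_genes)):
        s1[i], s4[i], d = signed_abs_avg_correlation(rhos[i])
        direction.append(d)
    sources = pd.DataFrame(
        {
            "s1_abs_avg_corr": s1,
            "s2_avg_shortest_path": [aspl[n] for n in network_genes],
            "s3_abs_log10_fc": np.abs(
                fold_changes_log10.loc[network_genes].to_numpy(dtype=float)
            ),
            "s4_signed_abs_avg_corr": s4,
        },
        index=pd.Index(network_genes, name="gene_id"),
    )
    ranked = aggregate_ranks(sources)
    ranked["direction_class"] = [
        direction[network_genes.index(gid)] for gid in ranked.index
    ]
    return ranked.reset_index()
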