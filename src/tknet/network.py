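"""Per-group-correlation gene network reconstruction.

For every pair of genes in a differential signature, Pearson correlation is
computed separately within each of k sample groups (e.g. mouse strains), the
k p values are merged with Fisher's combined probability test, and the pair
becomes an edge only when four criteria hold simultaneously:

1. the per-group correlation p value is below ``p_ind`` (default 0.3) in
   *every* group;
2. the Fisher combined p value is below ``p_comb`` (default 0.01);
3. the correlation sign is the same (strictly positive or strictly
   negative) in every group;
4. the sign is consistent with the two genes' fold changes:
   sign(r) = sign(lfc_a * lfc_b), i.e. co-regulated genes must correlate
   positively and oppositely regulated genes negatively.

Genes with at least one admissible edge are network members; the membership
fraction is reported, not asserted. Per-node average shortest path length
(unweighted hops, within the node's connected component) quantifies how
peripheral a gene sits — the network feature fed to the regulator ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t

from .errors import DataError
from .stats import CombinedResult, bh_fdr, fisher_combined, pearson_corr

__all__ = [
    "PerGroupCorr",
    "pergroup_correlations",
    "pairwise_pergroup",
    "edge_admissible",
    "build_network",
    "avg_shortest_path_length",
    "avg_shortest_path_lengths",
    "node_table",
    "edge_table",
]

_P_IND_DEFAULT = 0.3
_P_COMB_DEFAULT = 0.01


@dataclass(frozen=True)
class PerGroupCorr:
    """Correlation evidence for one gene pair across k groups."""

    gene_a: str
    gene_b: str
    r_by_group: tuple
    p_by_group: tuple
    combined: CombinedResult
    q: float = float("nan")


def _check_groups(expr_groups) -> list[pd.DataFrame]:
    groups = list(expr_groups)
    if not groups:
        raise DataError("at least one expression group is required")
    genes = groups[0].index
    for g in groups[1:]:
        if not genes.equals(g.index):
            raise DataError("expression groups must share an identical gene index")
    for g in groups:
        if g.shape[1] < 3:
            raise DataError("each expression group needs >=3 samples")
    return groups


def pergroup_correlations(expr_groups, gene_a: str, gene_b: str) -> PerGroupCorr:
    """Per-group Pearson correlation of one gene pair, Fisher-combined.

    A gene constant within any group makes the pair untestable
    (:class:`DataError` from the correlation kernel propagates).
    The batch-level q value is left NaN here; it is assigned when pairs are
    evaluated together (see :func:`pairwise_pergroup`).
    """
    groups = _check_groups(expr_groups)
    rs, ps = [], []
    for g in groups:
        if gene_a not in g.index or gene_b not in g.index:
            raise DataError(f"gene pair ({gene_a!r}, {gene_b!r}) absent from a group")
        res = pearson_corr(g.loc[gene_a].to_numpy(), g.loc[gene_b].to_numpy())
        rs.append(res.statistic)
        ps.append(res.p_value)
    return PerGroupCorr(
        gene_a=gene_a,
        gene_b=gene_b,
        r_by_group=tuple(rs),
        p_by_group=tuple(ps),
        combined=fisher_combined(ps),
    )


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix; constant rows yield NaN."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc * Xc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Xc.T) / np.outer(norm, norm)
    R[norm == 0, :] = np.nan
    R[:, norm == 0] = np.nan
    return np.clip(R, -1.0, 1.0)


def _corr_p(R: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p values for a matrix of correlation coefficients."""
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt(df / (1.0 - R * R))
    p = 2.0 * _t.sf(np.abs(tstat), df)
    p = np.where(np.abs(R) >= 1.0, 0.0, p)
    p[np.isnan(R)] = np.nan
    return np.minimum(p, 1.0)


def pairwise_pergroup(
    expr_groups, genes=None, *, zero_floor: float = 1e-300
) -> pd.DataFrame:
    """All-pairs per-group correlations with Fisher combination and FDR.

    Returns one row per unordered gene pair with per-group ``r_<i>`` /
    ``p_<i>`` columns, the combined chi-squared statistic and p value, a
    Benjamini–Hochberg q over the testable pairs of the batch, and a
    ``testable`` flag (False when a gene is constant within some group).
    """
    groups = _check_groups(expr_groups)
    if genes is not None:
        genes = [str(g) for g in genes]
        missing = set(genes) - set(groups[0].index.astype(str))
        if missing:
            raise DataError(f"gene(s) absent from expression groups: {sorted(missing)}")
        groups = [g.loc[genes] for g in groups]
    gene_ids = [str(g) for g in groups[0].index]
    m = len(gene_ids)
    iu, ju = np.triu_indices(m, k=1)
    k = len(groups)
    R = np.empty((k, iu.size))
    P = np.empty((k, iu.size))
    for gi, g in enumerate(groups):
        Rm = _corr_matrix(g.to_numpy(dtype=float))
        Pm = _corr_p(Rm, g.shape[1])
        R[gi] = Rm[iu, ju]
        P[gi] = Pm[iu, ju]
    testable = ~np.isnan(P).any(axis=0)
    chi2_stat = np.full(iu.size, np.nan)
    p_comb = np.full(iu.size, np.nan)
    if testable.any():
        Pc = np.maximum(P[:, testable], zero_floor)
        chi2_stat[testable] = -2.0 * np.log(Pc).sum(axis=0)
        p_comb[testable] = _chi2.sf(chi2_stat[testable], 2 * k)
    q = np.full(iu.size, np.nan)
    if testable.any():
        q[testable] = bh_fdr(p_comb[testable])
    data = {
        "gene_a": [gene_ids[i] for i in iu],
        "gene_b": [gene_ids[j] for j in ju],
    }
    for gi in range(k):
        data[f"r_{gi}"] = R[gi]
        data[f"p_{gi}"] = P[gi]
    data["chi2"] = chi2_stat
    data["p_combined"] = p_comb
    data["q"] = q
    data["testable"] = testable
    return pd.DataFrame(data)


def edge_admissible(
    pc: PerGroupCorr,
    lfc_a: float,
    lfc_b: float,
    p_ind: float = _P_IND_DEFAULT,
    p_comb: float = _P_COMB_DEFAULT,
) -> bool:
    """Apply the four edge-inclusion criteria to a single pair."""
    r = np.asarray(pc.r_by_group, dtype=float)
    p = np.asarray(pc.p_by_group, dtype=float)
    if np.isnan(r).any() or np.isnan(p).any():
        return False
    if not (p < p_ind).all():
        return False
    if not pc.combined.p_combined < p_comb:
        return False
    if not ((r > 0).all() or (r < 0).all()):
        return False
    if lfc_a == 0.0 or lfc_b == 0.0:
        return False
    return np.sign(r[0]) == np.sign(lfc_a) * np.sign(lfc_b)


def _admissible_mask(
    pairs: pd.DataFrame, lfc: pd.Series, k: int, p_ind: float, p_comb: float
) -> np.ndarray:
    R = pairs[[f"r_{i}" for i in range(k)]].to_numpy(dtype=float)
    P = pairs[[f"p_{i}" for i in range(k)]].to_numpy(dtype=float)
    testable = pairs["testable"].to_numpy(dtype=bool)
    ind_ok = np.where(testable, (P < p_ind).all(axis=1), False)
    comb_ok = np.where(testable, pairs["p_combined"].to_numpy() < p_comb, False)
    sign_ok = (R > 0).all(axis=1) | (R < 0).all(axis=1)
    la = lfc.loc[pairs["gene_a"]].to_numpy(dtype=float)
    lb = lfc.loc[pairs["gene_b"]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        fc_ok = (la != 0) & (lb != 0) & (np.sign(R[:, 0]) == np.sign(la) * np.sign(lb))
    return ind_ok & comb_ok & sign_ok & fc_ok


def build_network(
    expr_groups,
    fold_changes: pd.Series,
    gene_subset=None,
    p_ind: float = _P_IND_DEFAULT,
    p_comb: float = _P_COMB_DEFAULT,
) -> tuple[nx.Graph, dict]:
    """Reconstruct the gene network over a differential signature.

    ``fold_changes`` maps gene id to a signed log fold change (perturbed vs
    control); only its sign enters the admissibility rule. Returns the graph
    (nodes = genes with >=1 admissible edge, node attribute ``lfc``; edge
    attributes ``sign``, ``p_combined``, ``r_by_group``) and a summary dict
    with ``n_signature``, ``n_members``, ``membership_fraction``,
    ``n_edges``.
    """
    genes = (
        [str(g) for g in gene_subset]
        if gene_subset is not None
        else [str(g) for g in expr_groups[0].index]
    )
    if len(genes) < 2:
        raise DataError("gene subset must contain at least 2 genes")
    missing_fc = set(genes) - set(map(str, fold_changes.index))
    if missing_fc:
        raise DataError(f"fold change missing for gene(s): {sorted(missing_fc)[:5]}")
    pairs = pairwise_pergroup(expr_groups, genes)
    k = len(list(expr_groups))
    mask = _admissible_mask(pairs, fold_changes, k, p_ind, p_comb)
    g = nx.Graph()
    rcols = [f"r_{i}" for i in range(k)]
    for row in pairs.loc[mask].itertuples(index=False):
        rvals = tuple(getattr(row, c) for c in rcols)
        g.add_edge(
            row.gene_a,
            row.gene_b,
            sign=int(np.sign(rvals[0])),
            p_combined=float(row.p_combined),
            r_by_group=rvals,
        )
    for node in g.nodes:
        g.nodes[node]["lfc"] = float(fold_changes.loc[node])
    summary = {
        "n_signature": len(genes),
        "n_members": g.number_of_nodes(),
        "membership_fraction": g.number_of_nodes() / len(genes),
        "n_edges": g.number_of_edges(),
    }
    return g, summary


def avg_shortest_path_length(g: nx.Graph, node) -> float:
    """Mean unweighted shortest-path distance from ``node`` to every other
    node of its connected component. Undefined for isolated nodes."""
    if node not in g:
        raise DataError(f"node {node!r} not in network")
    if g.degree(node) == 0:
        raise DataError(f"node {node!r} is isolated; path length undefined")
    dist = nx.single_source_shortest_path_length(g, node)
    del dist[node]
    return float(np.mean(list(dist.values())))


def avg_shortest_path_lengths(g: nx.Graph) -> dict:
    """Average shortest path length for every non-isolated node."""
    return {
        node: avg_shortest_path_length(g, node) for node in g.nodes if g.degree(node) > 0
    }


def node_table(g: nx.Graph) -> pd.DataFrame:
    """Per-node summary: fold change, degree, average shortest path length."""
    aspl = avg_shortest_path_lengths(g)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "gene_id": nodes,
            "lfc": [g.nodes[n].get("lfc", np.nan) for n in nodes],
            "degree": [g.degree(n) for n in nodes],
            "avg_shortest_path": [aspl.get(n, np.nan) for n in nodes],
        }
    )


def edge_table(g: nx.Graph) -> pd.DataFrame:
    """Per-edge summary sorted by (gene_a, gene_b)."""
    rows = [
        {
            "gene_a": min(a, b),
            "gene_b": max(a, b),
            "sign": d["sign"],
            "p_combined": d["p_combined"],
        }
        for a, b, d in g.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "sign", "p_combined"])
    if len(df):
        df = df.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(
            drop=True
        )
    return df
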