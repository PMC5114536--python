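"""Differential abundance and cross-experiment concordance.

The exploratory phase of the pipeline: normalize counts to relative
abundances, test every feature for a two-group difference within each
perturbation experiment, adjust with Benjamini–Hochberg, and intersect two
independent experiments by direction-concordant significance. A feature that
shifts the same way under two different perturbations of the same factor is
far more likely to be genuinely regulated by it than one found in a single
experiment.

The two-group test runs on log2-transformed relative abundances by default
(pseudocount = half the smallest nonzero relative abundance in the table);
``log_transform=False`` tests the raw proportions. The same test doubles as
the expression differential test on log2(CPM + 0.5)-style matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as _t

from .errors import DataError
from .stats import bh_fdr
from .tables import FeatureTable, check_alignment

__all__ = [
    "to_relative_abundance",
    "differential_features",
    "concordant_features",
]


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total count.

    Raises :class:`DataError` naming the sample if a column sums to zero.
    """
    if table.kind != "counts":
        raise DataError("to_relative_abundance expects a counts table")
    sums = table.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise DataError(f"all-zero sample column(s): {list(zero.index)}")
    return FeatureTable(values=table.values / sums, kind="relative")


def _welch_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t test per row; returns (t, two-sided p).

    Rows where both groups are constant get NaN statistics.
    """
    nx, ny = X.shape[1], Y.shape[1]
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (X.mean(axis=1) - Y.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    degenerate = se2 == 0.0
    tstat[degenerate] = np.nan
    df[degenerate] = np.nan
    p = np.full(tstat.shape, np.nan)
    ok = ~degenerate
    p[ok] = 2.0 * _t.sf(np.abs(tstat[ok]), df[ok])
    np.minimum(p, 1.0, out=p)
    return tstat, p


def differential_features(
    table: FeatureTable,
    meta: pd.DataFrame,
    perturbed_label: str,
    control_label: str,
    *,
    log_transform: bool = True,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-feature two-group (Welch) test of perturbed versus control samples.

    Returns one record per feature with columns ``feature_id``,
    ``mean_perturbed``, ``mean_control`` (relative-abundance scale),
    ``direction`` (sign of perturbed - control, 0 when equal), ``log2_fc``
    (pseudocounted), ``p``, ``q`` and ``testable``. Features constant in both
    groups are flagged ``testable=False`` with missing p/q; q values come
    from Benjamini–Hochberg over the testable features.
    """
    if table.kind != "relative":
        raise DataError("differential_features expects a relative-abundance table")
    check_alignment(table, meta)
    groups = meta.loc[table.sample_ids, "group"]
    pert = [s for s, g in groups.items() if g == perturbed_label]
    ctrl = [s for s, g in groups.items() if g == control_label]
    if len(pert) < 2 or len(ctrl) < 2:
        raise DataError(
            f"need >=2 samples per group; got {len(pert)} {perturbed_label!r} "
            f"and {len(ctrl)} {control_label!r}"
        )
    values = table.values
    if pseudocount is None:
        nonzero = values.to_numpy()[values.to_numpy() > 0]
        pseudocount = float(nonzero.min()) / 2.0 if nonzero.size else 0.5
    Xr = values[pert].to_numpy()
    Yr = values[ctrl].to_numpy()
    if log_transform:
        X = np.log2(Xr + pseudocount)
        Y = np.log2(Yr + pseudocount)
    else:
        X, Y = Xr, Yr
    _, p = _welch_rows(X, Y)

    mean_p = Xr.mean(axis=1)
    mean_c = Yr.mean(axis=1)
    direction = np.sign(mean_p - mean_c).astype(int)
    log2_fc = np.log2((mean_p + pseudocount) / (mean_c + pseudocount))

    testable = ~np.isnan(p)
    q = np.full(p.shape, np.nan)
    if testable.any():
        q[testable] = bh_fdr(p[testable])
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "mean_perturbed": mean_p,
            "mean_control": mean_c,
            "direction": direction,
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "testable": testable,
        }
    )


def concordant_features(
    res_a: pd.DataFrame, res_b: pd.DataFrame, fdr: float = 0.1
) -> pd.DataFrame:
    """Intersect two differential-abundance result sets by concordance.

    A feature is concordant when it passes the FDR threshold in both
    experiments with the same (nonzero) direction of change. Returns one
    record per feature of the intersection with columns ``feature_id``,
    ``direction_a``, ``direction_b``, ``q_a``, ``q_b``, ``concordant``.
    """
    merged = res_a.merge(
        res_b, on="feature_id", how="inner", suffixes=("_a", "_b")
    )
    out = merged[["feature_id", "direction_a", "direction_b", "q_a", "q_b"]].copy()
    out["concordant"] = (
        (out["q_a"] < fdr)
        & (out["q_b"] < fdr)
        & (out["direction_a"] == out["direction_b"])
        & (out["direction_a"] != 0)
    )
    return out
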