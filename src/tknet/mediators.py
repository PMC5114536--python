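"""Sign-matched mediator screening.

Among features already shown to be regulated by the perturbed factor, this
stage nominates candidate mediators of a host phenotype by matching the sign
of the within-group feature–phenotype correlation to the direction of
regulation: a feature *depleted* by the factor that correlates *negatively*
with a disease metric is a candidate improver (removing the factor raises the
feature and lowers the metric); a feature *enriched* by the factor that
correlates *positively* is a candidate worsener. Correlations are computed
only within the factor-deficient (perturbed) group, so direct effects of the
factor cannot confound them — passing metadata containing control-group
samples is refused.

Also implements the cohort-style helpers: the minimum-abundance subject
filter and the cross-group sign-consistency summary with its exact
one-proportion test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .stats import one_proportion_test, pearson_corr, spearman_corr
from .tables import FeatureTable, check_alignment

__all__ = [
    "select_samples_by_feature",
    "phenotype_correlations",
    "regulation_from_direction",
    "nominate_mediators",
    "SignConsistencySummary",
    "sign_consistency_summary",
]

_CORR = {"spearman": spearman_corr, "pearson": pearson_corr}


def select_samples_by_feature(
    table: FeatureTable, feature_id: str, min_abund: float = 0.01
) -> list[str]:
    """Samples whose relative abundance of ``feature_id`` is >= ``min_abund``.

    Mirrors the cohort practice of restricting a correlation analysis to
    subjects in whom the focal microbe is biologically present (>=1% by
    default); at trace abundance other, more abundant, taxa dominate the
    phenotype.
    """
    if feature_id not in table.values.index:
        raise DataError(f"unknown feature {feature_id!r}")
    row = table.values.loc[feature_id]
    return [str(s) for s, v in row.items() if v >= min_abund]


def phenotype_correlations(
    table: FeatureTable,
    meta: pd.DataFrame,
    features,
    phenotype_names,
    method: str = "spearman",
    forbid_groups=(),
) -> pd.DataFrame:
    """Feature x phenotype correlations, pairwise-complete.

    One record per (feature, phenotype) with the correlation coefficient,
    its two-sided p, and the effective number of complete pairs. Pairs with
    fewer than three complete observations, or with a constant vector, are
    flagged ``testable=False`` (no exception).

    ``forbid_groups`` guards the within-perturbed-group design: if any sample
    of ``meta`` carries one of these group labels (e.g. the control label),
    the call is refused.
    """
    if method not in _CORR:
        raise ValueError(f"method must be one of {sorted(_CORR)}")
    corr = _CORR[method]
    forbidden = set(forbid_groups) & set(meta["group"].unique())
    if forbidden:
        raise DataError(
            f"metadata contains forbidden group label(s) {sorted(forbidden)}; "
            "mediator correlations must be restricted to the perturbed group"
        )
    check_alignment(table, meta)
    samples = table.sample_ids
    records = []
    for fid in features:
        if fid not in table.values.index:
            raise DataError(f"unknown feature {fid!r}")
        abund = table.values.loc[fid, samples].to_numpy(dtype=float)
        for pheno in phenotype_names:
            if pheno not in meta.columns:
                raise DataError(f"unknown phenotype column {pheno!r}")
            y = meta.loc[samples, pheno].to_numpy(dtype=float)
            mask = ~np.isnan(y)
            n_eff = int(mask.sum())
            rec = {
                "feature_id": fid,
                "phenotype": pheno,
                "method": method,
                "r": np.nan,
                "p": np.nan,
                "n": n_eff,
                "testable": False,
            }
            if n_eff >= 3:
                try:
                    res = corr(abund[mask], y[mask])
                except DataError:
                    pass  # constant vector: leave untestable
                else:
                    rec.update(r=res.statistic, p=res.p_value, testable=True)
            records.append(rec)
    return pd.DataFrame.from_records(records)


def regulation_from_direction(
    direction: int, factor_absent_in_perturbed: bool = True
) -> str:
    """Translate a perturbed-vs-control direction into factor terms.

    In both perturbation designs emulated here (genetic knockout and
    antibody blockade) the *perturbed* group is the factor-deficient one, so
    a feature higher in the perturbed group (direction +1) is *depleted by*
    the factor, and vice versa. Set ``factor_absent_in_perturbed=False`` for
    designs where the perturbation adds the factor.
    """
    if direction == 0:
        raise ValueError("direction must be nonzero")
    up_in_perturbed = direction > 0
    depleted = up_in_perturbed if factor_absent_in_perturbed else not up_in_perturbed
    return "depleted_by_factor" if depleted else "enriched_by_factor"


def nominate_mediators(
    concord: pd.DataFrame,
    corr: pd.DataFrame,
    alpha: float = 0.05,
    *,
    require_all_phenotypes: bool = True,
    factor_absent_in_perturbed: bool = True,
) -> pd.DataFrame:
    """Classify concordant features as candidate mediators of the phenotype.

    ``concord`` is the output of :func:`tknet.abundance.concordant_features`;
    only rows with ``concordant=True`` enter the screen. ``corr`` is the
    output of :func:`phenotype_correlations` over the perturbed group.

    Classification (per feature, over its phenotypes):

    * ``candidate_improver`` — depleted by the factor and every phenotype
      correlation negative with p < alpha;
    * ``candidate_worsener`` — enriched by the factor and every phenotype
      correlation positive with p < alpha;
    * ``not_candidate`` otherwise (mixed signs never classify).

    With ``require_all_phenotypes=False`` a single passing phenotype
    suffices, but a sign conflict among significant correlations still
    disqualifies. Output is ordered by the minimum p across phenotypes
    (feature id as deterministic tiebreak).
    """
    concordant = concord.loc[concord["concordant"]]
    regulated = dict(zip(concordant["feature_id"], concordant["direction_a"]))
    extra = sorted(set(corr["feature_id"]) - set(regulated))
    if extra:
        warnings.warn(
            f"skipping {len(extra)} feature(s) with correlations but no "
            f"concordance record: {extra[:5]}",
            stacklevel=2,
        )
    records = []
    for fid, sub in corr.groupby("feature_id", sort=True):
        if fid not in regulated:
            continue
        regulation = regulation_from_direction(
            int(regulated[fid]), factor_absent_in_perturbed
        )
        rhos = sub.set_index("phenotype")["r"]
        ps = sub.set_index("phenotype")["p"]
        testable = sub.set_index("phenotype")["testable"]
        signs = np.sign(rhos.to_numpy(dtype=float))
        all_testable = bool(testable.all())
        passing = testable & (ps < alpha)
        hits = passing.all() if require_all_phenotypes else passing.any()
        same_sign = all_testable and (np.all(signs < 0) or np.all(signs > 0))
        classification = "not_candidate"
        if hits and same_sign:
            if regulation == "depleted_by_factor" and np.all(signs < 0):
                classification = "candidate_improver"
            elif regulation == "enriched_by_factor" and np.all(signs > 0):
                classification = "candidate_worsener"
        rec = {
            "feature_id": fid,
            "regulation_direction": regulation,
            "classification": classification,
            "min_p": float(np.nanmin(ps.to_numpy(dtype=float)))
            if np.isfinite(ps.to_numpy(dtype=float)).any()
            else np.nan,
        }
        for pheno in sub["phenotype"]:
            rec[f"rho_{pheno}"] = rhos[pheno]
            rec[f"p_{pheno}"] = ps[pheno]
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.sort_values(
            ["min_p", "feature_id"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class SignConsistencySummary:
    """Cross-group sign-consistency counts with an exact proportion test.

    ``proportion_test_p`` asks whether the split of consistent genes between
    negative and positive correlation is compatible with a fair coin.
    """

    n_genes_tested: int
    n_consistent: int
    n_consistent_negative: int
    n_consistent_positive: int
    proportion_test_p: float


def sign_consistency_summary(per_group_r: pd.DataFrame) -> SignConsistencySummary:
    """Summarise per-gene correlation signs across groups.

    ``per_group_r`` holds one row per gene and one column per group, each
    cell the gene's correlation coefficient with the target in that group.
    A gene is consistent when its correlations share a strict sign in every
    group (a zero breaks consistency).
    """
    arr = per_group_r.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise DataError("per-group correlations contain missing values")
    neg = (arr < 0).all(axis=1)
    pos = (arr > 0).all(axis=1)
    n_neg = int(neg.sum())
    n_pos = int(pos.sum())
    n_cons = n_neg + n_pos
    p = (
        one_proportion_test(n_neg, n_cons, 0.5, "two_sided").p_value
        if n_cons > 0
        else float("nan")
    )
    return SignConsistencySummary(
        n_genes_tested=arr.shape[0],
        n_consistent=n_cons,
        n_consistent_negative=n_neg,
        n_consistent_positive=n_pos,
        proportion_test_p=p,
    )
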