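"""Differential-abundance testing and precision QC.

Default differential test is the pooled-variance two-sample t-test on log2
abundances with Benjamini-Hochberg correction across all tested features.
An optional empirical-Bayes moderation mode shrinks per-feature variances
toward the cohort's typical variance (a lightweight approximation of
moderated-t machinery, documented as such — exact equivalence with linear
model pipelines is not claimed).

The significance convention used downstream (volcanoes, over-representation
hit lists) is adjusted p <= 0.05 and |log2FC| >= 0.8, exposed as
``DEFAULT_DE_CUTOFFS``.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrices import AbundanceMatrix

#: adjusted-p and |log2FC| thresholds for calling a feature differential
DEFAULT_DE_CUTOFFS = {"max_adj_p": 0.05, "min_abs_log2fc": 0.8}

_VARIANCE_FLOOR = 1e-12


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DETable(NamedTuple):
    table: pd.DataFrame
    n_skipped: int  # features lacking >=2 non-missing replicates in a group


def two_sample_test(
    m: AbundanceMatrix,
    group_a: list[str],
    group_b: list[str],
    moderated: bool = False,
    prior_df: float = 4.0,
) -> DETable:
    """Two-sided two-sample t-tests per feature (A minus B on log2 scale).

    Features need >= 2 non-missing replicates in each group; others are
    skipped and counted.  Zero within-group variance is handled with a tiny
    variance floor and flagged.  BH adjustment runs over all tested features.
    """
    m.require_scale("log2")
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValidationError(f"group {name} needs >= 2 samples")
        missing = [s for s in grp if s not in m.samples]
        if missing:
            raise ValidationError(f"group {name} samples not in matrix: {missing}")

    a = m.data[group_a].to_numpy(dtype=float)
    b = m.data[group_b].to_numpy(dtype=float)
    n_a = (~np.isnan(a)).sum(axis=1)
    n_b = (~np.isnan(b)).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # empty/df<=0 slices
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)

    log2fc = mean_a - mean_b
    df_pool = n_a + n_b - 2
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / np.where(df_pool > 0, df_pool, 1)

    if moderated:
        s2 = pooled[testable]
        prior_var = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else _VARIANCE_FLOOR
        d = df_pool.astype(float)
        pooled = (prior_df * prior_var + d * pooled) / (prior_df + d)
        df_pool = df_pool + prior_df

    zero_var = testable & (pooled < _VARIANCE_FLOOR)
    pooled = np.maximum(pooled, _VARIANCE_FLOOR)
    se = np.sqrt(pooled * (1.0 / np.maximum(n_a, 1) + 1.0 / np.maximum(n_b, 1)))
    t = log2fc / se
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(df_pool, 1))

    idx = m.data.index[testable]
    table = pd.DataFrame(
        {
            "feature_id": idx,
            "log2fc": log2fc[testable],
            "t": t[testable],
            "df": df_pool[testable],
            "p": p[testable],
            "n_a": n_a[testable],
            "n_b": n_b[testable],
            "zero_variance": zero_var[testable],
        }
    )
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return DETable(table.reset_index(drop=True), int((~testable).sum()))


def de_hits(de: pd.DataFrame, cutoffs: Mapping[str, float] = DEFAULT_DE_CUTOFFS) -> pd.DataFrame:
    """Rows passing the differential-abundance convention."""
    return de[
        (de["adj_p"] <= cutoffs["max_adj_p"])
        & (de["log2fc"].abs() >= cutoffs["min_abs_log2fc"])
    ]


def one_way_anova(
    m: AbundanceMatrix,
    condition_map: Mapping[str, str],
    reference: str = "Control 4 h",
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Classic one-way ANOVA per feature with per-condition log2FC vs reference.

    Returns F, p, BH-adjusted p, one ``log2fc_vs_ref[<condition>]`` column per
    condition, and the max |log2FC| across non-reference conditions.
    """
    m.require_scale("log2")
    cond = pd.Series({s: condition_map.get(s) for s in m.samples})
    if cond.isna().any():
        raise ValidationError(f"sample(s) without condition: {list(cond.index[cond.isna()])}")
    conditions = list(pd.unique(cond))
    if reference not in conditions:
        raise ValidationError(f"reference condition {reference!r} absent from design")

    cols = {c: cond.index[cond == c] for c in conditions}
    rows = []
    for feature, values in m.data.iterrows():
        groups = {c: values[cols[c]].dropna().to_numpy() for c in conditions}
        usable = {c: g for c, g in groups.items() if len(g) >= min_replicates}
        if len(usable) < 2 or reference not in usable:
            continue
        f, p = sps.f_oneway(*usable.values())
        ref_mean = usable[reference].mean()
        fcs = {c: (usable[c].mean() - ref_mean if c in usable else np.nan) for c in conditions}
        row = {"feature_id": feature, "F": f, "p": p}
        row.update({f"log2fc_vs_ref[{c}]": fcs[c] for c in conditions})
        non_ref = [abs(fcs[c]) for c in conditions if c != reference and not np.isnan(fcs[c])]
        row["max_abs_log2fc"] = max(non_ref) if non_ref else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return table


def anova_hits(
    anova: pd.DataFrame, max_adj_p: float = 0.05, min_abs_log2fc: float = 1.0
) -> pd.DataFrame:
    """ANOVA features with adj p <= threshold and |log2FC| >= threshold in
    at least one non-reference condition."""
    return anova[(anova["adj_p"] <= max_adj_p) & (anova["max_abs_log2fc"] >= min_abs_log2fc)]


class CVResult(NamedTuple):
    per_feature: pd.DataFrame  # feature_id, group, percent_cv
    median_per_group: pd.Series
    n_skipped: int  # (feature, group) cells with zero mean


def percent_cv(m: AbundanceMatrix, replicate_map: Mapping[str, str]) -> CVResult:
    """% coefficient of variation of raw intensities within replicate groups."""
    m.require_scale("raw")
    groups = pd.Series({s: replicate_map.get(s) for s in m.samples}).dropna()
    rows = []
    n_skipped = 0
    for group in pd.unique(groups):
        sub = m.data[groups.index[groups == group]]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        ok = (n >= 2) & (mean > 0)
        n_skipped += int(((n >= 2) & ~(mean > 0)).sum())
        for feature in sub.index[ok]:
            rows.append(
                {
                    "feature_id": feature,
                    "group": group,
                    "percent_cv": 100.0 * sd[feature] / mean[feature],
                }
            )
    per_feature = pd.DataFrame(rows)
    med = (
        per_feature.groupby("group")["percent_cv"].median()
        if len(per_feature)
        else pd.Series(dtype=float)
    )
    return CVResult(per_feature, med, n_skipped)


def sample_correlation(m: AbundanceMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between samples."""
    m.require_scale("log2")
    corr = m.data.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr


class PCAScores(NamedTuple):
    scores: pd.DataFrame  # samples x components
    explained_variance_pct: np.ndarray
    n_features_used: int


def pca_scores(m: AbundanceMatrix, n_components: int = 2) -> PCAScores:
    """Sample scores from a feature-centered PCA on complete-case features."""
    m.require_scale("log2")
    complete = m.data.dropna(axis=0)
    if len(complete) < 3:
        raise ValidationError("need >= 3 complete-case features for PCA")
    if complete.shape[1] < 3:
        raise ValidationError("need >= 3 samples for PCA")
    x = complete.T.to_numpy(dtype=float)  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    k = min(n_components, min(x.shape) - 1)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    return PCAScores(
        pd.DataFrame(
            scores, index=complete.columns, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        model.explained_variance_ratio_ * 100.0,
        len(complete),
    )
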