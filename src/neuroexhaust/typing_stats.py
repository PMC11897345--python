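"""Firing-type classification and cohort statistics.

Cells are typed by a simple firing rule — T1 fires no APs anywhere in the
step protocol, T2 exactly one, T3 two or more — and, independently, by
unguided structure discovery on the 21 primary features: z-scored PCA and
agglomerative (Ward) clustering, with agreement to the rule labels scored
by the adjusted Rand index. Group-level statistics cover per-genotype type
proportions, per-group feature-feature Pearson correlation matrices with a
significance display mask, and Holm-adjusted two-group comparisons.

Masked (missing) feature values — AP-shape features of non-firing cells —
are imputed by the cohort column median inside this stage only; an
indicator is kept so downstream consumers can see what was imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .ccfeatures import PRIMARY_FEATURES

__all__ = [
    "TypingResult",
    "PCAResult",
    "CorrMatrix",
    "holm_adjust",
    "rule_type",
    "prepare_matrix",
    "pca_embed",
    "hcluster",
    "type_proportions",
    "correlation_matrix",
    "group_compare",
    "classify_cohort",
]

TYPE_LABELS = ("T1", "T2", "T3")


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down family-wise adjustment of a p-value family.

    Never decreases a p-value and preserves the raw ordering.
    """
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def rule_type(max_ap_count: float) -> str | None:
    """Firing-rule label: 0 APs -> T1, exactly 1 -> T2, >= 2 -> T3.

    Returns None (unclassified) when the AP count is missing.
    """
    if max_ap_count is None or not np.isfinite(max_ap_count):
        return None
    n = int(max_ap_count)
    if n == 0:
        return "T1"
    if n == 1:
        return "T2"
    return "T3"


def prepare_matrix(
    cohort: pd.DataFrame,
    features: Sequence[str] = tuple(PRIMARY_FEATURES),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute masked entries and z-score columns.

    Returns ``(z, imputed_mask)``. Columns with zero variance (after
    imputation) are dropped with a warning, as they carry no structure.
    """
    x = cohort.loc[:, list(features)].astype(float).copy()
    mask = x.isna()
    x = x.fillna(x.median(numeric_only=True))
    sd = x.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        import warnings

        warnings.warn(f"dropping zero-variance feature(s): {dead}")
        x = x.drop(columns=dead)
        mask = mask.drop(columns=dead)
        sd = sd.drop(index=dead)
    if x.isna().any().any():
        # a column that is entirely missing has no median; drop it
        allna = x.columns[x.isna().any()].tolist()
        x = x.drop(columns=allna)
        mask = mask.drop(columns=allna)
        sd = sd.drop(index=allna)
    z = (x - x.mean()) / x.std(ddof=0)
    return z, mask


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # feature x component
    scores: pd.DataFrame            # cell x component
    variance_explained: np.ndarray  # fraction per retained component


def pca_embed(
    cohort: pd.DataFrame,
    n_components: int = 2,
    features: Sequence[str] = tuple(PRIMARY_FEATURES),
) -> PCAResult:
    """PCA of the z-scored, median-imputed primary-feature matrix.

    Component sign is fixed by forcing each loading vector's
    largest-magnitude entry positive, making the embedding deterministic.
    """
    z, _ = prepare_matrix(cohort, features)
    if len(z) < 3:
        raise ValueError("PCA needs at least 3 cells")
    n_components = min(n_components, min(z.shape))
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(z.values)
    loadings = p.components_.T  # feature x component
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    idx = cohort["cell_id"] if "cell_id" in cohort else cohort.index
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=z.columns, columns=cols),
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        variance_explained=p.explained_variance_ratio_,
    )


def hcluster(
    cohort: pd.DataFrame,
    k: int = 3,
    features: Sequence[str] = tuple(PRIMARY_FEATURES),
) -> np.ndarray:
    """Agglomerative Ward/Euclidean clustering of the z-scored matrix,
    cut at ``k`` clusters and relabelled 1..k by ascending mean max-AP
    count (ties broken by cluster size) so cluster 1 is the least
    excitable. Returns integer labels aligned with the cohort rows.
    """
    z, _ = prepare_matrix(cohort, features)
    if k > len(z):
        raise ValueError(f"k={k} exceeds the number of cells ({len(z)})")
    if k == 1:
        return np.ones(len(z), dtype=int)
    lk = linkage(z.values, method="ward", metric="euclidean")
    raw = fcluster(lk, t=k, criterion="maxclust")
    order_key = {}
    for c in np.unique(raw):
        sel = raw == c
        if "max_ap_count" in cohort:
            mean_ap = float(np.nanmean(cohort.loc[sel, "max_ap_count"]))
        else:
            mean_ap = float(np.mean(z.values[sel]))
        order_key[c] = (mean_ap, int(sel.sum()))
    order = sorted(order_key, key=lambda c: order_key[c])
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


@dataclass
class TypingResult:
    labels: pd.Series               # per-cell rule label (T1/T2/T3 or None)
    clusters: np.ndarray            # per-cell cluster id, 1..k
    ari: float                      # rule labels vs clusters
    proportions: pd.DataFrame       # group x type fractions


def classify_cohort(cohort: pd.DataFrame, k: int = 3,
                    group_col: str = "genotype") -> TypingResult:
    """Rule-type every cell, cluster the cohort, and score agreement."""
    labels = cohort["max_ap_count"].map(rule_type)
    clusters = hcluster(cohort, k=k)
    ok = labels.notna()
    ari = adjusted_rand_score(labels[ok], clusters[ok.values]) if ok.any() \
        else np.nan
    props = type_proportions(labels, cohort[group_col])
    return TypingResult(labels=labels, clusters=clusters, ari=float(ari),
                        proportions=props)


def type_proportions(
    labels: Sequence[str], groups: Sequence[str]
) -> pd.DataFrame:
    """Per-group fractions of each firing type (rows sum to 1).

    A chi-square test of distribution difference across groups is attached
    as ``df.attrs['chi2_p']`` when every expected count is positive.
    """
    df = pd.DataFrame({"label": list(labels), "group": list(groups)})
    if df["group"].isna().any() or (df.groupby("group").size() == 0).any():
        raise ValueError("every cell needs a non-empty group")
    counts = (df.groupby(["group", "label"], observed=True).size()
              .unstack(fill_value=0)
              .reindex(columns=[t for t in TYPE_LABELS], fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    if counts.shape[0] >= 2 and (counts.values.sum(axis=0) > 0).all():
        try:
            chi2 = stats.chi2_contingency(
                counts.loc[:, counts.sum(axis=0) > 0])
            props.attrs["chi2_p"] = float(chi2.pvalue)
        except ValueError:
            pass
    return props


@dataclass
class CorrMatrix:
    r: pd.DataFrame        # feature x feature Pearson r
    p: pd.DataFrame        # two-sided p from the t distribution, n-2 df
    mask: pd.DataFrame     # True where displayed (p < alpha)
    alpha: float


def correlation_matrix(
    cohort: pd.DataFrame,
    features: Sequence[str] = tuple(PRIMARY_FEATURES),
    alpha: float = 0.01,
) -> CorrMatrix:
    """Pairwise-complete Pearson correlations with a display mask.

    p-values are two-sided from the t distribution with n-2 degrees of
    freedom; pairs with fewer than 4 complete observations or a constant
    feature get NaN r and are never displayed. The diagonal is r = 1 and
    always displayed.
    """
    x = cohort.loc[:, list(features)].astype(float)
    cols = x.columns
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    for i in range(m):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, m):
            pair = x.iloc[:, [i, j]].dropna()
            n = len(pair)
            if n < 4:
                continue
            a, b = pair.iloc[:, 0].values, pair.iloc[:, 1].values
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    mask = (pdf < alpha) & rdf.notna()
    return CorrMatrix(r=rdf, p=pdf, mask=mask, alpha=alpha)


def group_compare(
    cohort: pd.DataFrame,
    features: Sequence[str],
    group_col: str = "genotype",
    method: str = "t",
    adjust: str = "holm",
) -> pd.DataFrame:
    """Per-feature two-group (or k-group) comparison with family-wise
    adjustment over the feature family.

    ``method``: ``"t"`` (Welch two-sample), ``"mann_whitney"``, or
    ``"kruskal"`` (any number of groups). Holm step-down adjustment is the
    default; ``adjust=None`` reports raw p only (the convention for the
    Kruskal-Wallis metabolite panels).
    """
    groups = cohort[group_col]
    names = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for feat in features:
        samples = [cohort.loc[groups == g, feat].dropna().values for g in names]
        stat, pval = _run_test(samples, method)
        rows.append({"feature": feat, "statistic": stat, "p_raw": pval,
                     "n_per_group": tuple(len(s) for s in samples)})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        finite = out["p_raw"].notna()
        adj = np.full(len(out), np.nan)
        if finite.any():
            adj[finite.values] = holm_adjust(out.loc[finite, "p_raw"])
        out["p_adj"] = adj
    elif adjust not in (None, "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def _run_test(samples: list[np.ndarray], method: str) -> tuple[float, float]:
    if any(len(s) < 2 for s in samples):
        return np.nan, np.nan
    if method == "t":
        if len(samples) != 2:
            raise ValueError("t-test needs exactly two groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
    elif method == "mann_whitney":
        if len(samples) != 2:
            raise ValueError("Mann-Whitney needs exactly two groups")
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided")
    elif method == "kruskal":
        try:
            res = stats.kruskal(*samples)
        except ValueError:  # all values identical
            return np.nan, 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
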