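"""Cohort statistics: differential abundance, FDR, PCA, and clustering.

Works on the samples x proteins matrix of normalized log2 abundance
estimators.  Condition effects across control / cirrhosis / HCC are
assessed per protein with a fixed-effects linear model and F tests —
an overall condition test plus the three pairwise contrasts — with
Benjamini–Hochberg FDR control applied per contrast family across
proteins.  For the multivariate views, protein columns are centered and
scaled before principal component analysis and before Ward hierarchical
clustering of protein profiles on a Euclidean distance matrix.

Missing cells (typically analytes near the detection limit, a
left-censoring mechanism) are imputed with the protein's half-minimum
observed value for the complete-matrix methods only; the per-protein
differential fits use row-wise deletion instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .srm_data import ProteinAbundanceMatrix, ValidationError

__all__ = [
    "CONTRASTS",
    "fit_condition_model",
    "benjamini_hochberg",
    "run_pca",
    "cluster_proteins",
    "impute_half_min",
    "PCAResult",
    "ClusterResult",
]

CONDITION_ORDER = ["control", "cirrhosis", "HCC"]
CONTRASTS = [("HCC", "control"), ("cirrhosis", "control"), ("HCC", "cirrhosis")]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ProteinAbundanceMatrix):
        return matrix.values
    return matrix


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving.

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values,
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fit_condition_model(
    matrix,
    metadata: pd.DataFrame,
    subject_col: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein linear model of abundance on clinical condition.

    For each protein: a one-way fixed-effects fit across the three
    conditions (row-wise deletion of missing cells), the overall condition
    F test, and the three pairwise contrasts with effects in log2 units
    and F statistics from the pooled residual variance.  q-values are BH
    within each contrast family (overall, and each pairwise contrast)
    across proteins.

    When ``subject_col`` names a metadata column with repeated subjects
    (e.g. paired tissue from one patient), subject blocking is added via a
    two-way OLS fit (statsmodels) and the condition test is computed
    against the blocked residual.

    Returns a tidy DataFrame: protein, contrast ('overall' or 'A-B'),
    effect, F_statistic, p_value, q_value, untestable, zero_variance.
    """
    values = _as_frame(matrix)
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns \
        else metadata
    cond = meta.loc[values.index, "condition"]
    if subject_col is not None and meta[subject_col].duplicated().any():
        return _fit_blocked(values, cond, meta.loc[values.index, subject_col])

    rows = []
    for prot in values.columns:
        y = values[prot]
        ok = y.notna()
        yv, cv = y[ok].values, cond[ok].values
        groups = {c: yv[cv == c] for c in CONDITION_ORDER}
        sizes = {c: len(g) for c, g in groups.items()}
        untestable = any(n < 2 for n in sizes.values())
        n, k = len(yv), len(groups)
        if untestable:
            for label in ["overall"] + [f"{a}-{b}" for a, b in CONTRASTS]:
                rows.append(dict(protein=prot, contrast=label, effect=np.nan,
                                 F_statistic=np.nan, p_value=np.nan,
                                 q_value=np.nan, untestable=True,
                                 zero_variance=False))
            continue
        means = {c: g.mean() for c, g in groups.items()}
        sse = sum(((g - means[c]) ** 2).sum() for c, g in groups.items())
        mse = sse / (n - k)
        grand = yv.mean()
        ssb = sum(sizes[c] * (means[c] - grand) ** 2 for c in groups)
        zero_var = mse == 0
        if zero_var and ssb == 0:
            f_overall, p_overall = np.nan, 1.0
        elif zero_var:
            f_overall, p_overall = np.inf, np.nextafter(0, 1)
        else:
            f_overall = (ssb / (k - 1)) / mse
            p_overall = float(st.f.sf(f_overall, k - 1, n - k))
        rows.append(dict(protein=prot, contrast="overall", effect=np.nan,
                         F_statistic=f_overall, p_value=max(p_overall, 1e-300),
                         q_value=np.nan, untestable=False,
                         zero_variance=zero_var))
        for a, b in CONTRASTS:
            eff = means[a] - means[b]
            if zero_var:
                p = 1.0 if eff == 0 else np.nextafter(0, 1)
                fstat = np.nan if eff == 0 else np.inf
            else:
                se = np.sqrt(mse * (1 / sizes[a] + 1 / sizes[b]))
                t = eff / se
                fstat = t ** 2
                p = float(2 * st.t.sf(abs(t), n - k))
            rows.append(dict(protein=prot, contrast=f"{a}-{b}", effect=eff,
                             F_statistic=fstat, p_value=max(p, 1e-300),
                             q_value=np.nan, untestable=False,
                             zero_variance=zero_var))
    out = pd.DataFrame(rows)
    for label in out["contrast"].unique():
        sel = (out["contrast"] == label) & out["p_value"].notna()
        if sel.any():
            out.loc[sel, "q_value"] = benjamini_hochberg(out.loc[sel, "p_value"])
    return out


def _fit_blocked(values: pd.DataFrame, cond: pd.Series,
                 subject: pd.Series) -> pd.DataFrame:
    """Two-way (condition + subject) fits for repeated-measures designs."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for prot in values.columns:
        df = pd.DataFrame({"y": values[prot], "condition": cond,
                           "subject": subject}).dropna()
        try:
            fit = smf.ols("y ~ C(condition) + C(subject)", data=df).fit()
            an = sm.stats.anova_lm(fit, typ=2)
            f = float(an.loc["C(condition)", "F"])
            p = float(an.loc["C(condition)", "PR(>F)"])
        except Exception:
            f, p = np.nan, np.nan
        rows.append(dict(protein=prot, contrast="overall", effect=np.nan,
                         F_statistic=f, p_value=p, q_value=np.nan,
                         untestable=not np.isfinite(p), zero_variance=False))
        means = df.groupby("condition")["y"].mean()
        mse = fit.mse_resid if np.isfinite(p) else np.nan
        nsz = df.groupby("condition")["y"].size()
        for a, b in CONTRASTS:
            if a in means.index and b in means.index and np.isfinite(mse):
                eff = means[a] - means[b]
                se = np.sqrt(mse * (1 / nsz[a] + 1 / nsz[b]))
                t = eff / se
                pv = float(2 * st.t.sf(abs(t), fit.df_resid))
                rows.append(dict(protein=prot, contrast=f"{a}-{b}", effect=eff,
                                 F_statistic=t ** 2, p_value=max(pv, 1e-300),
                                 q_value=np.nan, untestable=False,
                                 zero_variance=False))
            else:
                rows.append(dict(protein=prot, contrast=f"{a}-{b}",
                                 effect=np.nan, F_statistic=np.nan,
                                 p_value=np.nan, q_value=np.nan,
                                 untestable=True, zero_variance=False))
    out = pd.DataFrame(rows)
    for label in out["contrast"].unique():
        sel = (out["contrast"] == label) & out["p_value"].notna()
        if sel.any():
            out.loc[sel, "q_value"] = benjamini_hochberg(out.loc[sel, "p_value"])
    return out


def impute_half_min(matrix) -> pd.DataFrame:
    """Fill missing cells with half the protein's minimum observed value
    (left-censored, below-detection-limit mechanism)."""
    values = _as_frame(matrix).copy()
    for col in values.columns:
        if values[col].isna().any():
            values[col] = values[col].fillna(values[col].min() / 2.0)
    return values


def _center_scale(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    warn = []
    sd = values.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        warn.append(f"zero-variance proteins excluded: {', '.join(zero)}")
        values = values.drop(columns=zero)
        sd = sd.drop(zero)
    scaled = (values - values.mean(axis=0)) / sd
    return scaled, warn


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # proteins x components
    variance_explained: np.ndarray  # fractions summing to 1
    warnings: list[str] = field(default_factory=list)


def run_pca(matrix) -> PCAResult:
    """PCA of the centered, unit-variance protein columns.

    Scores and loadings come from the singular value decomposition of the
    scaled matrix; variance-explained fractions sum to 1 over the
    min(n_samples - 1, n_proteins) retained components.
    """
    values = _as_frame(matrix)
    if values.isna().any().any():
        values = impute_half_min(values)
    if len(values) < 3:
        raise ValidationError("PCA needs at least 3 samples")
    scaled, warn = _center_scale(values)
    X = scaled.values
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    ncomp = int(min(X.shape[0] - 1, X.shape[1]))
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    comp = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(u * s, index=scaled.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=scaled.columns, columns=comp)
    var = s ** 2
    return PCAResult(scores=scores, loadings=loadings,
                     variance_explained=var / var.sum(), warnings=warn)


@dataclass
class ClusterResult:
    linkage: np.ndarray             # scipy linkage matrix over proteins
    assignments: dict[str, int]     # protein -> cluster id (1..k)
    proteins: list[str]
    newick: str


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def cluster_proteins(matrix, k: int = 2) -> ClusterResult:
    """Ward hierarchical clustering of protein abundance profiles.

    Protein columns are centered and scaled, then proteins are clustered
    by Ward's method on the Euclidean distance matrix between their
    profiles across samples, and the dendrogram is cut at ``k`` clusters
    (the cluster count is an inspection choice; 2 is the default).
    """
    values = _as_frame(matrix)
    if values.isna().any().any():
        values = impute_half_min(values)
    scaled, _ = _center_scale(values)
    proteins = list(scaled.columns)
    if k > len(proteins):
        raise ValidationError(f"k={k} exceeds {len(proteins)} proteins")
    X = scaled.values.T  # proteins as observations
    Z = sch.linkage(X, method="ward", metric="euclidean")
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        linkage=Z,
        assignments={p: int(c) for p, c in zip(proteins, flat)},
        proteins=proteins,
        newick=_linkage_to_newick(Z, proteins),
    )
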