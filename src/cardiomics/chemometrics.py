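"""Metabolomics chemometrics: filtering, normalisation, PCA/PLS-DA, VIP,
univariate testing with FDR, and pathway over-representation.

The processing chain mirrors common GC-MS practice: features are filtered
by missingness and by relative standard deviation across pooled QC
injections, intensities are median-normalised per sample, square-root
transformed and auto-scaled per feature, and group separation is assessed
by PCA (unsupervised) and PLS-DA (supervised) with Variable Importance in
Projection (VIP) scores and cross-validated R2/Q2.  Feature significance
combines an unpaired t-test with Benjamini-Hochberg FDR and the VIP score
(FDR < 0.05, p < 0.05, VIP > 1 by default); significant metabolites feed a
hypergeometric over-representation analysis against a pathway library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .flim_synth import ValidationError
from .metabo_synth import FeatureTable

__all__ = [
    "FilterReport",
    "NormalizationResult",
    "PcaResult",
    "PlsdaModel",
    "CvResult",
    "UnivariateResult",
    "EnrichmentResult",
    "filter_features",
    "impute_half_min",
    "normalize",
    "pca",
    "plsda",
    "cross_validate",
    "univariate",
    "ora_enrichment",
]


@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int
    n_removed_qc_rsd: int
    n_kept: int


def filter_features(
    table: FeatureTable,
    missing_max: float = 0.65,
    qc_rsd_max: float = 0.30,
) -> tuple[FeatureTable, FilterReport]:
    """Drop uninformative features by missingness and QC dispersion.

    Features missing in at least ``missing_max`` of all samples are
    removed first; then features whose relative standard deviation
    (SD/mean) across QC injections is at least ``qc_rsd_max``.  Without
    QC samples the RSD rule is skipped with a warning.  Idempotent.
    """
    intens = table.intensities
    n_input = intens.shape[1]
    missing_frac = intens.isna().mean(axis=0)
    keep1 = missing_frac < missing_max
    n_removed_missing = int((~keep1).sum())
    intens = intens.loc[:, keep1]

    n_removed_rsd = 0
    if table.sample_meta["is_qc"].any():
        qc = intens.loc[table.sample_meta["is_qc"]]
        with np.errstate(invalid="ignore"):
            rsd = qc.std(ddof=1) / qc.mean()
        keep2 = ~(rsd >= qc_rsd_max)  # NaN RSD (no QC data) is kept
        n_removed_rsd = int((~keep2).sum())
        intens = intens.loc[:, keep2]
    else:
        warnings.warn("no QC samples: skipping the QC-RSD filter")

    out = table.copy_with(intens)
    return out, FilterReport(n_input, n_removed_missing, n_removed_rsd, intens.shape[1])


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace missing values by half the feature's minimum observed intensity."""
    intens = table.intensities.copy()
    fill = intens.min(axis=0) / 2.0
    return table.copy_with(intens.fillna(fill))


@dataclass
class NormalizationResult:
    """Final table plus every intermediate stage (keyed by step name).

    ``stages["input"]`` is the starting table; fold changes are best read
    off a pre-autoscaling stage, where intensities are still positive.
    """

    table: FeatureTable
    stages: dict[str, FeatureTable] = field(default_factory=dict)
    steps: tuple[str, ...] = ()


def normalize(
    table: FeatureTable,
    steps: tuple[str, ...] = ("median_norm", "sqrt_transform", "autoscale"),
) -> NormalizationResult:
    """Apply the normalisation chain in order.

    median_norm: divide each sample by its median intensity (rescaled by
    the overall median so magnitudes stay interpretable); sqrt_transform:
    element-wise square root; log_transform: log2; autoscale: per-feature
    mean 0 / SD 1 (sample SD).
    """
    intens = table.intensities.copy()
    stages = {"input": table}
    for step in steps:
        if step == "median_norm":
            med = intens.median(axis=1, skipna=True)
            if (med <= 0).any():
                bad = med.index[med <= 0][0]
                raise ValidationError(f"sample {bad!r} has a non-positive median intensity")
            intens = intens.div(med, axis=0) * float(np.median(med))
        elif step == "sqrt_transform":
            intens = np.sqrt(intens)
        elif step == "log_transform":
            if (intens <= 0).any().any():
                raise ValidationError("log transform requires positive intensities")
            intens = np.log2(intens)
        elif step == "autoscale":
            intens = (intens - intens.mean(axis=0)) / intens.std(axis=0, ddof=1)
        else:
            raise ValidationError(f"unknown normalisation step {step!r}")
        stages[step] = table.copy_with(intens.copy())
    return NormalizationResult(stages[steps[-1]] if steps else table, stages, tuple(steps))


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(table: FeatureTable, n_components: int = 2, include_qc: bool = True) -> PcaResult:
    """Principal component analysis of the (complete) intensity matrix."""
    X = table.intensities if include_qc else table.biological
    if X.isna().any().any():
        raise ValidationError(
            "missing values present: impute first (e.g. impute_half_min) or drop features"
        )
    n_components = min(n_components, min(X.shape) - 1)
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        pd.DataFrame(scores, index=X.index, columns=cols),
        pd.DataFrame(model.components_.T, index=X.columns, columns=cols),
        model.explained_variance_ratio_,
    )


@dataclass
class PlsdaModel:
    n_components: int
    scores: pd.DataFrame
    weights: pd.DataFrame
    loadings: pd.DataFrame
    y_variance_explained: np.ndarray
    r2: float
    vip: pd.Series
    classes: tuple[str, ...]


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, tuple[str, ...]]:
    classes = tuple(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValidationError("PLS-DA requires at least two groups")
    if len(classes) == 2:
        y = (labels == classes[1]).to_numpy(float)[:, None]
    else:
        y = np.stack([(labels == c).to_numpy(float) for c in classes], axis=1)
    return y, classes


def plsda(table: FeatureTable, labels=None, n_components: int = 2) -> PlsdaModel:
    """Partial least squares discriminant analysis with VIP scores.

    Fits PLS on the biological samples (QCs excluded) against a one-hot
    class response.  VIP for feature j is

        VIP_j = sqrt( p * sum_a SSY_a * (w_aj / ||w_a||)^2 / sum_a SSY_a )

    with SSY_a the response variance captured by component a, so the mean
    squared VIP is exactly 1 (sum VIP^2 = n_features).
    """
    X_df = table.biological
    labels = table.groups if labels is None else pd.Series(labels, index=X_df.index)
    if X_df.isna().any().any():
        raise ValidationError("missing values present: impute before PLS-DA")
    y, classes = _one_hot(labels)
    X = X_df.to_numpy(float)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(f"n_components truncated from {n_components} to rank {max_rank}")
        n_components = max_rank

    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)

    T = model.x_scores_  # (n, A)
    W = model.x_weights_  # (p, A)
    Q = model.y_loadings_  # (m, A)
    # response variance captured per component
    ssy = np.array([(T[:, a] ** 2).sum() * (Q[:, a] ** 2).sum() for a in range(n_components)])
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = X.shape[1]
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())

    y_hat = model.predict(X)
    yc = y - y.mean(axis=0)
    tss = float((yc**2).sum())
    r2 = 1.0 - float(((y - y_hat) ** 2).sum()) / tss

    comp_cols = [f"LV{a + 1}" for a in range(n_components)]
    return PlsdaModel(
        n_components=n_components,
        scores=pd.DataFrame(T, index=X_df.index, columns=comp_cols),
        weights=pd.DataFrame(W, index=X_df.columns, columns=comp_cols),
        loadings=pd.DataFrame(model.x_loadings_, index=X_df.columns, columns=comp_cols),
        y_variance_explained=ssy / tss,
        r2=r2,
        vip=pd.Series(vip, index=X_df.columns, name="VIP"),
        classes=classes,
    )


@dataclass
class CvResult:
    r2: float
    q2: float
    folds: str


def cross_validate(
    table: FeatureTable,
    labels=None,
    n_components: int = 2,
    folds: int | str = "auto",
) -> CvResult:
    """R2 (full fit) and Q2 (held-out prediction) of the PLS-DA model.

    With ``folds="auto"`` leave-one-out is used whenever the smallest
    group has at most 3 samples (the triplicate design), otherwise k-fold
    with k = folds.  Q2 = 1 - PRESS / TSS and may be negative for
    uninformative models.
    """
    X_df = table.biological
    labels = table.groups if labels is None else pd.Series(labels, index=X_df.index)
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValidationError("cross-validation needs >= 2 samples in every group")
    y, _ = _one_hot(labels)
    X = X_df.to_numpy(float)
    n = X.shape[0]

    if folds == "auto":
        mode = "loo" if counts.min() <= 3 else "kfold5"
    elif folds in ("loo", n):
        mode = "loo"
    else:
        mode = f"kfold{int(folds)}"

    if mode == "loo":
        splits = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    else:
        k = int(mode.removeprefix("kfold"))
        idx = np.arange(n)
        parts = np.array_split(idx, k)
        splits = [(np.setdiff1d(idx, p).tolist(), p.tolist()) for p in parts]

    press = 0.0
    for train, test in splits:
        a = min(n_components, len(train) - 1, X.shape[1])
        m = PLSRegression(n_components=a, scale=False)
        m.fit(X[train], y[train])
        press += float(((y[test] - m.predict(X[test])) ** 2).sum())
    yc = y - y.mean(axis=0)
    tss = float((yc**2).sum())
    q2 = 1.0 - press / tss

    full = plsda(table, labels, n_components)
    return CvResult(r2=full.r2, q2=q2, folds=mode)


@dataclass
class UnivariateResult:
    """Per-feature unpaired t-test with BH FDR, fold change and the
    combined significance call (FDR < fdr_max, p < p_max, VIP > vip_min)."""

    table: pd.DataFrame  # columns: t, p, q, log2_fc, vip, significant
    rule: str


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    q = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
    return q


def univariate(
    table: FeatureTable,
    labels=None,
    fc_table: FeatureTable | None = None,
    vip: pd.Series | None = None,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
    vip_min: float = 1.0,
) -> UnivariateResult:
    """Unpaired t-tests per feature with BH FDR and log2 fold changes.

    Tests run on the (autoscaled) analysis table; fold changes are the
    log2 ratio of group means taken from ``fc_table`` — typically the
    normalised, pre-autoscaling stage where intensities are positive.
    Features with zero within-group variance are flagged with NaN p.
    The significance flag applies the three-way rule when a VIP series is
    given, else the two-way p/FDR rule.
    """
    X_df = table.biological
    labels = table.groups if labels is None else pd.Series(labels, index=X_df.index)
    classes = tuple(dict.fromkeys(labels))
    if len(classes) != 2:
        raise ValidationError("univariate testing expects exactly two groups")
    g1 = X_df.loc[labels == classes[0]].to_numpy(float)
    g2 = X_df.loc[labels == classes[1]].to_numpy(float)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features trip scipy's precision warning; they are
        # flagged explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(g2, g1, axis=0)
    degenerate = ~np.isfinite(p)
    p_for_q = np.where(degenerate, 1.0, p)
    q = benjamini_hochberg(p_for_q)
    q = np.where(degenerate, np.nan, q)

    fc_src = fc_table if fc_table is not None else table
    f1 = fc_src.biological.loc[labels == classes[0]].mean(axis=0).to_numpy(float)
    f2 = fc_src.biological.loc[labels == classes[1]].mean(axis=0).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(f2 / f1)

    out = pd.DataFrame(
        {"t": t, "p": p, "q": q, "log2_fc": log2_fc},
        index=X_df.columns,
    )
    if vip is not None:
        out["vip"] = vip.reindex(out.index)
        out["significant"] = (out["q"] < fdr_max) & (out["p"] < p_max) & (out["vip"] > vip_min)
        rule = f"FDR<{fdr_max} & p<{p_max} & VIP>{vip_min}"
    else:
        out["significant"] = (out["q"] < fdr_max) & (out["p"] < p_max)
        rule = f"FDR<{fdr_max} & p<{p_max}"
    out["significant"] = out["significant"].fillna(False)
    return UnivariateResult(out, rule)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per pathway: hits, size, universe, query, p, enrichment_ratio, enriched
    p_max: float


def ora_enrichment(
    query,
    library: dict[str, list[str]],
    universe,
    p_max: float = 0.1,
) -> EnrichmentResult:
    """Hypergeometric over-representation analysis of a metabolite set.

    For each pathway with K members in a universe of M features and a
    query of n significant features with k hits, p = P[X >= k] under the
    hypergeometric null.  The enrichment ratio is observed/expected hits.
    A lenient default cutoff (p < 0.1) compensates for the limited
    coverage of GC-MS-amenable metabolites.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValidationError("empty query set")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, members in library.items():
        members_in = set(members) & universe
        K = len(members_in)
        if K == 0:
            continue
        k = len(members_in & query)
        pval = float(stats.hypergeom.sf(k - 1, M, K, n))
        expected = K * n / M
        rows.append(
            {
                "pathway": name,
                "hits": k,
                "size": K,
                "universe": M,
                "query": n,
                "p": pval,
                "enrichment_ratio": k / expected if expected > 0 else np.nan,
                "enriched": pval < p_max,
            }
        )
    tab = pd.DataFrame(rows).set_index("pathway").sort_values("p") if rows else pd.DataFrame()
    return EnrichmentResult(tab, p_max)
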