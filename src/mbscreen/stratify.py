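"""Expression-based patient stratification and survival comparison.

The procedure mirrors how resistant-model expression signatures are
projected onto a patient cohort:

1. paired differential selection between matched sensitive (S) and
   resistant (R) models — per-feature paired t-test on per-model
   medians, with a Z score standardizing the median S/R differences
   across features;
2. Spearman correlation of every patient to every reference (resistant
   model) sample over the differential gene set, giving a patients ×
   references similarity matrix;
3. k-means (Euclidean) on the rows of that matrix, with k chosen by the
   elbow rule on the within-cluster sum of squares (WSS);
4. Kaplan–Meier curves per cluster and a log-rank (Mantel–Cox) test of
   overall-survival differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans

from ._errors import InsufficientDesignError, ParameterError, ValidationError


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values (log2 scale) with annotations."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids
    sample_info: pd.DataFrame | None = None  # index: sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.data.isna().any().any() or not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("expression values must be finite")

    def model_of(self, sample: str) -> str:
        if self.sample_info is None or "model" not in self.sample_info.columns:
            raise ValidationError("sample_info with a 'model' column required")
        return str(self.sample_info.loc[sample, "model"])


def paired_differential(
    S: ExpressionMatrix, R: ExpressionMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t-test of resistant vs sensitive per-model medians.

    Features are first intersected across both matrices (only features
    measured in every model enter). Per model, replicate samples are
    collapsed to their median; the paired test then runs across models.
    The per-feature Z score standardizes the median (over models) R−S
    difference across all features. Returns a frame indexed by feature
    with columns median_S, median_R, z_of_median, p_paired, selected.
    """
    genes = S.data.index.intersection(R.data.index)
    if len(genes) == 0:
        raise InsufficientDesignError("no shared features between S and R")

    def per_model_medians(x: ExpressionMatrix) -> pd.DataFrame:
        models = [x.model_of(s) for s in x.data.columns]
        return x.data.loc[genes].T.groupby(pd.Index(models, name="model")).median().T

    med_S, med_R = per_model_medians(S), per_model_medians(R)
    shared_models = med_S.columns.intersection(med_R.columns)
    if len(shared_models) < 2:
        raise InsufficientDesignError(
            f"paired test needs >= 2 matched models, got {len(shared_models)}"
        )
    a = med_R[shared_models].to_numpy()
    b = med_S[shared_models].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_rel(a, b, axis=1)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)  # zero-variance pairs: no evidence
    diff = np.median(a - b, axis=1)
    z = (diff - diff.mean()) / (diff.std(ddof=1) if len(diff) > 1 else 1.0)
    return pd.DataFrame(
        {
            "median_S": b.mean(axis=1),
            "median_R": a.mean(axis=1),
            "z_of_median": z,
            "p_paired": p,
            "selected": p < alpha,
        },
        index=genes,
    )


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks down each column (ties get their mean rank)."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def correlate_to_references(
    cohort: ExpressionMatrix | pd.DataFrame,
    refs: ExpressionMatrix | pd.DataFrame,
    genes: list[str] | pd.Index | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each patient to each reference sample.

    Computed over the shared subset of ``genes`` (a differential gene
    list; all shared genes when None) as Pearson correlation of average
    ranks, vectorised over the full patients × references matrix.
    """
    coh = cohort.data if isinstance(cohort, ExpressionMatrix) else cohort
    ref = refs.data if isinstance(refs, ExpressionMatrix) else refs
    shared = coh.index.intersection(ref.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) < 3:
        raise InsufficientDesignError(
            f"only {len(shared)} shared genes; need >= 3"
        )
    rc = _rank_columns(coh.loc[shared].to_numpy(float))
    rr = _rank_columns(ref.loc[shared].to_numpy(float))
    rc = (rc - rc.mean(axis=0)) / rc.std(axis=0)
    rr = (rr - rr.mean(axis=0)) / rr.std(axis=0)
    corr = rc.T @ rr / len(shared)
    return pd.DataFrame(corr, index=coh.columns, columns=ref.columns)


@dataclass
class ElbowResult:
    k: int
    labels: np.ndarray
    wss_curve: pd.Series  # indexed by k = 1..k_max
    elbow_scores: pd.Series  # second differences, candidates 2..k_max−1


def elbow_kmeans(
    corr: pd.DataFrame | np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    restarts: int = 50,
    min_drop: float = 0.5,
) -> ElbowResult:
    """k-means over k = 1..k_max with elbow selection of k.

    The elbow is the k maximizing the second difference of the WSS
    curve, WSS(k−1) − 2·WSS(k) + WSS(k+1). A k > 1 is accepted only if
    clustering at that k removes at least ``min_drop`` of the total WSS
    (1 − WSS(k*)/WSS(1) ≥ min_drop, i.e. by default the partition must
    halve the pooled variance); otherwise the data are treated as one
    cluster. The guard exists because second differences alone can
    never return k = 1, yet k-means reduces WSS smoothly even on
    unclustered data (for a 1-D Gaussian the best 2-split removes at
    most 1 − 2/π ≈ 36%), whereas genuinely separated clusters place
    most variance between clusters. Degenerate all-identical input
    returns k = 1 directly.
    """
    X = corr.to_numpy(float) if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    n = len(X)
    if n < k_max + 1:
        raise InsufficientDesignError(f"need >= {k_max + 1} patients for k_max={k_max}")
    if np.allclose(X, X[0]):
        warnings.warn("all rows identical: k = 1", stacklevel=2)
        ks = pd.RangeIndex(1, k_max + 1, name="k")
        return ElbowResult(
            1, np.zeros(n, int), pd.Series(0.0, index=ks),
            pd.Series(0.0, index=pd.RangeIndex(2, k_max, name="k")),
        )
    wss, labels_by_k = [], {}
    center = X - X.mean(axis=0)
    wss.append(float(np.sum(center**2)))  # k = 1 closed form
    labels_by_k[1] = np.zeros(n, int)
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels_by_k[k] = km.fit_predict(X)
        wss.append(float(km.inertia_))
    wss_curve = pd.Series(wss, index=pd.RangeIndex(1, k_max + 1, name="k"))
    second_diff = pd.Series(
        [wss[k - 2] - 2 * wss[k - 1] + wss[k] for k in range(2, k_max)],
        index=pd.RangeIndex(2, k_max, name="k"),
    )
    k_star = int(second_diff.idxmax())
    if 1.0 - wss_curve[k_star] / wss_curve[1] < min_drop:
        k_star = 1
    return ElbowResult(k_star, labels_by_k[k_star], wss_curve, second_diff)


@dataclass
class SurvivalComparison:
    km_curves: dict[int, pd.DataFrame]  # cluster -> timeline/S(t) frame
    statistic: float
    p_value: float  # NaN when no events
    n_events: int
    pairwise: pd.DataFrame | None = None


def survival_compare(
    surv: pd.DataFrame, pairwise: bool = False
) -> SurvivalComparison:
    """Kaplan–Meier curves per cluster and log-rank (Mantel–Cox) test.

    ``surv`` needs columns time (years, >= 0), event (1 = death,
    0 = censored) and cluster. With zero events the KM curves are flat
    at 1 and the p-value is NaN.
    """
    for col in ("time", "event", "cluster"):
        if col not in surv.columns:
            raise ParameterError(f"survival table missing column {col!r}")
    if (surv["time"] < 0).any() or not surv["event"].isin((0, 1)).all():
        raise ValidationError("need time >= 0 and event in {0, 1}")
    clusters = sorted(surv["cluster"].unique())
    if len(clusters) < 2:
        raise InsufficientDesignError("need >= 2 clusters to compare")
    curves = {}
    for c in clusters:
        sub = surv[surv["cluster"] == c]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(c))
        curves[c] = kmf.survival_function_.rename(columns={str(c): "S"})
    n_events = int(surv["event"].sum())
    if n_events == 0:
        return SurvivalComparison(curves, float("nan"), float("nan"), 0)
    res = multivariate_logrank_test(surv["time"], surv["cluster"], surv["event"])
    pw = None
    if pairwise:
        rows = []
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                sub = surv[surv["cluster"].isin((a, b))]
                r = multivariate_logrank_test(sub["time"], sub["cluster"], sub["event"])
                rows.append({"a": a, "b": b, "statistic": r.test_statistic, "p": r.p_value})
        pw = pd.DataFrame(rows)
    return SurvivalComparison(
        curves, float(res.test_statistic), float(res.p_value), n_events, pw
    )


@dataclass
class CohortStratification:
    """End-to-end result: similarity matrix, clusters, survival."""

    corr: pd.DataFrame
    k: int
    labels: pd.Series  # indexed by patient id
    wss_curve: pd.Series
    survival: SurvivalComparison | None = None


def stratify_cohort(
    cohort: ExpressionMatrix | pd.DataFrame,
    refs: ExpressionMatrix | pd.DataFrame,
    genes: list[str] | None = None,
    surv: pd.DataFrame | None = None,
    k_max: int = 8,
    seed: int = 0,
    restarts: int = 50,
) -> CohortStratification:
    """Correlate → cluster → (optionally) compare survival."""
    corr = correlate_to_references(cohort, refs, genes)
    elbow = elbow_kmeans(corr, k_max=k_max, seed=seed, restarts=restarts)
    labels = pd.Series(elbow.labels, index=corr.index, name="cluster")
    survival = None
    if surv is not None and elbow.k > 1:
        merged = surv.copy()
        merged["cluster"] = labels.loc[merged.index].to_numpy()
        survival = survival_compare(merged)
    return CohortStratification(corr, elbow.k, labels, elbow.wss_curve, survival)
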