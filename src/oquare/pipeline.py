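"""Statistical evaluation of a scored cohort.

The trial's outcome analysis, runnable on any scored cohort: a balanced
two-way fixed-effects ANOVA (training x topic, with interaction) per
subcharacteristic; per-topic two-sample t-tests with per-arm confidence
intervals; absolute mean distances to the gold standard arranged as two
29 x 6 matrices (D1 untrained, D2 trained); Ward hierarchical clustering and
K-means over the subcharacteristic rows; and a centered PCA ordering the
subcharacteristics along their dominant distance pattern.

The ANOVA is computed in closed form, which is exact for the balanced
design the trial uses (equal cell sizes); unbalanced tables are rejected
rather than silently reinterpreted.  Scores enter as a long-format table
with columns ``ontology_id, student, topic, task, arm, subcharacteristic,
score``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .scoring import QualityModelConfig, evaluate_ontology
from .synthetic import ARMS, Cohort, CohortRecord, TOPICS

SCORE_COLUMNS = ("ontology_id", "student", "topic", "task", "arm", "subcharacteristic", "score")


class PipelineError(ValueError):
    """Raised for design violations (unbalanced tables, missing cells...)."""


# ---------------------------------------------------------------------------
# score tables


def build_score_table(
    records: Sequence[CohortRecord] | Cohort,
    config: QualityModelConfig | None = None,
) -> pd.DataFrame:
    """Score every labeled ontology: one row per (ontology, subcharacteristic)."""
    if isinstance(records, Cohort):
        records = records.records
    if config is None:
        config = QualityModelConfig.default()
    rows = []
    for rec in records:
        try:
            card = evaluate_ontology(rec.graph, config)
        except Exception as exc:
            raise PipelineError(f"scoring failed for {rec.ontology_id!r}: {exc}") from exc
        for name, score in card.subcharacteristic_scores.items():
            rows.append((rec.ontology_id, rec.student, rec.topic, rec.task, rec.arm, name, score))
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def build_gold_table(
    golds: Mapping[tuple[str, int], object],
    config: QualityModelConfig | None = None,
) -> pd.DataFrame:
    """Score the gold standards: columns topic, task, subcharacteristic, score."""
    if config is None:
        config = QualityModelConfig.default()
    rows = []
    for (topic, task), graph in sorted(golds.items()):
        card = evaluate_ontology(graph, config)
        for name, score in card.subcharacteristic_scores.items():
            rows.append((topic, task, name, score))
    return pd.DataFrame(rows, columns=["topic", "task", "subcharacteristic", "score"])


def _subchar_slice(table: pd.DataFrame, subcharacteristic: str) -> pd.DataFrame:
    sub = table[table["subcharacteristic"] == subcharacteristic]
    if sub.empty:
        raise PipelineError(f"no rows for subcharacteristic {subcharacteristic!r}")
    return sub


# ---------------------------------------------------------------------------
# ANOVA and t-tests


def anova_training_by_topic(table: pd.DataFrame, subcharacteristic: str) -> dict:
    """Balanced two-way fixed-effects ANOVA of score ~ training * topic.

    Returns ``{"training": {...}, "topic": {...}, "interaction": {...},
    "residual": {...}, "total_ss": float}`` where each effect carries
    ``ss, df, F, p``.  The sums of squares decompose exactly:
    SS_training + SS_topic + SS_interaction + SS_residual = SS_total.
    With no variance anywhere, all SS are 0 and p is reported as 1.

    Raises :class:`PipelineError` on unbalanced cells or cells with fewer
    than two observations, since the closed-form decomposition (and the
    trial's inference argument) requires a balanced design.
    """
    sub = _subchar_slice(table, subcharacteristic)
    arms = sorted(sub["arm"].unique())
    topics = sorted(sub["topic"].unique())
    a, b = len(arms), len(topics)
    if a < 2 or b < 2:
        raise PipelineError("two-way ANOVA needs >= 2 levels of both training and topic")
    sizes = sub.groupby(["arm", "topic"], observed=True)["score"].size()
    if len(sizes) != a * b or sizes.nunique() != 1:
        raise PipelineError("unbalanced design: all (arm, topic) cells must have equal size")
    n = int(sizes.iloc[0])
    if n < 2:
        raise PipelineError("need >= 2 observations per cell")

    cells = (
        sub.groupby(["arm", "topic"], observed=True)["score"]
        .mean()
        .unstack()
        .reindex(index=arms, columns=topics)
        .to_numpy()
    )
    y = sub["score"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    arm_means = cells.mean(axis=1)
    topic_means = cells.mean(axis=0)
    ss_a = n * b * float(np.sum((arm_means - grand) ** 2))
    ss_b = n * a * float(np.sum((topic_means - grand) ** 2))
    ss_cells = n * float(np.sum((cells - grand) ** 2))
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)
    ss_e = max(ss_total - ss_cells, 0.0)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    mse = ss_e / df_e

    def effect(ss: float, df: int) -> dict:
        if mse > 0:
            F = (ss / df) / mse
            p = float(stats.f.sf(F, df, df_e))
        elif ss > 0:  # perfect cell separation, zero residual
            F, p = float("inf"), 0.0
        else:  # no variance at all
            F, p = 0.0, 1.0
        return {"ss": ss, "df": df, "F": F, "p": p}

    return {
        "training": effect(ss_a, df_a),
        "topic": effect(ss_b, df_b),
        "interaction": effect(ss_ab, df_ab),
        "residual": {"ss": ss_e, "df": df_e},
        "total_ss": ss_total,
        "n_per_cell": n,
    }


def ttest_by_topic(
    table: pd.DataFrame,
    subcharacteristic: str,
    topic: str,
    equal_var: bool = True,
    confidence: float = 0.95,
) -> dict:
    """Two-sample t-test untrained vs trained within one topic.

    Returns the t statistic, two-sided p, and per-arm means with
    ``confidence``-level confidence intervals.  Pooled variance by default
    (the design is balanced); ``equal_var=False`` switches to Welch.
    Identical constant arms report t = 0, p = 1.
    """
    sub = _subchar_slice(table, subcharacteristic)
    sub = sub[sub["topic"] == topic]
    groups = {arm: sub.loc[sub["arm"] == arm, "score"].to_numpy(dtype=float) for arm in ARMS}
    for arm, values in groups.items():
        if len(values) < 2:
            raise PipelineError(f"topic {topic!r} has <2 observations in arm {arm!r}")
    x1, x2 = groups["untrained"], groups["trained"]
    if np.ptp(x1) == 0 and np.ptp(x2) == 0 and x1[0] == x2[0]:
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(x1, x2, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t_stat):
            t_stat, p = 0.0, 1.0

    out = {"t": t_stat, "p": p, "arms": {}}
    for arm, values in groups.items():
        m = float(values.mean())
        sem = float(values.std(ddof=1) / np.sqrt(len(values)))
        half = float(stats.t.ppf(0.5 + confidence / 2, len(values) - 1)) * sem
        out["arms"][arm] = {"mean": m, "ci": (m - half, m + half), "n": int(len(values))}
    return out


# ---------------------------------------------------------------------------
# distances to the gold standard


def distance_to_gold(
    table: pd.DataFrame,
    gold: pd.DataFrame,
    subchar_order: Sequence[str] | None = None,
    topic_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The (D1, D2) matrices: absolute distance of arm means to the gold score.

    ``D_k[s, topic] = |G(s, topic) - mean_k(s, topic)|`` with k = 1 the
    untrained and k = 2 the trained arm; G is the mean gold score over that
    topic's gold ontologies.  Rows are subcharacteristics, columns topics.
    """
    if subchar_order is None:
        subchar_order = list(dict.fromkeys(table["subcharacteristic"]))
    if topic_order is None:
        topic_order = [t for t in TOPICS if t in set(table["topic"])]
    G = gold.groupby(["subcharacteristic", "topic"], observed=True)["score"].mean()
    means = table.groupby(["arm", "subcharacteristic", "topic"], observed=True)["score"].mean()
    matrices = []
    for arm in ARMS:
        data = np.empty((len(subchar_order), len(topic_order)))
        for i, s in enumerate(subchar_order):
            for j, t in enumerate(topic_order):
                try:
                    g_val = G.loc[(s, t)]
                except KeyError:
                    raise PipelineError(f"missing gold score for ({s!r}, {t!r})") from None
                try:
                    x_bar = means.loc[(arm, s, t)]
                except KeyError:
                    raise PipelineError(f"missing {arm} mean for ({s!r}, {t!r})") from None
                data[i, j] = abs(g_val - x_bar)
        matrices.append(pd.DataFrame(data, index=list(subchar_order), columns=list(topic_order)))
    return matrices[0], matrices[1]


# ---------------------------------------------------------------------------
# clustering and ordering


def hier_cluster(D: pd.DataFrame, k: int = 4) -> tuple[pd.Series, pd.DataFrame]:
    """Ward/Euclidean agglomerative clustering of the matrix rows.

    Returns (labels, centers): ``labels`` assigns each row a group in 1..k,
    ``centers`` holds per-group column means.
    """
    if not 1 <= k <= len(D):
        raise PipelineError(f"k must lie in [1, {len(D)}], got {k}")
    X = D.to_numpy(dtype=float)
    if len(D) == 1:
        labels = np.ones(1, dtype=int)
    else:
        Z = linkage(X, method="ward", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(labels, index=D.index, name="group")
    centers = pd.DataFrame(
        {g: X[labels.to_numpy() == g].mean(axis=0) for g in sorted(set(labels))},
        index=D.columns,
    ).T
    centers.index.name = "group"
    return labels, centers


def kmeans_cluster(
    D: pd.DataFrame, k: int = 4, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, pd.DataFrame, float, dict[int, float]]:
    """K-means over the matrix rows with multiple restarts.

    Returns (labels, centers, between_pct, within_pct): ``between_pct`` is
    the percentage of total variance explained between groups,
    ``within_pct`` maps each group to its within-group share of the total
    variance (the unexplained remainder, per group).
    """
    if not 1 <= k <= len(D):
        raise PipelineError(f"k must lie in [1, {len(D)}], got {k}")
    X = D.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = pd.Series(km.labels_ + 1, index=D.index, name="group")
    centers = pd.DataFrame(km.cluster_centers_, index=range(1, k + 1), columns=D.columns)
    centers.index.name = "group"
    ss_total = float(np.sum((X - X.mean(axis=0)) ** 2))
    within = {
        g: float(np.sum((X[labels.to_numpy() == g] - centers.loc[g].to_numpy()) ** 2))
        for g in range(1, k + 1)
    }
    if ss_total > 0:
        between_pct = 100.0 * (1.0 - sum(within.values()) / ss_total)
        within_pct = {g: 100.0 * w / ss_total for g, w in within.items()}
    else:
        between_pct = 100.0
        within_pct = {g: 0.0 for g in within}
    return labels, centers, between_pct, within_pct


@dataclass(frozen=True)
class PCAResult:
    """Centered PCA of a distance matrix over its subcharacteristic rows."""

    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # topics x components
    explained_pct: tuple[float, ...]

    @property
    def order(self) -> list[str]:
        """Row labels sorted by first-component score (descending)."""
        return list(self.scores.sort_values("PC1", ascending=False).index)


def pca_order(D: pd.DataFrame, standardize: bool = False) -> PCAResult:
    """Column-centered PCA of a distance matrix.

    Component scores per row (subcharacteristic), topic loadings
    (right-singular vectors) and percentage of variance per component,
    summing to 100.  ``standardize=True`` scales columns to unit variance
    first (correlation PCA); zero-variance columns are left centered only.
    A zero-variance matrix yields all-zero scores and variances, keeping
    the input order.
    """
    X = D.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if standardize:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        X = np.divide(X, sd, out=X.copy(), where=sd > 0)
    n_comp = min(X.shape)
    names = [f"PC{i + 1}" for i in range(n_comp)]
    if not np.any(X):
        scores = pd.DataFrame(0.0, index=D.index, columns=names)
        loadings = pd.DataFrame(0.0, index=D.columns, columns=names)
        return PCAResult(scores=scores, loadings=loadings, explained_pct=tuple(0.0 for _ in names))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for i in range(n_comp):
        pivot = np.argmax(np.abs(Vt[i]))
        if Vt[i, pivot] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = pd.DataFrame(U[:, :n_comp] * S[:n_comp], index=D.index, columns=names)
    loadings = pd.DataFrame(Vt[:n_comp].T, index=D.columns, columns=names)
    var = S[:n_comp] ** 2
    explained = tuple(100.0 * v / var.sum() for v in var)
    return PCAResult(scores=scores, loadings=loadings, explained_pct=explained)


# ---------------------------------------------------------------------------
# simulated score tables (calibration/power studies)


def simulate_score_table(
    shift: Mapping[tuple[str, str], float] | None = None,
    sigma: float = 0.5,
    n_per_cell: int = 18,
    baseline: float = 3.0,
    rng: np.random.Generator | int | None = None,
    subcharacteristic: str = "S",
    topics: Sequence[str] = TOPICS,
) -> pd.DataFrame:
    """Draw a balanced score table from a Gaussian cell-means model.

    ``shift`` maps (arm, topic) cells to additive mean shifts over
    ``baseline``; every cell receives ``n_per_cell`` observations with
    residual standard deviation ``sigma``.  Used for type-I-error and
    power calibration of the ANOVA/t-test stage.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    shift = shift or {}
    rows = []
    i = 0
    for arm in ARMS:
        for topic in topics:
            mu = baseline + shift.get((arm, topic), 0.0)
            for value in mu + sigma * rng.standard_normal(n_per_cell):
                rows.append((f"o{i:05d}", i, topic, 0, arm, subcharacteristic, float(value)))
                i += 1
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
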