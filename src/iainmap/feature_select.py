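"""Feature ranking by class separability and random-forest importance.

Two complementary scores drive the choice of optimal bands/periods:

* the Jeffries–Matusita (JM) distance, a [0, 2]-bounded pairwise class
  separability measure, JM = 2(1 - exp(-B)) with B the Bhattacharyya
  distance between Gaussian class models;
* the Gini importance from a random forest — the sum over all trees of the
  Gini impurity decreases attributed to each feature.

Features with high JM on the crop pairs of interest (rule of thumb: above
1.5) and high Gini scores are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass
class FeatureSelectConfig:
    """Knobs for the ranking stage.

    ntree / mtry follow random-forest practice for this task: 1000 trees and
    sqrt(n_features) candidate splits per node.  ``jm_floor`` is the minimum
    pairwise JM for a feature to count as separating (the usual 1.5 rule);
    ``gini_floor`` is a *relative* cutoff on a 0–100 scale of the maximum
    observed Gini score, since raw Gini sums are data-scale dependent.
    """

    ntree: int = 1000
    seed: int = 0
    jm_floor: float = 1.5
    gini_floor: float = 30.0
    ridge: float = 1e-6
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


def jm_distance(
    sample_a: np.ndarray, sample_b: np.ndarray, ridge: float = 1e-6
) -> float:
    """Jeffries–Matusita distance between two sample sets, in [0, 2].

    Gaussian class models: B = (1/8) dm' S^-1 dm
    + (1/2) ln( det S / sqrt(det Sa det Sb) ) with S = (Sa + Sb)/2, and
    JM = 2 (1 - exp(-B)).  Covariances get an ``ridge``·I regularizer.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if a.ndim == 2 and a.shape[1] != b.shape[1]:
        raise ValueError("samples have different feature counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples")
    p = a.shape[1]
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.cov(a, rowvar=False).reshape(p, p) + ridge * np.eye(p)
    cov_b = np.cov(b, rowvar=False).reshape(p, p) + ridge * np.eye(p)
    cov_m = 0.5 * (cov_a + cov_b)
    dm = mu_a - mu_b
    sign_m, logdet_m = np.linalg.slogdet(cov_m)
    sign_a, logdet_a = np.linalg.slogdet(cov_a)
    sign_b, logdet_b = np.linalg.slogdet(cov_b)
    if sign_m <= 0 or sign_a <= 0 or sign_b <= 0:
        raise np.linalg.LinAlgError("singular covariance after regularization")
    try:
        maha = float(dm @ np.linalg.solve(cov_m, dm))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise np.linalg.LinAlgError("singular covariance") from exc
    bhatt = maha / 8.0 + 0.5 * (logdet_m - 0.5 * (logdet_a + logdet_b))
    return float(2.0 * (1.0 - np.exp(-max(bhatt, 0.0))))


def pairwise_jm(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Per-feature JM distance for every unordered class pair.

    Rows with a missing value in a feature are excluded for that feature;
    a pair where either class then has fewer than 2 values is reported as
    NaN (unavailable) rather than an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=object)
    classes = sorted(set(y), key=str)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    rows = []
    for j, name in enumerate(feature_names):
        col = X[:, j]
        present = np.isfinite(col)
        for ca, cb in itertools.combinations(classes, 2):
            va = col[present & (y == ca)][:, None]
            vb = col[present & (y == cb)][:, None]
            if va.shape[0] < 2 or vb.shape[0] < 2:
                jm = float("nan")
            else:
                jm = jm_distance(va, vb, ridge=ridge)
            rows.append(
                {"feature": name, "class_a": ca, "class_b": cb, "jm": jm}
            )
    return pd.DataFrame(rows)


def gini_importance(
    X: np.ndarray,
    y,
    config: FeatureSelectConfig | None = None,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Random-forest Gini importance, summed over all trees.

    The forest uses ``config.ntree`` trees and sqrt(n_features) candidate
    features per split.  Missing entries are mean-imputed per feature — for
    ranking only; classification never imputes.  Scores are the raw
    (unnormalized) sums of Gini impurity decreases, weighted by node sample
    fractions, over all trees.
    """
    config = config or FeatureSelectConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=object)
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]

    # mean imputation (ranking only)
    Xi = X.copy()
    col_means = np.nanmean(Xi, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    nan_r, nan_c = np.where(~np.isfinite(Xi))
    Xi[nan_r, nan_c] = col_means[nan_c]

    forest = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features="sqrt",
        criterion="gini",
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(Xi, y.astype(str))
    total = np.zeros(X.shape[1])
    for est in forest.estimators_:
        total += est.tree_.compute_feature_importances(normalize=False)
    return pd.DataFrame({"feature": feature_names, "gini": total})


def rank_and_select(
    jm_table: pd.DataFrame,
    gini_table: pd.DataFrame,
    config: FeatureSelectConfig | None = None,
    target_pairs: list[tuple] | None = None,
) -> list[str]:
    """Rank features by Gini and retain the separating ones.

    A feature is retained when its Gini score reaches ``gini_floor`` percent
    of the maximum score (or its Gini rank is within ``top_k``), or when its
    minimum JM over the target class pairs reaches ``jm_floor``.  The output
    order is Gini descending, feature name ascending on ties.
    """
    config = config or FeatureSelectConfig()
    if jm_table.empty or gini_table.empty:
        raise ValueError("empty ranking tables")
    if set(jm_table["feature"]) != set(gini_table["feature"]):
        raise ValueError("JM and Gini tables cover different feature universes")

    jm = jm_table.copy()
    if target_pairs is not None:
        pairs = {frozenset(p) for p in target_pairs}
        jm = jm[
            [frozenset((a, b)) in pairs for a, b in zip(jm["class_a"], jm["class_b"])]
        ]
    min_jm = jm.groupby("feature")["jm"].min()

    g = gini_table.set_index("feature")["gini"]
    gmax = g.max()
    rel = 100.0 * g / gmax if gmax > 0 else g * 0.0
    order = sorted(g.index, key=lambda f: (-g[f], f))
    ranks = {f: r for r, f in enumerate(order)}

    selected = []
    for f in order:
        by_gini = rel[f] >= config.gini_floor or (
            config.top_k is not None and ranks[f] < config.top_k
        )
        by_jm = f in min_jm.index and np.isfinite(min_jm[f]) and (
            min_jm[f] >= config.jm_floor
        )
        if by_gini or by_jm:
            selected.append(f)
    return selected
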