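"""Biomarker discovery between two community groups.

Three complementary routes: a LEfSe-style two-stage screen (Kruskal-Wallis
filter then a bootstrapped one-dimensional Fisher LDA effect size on
relative abundances scaled to parts-per-million), SIMPER decomposition of
the between-group Bray-Curtis dissimilarity into per-taxon contributions,
and a six-family classifier screen evaluated by test-set AUC with
permutation importances for the winning model.

The LEfSe subclass (within-class Wilcoxon) stage is intentionally omitted:
these designs have no subclasses.  Scores are therefore not numerically
identical to the original LEfSe implementation, but the contractual
thresholds (|LDA| > 2.5 at p < 0.05) behave the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LefseResult",
    "SimperResult",
    "ScreenResult",
    "lefse_like",
    "simper",
    "screen_classifiers",
    "auc_rank",
]


# ---------------------------------------------------------------------------
# LEfSe-style discriminant scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LefseResult:
    """Retained biomarkers: kw_p < alpha and |lda_score| > threshold."""

    table: pd.DataFrame  # index feature; columns kw_p, lda_score, enriched_group
    alpha: float
    lda_threshold: float


def _fisher_lda_direction(x: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Unit-norm Fisher LDA direction with trace-scaled ridge regularization."""
    m1 = x[y == 0].mean(axis=0)
    m2 = x[y == 1].mean(axis=0)
    xc = np.vstack([x[y == 0] - m1, x[y == 1] - m2])
    cov = xc.T @ xc / max(len(x) - 2, 1)
    lam = ridge * np.trace(cov) / cov.shape[0] if np.trace(cov) > 0 else ridge
    cov = cov + lam * np.eye(cov.shape[0])
    w = np.linalg.solve(cov, m1 - m2)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse_like(
    relabund: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lda_threshold: float = 2.5,
    n_boot: int = 30,
    seed: int = 0,
) -> LefseResult:
    """Two-stage biomarker screen on a samples x features relative table.

    Stage 1 keeps features with a Kruskal-Wallis p below ``alpha``; stage 2
    averages, over ``n_boot`` seeded 2/3-subsample rounds, a per-feature
    effect combining the feature's Fisher-LDA loading (times the projected
    class-mean difference) with its raw class-mean difference, on the
    parts-per-million scale.  The score is ``sign * log10(1 + effect)``.
    """
    g = pd.Series(groups).loc[relabund.index] if isinstance(groups, (pd.Series, Mapping)) else pd.Series(list(groups), index=relabund.index)
    names = sorted(map(str, pd.unique(g)))
    if len(names) != 2:
        raise ValueError("lefse_like requires exactly two groups")
    x_all = relabund.to_numpy(dtype=float) * 1e6
    y = (g.astype(str) == names[1]).to_numpy().astype(int)

    kw_p = np.ones(x_all.shape[1])
    for f in range(x_all.shape[1]):
        a, b = x_all[y == 0, f], x_all[y == 1, f]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue  # identical across groups: cannot discriminate
        kw_p[f] = stats.kruskal(a, b).pvalue
    survivors = np.flatnonzero(kw_p < alpha)
    empty = pd.DataFrame(columns=["kw_p", "lda_score", "enriched_group"])
    if survivors.size < 2:
        return LefseResult(empty, alpha, lda_threshold)

    xs = x_all[:, survivors]
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    effects = np.zeros((n_boot, survivors.size))
    for b in range(n_boot):
        # subsample via one label-independent permutation of all samples, so
        # renaming the groups cannot change which samples are drawn (exact
        # sign equivariance)
        order = rng.permutation(len(y))
        sub = np.concatenate(
            [
                [i for i in order if i in set(idx0)][: max(2, int(np.ceil(len(idx0) * 2 / 3)))],
                [i for i in order if i in set(idx1)][: max(2, int(np.ceil(len(idx1) * 2 / 3)))],
            ]
        ).astype(int)
        xb, yb = xs[sub], y[sub]
        w = _fisher_lda_direction(xb, yb)
        md = xb[yb == 0].mean(axis=0) - xb[yb == 1].mean(axis=0)
        proj = float(w @ md)
        effects[b] = np.abs(w * proj + md) / 2.0

    effect = effects.mean(axis=0)
    md_full = x_all[y == 0][:, survivors].mean(axis=0) - x_all[y == 1][:, survivors].mean(axis=0)
    sign = np.sign(md_full)
    score = sign * np.log10(1.0 + effect)
    enriched = np.where(md_full > 0, names[0], names[1])

    tbl = pd.DataFrame(
        {
            "kw_p": kw_p[survivors],
            "lda_score": score,
            "enriched_group": enriched,
        },
        index=relabund.columns[survivors],
    )
    tbl = tbl[np.abs(tbl["lda_score"]) > lda_threshold]
    tbl = tbl.sort_values("lda_score", ascending=False)
    return LefseResult(tbl, alpha, lda_threshold)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimperResult:
    """Per-taxon share of mean between-group Bray-Curtis dissimilarity."""

    table: pd.DataFrame  # index taxon; columns mean_contribution, cumulative
    mean_dissimilarity: float  # mean Bray-Curtis over between-group pairs


def simper(relabund: pd.DataFrame, groups) -> SimperResult:
    """Decompose between-group Bray-Curtis into per-taxon contributions.

    For each between-group sample pair the per-taxon term is
    ``|x_fi - x_fj| / sum_g (x_gi + x_gj)``; terms are averaged over pairs
    (their sum is exactly the mean pairwise Bray-Curtis) then normalized to
    fractions and ranked descending with a cumulative column.
    """
    g = pd.Series(groups).loc[relabund.index] if isinstance(groups, (pd.Series, Mapping)) else pd.Series(list(groups), index=relabund.index)
    names = sorted(map(str, pd.unique(g)))
    if len(names) != 2:
        raise ValueError("simper requires exactly two groups")
    a = relabund.loc[g.astype(str) == names[0]].to_numpy(dtype=float)
    b = relabund.loc[g.astype(str) == names[1]].to_numpy(dtype=float)

    contrib = np.zeros(relabund.shape[1])
    n_pairs = a.shape[0] * b.shape[0]
    for i in range(a.shape[0]):
        num = np.abs(a[i][None, :] - b)  # nb x T
        den = (a[i][None, :] + b).sum(axis=1, keepdims=True)
        contrib += (num / den).sum(axis=0)
    contrib /= n_pairs
    mean_bc = float(contrib.sum())

    frac = contrib / mean_bc if mean_bc > 0 else contrib
    tbl = pd.DataFrame({"mean_contribution": frac}, index=relabund.columns)
    tbl = tbl.sort_values("mean_contribution", ascending=False, kind="stable")
    tbl["cumulative"] = tbl["mean_contribution"].cumsum()
    return SimperResult(tbl, mean_bc)


# ---------------------------------------------------------------------------
# Classifier screen
# ---------------------------------------------------------------------------


def auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney U) formulation, midrank ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def default_models(seed: int) -> dict:
    """The six classical families with fixed, documented hyperparameters."""
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "gaussian_nb": GaussianNB(),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=500, random_state=seed),
    }


@dataclass(frozen=True)
class ScreenResult:
    aucs: dict[str, float]
    rocs: dict[str, tuple[np.ndarray, np.ndarray]]  # model -> (fpr, tpr)
    best_model: str
    importance: pd.Series  # permutation importance (mean AUC drop), best model


def screen_classifiers(
    features: pd.DataFrame,
    labels,
    split: float = 0.7,
    seed: int = 0,
    models: dict | None = None,
    n_importance_shuffles: int = 20,
) -> ScreenResult:
    """Stratified 70/30 screen of six classifier families by test AUC.

    The best model (ties to the alphabetically first name) gets permutation
    importances: for each feature, the mean test-AUC drop over
    ``n_importance_shuffles`` seeded shuffles of that feature's test column.
    """
    y_raw = pd.Series(labels).loc[features.index] if isinstance(labels, (pd.Series, Mapping)) else pd.Series(list(labels), index=features.index)
    classes = sorted(map(str, pd.unique(y_raw)))
    if len(classes) != 2:
        raise ValueError("screen_classifiers requires two classes")
    y = (y_raw.astype(str) == classes[1]).to_numpy().astype(int)
    x = features.to_numpy(dtype=float)

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=split, stratify=y, random_state=seed % (2**32)
    )
    if min(int(y_te.sum()), int((1 - y_te).sum())) < 2:
        raise ValueError("test fold needs >= 2 members of each class")

    models = models if models is not None else default_models(seed % (2**32))
    aucs: dict[str, float] = {}
    rocs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fitted = {}
    for name in sorted(models):
        est = models[name]
        est.fit(x_tr, y_tr)
        s = est.predict_proba(x_te)[:, 1]
        aucs[name] = auc_rank(s, y_te)
        fpr, tpr, _ = roc_curve(y_te, s)
        rocs[name] = (fpr, tpr)
        fitted[name] = est

    best = min(aucs, key=lambda nm: (-aucs[nm], nm))
    est = fitted[best]
    base = aucs[best]
    rng = np.random.default_rng(seed)
    drops = np.zeros(x.shape[1])
    for f in range(x.shape[1]):
        acc = 0.0
        for _ in range(n_importance_shuffles):
            x_shuf = x_te.copy()
            x_shuf[:, f] = rng.permutation(x_shuf[:, f])
            acc += base - auc_rank(est.predict_proba(x_shuf)[:, 1], y_te)
        drops[f] = acc / n_importance_shuffles
    importance = pd.Series(drops, index=features.columns, name="auc_drop").sort_values(
        ascending=False, kind="stable"
    )
    return ScreenResult(aucs, rocs, best, importance)
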