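"""Constrained ordination linking community structure to host variables.

A Spearman collinearity pre-filter prunes redundant explanatory variables,
then redundancy analysis (RDA) regresses the Hellinger-transformed
community matrix on the retained variables.  Significance of the global
model and of each variable's marginal contribution comes from seeded
permutation tests (residuals-of-reduced-model permutation for the marginal
tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RdaResult", "collinearity_filter", "hellinger", "rda"]


def collinearity_filter(variables: pd.DataFrame, r_max: float = 0.6) -> list[str]:
    """Iteratively drop variables until no |Spearman| exceeds ``r_max``.

    At each step the worst (largest |rho|) pair is found and the member with
    the larger mean absolute correlation to all other retained variables is
    dropped (ties to the later column).  Deterministic in column order.
    """
    if variables.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    cols = list(variables.columns)
    rho = pd.DataFrame(
        stats.spearmanr(variables.to_numpy(dtype=float)).statistic
        if variables.shape[1] > 2
        else _rho_2col(variables),
        index=cols,
        columns=cols,
    ).abs()
    retained = list(cols)
    while True:
        sub = rho.loc[retained, retained].to_numpy().copy()
        sub = np.maximum(sub, sub.T)  # guard tiny float asymmetries
        np.fill_diagonal(sub, 0.0)
        worst = sub.max()
        if worst <= r_max:
            return retained
        # worst pair: first occurrence scanning the upper triangle row-major
        upper = np.triu(sub, k=1)
        i, j = np.unravel_index(int(np.argmax(upper)), upper.shape)
        a, b = retained[i], retained[j]
        mean_a = sub[i].sum() / (len(retained) - 1)
        mean_b = sub[j].sum() / (len(retained) - 1)
        drop = b if mean_b >= mean_a else a  # tie -> later column
        retained.remove(drop)


def _rho_2col(variables: pd.DataFrame) -> np.ndarray:
    r = stats.spearmanr(variables.iloc[:, 0], variables.iloc[:, 1]).statistic
    return np.array([[1.0, r], [r, 1.0]])


def hellinger(community: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-normalized abundances."""
    rel = community.div(community.sum(axis=1), axis=0)
    return np.sqrt(rel)


@dataclass(frozen=True)
class RdaResult:
    F: float
    p: float
    constrained_fraction: float  # of total inertia
    unconstrained_fraction: float
    eigenvalues: np.ndarray  # constrained axes
    site_scores: pd.DataFrame  # samples x constrained axes
    biplot_scores: pd.DataFrame  # variables x constrained axes (correlations)
    marginal: pd.DataFrame  # per variable: F, p
    n_permutations: int


def rda(
    community: pd.DataFrame,
    explanatory: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    hellinger_transform: bool = True,
) -> RdaResult:
    """Redundancy analysis with permutation tests.

    The community matrix is Hellinger-transformed (optional) and column
    centred; explanatory variables are standardized.  The global pseudo-F is
    ``(constrained/q) / (residual/(n-q-1))`` with q the number of
    constraints; its p-value permutes sample rows of the explanatory matrix.
    Marginal tests permute the residuals of the model without the focal
    variable.
    """
    common = [s for s in community.index if s in explanatory.index]
    y = community.loc[common]
    x = explanatory.loc[common].astype(float)
    n, q = x.shape
    if n <= q + 1:
        raise ValueError("need n_samples > n_variables + 1")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < q:
        raise ValueError("explanatory matrix is rank deficient after centring")

    if hellinger_transform:
        y = hellinger(y)
    yc = (y - y.mean(axis=0)).to_numpy(dtype=float)
    xs = ((x - x.mean(axis=0)) / x.std(axis=0, ddof=1)).to_numpy(dtype=float)

    def pseudo_f(c: float, total: float) -> float:
        resid = max(total - c, 0.0)
        if resid == 0.0:
            return float("inf")
        return (c / q) / (resid / (n - q - 1))

    qmat, _ = np.linalg.qr(xs)
    total = float((yc**2).sum())
    proj = qmat.T @ yc
    constrained = float((proj**2).sum())
    residual = max(total - constrained, 0.0)
    f_obs = pseudo_f(constrained, total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pr = qmat[perm].T @ yc
        if pseudo_f(float((pr**2).sum()), total) >= f_obs:
            exceed += 1
    p_global = (1 + exceed) / (1 + n_perm)

    # constrained axes: SVD of the fitted values
    fitted = qmat @ proj
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    evals = (s**2) / (n - 1)
    keep = evals > 1e-12 * max(evals[0], 1.0) if evals.size else np.array([], bool)
    evals = evals[keep]
    axes = [f"RDA{i + 1}" for i in range(evals.size)]
    sites = u[:, keep] * s[keep]
    for a in range(sites.shape[1]):  # deterministic axis orientation
        i = int(np.argmax(np.abs(sites[:, a])))
        if sites[i, a] < 0:
            sites[:, a] = -sites[:, a]
    site_scores = pd.DataFrame(sites, index=common, columns=axes)
    biplot = pd.DataFrame(
        np.corrcoef(xs, sites, rowvar=False)[:q, q:], index=x.columns, columns=axes
    )

    # marginal (type III-like) per-variable tests
    recs = []
    for v_i, v_name in enumerate(x.columns):
        others = [j for j in range(q) if j != v_i]
        if others:
            q_red, _ = np.linalg.qr(xs[:, others])
            y_fit_red = q_red @ (q_red.T @ yc)
            v_res = xs[:, v_i] - q_red @ (q_red.T @ xs[:, v_i])
        else:
            y_fit_red = np.zeros_like(yc)
            v_res = xs[:, v_i].copy()
        v_res = v_res / np.linalg.norm(v_res)
        y_res = yc - y_fit_red
        extra = float(((v_res @ yc) ** 2).sum())
        f_v = extra / (residual / (n - q - 1)) if residual > 0 else float("inf")
        exceed_v = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            y_perm_res = y_res[perm]
            extra_p = float(((v_res @ y_perm_res) ** 2).sum())
            resid_p = max(float((y_perm_res**2).sum()) - extra_p, 1e-300)
            if extra_p / (resid_p / (n - q - 1)) >= f_v:
                exceed_v += 1
        recs.append(
            {"variable": v_name, "F": f_v, "p": (1 + exceed_v) / (1 + n_perm)}
        )
    marginal = pd.DataFrame(recs).set_index("variable")

    return RdaResult(
        F=float(f_obs),
        p=float(p_global),
        constrained_fraction=constrained / total,
        unconstrained_fraction=residual / total,
        eigenvalues=evals,
        site_scores=site_scores,
        biplot_scores=biplot,
        marginal=marginal,
        n_permutations=n_perm,
    )
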