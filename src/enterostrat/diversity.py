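"""Alpha and beta diversity, permutation tests, and group comparisons.

Alpha metrics are the classical estimators: observed richness, Shannon
entropy (natural log), Chao1 (bias-corrected), ACE (rare cutoff 10) and
Faith's phylogenetic diversity including the root-spanning path.  Beta
diversity uses Bray-Curtis on relative abundances.  PERMANOVA and PERMDISP
are one-way, seeded permutation tests on the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .core_io import CountTable, to_relative

__all__ = [
    "PermanovaResult",
    "alpha_diversity",
    "faith_pd",
    "bray_curtis",
    "permanova",
    "permdisp",
    "upset_partition",
    "compare_groups",
    "rarefy",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare taxa are singletons; coverage undefined, fall back to Chao1
        return _chao1(counts)
    fi = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = (s_rare / c_ace) * (i * (i - 1) * fi).sum() / (
        n_rare * (n_rare - 1)
    ) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def faith_pd(ct: CountTable, tree: TreeNode, include_root_path: bool = True) -> pd.Series:
    """Faith's PD per sample: total branch length spanning observed tips.

    By default the path connecting the observed subtree to the root counts
    toward PD (the common convention); disable with
    ``include_root_path=False`` to sum only branches within the spanned
    subtree (the minimal spanning subtree excluding the stem to the root).
    """
    tip_index: dict[str, int] = {}
    for tip in tree.tips():
        tip_index[tip.name] = len(tip_index)
    missing = [t for t in ct.taxon_ids if t not in tip_index]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")

    present = np.zeros((len(tip_index), ct.n_samples), dtype=bool)
    arr = ct.data.to_numpy() > 0
    for j, tid in enumerate(ct.taxon_ids):
        present[tip_index[tid]] |= arr[:, j]

    # postorder accumulation: an edge contributes to a sample's PD when its
    # subtree holds at least one of the sample's observed tips
    pd_vals = np.zeros(ct.n_samples)
    n_observed = present.sum(axis=0)  # observed tips per sample
    subtree: dict[int, np.ndarray] = {}
    stem = np.zeros(ct.n_samples)  # root-to-MRCA path length per sample
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            count = present[tip_index[node.name]].astype(np.int32)
        else:
            count = np.zeros(ct.n_samples, dtype=np.int32)
            for child in node.children:
                count = count + subtree.pop(id(child))
        subtree[id(node)] = count
        if node.parent is not None and node.length:
            pd_vals += np.where(count > 0, node.length, 0.0)
            # edges above the MRCA are exactly those whose subtree holds ALL
            # of the sample's observed tips
            stem += np.where(count == n_observed, node.length, 0.0)
    if not include_root_path:
        pd_vals -= stem
    return pd.Series(pd_vals, index=ct.sample_ids, name="faith_pd")


def alpha_diversity(ct: CountTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity table.

    Columns: observed, shannon (nats), chao1, ace, and faith_pd when a tree
    is supplied.  No rarefaction is applied; use :func:`rarefy` first if a
    common depth is wanted.
    """
    rows = {}
    for sid in ct.sample_ids:
        c = ct.data.loc[sid].to_numpy()
        rows[sid] = {
            "observed": int((c > 0).sum()),
            "shannon": _shannon(c),
            "chao1": _chao1(c),
            "ace": _ace(c),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if tree is not None:
        out["faith_pd"] = faith_pd(ct, tree)
    return out.loc[ct.sample_ids]


def rarefy(ct: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    rng = np.random.default_rng(seed)
    totals = ct.totals()
    if (totals < depth).any():
        low = totals[totals < depth].index.tolist()
        raise ValueError(f"samples below rarefaction depth {depth}: {low}")
    out = np.zeros_like(ct.data.to_numpy())
    for i, sid in enumerate(ct.sample_ids):
        c = ct.data.loc[sid].to_numpy()
        pool = np.repeat(np.arange(c.size), c)
        take = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(take, minlength=c.size)
    return CountTable(pd.DataFrame(out, index=ct.sample_ids, columns=ct.taxon_ids))


# ---------------------------------------------------------------------------
# Beta diversity and permutation tests
# ---------------------------------------------------------------------------


def bray_curtis(table: CountTable | pd.DataFrame, relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, by default on relative abundances."""
    if isinstance(table, CountTable):
        df = to_relative(table) if relative else table.data.astype(float)
    else:
        df = table.div(table.sum(axis=1), axis=0) if relative else table
    d = squareform(pdist(df.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=list(df.index))


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def _align_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, (pd.Series, Mapping)):
        g = pd.Series(groups).loc[list(dm.ids)]
        return g.to_numpy()
    return np.asarray(list(groups))


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for c in range(k):
        idx = np.flatnonzero(codes == c)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA: location test on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` with seeded label
    permutations; ``R2 = SS_between / SS_total``.
    """
    labels = _align_groups(dm, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2 or min(np.bincount(codes)) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)

    def f_stat(c: np.ndarray) -> float:
        ss_w = _ss_within(d2, c, k)
        ss_b = ss_total - ss_w
        return (ss_b / (k - 1)) / (ss_w / (n - k))

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if f_stat(perm) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    ss_w = _ss_within(d2, codes, k)
    r2 = (ss_total - ss_w) / ss_total
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def permdisp(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    centroid: str = "spatial",
) -> dict:
    """Homogeneity-of-dispersion test (betadisper construction).

    Samples are embedded by PCoA keeping negative eigenvalues as imaginary
    axes; each sample's distance to its group centroid subtracts the
    imaginary-axis component (clamped at zero) per the standard correction.
    The F statistic is a one-way ANOVA on those distances; p comes from
    seeded permutations of group labels over the fixed distances.
    """
    labels = _align_groups(dm, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2 or min(np.bincount(codes)) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    gram = 0.5 * (gram + gram.T)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals).max(), 1.0)
    pos, neg = evals > tol, evals < -tol
    x_pos = evecs[:, pos] * np.sqrt(evals[pos])
    x_neg = evecs[:, neg] * np.sqrt(-evals[neg])

    zdist = np.zeros(n)
    for c in range(k):
        idx = np.flatnonzero(codes == c)
        if centroid == "spatial":
            c_pos = x_pos[idx].mean(axis=0)
            c_neg = x_neg[idx].mean(axis=0) if x_neg.size else np.zeros(0)
        elif centroid == "median":
            c_pos = np.median(x_pos[idx], axis=0)
            c_neg = np.median(x_neg[idx], axis=0) if x_neg.size else np.zeros(0)
        else:
            raise ValueError("centroid must be 'spatial' or 'median'")
        z2 = ((x_pos[idx] - c_pos) ** 2).sum(axis=1)
        if x_neg.size:
            z2 = z2 - ((x_neg[idx] - c_neg) ** 2).sum(axis=1)
        zdist[idx] = np.sqrt(np.maximum(z2, 0.0))

    def anova_f(c: np.ndarray) -> float:
        grand = zdist.mean()
        ss_b = sum(
            np.flatnonzero(c == g).size * (zdist[c == g].mean() - grand) ** 2
            for g in range(k)
        )
        ss_w = sum(((zdist[c == g] - zdist[c == g].mean()) ** 2).sum() for g in range(k))
        if ss_w == 0:
            return float("inf") if ss_b > 0 else 0.0
        return (ss_b / (k - 1)) / (ss_w / (n - k))

    f_obs = anova_f(codes)
    rng = np.random.default_rng(seed)
    exceed = sum(
        anova_f(rng.permutation(codes)) >= f_obs for _ in range(n_perm)
    )
    return {"F": float(f_obs), "p": float((1 + exceed) / (1 + n_perm)), "n_permutations": n_perm}


# ---------------------------------------------------------------------------
# Shared/unique accounting and group comparisons
# ---------------------------------------------------------------------------


def upset_partition(ct: CountTable, groups) -> dict:
    """Exact intersection cells of per-group taxon memberships.

    A taxon belongs to a group when it has count > 0 in at least one of the
    group's samples.  Returns ``{(sorted group names): {"count", "fraction"}}``
    over every nonempty cell; fractions are over the union of all taxa
    observed in any group.
    """
    g = pd.Series(_align_groups_ct(ct, groups), index=ct.sample_ids)
    names = sorted(map(str, pd.unique(g)))
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    member = {}
    for name in names:
        idx = g.index[g.astype(str) == name]
        member[name] = ct.data.loc[idx].sum(axis=0) > 0
    mat = pd.DataFrame(member)  # taxa x groups bool
    mat = mat[mat.any(axis=1)]
    total = len(mat)
    cells: dict[tuple[str, ...], dict] = {}
    for key, sub in mat.groupby(list(mat.columns)):
        combo = tuple(name for name, flag in zip(mat.columns, key) if flag)
        if combo:
            cells[combo] = {"count": int(len(sub)), "fraction": len(sub) / total}
    return cells


def _align_groups_ct(ct: CountTable, groups) -> np.ndarray:
    if isinstance(groups, (pd.Series, Mapping)):
        return pd.Series(groups).loc[ct.sample_ids].to_numpy()
    return np.asarray(list(groups))


def compare_groups(
    values: pd.DataFrame,
    groups,
    test: str = "mannwhitney",
    fdr: bool = True,
) -> pd.DataFrame:
    """Two-group per-variable tests with optional Benjamini-Hochberg q-values.

    ``values`` is samples x variables; ``test`` is ``"mannwhitney"``
    (tie-corrected normal approximation) or ``"t"`` (Welch).
    """
    g = pd.Series(groups).loc[values.index] if isinstance(groups, (pd.Series, Mapping)) else pd.Series(list(groups), index=values.index)
    uniq = pd.unique(g)
    if len(uniq) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    a_idx, b_idx = g == uniq[0], g == uniq[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    recs = []
    for col in values.columns:
        a = values.loc[a_idx, col].to_numpy(dtype=float)
        b = values.loc[b_idx, col].to_numpy(dtype=float)
        if test == "mannwhitney":
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                stat, p = float(a.size * b.size / 2), 1.0
            else:
                stat, p = stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="asymptotic"
                )
        elif test == "t":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            if np.isnan(p):
                stat, p = 0.0, 1.0
        else:
            raise ValueError("test must be 'mannwhitney' or 't'")
        recs.append({"variable": col, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(recs).set_index("variable")
    if fdr:
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
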