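"""Levins niche breadth and generalist/specialist classification.

Levins' breadth ``B = 1 / sum_s p_s^2`` measures how evenly a taxon spreads
over samples: B = 1 for a taxon confined to one sample, B = n for a taxon
spread uniformly over n samples.  Classification compares each taxon's
observed B with a permutation null that shuffles the taxon's counts across
samples (independently per taxon, preserving taxon totals); taxa above the
null 95% interval are generalists, below it specialists, otherwise neutral.

Breadth for classification is computed on within-sample relative-abundance
shares rather than raw counts: utilization of a sample should not scale
with that sample's sequencing depth, and on the share scale the
within-taxon shuffle null is informative (a raw-count B is blind to which
sample a count came from, so shuffling could never move it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountTable

__all__ = [
    "NicheClassification",
    "levins_breadth",
    "levins_breadth_all",
    "classify_niche",
    "compare_group_breadth",
]


def _breadth_from_profile(x: np.ndarray, axis: int = 0) -> np.ndarray:
    tot = x.sum(axis=axis, keepdims=True)
    p = np.divide(x, tot, out=np.zeros_like(x, dtype=float), where=tot > 0)
    return 1.0 / (p**2).sum(axis=axis)


def levins_breadth(ct: CountTable, taxon: str, use_relative: bool = False) -> float:
    """Levins breadth of one taxon over the samples.

    ``p_s`` is the taxon's count in sample s over its total across samples
    (or its within-sample relative-abundance share with
    ``use_relative=True``).
    """
    if taxon not in ct.data.columns:
        raise KeyError(f"taxon {taxon!r} not in table")
    x = ct.data[taxon].to_numpy(dtype=float)
    if x.sum() == 0:
        raise ValueError(f"taxon {taxon!r} has zero total count")
    if use_relative:
        x = x / ct.data.sum(axis=1).to_numpy()
    return float(_breadth_from_profile(x))


def levins_breadth_all(ct: CountTable, use_relative: bool = False) -> pd.Series:
    """Levins breadth for every taxon with nonzero total."""
    x = ct.data.to_numpy(dtype=float)
    if use_relative:
        x = x / x.sum(axis=1, keepdims=True)
    keep = x.sum(axis=0) > 0
    b = _breadth_from_profile(x[:, keep], axis=0)
    return pd.Series(b, index=ct.data.columns[keep], name="levins_b")


@dataclass(frozen=True)
class NicheClassification:
    table: pd.DataFrame  # per taxon: B, ci_low, ci_high, class
    mean_b: float
    fractions: dict[str, float]  # generalist / specialist / neutral


def classify_niche(
    ct: CountTable,
    n_perm: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> NicheClassification:
    """Permutation classification into generalist / specialist / neutral.

    Each permutation shuffles every taxon's counts across samples
    independently (taxon totals preserved), then recomputes within-sample
    shares from the shuffled matrix's new sample totals and B from those
    shares.  The per-taxon null distribution of B yields a central ``ci``
    interval and the observed B is compared against it.  The renormalization
    step matters: B on raw counts depends only on the multiset of a taxon's
    counts, which the shuffle preserves, so only the share scale gives the
    null any spread.
    """
    if ct.n_samples < 5:
        raise ValueError("need at least 5 samples")
    counts = ct.data.to_numpy(dtype=float)
    keep = np.flatnonzero(counts.sum(axis=0) > 0)
    counts = counts[:, keep]
    n, t = counts.shape

    def shares_b(mat: np.ndarray) -> np.ndarray:
        tot = mat.sum(axis=1, keepdims=True)
        sh = np.divide(mat, tot, out=np.zeros_like(mat), where=tot > 0)
        return _breadth_from_profile(sh, axis=0)

    obs = shares_b(counts)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_perm, t))
    for r in range(n_perm):
        order = np.argsort(rng.random((n, t)), axis=0)
        nulls[r] = shares_b(np.take_along_axis(counts, order, axis=0))
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(nulls, alpha, axis=0)
    hi = np.quantile(nulls, 1.0 - alpha, axis=0)
    cls = np.where(obs > hi, "generalist", np.where(obs < lo, "specialist", "neutral"))

    table = pd.DataFrame(
        {"B": obs, "ci_low": lo, "ci_high": hi, "class": cls},
        index=ct.data.columns[keep],
    )
    fractions = {
        name: float((cls == name).sum() / t)
        for name in ("generalist", "specialist", "neutral")
    }
    return NicheClassification(table, float(obs.mean()), fractions)


def compare_group_breadth(ct: CountTable, group_assignments) -> dict:
    """Compare per-taxon breadth distributions between two sample groups.

    B is computed within each group's sample subset over the taxa present
    there; the two distributions are compared by Mann-Whitney U.
    """
    g = (
        pd.Series(group_assignments).loc[ct.sample_ids]
        if isinstance(group_assignments, (pd.Series, Mapping))
        else pd.Series(list(group_assignments), index=ct.sample_ids)
    )
    names = sorted(map(str, pd.unique(g)))
    if len(names) != 2:
        raise ValueError("compare_group_breadth requires two groups")
    dists: dict[str, pd.Series] = {}
    for name in names:
        idx = g.index[g.astype(str) == name]
        if len(idx) < 5:
            warnings.warn(f"group {name!r} has fewer than 5 samples")
        sub = CountTable(ct.data.loc[idx].pipe(lambda df: df.loc[:, df.sum(axis=0) > 0]))
        dists[name] = levins_breadth_all(sub, use_relative=True)
    u, p = stats.mannwhitneyu(
        dists[names[0]].to_numpy(),
        dists[names[1]].to_numpy(),
        alternative="two-sided",
        method="asymptotic",
    )
    return {
        "breadths": dists,
        "statistic": float(u),
        "p": float(p),
        "median_b": {name: float(dists[name].median()) for name in names},
    }
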