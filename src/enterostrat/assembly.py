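"""Community-assembly inference.

Three linked analyses quantify how much of community turnover is stochastic:

* :func:`fit_ncm` fits Sloan's neutral community model — the occurrence
  frequency of a taxon as a function of its mean relative abundance follows
  ``1 - BetaCDF(1/N; Nm p, Nm (1-p))`` under neutral drift-plus-immigration,
  where N is the mean reads per sample and m the immigration rate.
* :func:`beta_nti` computes the standardized effect size of the abundance-
  weighted beta mean nearest taxon distance (betaMNTD) against a
  tip-label-shuffle null: |betaNTI| >= 2 flags deterministic (selection)
  assembly, the sign telling homogeneous (-) from heterogeneous (+).
* :func:`raup_crick_matrix` computes the Raup-Crick index on Bray-Curtis
  distances against a null preserving each sample's richness and read total,
  with taxa drawn by occurrence frequency and reads allocated by
  metacommunity relative abundance.

:func:`classify_processes` combines the two pairwise statistics into the
five-way ecological-process partition (homogeneous/heterogeneous selection,
dispersal limitation, homogenizing dispersal, drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skbio import TreeNode

from .core_io import CountTable, to_relative

__all__ = [
    "NcmFit",
    "AssemblyResult",
    "fit_ncm",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "raup_crick_bray",
    "raup_crick_matrix",
    "classify_processes",
    "assembly_analysis",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NcmFit:
    m: float  # immigration rate
    N: float  # mean reads per sample
    Nm: float  # product, the commonly reported summary
    r2: float  # 1 - SSE/SST on the frequency scale (can be negative)
    table: pd.DataFrame  # per taxon: mean_relabund, occ_freq, predicted_freq,
    #                      ci_low, ci_high, partition


def _wilson_interval(p: np.ndarray, n: int, z: float = 1.959963984540054):
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def ncm_predicted_freq(p: np.ndarray, N: float, m: float) -> np.ndarray:
    """Neutral expectation of occurrence frequency at detection limit 1/N."""
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(1.0 / N, a, b)


def fit_ncm(ct: CountTable) -> NcmFit:
    """Least-squares fit of the Sloan model on the untransformed frequency scale.

    ``m`` is estimated by bounded scalar minimization of the SSE over
    (0, 1]; the 95% band around the fitted curve is the Wilson binomial
    interval at the number of samples, and taxa are partitioned into
    above/within/below the band.
    """
    if ct.n_samples < 10:
        raise ValueError("NCM fit needs at least 10 samples")
    rel = to_relative(ct)
    p_all = rel.mean(axis=0)
    observed = p_all > 0  # unobserved taxa carry no frequency information
    p = p_all[observed].to_numpy()
    occ = (ct.data.loc[:, observed.to_numpy()] > 0).mean(axis=0).to_numpy()
    taxa = list(p_all.index[observed])
    N = float(ct.totals().mean())

    def sse(m: float) -> float:
        resid = occ - ncm_predicted_freq(p, N, m)
        return float(resid @ resid)

    res = optimize.minimize_scalar(
        sse, bounds=(1e-6, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"NCM fit did not converge: {res}")
    m = float(res.x)
    pred = ncm_predicted_freq(p, N, m)
    sst = float(((occ - occ.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lo, hi = _wilson_interval(pred, ct.n_samples)
    partition = np.where(occ > hi, "above", np.where(occ < lo, "below", "within"))
    table = pd.DataFrame(
        {
            "mean_relabund": p,
            "occ_freq": occ,
            "predicted_freq": pred,
            "ci_low": lo,
            "ci_high": hi,
            "partition": partition,
        },
        index=taxa,
    )
    return NcmFit(m=m, N=N, Nm=N * m, r2=float(r2), table=table)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def _patristic_matrix(ct: CountTable, tree: TreeNode) -> np.ndarray:
    dm = tree.tip_tip_distances()
    missing = [t for t in ct.taxon_ids if t not in dm.ids]
    if missing:
        raise ValueError(f"tree does not span taxa: {missing[:5]}")
    idx = [dm.index(t) for t in ct.taxon_ids]
    return np.asarray(dm.data)[np.ix_(idx, idx)]


def _bmntd_from_distance(w: np.ndarray, present: np.ndarray, d: np.ndarray) -> np.ndarray:
    """All-pairs abundance-weighted betaMNTD.

    ``w``: samples x taxa relative abundances; ``present``: boolean mask;
    ``d``: taxa x taxa patristic distances (zero diagonal, so a taxon present
    on both sides finds itself at distance 0).
    """
    n, t = w.shape
    md = np.empty((n, t), dtype=d.dtype)
    for s in range(n):
        cols = np.flatnonzero(present[s])
        np.min(d[:, cols], axis=1, out=md[s])
    # m[a,b] = sum_i w_a[i] * min_{j in b} d(i,j)
    m = w.astype(np.float32) @ md.astype(np.float32).T
    return (0.5 * (m + m.T)).astype(np.float64)


def beta_mntd_matrix(ct: CountTable, tree: TreeNode) -> pd.DataFrame:
    """Square matrix of abundance-weighted betaMNTD values."""
    arr = ct.data.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("sample with no taxa")
    w = arr / arr.sum(axis=1, keepdims=True)
    present = arr > 0
    d = _patristic_matrix(ct, tree)
    out = _bmntd_from_distance(w, present, d)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=ct.sample_ids, columns=ct.sample_ids)


def beta_mntd(ct: CountTable, tree: TreeNode, pair: tuple[str, str]) -> float:
    """betaMNTD for one sample pair (symmetric in the pair)."""
    sub = CountTable(ct.data.loc[list(pair)].pipe(lambda df: df.loc[:, df.sum(axis=0) > 0]))
    return float(beta_mntd_matrix(sub, tree).iloc[0, 1])


def beta_nti(
    ct: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardized effect size of betaMNTD against the tip-shuffle null.

    The null shuffles taxon labels across the tree tips present in the
    table (equivalently, permutes rows/columns of the patristic matrix)
    ``n_null`` times with a seeded generator; betaNTI = (obs - mean) / sd
    of the null distribution, per sample pair.

    Distances are quantized to 16 bits of the matrix range internally: the
    quantization is monotone (minima are preserved exactly) and the z-score
    is invariant to the overall distance scale, so only a ~1e-4 relative
    rounding enters the abundance weighting -- far below the null sd.
    """
    # canonical taxon order: the seeded shuffle stream must not depend on
    # the order columns happen to arrive in
    ct = CountTable(ct.data[sorted(ct.data.columns)])
    arr = ct.data.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("sample with no taxa")
    w = arr / arr.sum(axis=1, keepdims=True)
    present = arr > 0
    d = _patristic_matrix(ct, tree)
    scale = d.max()
    d = np.round(d / (scale if scale > 0 else 1.0) * 65535).astype(np.uint16)

    obs = _bmntd_from_distance(w, present, d)
    rng = np.random.default_rng(seed)
    t = d.shape[0]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(t)
        null = _bmntd_from_distance(w, present, d[np.ix_(perm, perm)])
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = acc2 / n_null - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    off = ~np.eye(len(obs), dtype=bool)
    if (sd[off] <= 1e-12).any():
        raise ValueError("degenerate null (sd = 0); tree has no usable structure")
    z = np.zeros_like(obs)
    np.divide(obs - mean, sd, out=z, where=off)
    return pd.DataFrame(z, index=ct.sample_ids, columns=ct.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------


def _null_communities(
    rng: np.random.Generator,
    n_null: int,
    richness: int,
    total: int,
    occ_w: np.ndarray,
    abund_p: np.ndarray,
) -> np.ndarray:
    """Batch of null communities (n_null x taxa count matrix).

    Taxa are drawn without replacement with probability proportional to
    occurrence frequency (Gumbel top-k); each drawn taxon receives one read
    so realized richness is exact, and the remaining reads are allocated
    proportionally to metacommunity relative abundance.
    """
    t = occ_w.size
    with np.errstate(divide="ignore"):
        logw = np.where(occ_w > 0, np.log(np.where(occ_w > 0, occ_w, 1.0)), -np.inf)
    keys = logw[None, :] + rng.gumbel(size=(n_null, t))
    idx = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    pv = abund_p[idx]
    pv = pv / pv.sum(axis=1, keepdims=True)
    counts = 1 + rng.multinomial(total - richness, pv)
    out = np.zeros((n_null, t), dtype=np.int64)
    np.put_along_axis(out, idx, counts, axis=1)
    return out


def _bray_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(a - b).sum(axis=-1) / (a + b).sum(axis=-1)


def _sample_null_batch(
    ct: CountTable,
    sample: str,
    n_null: int,
    seed: int,
    occ_w: np.ndarray,
    abund_p: np.ndarray,
) -> np.ndarray:
    """Null batch for one sample, on a substream derived from the sample ID.

    Seeding per sample makes each pair's Raup-Crick value independent of
    which other pairs are computed (the i-th null of sample a is paired
    with the i-th null of sample b).
    """
    import zlib

    s_seed = (seed * 1_000_003 + zlib.crc32(str(sample).encode())) % (2**31 - 1)
    rng = np.random.default_rng(s_seed)
    x = ct.data.loc[sample].to_numpy()
    return _null_communities(
        rng, n_null, int((x > 0).sum()), int(x.sum()), occ_w, abund_p
    )


def _rc_from_nulls(obs: float, null: np.ndarray, n_null: int) -> float:
    less = int((null < obs - 1e-12).sum())
    equal = int((np.abs(null - obs) <= 1e-12).sum())
    return float(2.0 * (less + 0.5 * equal) / n_null - 1.0)


def raup_crick_bray(
    ct: CountTable,
    pair: tuple[str, str],
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Raup-Crick index for one sample pair, in [-1, 1].

    ``rc = 2 [#(null < obs) + 0.5 #(null = obs)] / n_null - 1``: +1 means the
    observed Bray-Curtis exceeds every null draw (more divergent than
    expected by chance), -1 the reverse.
    """
    occ_w = (ct.data > 0).sum(axis=0).to_numpy(dtype=float)
    abund_p = to_relative(ct).mean(axis=0).to_numpy()
    a = ct.data.loc[pair[0]].to_numpy(dtype=float)
    b = ct.data.loc[pair[1]].to_numpy(dtype=float)
    obs = float(_bray_counts(a, b))
    null_a = _sample_null_batch(ct, pair[0], n_null, seed, occ_w, abund_p)
    null_b = _sample_null_batch(ct, pair[1], n_null, seed, occ_w, abund_p)
    null = np.abs(null_a - null_b).sum(axis=1) / (a.sum() + b.sum())
    return _rc_from_nulls(obs, null, n_null)


def raup_crick_matrix(
    ct: CountTable,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All-pairs Raup-Crick (Bray-Curtis).

    Null batches are generated once per sample on per-sample substreams and
    reused across that sample's pairs; every null community preserves its
    sample's observed richness and read total, so each pair's null
    Bray-Curtis denominator is the fixed pair total.
    """
    ids = ct.sample_ids
    occ_w = (ct.data > 0).sum(axis=0).to_numpy(dtype=float)
    abund_p = to_relative(ct).mean(axis=0).to_numpy()
    arr = ct.data.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    batches = [
        _sample_null_batch(ct, s, n_null, seed, occ_w, abund_p).astype(np.int32)
        for s in ids
    ]
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            obs = float(np.abs(arr[i] - arr[j]).sum() / (totals[i] + totals[j]))
            null = np.abs(batches[i] - batches[j]).sum(axis=1) / (totals[i] + totals[j])
            rc = _rc_from_nulls(obs, null, n_null)
            out.iloc[i, j] = out.iloc[j, i] = rc
    return out


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyResult:
    pairs: pd.DataFrame  # sample_a, sample_b, bnti, rc, process
    fractions: dict[str, float]


def _classify_one(bnti: float, rc: float) -> str:
    # strict inequalities as quoted; exact boundaries fall through to drift
    if bnti < -2.0:
        return "homogeneous_selection"
    if bnti > 2.0:
        return "heterogeneous_selection"
    if abs(bnti) < 2.0 and rc > 0.95:
        return "dispersal_limitation"
    if abs(bnti) < 2.0 and rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def classify_processes(bnti: pd.DataFrame, rc: pd.DataFrame) -> AssemblyResult:
    """Five-way process partition from aligned pairwise matrices.

    Every unordered sample pair is classified exactly once; fractions are
    over all pairs and sum to 1.
    """
    ids = list(bnti.index)
    if list(rc.index) != ids or list(rc.columns) != ids:
        raise ValueError("bnti and rc matrices must share sample ids")
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            z = float(bnti.loc[a, b])
            r = float(rc.loc[a, b])
            rows.append(
                {"sample_a": a, "sample_b": b, "bnti": z, "rc": r, "process": _classify_one(z, r)}
            )
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "bnti", "rc", "process"])
    n = len(pairs)
    fractions = {
        proc: float((pairs["process"] == proc).sum() / n) if n else 0.0
        for proc in PROCESSES
    }
    return AssemblyResult(pairs, fractions)


def assembly_analysis(
    ct: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    min_mean_relabund: float = 1e-4,
) -> tuple[AssemblyResult, NcmFit]:
    """Full within-group assembly pipeline: filter, NCM, betaNTI, RC, classify."""
    from .core_io import filter_taxa

    kept = filter_taxa(ct, min_mean_relabund=min_mean_relabund)
    ncm = fit_ncm(ct)
    bnti = beta_nti(kept, tree, n_null=n_null, seed=seed)
    rc = raup_crick_matrix(kept, n_null=n_null, seed=seed + 1)
    return classify_processes(bnti, rc), ncm
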