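"""Seeded generators for synthetic microbiome datasets.

Three regimes cover the assumptions of the downstream analyses:

* :func:`simulate_enterotype_dataset` — two latent compositional clusters
  (Dirichlet-multinomial mixture) with a two-phylum taxonomy whose balance
  differs between clusters, cluster-correlated host body weight, and
  season/habitat labels, emulating a two-enterotype gut community survey.
* :func:`simulate_neutral_communities` — Hubbell/Moran neutral local
  communities coupled to a fixed metacommunity by migration ``m``, the
  regime the Sloan neutral community model is built to detect.
* :func:`simulate_selection_communities` — environmental filtering on a
  phylogenetically conserved (Brownian) trait, producing the deterministic
  (homogeneous/heterogeneous selection) signal that the betaNTI null model
  is built to detect.

All generators are pure functions of their spec: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import CountTable, SampleMetadata, TaxonomyMap

__all__ = [
    "EnterotypeSimSpec",
    "NeutralSimSpec",
    "SelectionSimSpec",
    "simulate_enterotype_dataset",
    "simulate_neutral_communities",
    "simulate_selection_communities",
    "simulate_yule_tree",
    "survey_shaped_dataset",
]

# Season / habitat composition of the two clusters in the emulated survey
# (spring, summer, autumn) and (woodland, farmland, grassland) proportions.
_SEASON_PROPS = {1: (37 / 63, 11 / 63, 15 / 63), 2: (31 / 34, 3 / 34, 0 / 34)}
_HABITAT_PROPS = {1: (22 / 63, 25 / 63, 16 / 63), 2: (18 / 34, 12 / 34, 4 / 34)}
_SEASON_NAMES = ("spring", "summer", "autumn")
_HABITAT_NAMES = ("woodland", "farmland", "grassland")


@dataclass(frozen=True)
class EnterotypeSimSpec:
    """Two-cluster Dirichlet-multinomial community spec.

    ``theta`` is the Dirichlet concentration (larger = less within-cluster
    compositional noise); ``separation`` is the SD of per-genus log-abundance
    offsets between the two cluster base compositions; ``ratio_shift``
    multiplies cluster-2's phylum-1 ("Bacillota-like") genera so cluster 2
    has the higher phylum-1/phylum-2 balance in expectation.  Body weight is
    in grams, lengths in cm; only weight (hence BMI) differs by cluster.
    """

    n_samples: tuple[int, int] = (63, 34)
    n_taxa: int = 2000
    theta: float = 50.0
    base_compositions: tuple[np.ndarray, np.ndarray] | None = None
    n_genera: int | None = None
    separation: float = 1.2
    ratio_shift: float = 2.5
    depth_log_mean: float = float(np.log(20_000))
    depth_log_sd: float = 0.35
    trait_means: tuple[float, float] = (230.0, 275.0)
    trait_sd: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if any(n < 1 for n in self.n_samples):
            raise ValueError("each cluster needs at least one sample")
        if self.base_compositions is not None:
            for q in self.base_compositions:
                q = np.asarray(q, dtype=float)
                if q.shape != (self.n_taxa,):
                    raise ValueError(
                        f"base composition length {q.shape} != n_taxa {self.n_taxa}"
                    )
                if not np.isclose(q.sum(), 1.0):
                    raise ValueError("base compositions must sum to 1")


@dataclass(frozen=True)
class NeutralSimSpec:
    """Moran-type neutral local communities under migration from a metacommunity.

    Each local community holds ``local_size`` individuals; at every event one
    random individual dies and is replaced, with probability ``migration``,
    by an immigrant drawn from ``metacommunity_props``, otherwise by the
    offspring of a random local individual.  ``burn_in_steps`` is measured in
    generations (``local_size`` events each).  Reads are a multinomial
    subsample of the final local composition.
    """

    metacommunity_props: np.ndarray
    local_size: int = 1000
    migration: float = 0.1
    n_samples: int = 50
    reads_per_sample: int = 1000
    burn_in_steps: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.metacommunity_props, dtype=float)
        if not (0.0 < self.migration <= 1.0):
            raise ValueError("migration must be in (0, 1]")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("metacommunity_props must sum to 1")
        if (p < 0).any():
            raise ValueError("metacommunity_props must be nonnegative")
        object.__setattr__(self, "metacommunity_props", p)


@dataclass(frozen=True)
class SelectionSimSpec:
    """Environmental filtering on a phylogenetically conserved trait.

    A trait evolves along ``tree`` by early-burst Brownian motion (rate
    ``sigma2 * exp(-trait_decay * relative depth)``), concentrating
    divergence in deep branches the way microbial habitat preferences are
    conserved at coarse taxonomic levels; ``trait_decay = 0`` recovers plain
    Brownian motion.  Traits are standardized across tips.  Each sample
    group has an environmental optimum on that scale — a float, or the
    string ``"anchor"`` to place the optimum at the trait of a randomly
    drawn taxon, guaranteeing it sits in a realized clade — and taxa are
    sampled with weight proportional to
    ``exp(-(trait - optimum)^2 / (2 tau^2))`` times a lognormal base
    abundance (sd ``base_sd``).  Small ``tau`` = strong filtering.  Each
    sample independently occupies a random ``occupancy`` fraction of the
    pool with lognormal ``sample_jitter_sd`` abundance noise (the
    membership turnover that phylogenetic turnover statistics measure), and
    a small ``background`` weight floor admits transient taxa from outside
    the filtered clade, keeping the regional pool phylogenetically broad
    the way real surveys are.
    """

    tree: TreeNode
    group_optima: Sequence[tuple[float | str, int]] = (("anchor", 15),)
    sigma2: float = 1.0
    trait_decay: float = 10.0
    tau: float = 0.2
    depth: int = 1000
    base_sd: float = 0.1
    sample_jitter_sd: float = 0.3
    occupancy: float = 0.6
    background: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


# ---------------------------------------------------------------------------
# Enterotype-structured data
# ---------------------------------------------------------------------------


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary parts (content-addressed)."""
    import zlib

    h = 0
    for p in parts:
        if isinstance(p, np.ndarray):
            b = np.ascontiguousarray(p).tobytes()
        else:
            b = repr(p).encode()
        h = zlib.crc32(b, h)
    return h % (2**31 - 1)


def _default_taxonomy_and_bases(rng: np.random.Generator, spec: EnterotypeSimSpec):
    """Assign taxa to genera within two phyla and build cluster base compositions."""
    n_taxa = spec.n_taxa
    n_genera = spec.n_genera or max(20, n_taxa // 16)
    n_genera = min(n_genera, n_taxa)
    genus_of_taxon = np.sort(rng.integers(0, n_genera, size=n_taxa))
    # make sure every genus index in range has >=0 members; relabel to the
    # set actually used so genus ids are dense
    used = np.unique(genus_of_taxon)
    remap = {g: i for i, g in enumerate(used)}
    genus_of_taxon = np.array([remap[g] for g in genus_of_taxon])
    n_genera = len(used)
    phylum_of_genus = np.array([0 if g < n_genera / 2 else 1 for g in range(n_genera)])

    # genus-level base masses shared by the clusters, then cluster-specific
    # log-offsets (separation) plus the phylum-balance shift for cluster 2
    base_mass = rng.lognormal(mean=0.0, sigma=1.2, size=n_genera)
    offset = rng.normal(0.0, spec.separation, size=n_genera)
    mass1 = base_mass * np.exp(offset / 2.0)
    mass2 = base_mass * np.exp(-offset / 2.0)
    mass2 = mass2 * np.where(phylum_of_genus == 0, spec.ratio_shift, 1.0)

    # split each genus mass over its member ASVs
    asv_share = rng.gamma(shape=0.7, scale=1.0, size=n_taxa) + 1e-12
    q = np.zeros((2, n_taxa))
    for k, mass in enumerate((mass1, mass2)):
        w = asv_share * mass[genus_of_taxon]
        q[k] = w / w.sum()
    return genus_of_taxon, phylum_of_genus, (q[0], q[1])


def _proportional_counts(props: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n items over fixed proportions."""
    raw = np.asarray(props, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def simulate_enterotype_dataset(
    spec: EnterotypeSimSpec,
) -> tuple[CountTable, TaxonomyMap, SampleMetadata, pd.Series]:
    """Generate a two-cluster community survey.

    Returns ``(counts, taxonomy, metadata, true_labels)`` where labels are 1/2.
    Each cluster's samples are drawn from a content-addressed substream of the
    seed, so swapping the two clusters' parameters swaps the generated blocks
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    hierarchical = spec.base_compositions is None
    if hierarchical:
        genus_of_taxon, phylum_of_genus, (q1, q2) = _default_taxonomy_and_bases(rng, spec)
    else:
        q1 = np.asarray(spec.base_compositions[0], dtype=float)
        q2 = np.asarray(spec.base_compositions[1], dtype=float)
        n_genera = spec.n_genera or max(20, spec.n_taxa // 16)
        n_genera = min(n_genera, spec.n_taxa)
        genus_of_taxon = np.sort(rng.integers(0, n_genera, size=spec.n_taxa))
        used = np.unique(genus_of_taxon)
        genus_of_taxon = np.array([{g: i for i, g in enumerate(used)}[g] for g in genus_of_taxon])
        phylum_of_genus = np.array([0 if g < len(used) / 2 else 1 for g in range(len(used))])

    taxon_ids = [f"ASV{i + 1:05d}" for i in range(spec.n_taxa)]
    phyla = ("Bacillota", "Bacteroidota")
    lineages = {}
    for i, tid in enumerate(taxon_ids):
        g = genus_of_taxon[i]
        ph = phyla[phylum_of_genus[g]]
        lineages[tid] = (
            "Bacteria",
            ph,
            f"{ph}_class",
            f"{ph}_order",
            f"{ph}_family_{g // 10}",
            f"genus_{g:04d}",
            "",
        )
    taxonomy = TaxonomyMap(lineages)

    blocks = []
    labels = []
    weights = []
    lengths = []
    tails = []
    seasons: list[str] = []
    habitats: list[str] = []
    n_genera = int(genus_of_taxon.max()) + 1
    genus_onehot = np.zeros((spec.n_taxa, n_genera))
    genus_onehot[np.arange(spec.n_taxa), genus_of_taxon] = 1.0

    for k, (q, n_k, mu) in enumerate(
        zip((q1, q2), spec.n_samples, spec.trait_means), start=1
    ):
        crng = np.random.default_rng(_stable_seed(spec.seed, q, mu, n_k))
        if hierarchical:
            # two-level draw: genus proportions ~ Dirichlet(theta * q_genus),
            # then the genus mass split over member ASVs with mild jitter.
            # ASVs of a genus therefore co-vary across samples, giving real
            # co-occurrence structure at the ASV grain.
            q_genus = q @ genus_onehot
            within = q / np.maximum(q_genus[genus_of_taxon], 1e-300)
            gam = crng.gamma(
                shape=np.tile(spec.theta * q_genus, (n_k, 1)), scale=1.0
            )
            gam = np.where(gam <= 0, 1e-300, gam)
            gprops = gam / gam.sum(axis=1, keepdims=True)
            jitter = crng.lognormal(0.0, 0.5, size=(n_k, spec.n_taxa))
            w = gprops[:, genus_of_taxon] * within[None, :] * jitter
            props = w / w.sum(axis=1, keepdims=True)
        else:
            alpha = spec.theta * q
            # gamma construction: robust for tiny alphas (dirichlet underflows)
            gam = crng.gamma(shape=np.tile(alpha, (n_k, 1)), scale=1.0)
            gam = np.where(gam <= 0, 1e-300, gam)
            props = gam / gam.sum(axis=1, keepdims=True)
        depths = np.maximum(
            100, np.round(crng.lognormal(spec.depth_log_mean, spec.depth_log_sd, n_k))
        ).astype(int)
        counts = np.vstack(
            [crng.multinomial(depths[i], props[i]) for i in range(n_k)]
        )
        blocks.append(counts)
        labels.extend([k] * n_k)
        weights.extend(crng.normal(mu, spec.trait_sd, n_k).tolist())
        lengths.extend(crng.normal(18.0, 1.2, n_k).tolist())
        tails.extend(crng.normal(4.5, 0.5, n_k).tolist())
        n_season = _proportional_counts(_SEASON_PROPS[min(k, 2)], n_k)
        n_habitat = _proportional_counts(_HABITAT_PROPS[min(k, 2)], n_k)
        for name, cnt in zip(_SEASON_NAMES, n_season):
            seasons.extend([name] * cnt)
        for name, cnt in zip(_HABITAT_NAMES, n_habitat):
            habitats.extend([name] * cnt)

    counts = np.vstack(blocks)
    n_total = counts.shape[0]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    # drop taxa never observed so the table satisfies downstream expectations
    ct = CountTable(pd.DataFrame(counts, index=sample_ids, columns=taxon_ids))
    keep = ct.data.sum(axis=0) > 0
    ct = CountTable(ct.data.loc[:, keep])

    weights_arr = np.maximum(60.0, np.asarray(weights))
    lengths_arr = np.maximum(10.0, np.asarray(lengths))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "season": seasons,
                "habitat": habitats,
                "body_weight": weights_arr,
                "body_length": lengths_arr,
                "tail_length": np.maximum(1.0, np.asarray(tails)),
            },
            index=sample_ids,
        )
    )
    true_labels = pd.Series(labels, index=sample_ids, name="true_cluster")
    return ct, taxonomy, meta, true_labels


def survey_shaped_dataset(seed: int = 0, n_taxa: int = 2000):
    """The default survey-shaped fixture: 97 samples in a 63/34 split."""
    spec = EnterotypeSimSpec(n_samples=(63, 34), n_taxa=n_taxa, seed=seed)
    return simulate_enterotype_dataset(spec)


# ---------------------------------------------------------------------------
# Neutral communities
# ---------------------------------------------------------------------------


def simulate_neutral_communities(spec: NeutralSimSpec) -> CountTable:
    """Evolve neutral local communities and return multinomial read counts.

    All samples are evolved in lockstep (one vectorized Moran event across
    samples per step), which is statistically identical to independent serial
    simulation because samples never interact.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.metacommunity_props
    n_taxa = p.size
    S, N = spec.n_samples, spec.local_size
    cdf = np.cumsum(p)
    cdf[-1] = 1.0

    # individuals as taxon labels; init = iid draws from the metacommunity
    state = np.searchsorted(cdf, rng.random((S, N)), side="right").astype(np.int32)

    n_events = spec.burn_in_steps * N
    rows = np.arange(S)
    chunk = 4000
    done = 0
    while done < n_events:
        b = min(chunk, n_events - done)
        death = rng.integers(0, N, size=(b, S))
        parent = rng.integers(0, N, size=(b, S))
        migrate = rng.random((b, S)) < spec.migration
        imm = np.searchsorted(cdf, rng.random((b, S)), side="right").astype(np.int32)
        for t in range(b):
            new = np.where(migrate[t], imm[t], state[rows, parent[t]])
            state[rows, death[t]] = new
        done += b

    counts = np.zeros((S, n_taxa), dtype=np.int64)
    for s in range(S):
        local = np.bincount(state[s], minlength=n_taxa).astype(float)
        counts[s] = rng.multinomial(spec.reads_per_sample, local / local.sum())

    sample_ids = [f"N{s + 1:03d}" for s in range(S)]
    taxon_ids = [f"ASV{i + 1:05d}" for i in range(n_taxa)]
    df = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    return CountTable(df)


# ---------------------------------------------------------------------------
# Selection-structured communities
# ---------------------------------------------------------------------------


def brownian_traits(
    tree: TreeNode,
    sigma2: float,
    rng: np.random.Generator,
    decay: float = 0.0,
) -> pd.Series:
    """(Early-burst) Brownian motion along the tree; standardized tip traits.

    With ``decay > 0`` the Brownian rate falls as ``exp(-decay * d)`` where
    ``d`` is relative depth from the root, so most trait divergence happens
    on deep branches and clades carry coherent trait values.
    """
    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    height = max((depth[id(t)] for t in tree.tips()), default=0.0)
    height = height if height > 0 else 1.0

    value = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        d0 = depth[id(node.parent)] / height
        d1 = depth[id(node)] / height
        if decay > 0:
            var = sigma2 * (np.exp(-decay * d0) - np.exp(-decay * d1)) / decay
        else:
            var = sigma2 * (d1 - d0)
        value[id(node)] = value[id(node.parent)] + rng.normal(
            0.0, np.sqrt(max(var, 1e-12))
        )
    tips = pd.Series({t.name: value[id(t)] for t in tree.tips()})
    sd = tips.std(ddof=0)
    return (tips - tips.mean()) / (sd if sd > 0 else 1.0)


def simulate_selection_communities(
    spec: SelectionSimSpec,
) -> tuple[CountTable, TreeNode]:
    """Communities filtered around per-group environmental optima.

    As ``tau`` grows the Gaussian filter flattens and sampling reduces to the
    neutral base-abundance weighting.
    """
    rng = np.random.default_rng(spec.seed)
    traits = brownian_traits(spec.tree, spec.sigma2, rng, decay=spec.trait_decay)
    taxon_ids = list(traits.index)
    base = rng.lognormal(0.0, spec.base_sd, size=len(taxon_ids))

    rows = []
    sample_ids = []
    groups = []
    i = 0
    for g, (optimum, n_k) in enumerate(spec.group_optima, start=1):
        if optimum == "anchor":
            optimum = float(traits.iloc[int(rng.integers(len(taxon_ids)))])
        filt = np.exp(-((traits.to_numpy() - float(optimum)) ** 2) / (2.0 * spec.tau**2))
        filt = filt + spec.background
        for _ in range(n_k):
            i += 1
            jitter = rng.lognormal(0.0, spec.sample_jitter_sd, size=len(taxon_ids))
            occ = rng.random(len(taxon_ids)) < spec.occupancy
            w = base * filt * jitter * occ
            if w.sum() <= 0:  # degenerate draw: fall back to the full pool
                w = base * filt
            if w.sum() <= 0:
                raise ValueError("filter removed all taxa; increase tau")
            rows.append(rng.multinomial(spec.depth, w / w.sum()))
            sample_ids.append(f"G{g}_{i:03d}")
            groups.append(g)

    df = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=taxon_ids)
    keep = df.sum(axis=0) > 0
    return CountTable(df.loc[:, keep]), spec.tree


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_yule_tree(
    n_tips: int,
    seed: int = 0,
    ultrametric: bool = False,
    tip_names: Sequence[str] | None = None,
    branch_scale: float = 0.1,
) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_tips`` uniquely labelled tips.

    With ``ultrametric=True`` branch lengths come from the birth process's
    waiting times so every root-to-tip distance is equal; otherwise branch
    lengths are iid exponential with mean ``branch_scale``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if tip_names is not None and len(tip_names) != n_tips:
        raise ValueError("tip_names length must equal n_tips")
    rng = np.random.default_rng(seed)

    root = TreeNode(length=None)
    birth: dict[int, float] = {}
    t = 0.0
    active: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(length=0.0)
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(0, len(active)))
        node = active.pop(idx)
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode(length=0.0)
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t_present = t + rng.exponential(1.0 / n_tips)
    for node in active:
        node.length = t_present - birth[id(node)]

    if not ultrametric:
        for node in root.traverse(include_self=False):
            node.length = float(rng.exponential(branch_scale)) + 1e-9

    names = list(tip_names) if tip_names is not None else [
        f"ASV{i + 1:05d}" for i in range(n_tips)
    ]
    for name, tip in zip(names, root.tips()):
        tip.name = name
    for j, node in enumerate(root.non_tips(include_self=True)):
        node.name = None
    return root
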