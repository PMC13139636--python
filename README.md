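# enterostrat

Enterotype stratification and community-ecology analysis for microbiome
count tables.

Gut microbial communities often fall into a small number of discrete,
recurrent compositional states — *enterotypes* — rather than varying along
a continuum. Identifying those states, and asking how their member
communities assemble, interact and relate to host traits, is a standard
analysis arc in wildlife and host-associated microbiome studies.
`enterostrat` implements that arc as a tested, reusable library and CLI
operating on ASV (amplicon sequence variant) count tables, with seeded
synthetic-data generators so every stage can be exercised and calibrated
without raw sequencing data.

## What it computes

* **Enterotyping** — genus-level Jensen–Shannon distance
  (√JSD, with JSD = H(M) − [H(p)+H(q)]/2, M = (p+q)/2), partitioning
  around medoids (PAM; exact enumeration when the medoid search space is
  small), cluster number chosen by maximizing the Calinski–Harabasz index,
  silhouettes as corroboration, classical-scaling PCoA.
* **Diversity** — observed richness, Shannon (nats), Chao1, ACE, Faith PD;
  Bray–Curtis β diversity; one-way PERMANOVA and PERMDISP (seeded
  permutation tests); shared/unique ASV (UpSet) accounting;
  Mann–Whitney / Welch tests with Benjamini–Hochberg FDR.
* **Biomarkers** — LEfSe-style two-stage screen (Kruskal–Wallis filter,
  bootstrapped Fisher-LDA effect size, |LDA| > 2.5 at p < 0.05), SIMPER
  decomposition of between-group Bray–Curtis, and a six-family classifier
  screen (k-NN, random forest, Gaussian NB, logistic regression, decision
  tree, gradient-boosted trees) with 70/30 stratified split, rank-formula
  AUC and permutation importances.
* **Co-occurrence networks** — Spearman |ρ| > 0.6 at BH-q < 0.05 after
  abundance (≥ 0.01 %) and prevalence (≥ 30 %) filtering; node topology
  (degree, closeness, betweenness, eccentricity) and network topology
  (density, clustering, path length, modularity).
* **Community assembly** — Sloan's neutral community model
  (occurrence frequency vs. mean relative abundance; fitted migration m,
  Nm, R²); βMNTD/βNTI against a tip-shuffle null; Raup–Crick on
  Bray–Curtis with richness- and depth-preserving nulls; five-way process
  partition (homogeneous/heterogeneous selection at βNTI ∓2, dispersal
  limitation / homogenizing dispersal at RC ±0.95, drift otherwise).
* **Niche breadth** — Levins B = 1/Σp² per taxon, permutation-null
  classification into generalists/specialists/neutrals, and group-level
  breadth comparison.
* **Trait association** — Spearman collinearity pre-filter (|ρ| > 0.6) and
  redundancy analysis (Hellinger-transformed community ~ body size +
  α diversity + enterotype dummies) with permutation tests.

## Worked example

```python
import enterostrat as es

spec = es.EnterotypeSimSpec(n_samples=(20, 12), n_taxa=400, seed=7)
counts, taxonomy, metadata, truth = es.simulate_enterotype_dataset(spec)

ent = es.select_enterotypes(counts, taxonomy, k_range=range(2, 6))
print("chosen k:", ent.chosen_k)
print("CH by k:", {k: round(v, 1) for k, v in ent.ch_by_k.items()})

bc = es.bray_curtis(counts)
res = es.permanova(bc, ent.labels.map("E{}".format), n_perm=999, seed=0)
print(f"PERMANOVA: R2 = {res.R2:.3f}, p = {res.p:.3f}")

fit = es.fit_ncm(counts.subset_samples(ent.group_ids(1)))
print(f"NCM (E1): m = {fit.m:.4f}, Nm = {fit.Nm:.0f}, R2 = {fit.r2:.3f}")
```

prints

```
chosen k: 2
CH by k: {2: 20.5, 3: 12.3, 4: 9.1, 5: 7.7}
PERMANOVA: R2 = 0.311, p = 0.001
NCM (E1): m = 0.0945, Nm = 2348, R2 = 0.681
```

The CH profile peaks at k = 2, recovering the two simulated enterotypes
exactly (ARI = 1.0 against the generator's labels); community structure
differs significantly between them (PERMANOVA), and the Sloan fit says a
neutral immigration–drift model explains ~68 % of the occupancy–abundance
relationship in the major enterotype, with migration rate m ≈ 0.09.

## Command line

```bash
enterostrat simulate --seed 7 --outdir sim/          # counts/taxonomy/metadata/tree
enterostrat run --config pipeline.yaml --seed 5      # full pipeline -> report.json
enterostrat enterotype --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv
enterostrat network --counts sim/counts.tsv
enterostrat assembly --counts sim/counts.tsv --tree sim/tree.nwk --seed 1
enterostrat niche --counts sim/counts.tsv --seed 1
enterostrat rda --counts sim/counts.tsv --metadata sim/metadata.tsv --seed 1
```

The `run` subcommand executes every stage in order (enterotype →
diversity → biomarkers → per-enterotype network/assembly/niche →
association) and writes per-stage TSVs plus a single `report.json` that is
byte-identical across runs with the same config and seed.

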