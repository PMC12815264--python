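# hgtcooc

Horizontal gene transfer (HGT) and co-occurrence analysis for marine
prokaryotic genomes.

Co-occurring microbes are widely observed to exchange genes more often —
but co-occurrence is confounded with phylogenetic relatedness (close
relatives both co-occur and retain ancestral similarity) and with shared
environmental preference. `hgtcooc` implements, as a tested reusable
pipeline, the analysis needed to disentangle these factors in ocean
metagenome data:

1. **HGT calling** from gene sequences, two ways: full-length gene
   clustering (≥ 95% identity, ≥ 95% mutual coverage) followed by
   cross-genus reciprocal best hits (the focal, conservative path), and a
   sensitive seed-and-extend search for identity segments ≥ 500 bp at
   ≥ 95% identity intersected with gene annotations (the network-level
   path). Events are binned by identity (≥ 99% "recent" vs 95–99% "older")
   and by the lowest taxonomic rank separating the genomes.
2. **Co-occurrence** from breadth-of-coverage presence calls (≥ 30%
   breadth, ≥ 10 samples prevalence): upper-tail hypergeometric tests with
   BH correction, plus the simple overlap |S₁∩S₂|/min(|S₁|,|S₂|) and
   compositional proportionality ρ_p as robustness checks, size-fraction
   classification of genomes, and per-sample HGT prevalence.
3. **The focal model** — a genome-pair logistic regression

   logit P(HGT_ij = 1) = β₀ + β₁·cooccur_ij + β₂·d̃_ij + Σ_v γ_v·|Δmedian_v|ĩj + fraction class

   with orderNorm-transformed continuous predictors, VIF diagnostics, AIC
   model comparison, and a collider-bias simulation showing why
   conditioning on HGT induces a spurious distance difference between
   co-occurrence strata.
4. **Functional enrichment** of transferred genes: majority-rule COG
   categories per cluster, stratified Fisher exact tests, and gene-level
   mobile-genetic-element fold enrichments.
5. **Environmental modelling** of per-sample HGT prevalence: redundancy
   filtering, |1 − ρ| variable clustering, a 10 000-tree-capable random
   forest with out-of-bag permutation importance, shuffle-null importance
   significance, ICE curves and Friedman–Popescu H-statistics.

Because the real inputs (thousands of genomes, ~1900 ocean metagenomes) are
external downloads, the package ships a first-class synthetic-data module
(`hgtcooc.simulate`) that generates the whole study — taxonomy-consistent
phylogeny, vertically diverged gene families, planted transfers at
controlled identities and taxonomic gaps, niche-driven presence/abundance
matrices and environmental covariates — with a ground-truth table for every
planted signal, so every stage of the analysis is testable end to end.

## Worked example

```python
from hgtcooc import association, cooccurrence, detect
from hgtcooc.simulate import simulate_dataset

ds = simulate_dataset(seed=0)          # 50 genomes, 40 planted transfers
genes = {g.gene_id: g for gm in ds.genomes for g in gm.genes()}
taxonomy = {g.genome_id: g.taxonomy for g in ds.genomes}
contig_lengths = {c.contig_id: c.length for gm in ds.genomes for c in gm.contigs}

clusters = detect.cluster_genes(list(genes.values()))
events = detect.call_rbh_hgt(clusters, genes, taxonomy, contig_lengths)

pres = cooccurrence.call_presence(ds.samples.breadth, ds.samples.rpkm)
retained, _ = cooccurrence.filter_prevalence(pres.present)
present = cooccurrence.drop_empty_samples(pres.present[retained])
cooc = cooccurrence.hypergeom_cooccurrence(present)

fracs = cooccurrence.classify_size_fraction(
    present, pres.rpkm.loc[present.index, retained], ds.samples.fractions)
env_medians = association.genome_env_medians(present, ds.samples.env)
table = association.build_pair_table(
    events, cooc, ds.patristic, env_medians, fracs, taxonomy,
    retained_genomes=retained)
env_t = [c for c in table.columns if c.endswith("_diff_t")]
res = association.PairLogit(
    table, ["cooccur", "phylo_dist_t", *env_t, "fraction_class"]).fit()
print(res.summary())
```

which prints (abridged):

```
called 40 putative HGT events (24 at >=99% identity)
228 of 1225 genome pairs co-occur (q<0.05, ratio>1)
Pair-level logistic regression (HGT ~ ecology + phylogeny)
  n = 1219, logLik = -104.31, AIC = 242.62
  intercept = -5.274

  term                             coef      se                ci95         p
  cooccur                         1.792   0.642      [ 0.53,  3.05]   0.00527
  phylo_dist_t                   -0.937   0.226      [-1.38, -0.49]  3.42e-05
  ...
  fraction_class[combined_fl_pa]  1.597   0.866      [-0.10,  3.29]    0.0652
```

Read-out: both planted drivers are recovered — genome pairs flagged as
co-occurring have `exp(1.79) ≈ 6.0`-fold increased odds of sharing a
transfer after controlling for phylogeny and environment, and each standard
deviation of phylogenetic distance multiplies the odds by `exp(−0.94) ≈
0.39`. The environmental median-difference terms are small, and the
particle-attached-inclusive fraction class trends positive — the same
qualitative structure the planted truth encodes.

The same analysis runs from the shell:

```bash
hgtcooc run-all --out runs/demo --seed 0
```

writing per-stage TSV outputs and a manifest under `runs/demo/`; reruns
with the same configuration are byte-identical and completed stages are
reused.

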