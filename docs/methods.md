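# Methods

`hgtcooc` implements an end-to-end analysis linking horizontal gene transfer
(HGT) between prokaryotic genomes to their co-occurrence across metagenomic
samples, their phylogenetic distance, and the sampled environment. Because
the analysis is exercised on synthetic data with planted truth, this note
describes both the analysis methods and the generative model they are tested
against, including which features of real data the generator does and does
not emulate.

## Synthetic study conditions

### Taxonomy and phylogeny

Genomes carry a seven-rank taxonomy (domain → species). The phylogeny is
ultrametric and defined directly by the taxonomy: the internal node joining
taxa that differ at rank *r* sits at height `divergence[r] / 2`, so two
genomes whose lowest differing rank is *r* are exactly `divergence[r]`
substitutions/site apart. Default divergences (species → domain):
0.10, 0.18, 0.30, 0.45, 0.60, 0.78, 1.00; same-species genomes are 0.02
apart. Leaves are sampled uniformly from the enumerated species so a 50-genome
set contains a natural mix of within-genus, within-family, … cross-domain
pairs. No branch-length jitter is applied: an ultrametric tree makes the
taxonomy/tree concordance property exact and the patristic matrix analytic
(the newick emitted alongside is verified against an independent
path-sum oracle in the tests).

### Sequence evolution and calibration

Each genome receives one gene per ortholog family (default 100 families of
900 bp), tiled on 1–5 contigs. Gene order is an independent permutation per
genome, so a transferred gene is flanked by unrelated sequence in the
recipient — the situation the region detector faces in rearranged real
genomes. Sites evolve independently down the tree: on a branch of length
*t*, a site substitutes with probability `1 − exp(rate·t)` and is redrawn
uniformly from the three alternative bases (a Jukes–Cantor-like process
without indels, so identity is `1 − Hamming/length`). The exact expected
ortholog identity composes the per-branch kernels:
`P(same) = 1/4 + 3/4 · Π_i (4·exp(−rate·t_i) − 1)/3` over the path edges.

The species-level divergence (0.10) is deliberately set so that **every**
vertical ortholog pair — within-genus included — sits below the 0.95
identity threshold the detectors use (within-genus expectation ≈ 0.91,
cross-genus ≈ 0.84, with ±0.01 binomial noise at 900 bp). Any
multi-member gene cluster therefore reflects a planted transfer, which makes
"zero false-positive genome pairs" a meaningful, checkable property rather
than a tolerance. This is a testability calibration, not an empirical claim
about marine genomes.

### Planting transfers

A transfer copies the donor's gene over the recipient's gene of the same
family (orthologous replacement keeps contig tiling intact), then mutates
the copy per-site to a target identity. "Recent" events target ≥ 99%
identity, "older" events 95.5–98.5%; the realized identity (recorded in the
truth table) is the target plus binomial noise, and detectability is judged
on the realized value. The default fixture plants 28 recent + 12 older
events (70% recent, matching the observed preponderance of high-identity
transfers) plus two negative controls: one event whose recipient gene sits
on a < 5000 bp contig (must be removed by the contig filter) and one 400 bp
window copied into an unrelated host gene (below the region detector's
500 bp minimum).

A family may host several transfers provided the genomes involved are all
distinct and pairwise cross-genus; vertical divergence then keeps the
per-event clusters separate and no spurious high-identity pair arises
between events. Event pairs are sampled with weight
`exp(−patristic/0.35)` (planting the negative distance effect), boosted
×20 for pairs that co-occur (see below) and ×4 for pairs of
particle-attached-classified genomes; families of the defense (V) COG
category are favoured ×25 (planting the functional enrichment).

### Samples, environment, abundance

Twelve oceanographic covariates (latitude, longitude, depth, temperature,
potential density, salinity, nitrate, oxygen, chlorophyll *a*, PAR, fCDOM,
bbp470) are drawn with a shared latent depth gradient, producing realistic
mutual correlations (|ρ| < 0.95, so all twelve survive the redundancy
filter by default). Genome occupancy is logistic in one or two covariates:
ten niche groups of three genomes share response parameters (slopes
1.2–2.0) and therefore co-occur; remaining genomes get weak individual
responses (slopes 0.15–0.5). Thirteen genomes are instead tied to a
size-fraction label: present with probability 0.55 in samples of their
fraction and 0.03 elsewhere, with boosted abundance in-fraction. Genomes
touched by HGT get an occupancy shift (+0.6·z(nitrate) − 0.6·z(PAR)),
planting the environment → HGT-prevalence link.

Because environment-driven co-occurrence extends well beyond the labelled
niche groups, the sample matrix is drawn twice with one seed: a draft pass
(without the carrier shift) determines which pairs *actually* co-occur
significantly, planting bias targets those pairs, and the final pass
regenerates identically except for the carrier shift. The planted
"co-occurring pairs exchange genes more" statement is thus true of the
realized presence matrix, not merely of labels.

Breadth of coverage is U(0.45, 1) when present and usually 0 (occasionally
U(0, 0.295), below the 30% presence cut-off) when absent; abundance (RPKM)
is log-normal per genome, with small spurious values for some absent
genomes to exercise the post-presence zeroing.

What the generator does **not** emulate: indels and rearranged gene
fragments, assembly chimerism and contamination, read-level noise in
breadth/RPKM, non-ultrametric rate variation, within-species population
structure, and spatially autocorrelated sampling. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability of
planted effects under idealized noise — not detector performance on real
metagenome-assembled genomes.

## HGT detection

**Cluster-RBH path (focal).** Genes are clustered greedily in descending
length (ties by identifier): a gene joins the first cluster whose
representative it matches at ≥ 95% identity with a length ratio ≥ 0.95,
else founds a cluster. Identity is Hamming-based for equal lengths and
`1 − editDistance/max(len)` otherwise (global alignment covers both
sequences end-to-end, so the length-ratio check is the operative coverage
condition). A shared-16-mer prefilter restricts candidate representatives;
at these thresholds a qualifying pair always shares an exact 16-mer (≤ 5%
mismatches spaced over length L leave a clean run of ≥ (L−m)/(m+1) ≥ 18
bases), so the partition equals the all-pairs greedy scan, which the tests
verify against a brute-force oracle. Within each multi-member cluster,
genome pairs differing at the genus level or above yield an event when two
genes are reciprocally each other's highest-identity match (ties by gene
id) at ≥ 95% identity; at most one event per (cluster, genome pair), and
events on contigs < 5000 bp are removed *after* calling.

**Region path (sensitive).** Exact shared 31-mers between contigs seed
diagonal chains (seeds ≤ 300 bp apart are chained); each chained run is
extended ungapped in both directions while the running identity of
run + extension stays ≥ 95%, with an X-drop stop (score = matches −
mismatches falling 20 below its maximum) as a secondary rule, trimmed back
to the furthest matching position. Overlapping extensions on a diagonal are
merged and identity is recomputed over the union; segments ≥ 500 bp at
≥ 95% identity are reported. Per genome pair, overlapping segments are
resolved to the highest score (ties: longer, then lexicographic
coordinates) before genes are intersected (≥ 1 bp overlap ⇒ one event per
gene). Gapped alignment is deliberately omitted: qualifying hits are ≥ 95%
identical and the generator is indel-free, so ungapped extension is exact
here; on real data this choice would shorten hits across indels.

Events carry an identity bin (≥ 99% "recent" vs 95–99% "older") and the
lowest taxonomic rank at which the two genomes differ; per-level rates are
normalized by the number of genome comparisons at each level.

## Co-occurrence

Presence is `breadth ≥ 0.30` (inclusive); RPKM is zeroed where absent;
genomes present in < 10 samples and samples with no present genome are
dropped. The focal test is upper-tail hypergeometric
(`p = P[X ≥ obs]`, observed table included) with Benjamini–Hochberg
correction across all tested pairs; "co-occurring" means q < 0.05 and
observed/expected ratio > 1. On discrete support this exact convention is
conservative, so its null p-values are super-uniform; a mid-p variant
(`P[X > obs] + pmf/2`) is provided for calibration diagnostics, where it is
near-uniform. Two alternative measures are implemented: the simple overlap
`|S₁∩S₂| / min(|S₁|,|S₂|)` and proportionality ρ_p on centred log-ratios of
pseudocounted RPKM (pseudocount 1 RPKM-unit by default; which
proportionality variant best matches compositional practice is left
configurable).

Size-fraction classification requires strictly > 75% of a genome's occupied
samples in one group *and* the highest median RPKM there; unlabelled
samples count in the denominator (conservative). Per-sample feature
prevalence is the fraction of present genomes carrying a feature; matched
small/large-fraction samples are compared with two-sided paired Wilcoxon
tests (p = 1 when all differences vanish) and fold change
mean(large)/mean(small), BH-corrected across features.

## Pair-level association model

The feature table holds one row per cross-genus pair of retained genomes:
the binary HGT response, the binary co-occurrence flag, patristic distance,
|difference in median environmental value| per variable (medians over each
genome's occupied samples), and a pair-level size-fraction class whose
reference level is "mixed or unclassified" — so the two fitted dummies read
as the free-living and particle-attached-inclusive effects. Continuous
predictors are orderNorm-transformed: average ranks mapped through
Φ⁻¹((rank − 0.5)/n). The transform is monotone and rank-invariant; with
heavy ties (patristic distance takes only seven values on an ultrametric
tree) the output deviates slightly from exact zero mean / unit variance,
which is inherent to rank mapping of tied data.

`PairLogit.fit()` is an IRLS maximum-likelihood logit (statsmodels GLM,
deviance tolerance 1e−8) returning coefficients with Fisher-information
standard errors, Wald z p-values, ±1.96·SE confidence intervals,
log-likelihood and AIC. Possible complete separation (which genuinely
arises when a fraction class contains no transfer pair) is flagged rather
than hidden. VIF uses the generalized (determinant) form so categorical
terms get one value per term. Model comparison is by AIC on identical rows.
The collider simulation draws distance and co-occurrence independently,
generates HGT from the logistic model with the focal effect magnitudes
(+2.26, −1.66), and shows that conditioning on HGT makes non-co-occurring
pairs look closer — the qualitative artifact pattern, with no mechanistic
link planted.

## Functional enrichment

Clusters receive a majority-rule COG category (every letter of a
multi-category annotation votes; ties and unannotated clusters are
unassigned; the eukaryote-specific categories A, B, Y, Z never vote).
Per stratum (identity bin × divergence level, plus an unstratified sweep),
each category is tested two-sided Fisher-exact on clusters-in-category ×
clusters-with-≥1-transfer against the COG-assigned universe, BH-corrected
within the stratum. Mobile-element enrichment is tested at the gene level
(the flags are gene- or contig-level annotations); zero margins get the
Haldane–Anscombe 0.5 correction on the odds ratio, flagged, with the
p-value always from the uncorrected exact test.

## Environmental random forest

Redundant variables (|Spearman ρ| ≥ 0.95 to an already-retained one,
greedy in column order) are dropped with their representative recorded;
the rest are clustered by average linkage on |1 − ρ| (kept as printed, so
perfect anticorrelation maps to distance 2, not 0). The forest is a bagging
ensemble of regression trees with per-split feature subsampling
(mtry = ⌊√p⌋, i.e. 3 for 12 variables) — the classic random-forest
construction, built on `BaggingRegressor` because it exposes each tree's
bootstrap indices publicly, which the out-of-bag (OOB) machinery needs.
OOB R² aggregates per-tree OOB predictions; variable importance is the mean
OOB MSE increase when that variable is permuted within each tree's OOB set,
evaluated in one stacked predict call per tree.

Significance comes from a shuffle null: the response is permuted and the
forest refitted `n_replicates` times (default 1000; null forests may use
fewer trees than the observed fit — 100 vs 300 at desk scale — since only
the importance ranks of the null matter). Two p-value conventions are
offered: the plain proportion of null importances at or above the observed
one, and a (+1)/(n+1) variant that avoids zero p-values. The plain
proportion is the default for the recovery analyses because with m
variables the (+1)/(n+1) floor makes BH significance unreachable at
moderate replicate counts (minimum q = m/(n+1), e.g. 12/201 ≈ 0.06 at 200
replicates with 12 variables). The Spearman sign of each variable with the
response is attached as directional context only.

ICE curves substitute a grid into one variable per sample; their mean is
identically the partial-dependence curve (asserted to 1e−10). The
Friedman–Popescu H² for a variable pair is
`Σ[PD_jk − PD_j − PD_k]² / Σ PD_jk²` with all partial-dependence functions
mean-centred over the sample, evaluated at the observed points; it is
symmetric by construction and undefined when the joint PD is identically
zero. Note that small mtry attenuates estimated joint effects, so H² for a
pure product response approaches its theoretical value only when trees can
see both variables (mtry near p).

## Problem sizes and numerical choices

The shipped study conditions use 50 genomes × 100 genes × 900 bp,
200 samples, 40 detectable planted events, and seed-pinned generation
throughout; every stochastic operation takes an explicit seed and reruns
are byte-identical. The recovery analyses use 100 logistic replicates at
1500 pairs; the forest analyses use n = 150 samples with 12 variables
(mirroring the scale of the in-depth environmental analysis), 200 shuffle
replicates for recovery and 100 for the null-calibration sweep, with
300-tree observed and 40–100-tree null forests. These sizes were chosen as
the smallest at which the planted effects are comfortably powered. Fixture
serialization writes floats with `%.17g` and reads them with round-trip
parsing so write → read is bit-exact.

## Known limitations

- No indel evolution and no gapped extension: identities are exact here but
  both detectors would under-call across indels on real data.
- The region path reports dilution-limited segment ends; a few flanking
  bases beyond a planted interval can attach, occasionally touching an
  adjacent gene (consistent with this path's more-sensitive,
  more-false-positive role).
- The ultrametric, taxonomy-locked tree makes patristic distance discrete;
  orderNorm on it is well-defined but coarsely binned.
- The mixed-model variant with a per-genome random effect (duplicated-table
  design) is not fitted; only the design-table constructor
  (`association.duplicate_pair_table`) is provided, since the duplication
  invalidates the variability estimates such a model would report.
- The generator's category frequencies, effect sizes and noise levels are
  design choices for detector testability, not estimates of ocean
  conditions.
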