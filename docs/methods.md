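# Methods

`steppedemo` implements a simulation-based inference pipeline for the late
Quaternary demography of paired steppe lineages: an *extrazonal* lineage
(EZ; isolated steppe patches embedded in forested Europe) and a *zonal*
lineage (Z; the continuous Pontic–Kazakh steppe belt) of the same species.
The question is whether the last glacial period (LGP, ~115–12 kya) drove
demographic expansions in both lineages, only in the zonal one, or in
neither, and — under the chosen scenario — how large the expansions and the
subsequent Holocene contractions were.

## Demographic model

Both lineages descend from one ancestral population that split
`t_split` years ago. Backward in time from the present, three epochs are
bounded by the Holocene contraction time `t_contr`, the LGP expansion time
`t_exp`, and `t_split` (0 < t_contr < t_exp < t_split). Each lineage has
one diploid effective size per epoch (`n_*_post`, `n_*_lgp`, `n_*_pre`),
plus the ancestral `n_anc`; sizes are piecewise constant. Bidirectional
migration acts only in the pre-LGP and LGP epochs, parameterized as the
forward-time per-generation migrant fraction (the proportion of the
receiving deme replaced by migrants); the Holocene epoch has no migration.

Three scenarios constrain the size trajectories:

* **Parallel expansion** — both lineages satisfy
  `n_lgp > max(n_pre, n_post)`;
* **Zonal expansion only** — the EZ sizes are constant across epochs, the
  Z lineage expands;
* **No expansion** — both lineages are constant.

The equality constraints are applied by copying after the prior draw; the
expansion orderings (which *define* an expansion scenario) are enforced by
rejection re-sampling, the same mechanism used for the time ordering, so
marginal priors are preserved within the admissible region.

### Priors (defaults; all overridable via config)

| parameter | prior | rationale |
|---|---|---|
| `t_split` | uniform 300 ky – 1.6 My | mid-Pleistocene divergence window |
| `t_exp` | uniform 30 – 115 ky | span of the last glacial period |
| `t_contr` | uniform 1 – 12 ky | Holocene |
| interglacial + ancestral sizes | log-uniform 1e3 – 1e5 | small enough that the 1–12 ky Holocene and the pre-LGP epoch register on the coalescent clock |
| LGP sizes | log-uniform 1e3 – 1e7, with expansion ordering | spans the tens-fold glacial expansions the system shows |
| migrant fractions | log-uniform 1e-8 – 1e-4 | typical 4Nm ≲ 1: gene flow restricted enough for two lineages to stay distinct over ~1 My, with tens of migrants/generation in the upper tail |

The size and migration priors are deliberately *informative*. Under fully
diffuse size priors (several orders of magnitude for every epoch) most
draws place all coalescence outside the glacial window and the three
scenarios become nearly indistinguishable — no classifier, however strong,
can then reach the accuracies this kind of analysis is meant to deliver;
and under migrant fractions approaching 1e-3, 4Nm ≫ 1 makes the split time
unidentifiable. Both statements were verified empirically with
summary-statistic oracle classifiers/regressors during development.

## Coalescent simulation

Loci are 89-bp RAD fragments: non-recombining internally, freely
recombining between loci, one biallelic SNP retained per fragment.
Simulation uses msprime, one single-locus genealogy per replicate, with
the epoch structure translated into backward-time events
(`event_schedule` → `msprime.Demography`). Forward migrant fractions map
to msprime's backward convention (the forward fraction of deme B replaced
from A equals the backward rate of lineages moving B→A); the conversion is
unit-tested against the two-island equilibrium FST = 1/(1+8Nm) and a
directional diversity check.

Three ways of producing the SNP matrix:

* `conditional` — exactly one segregating site per genealogy, on a branch
  drawn proportionally to branch length (the classic `ms -s 1` device).
  Note the implied site-frequency law is E[ℓᵢ/ℓ_T], slightly
  singleton-enriched relative to the 1/i law, and is tested against an
  independent genealogy-based Monte-Carlo oracle.
* `calibrated` (default for species-shaped data) — as `conditional`, but
  the realized SNP count is drawn as Binomial(`n_loci`, p̂), with p̂ the
  mean per-locus segregation probability 1 − exp(−µLℓ_T) estimated from
  the simulated genealogies. Low-diversity histories thus yield fewer
  columns than the image width and appear as zero-padding — the diversity
  information a fixed-locus-count simulation feeding fixed-size images
  carries. Default `n_loci` = 10× the SNP target.
* `mutation` — mutations dropped at rate µ, monomorphic loci skipped, an
  informative error if the yield is below the target (the mode for
  µ-sensitive studies; used by the 1/i SFS oracle test).

Missing data are injected at the species' empirical genotype-missingness
rate: each (individual, site) genotype is masked independently, always
both haplotype rows together; all-missing columns are re-drawn.

## Image encoding

SNP matrices become fixed-size three-level images: −1 reference, +1
alternative, 0 missing; EZ rows on top, Z rows below; columns truncated or
zero-padded on the right to a fixed width. Row-order policies:

* `sorted` — whole rows sorted within each lineage block by descending +1
  count (ties by row content, so the image is invariant to the input row
  permutation);
* `within_column` (CNN pipeline default) — each column of a block is
  re-stacked canonically: derived pixels, then reference, then missing.
  Since RAD loci are unlinked, haplotype identity across columns carries
  no information, and this renders each column's (derived, called) counts
  as bar heights.

Columns are additionally sorted by their per-lineage derived-allele
pattern (`column_order="sorted"`), so position along the SNP axis encodes
a frequency quantile and the image becomes a staircase rendering of the
joint site frequency spectrum plus missingness. In development this
encoding was the difference between a CNN stuck at chance and one matching
a gradient-boosting oracle built directly on joint-SFS summaries.

## CNN, calibration, ABC

The network is implemented in-house in numpy (deterministic, CPU,
seeded): stacked 1-D convolution blocks along the SNP axis with the
haplotype rows as input channels, each block conv → batch norm → ReLU →
pooling, distinct kernel sizes per block (defaults 2/5/10, 32 channels),
global average pooling (or a flatten head) and a dense output. Training is
Adam with decoupled weight decay (1e-4), batch 64, learning rate 5e-4,
25 epochs, with the best-validation-accuracy epoch restored. All layers
pass central-difference gradient checks; training is bit-reproducible for
a fixed seed on a fixed BLAS configuration.

Probabilities are calibrated by temperature scaling: a single T ∈
[0.05, 20] minimizing validation NLL of `logits/T` (bounded scalar
optimization). T = 1 is always a feasible fallback, so calibration never
increases validation NLL and never changes a predicted class.

Model selection: the calibrated probability vectors of the observed
dataset and of an independent simulated reference set are ABC summary
statistics; plain rejection retains the `tolerance` fraction with the
smallest Euclidean distance (stable ties), and scenario posterior
probabilities are the label frequencies among retained records.
Parameter estimation: a CNN regressor (same trunk, MSE) predicts
log10-transformed sizes/times and logit-transformed migrant fractions;
rejection runs on reference-SD-standardized predicted vectors; posteriors
are the true parameters of retained records, summarized by median and
95% HPD (shortest contiguous interval over the sorted samples containing
⌈0.95·n⌉ points; cross-checked against arviz).

## Time calibration and SFS

`tau_to_years` converts multispecies-coalescent divergence estimates
(τ = 2µt, t in generations) to years per posterior sample, drawing µ and
the generation time from gamma distributions specified by mean and sd
(shape = (mean/sd)², rate = mean/sd²; sd = 0 is a point mass). "±" values
such as a 10 ± 2 y generation time are read as mean ± sd. The upstream MSC
MCMC itself is out of scope; τ samples are an input.

The SFS module handles missing data by hypergeometric down-projection:
each site's contribution at projected size `n_proj` is the expected
derived-count distribution over all subsamples of its called alleles;
sites with fewer called alleles than `n_proj` are dropped and counted.
Joint spectra accumulate the outer product across the two populations;
folding happens after projection (joint folding dadi-style on total
count, central cells split evenly). `choose_projection` scans candidate
sizes and keeps the one maximizing expected segregating sites, ties to
the larger size. Correctness is established against brute-force
enumeration of every subsample on small matrices.

## Synthetic data and what passing tests show

Five species-shaped fixtures pin the dataset geometries (individuals per
lineage, SNP count, missingness, µ, generation time) of the study system,
e.g. 10+10 individuals × 1,763 SNPs at 42% missingness for the
*O. petraeus* shape. Pseudo-observed datasets carry their true parameters;
their random streams are namespaced so they can never collide with a
reference table built from the same master seed (asserted by test).

The generator emulates: unlinked biallelic RAD loci, two-deme epoch
demography, genotype-level missingness uniform over individuals and
sites. It does **not** emulate: RAD locus dropout structure (allelic
dropout correlated with divergence), sequencing error, within-locus
multi-SNP haplotypes, or population substructure within lineages. Passing
tests therefore validate the inference machinery under the stated model,
not robustness to those real-data artifacts.

## Problem sizes and expected performance

All shipped runs are desk-scale, sized for a single CPU: the acceptance
script uses 300 SNP columns (n_loci 3,000) and 400/60/100
train/validation/test simulations per scenario per species shape
(~4–6 min each); the test suite uses smaller versions of the same
protocols. At this scale the held-out three-scenario accuracy of the
calibrated CNN is around 0.45–0.60 — far above chance (binomial p ≪ 1e-6)
but below the 0.65–0.88 cross-validation accuracies attainable with the
study-scale data (1,763–12,542 SNP columns, 10,000 simulations per
scenario): accuracy rises monotonically with both image width and
training-set size in side experiments, and a gradient-boosting classifier
on ideal joint-SFS summary statistics shows the same ceiling on the same
desk-scale data, locating the limit in the information content of the
scaled-down datasets rather than in the estimator. The same applies to
parameter recovery: 95% HPD coverage is nominal, posterior medians of
recent-epoch sizes track the truth well (Spearman ρ ≈ 0.8), while split
time and LGP peak size are weakly identified at 150–300 SNP columns
(ρ ≈ 0.2).

## Numerical and degenerate-input choices

Years→generations conversion is exact (float); event times are linear in
1/generation-time by construction. Rejection sampling of constrained
priors is bounded (1,000 attempts → configuration error). ABC retains
round(tolerance·N) ≥ 1 records; zero-variance summary dimensions are
dropped with a warning; HPD falls back to the sample range below 20
samples. All-missing columns after masking are re-drawn (bounded), then
one genotype is force-called. Empty matrices, single-class calibration
sets, mixed-scenario regressor inputs, non-positive times/sizes and
out-of-range fractions raise explicit errors.
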