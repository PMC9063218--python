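# Methods

## Pipeline overview

`epinet` turns a case/control genotype cohort and a disease-map gene list
into, per map: gene–gene epistasis scores, selected epistatic edges
(separately for physical and cis-eQTL SNP→gene mapping, plus their union),
a missense-filtered pair list, a direction table for eQTL-mapped pairs, and
permutation p-values for network connectivity and maximum degree. All
randomness (control subsampling, EM restarts, cross-validation folds,
permutation sampling) is driven by explicit seeds recorded in the run
manifest; a manifest suffices to reproduce a run bit for bit.

## Cohort QC

The genomic inflation factor is median(statistic)/0.4549364, the
denominator being the median of the χ²(1) distribution (fixed constant).
The per-SNP statistic is the Cochran–Armitage trend test with additive
scores 0/1/2 — any 1-df association statistic would serve for this
diagnostic; the trend test is the standard choice for case/control GWAS.
Controls are subsampled uniformly at random (seeded) to match the case
count; the minor allele is redefined within the cohort after balancing.
Missing genotype calls are imputed to the SNP's rounded mean count before
any modeling; files keep the missing sentinel.

## Haplotype-cluster HMM and propensities

Each haplotype is a walk over K ancestral clusters: at site j the walk
stays with probability 1−ρ_j or jumps to cluster k with probability
ρ_j·α_jk; cluster k emits the minor allele with frequency θ_jk. A diploid
genotype is the sum of two independent chains, so all inference runs on the
K×K product chain; the Kronecker structure of the pair transition keeps
every forward/backward step at O(K³) per sample. EM (Baum–Welch) updates
all parameters; θ is clipped to [1e−4, 1−1e−4]; the observed-data
log-likelihood is non-decreasing by construction and is asserted in tests.
Initialization: uniform α, ρ = 0.05, θ = allele frequency plus seeded
N(0, 0.1) jitter, 3 random restarts by default (best final likelihood
wins). K defaults to 12 for real-scale cohorts; the bundled synthetic
studies use K ∈ {2, 4}, matching their generating models.

The propensity of a target SNP is P(binarized state = 1 | other sites),
read from the predictive state distribution at the target site: forward
message into the site times backward message out of it, neither including
the target's own emission. Conditioning on both flanks is the default; a
forward-only (left flank) variant is kept as an option since either reading
of "apply the forward algorithm" is defensible. Propensities are clipped to
[ε, 1−ε], ε = 0.01 by default, to protect the inverse weights.

Target binarization is dominant (≥1 minor allele → 1) by default: for the
low-MAF SNPs typical of GWAS panels this maximizes the balance of the two
propensity arms. Recessive encoding is available. Targets whose binarized
state is constant are degenerate: they are flagged, their score rows are
zero, and they cannot win any ranking.

## Interaction scoring

Phenotypes are coded ±1 (cases +1) so both arms contribute to the modified
outcome. The robust variant divides the treated weights Ã/π and control
weights (1−Ã)/(1−π) by their respective sample means (Hájek
self-normalization), the small-large-sample-variance correction family; it
reduces exactly to the plain variant when π is constant at the empirical
arm share. The elastic net (mixing 0.5, penalty chosen by seeded 5-fold
cross-validated MSE over a 50-point grid) is fitted on per-column
standardized candidates; scores are absolute coefficients. Candidates are
all other mapped SNPs of the same disease map (gene-level scores only
consume within-map ranks); a genome-wide candidate set is a configuration
choice away but quadratically more expensive.

## Rank aggregation and tie handling

Within each target row, candidates are ranked by decreasing score. Sparse
fits tie most candidates at score zero, and this forced a design decision:
any fixed tie *order* (e.g. ascending SNP index) injects systematic rank
noise into the gene-level averages — enough, in our planted-signal studies,
to let arbitrary small-gene pairs overtake a genuinely epistatic pair.
Since tied scores carry no ordering evidence, the default assigns them
midranks (the mean of the spanned rank range, the standard treatment of
ties); the SNP-pair score 1/√(r_ij+r_ji) and its bounds are unchanged.
Deterministic permutation tie rules (ascending index, or a seeded random
key) remain available for workflows that require integer rank permutations.

With ranks starting at 1, SNP-pair scores live in
[1/√(2(p−1)), 1/√2] ≈ [0.022, 0.707] for p = 1000; the lower bound is the
sharp one. Gene scores average the SNP-pair scores over the cross product
of the two genes' SNP sets, which removes gene-size effects; a SNP mapped
to both genes of a pair is excluded from both sides for that pair, and
self-pairs are never scored. Selection keeps the top 2% of a map's gene
pairs, k = nearest integer (half up) of 0.02 × #pairs with a floor of one —
the only rounding rule consistent with the published per-map edge counts —
with cutoff ties broken by score then lexicographic gene pair.

## Direction of the epistatic effect

For each selected gene pair the top-scoring SNP pair enters an unpenalized
logistic interaction fit on additive allele counts (additive coding matches
the linear eQTL expression model e = γ + βx it is combined with).
Separation is flagged (optimizer non-convergence or |coefficient| > 15) and
flagged pairs are excluded rather than Firth-corrected. eQTL effect sizes
come from β = Z/√(2q(1−q)(m+Z²)). The direction is sign(α₁₂/(β₁β₂)) —
algebraically, rescaling the SNPs to expression units divides α₁₂ by β₁β₂,
so this is the interaction sign on the expression scale; it is invariant
under flipping both β signs (allele-coding invariance). The same-sign
filter keeps pairs with β₁, β₂, α₁₂ all strictly positive ("inhibit both")
or all strictly negative ("activate both").

## Network permutation tests

The null model samples m distinct vertex pairs (edges) uniformly among the
C(n,2) pairs of the map's n mapped genes, S = 1000 times by default, and
reports raw S′/S (no pseudo-count, so a single-edge network prints exactly
1.000). Connectivity is judged on the subgraph induced by the edges —
isolated vertices are ignored, which is what makes one-edge networks
"connected". Hubs are the max-degree vertices (all ties reported) when the
max-degree p-value is below 0.05. Sampling is without replacement among
distinct pairs, matching the observed networks, which cannot carry
duplicate edges.

## Synthetic study conditions

The generator emulates the shape of the real inputs without reproducing any
real data. Defaults: 2000 samples, 100 SNPs on 2 chromosomes, 20 genes of
heterogeneous size (2–8 SNPs), MAF drawn uniformly in [0.1, 0.5], K = 4
generating clusters, within-gene jump rate 0.05, and one planted epistatic
gene pair with interaction log-odds α₁₂ = 1.0 and all-positive planted eQTL
Z-scores (so the pair should survive the same-sign filter with direction
+1). Cluster emissions split into balanced minor-allele-rich/-poor groups
(±d around the site frequency, d up to min(f, 1−f)), so the expected MAF
equals the drawn frequency while cluster runs carry LD that decays with
distance (adjacent r² ≈ 0.1–0.15, near zero beyond ~10 sites).
Recombination hotspots (jump probability 0.95) at gene-block starts emulate
disease-map genes being scattered across the genome, so between-gene LD is
negligible — as in the real setting, where map genes sit megabases apart.
Phenotypes are Bernoulli draws from the planted logistic model with the
linear predictor centered, so the null case fraction is ½. An
independent-sites generator (no LD) is kept as a deliberate
misspecification switch.

What the generator does *not* emulate: realistic allele-frequency spectra,
long-range LD and population structure, genotyping error, and real
disease-map content. Passing recovery tests therefore demonstrate internal
consistency of the statistical machinery under its own assumptions, not
performance on real cohorts.

## Test problem sizes

Recovery-style properties run as replicate studies sized for a desk-scale
budget: planted-pair recovery uses 10 replicates of the full workflow
(n = 2000, 20 genes, α₁₂ = 1.5 as the "strong" interaction) with a
threshold of 8/10; direction recovery uses 20 replicates with a threshold
of 18/20; modified-outcome unbiasedness uses n = 5000 with 3-standard-error
bands; permutation p-values are checked against full enumeration for
n ≤ 10, m ≤ 4. Exhaustive-enumeration oracles for the HMM use ≤3-site,
K = 2 toys where summing over all hidden path pairs is exact.

## Known limitations

- The exact robust-outcome variant of the original targeted-epistasis
  estimator is defined in its own reference implementation; the Hájek
  per-arm normalization here is a reconstruction of that family.
- Gene-level scores inherit the dilution of cross-product averaging: an
  interaction carried by one SNP pair inside two large genes is diluted by
  the factor |G₁||G₂|. Midrank ties mitigate but do not remove this.
- An interaction also induces *marginal* phenotype association on its two
  SNPs, which leaks (zero in expectation, O(1/√n) in finite samples) into
  the modified outcome of every other target; pairs of one truly epistatic
  gene with a random partner therefore score spuriously well. Together with
  the dilution above, this makes recovery of a planted pair into a tight
  top-2% cut borderline in the replicate study the suite runs: the planted
  gene pair ranks in the top ~5% of pairs in every replicate, but does not
  always clear the 2% line.
- Permutation p-values are raw S′/S; with S = 1000 the smallest resolvable
  non-zero p is 0.001.
- The HMM assumes missing-at-random genotypes already imputed; no reference
  panel imputation.
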