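# Methods

`hybridscan` analyses cross-sectional cohorts of admixed individuals from an
avian hybrid zone, genotyped at ancestry informative markers (AIMs), for
signatures of extrinsic postzygotic selection: loci and locus pairs at which
genotype frequencies shift across age classes, and structural-variant
(inversion-like) regions that could hold co-adapted alleles together.  This
note documents the models, the synthetic-data generator, the validation
scenarios, and the numerical conventions.

## Data model

Ancestry states are coded 0 (homozygous coastal), 1 (interspecific
heterozygote), 2 (homozygous inland), `NaN` missing.  Genome-wide ancestry is
`q = mean(state)/2` over non-missing loci (coastal parental 0, F1 0.5, inland
parental 1); individual heterozygosity `h` is the proportion of loci in
state 1.  Loci are sorted lexicographically by chromosome label and position;
all locus indices refer to this order.  AIM hard-calling uses a strict
posterior threshold (> 0.9, otherwise missing), and AIM selection from
parental panel counts uses a strict allele-frequency-difference threshold
(> 0.5).  Z-chromosome states are taken as given; no hemizygous recoding.

## Viability scans

Per locus, the response is the binary interspecific-heterozygosity indicator
and the model is

    het ~ ancestry_q * age + sex,   binomial(logit)

with age numeric (HY=0, SY=1, ASY=2).  Age is treated as a single linear
term: the alternative ordered-factor coding would produce two coefficients
and no single per-term p-value, and the biological prediction (monotone
change across age classes under viability selection) is linear.  Per-pair,
the response is the ancestry-mismatch distance — the perpendicular Euclidean
distance of the two-locus genotype point from the line joining the coastal
and inland panel-mean points — fitted with the same design under a Poisson
log link.  The distance is continuous and non-negative; the Poisson fit is
therefore a quasi-likelihood estimating equation (coefficients and Wald
tests identical to R's `glm` on such data), and the scan logs this caveat
once per run.

Fitting is iteratively reweighted least squares with dispersion fixed at 1,
convergence at a maximum absolute coefficient change below 1e-8 (at most 100
iterations), Wald two-sided p-values from the normal distribution, and
rank-deficient design columns dropped and flagged.  Perfect separation is
detected as any coefficient exceeding 30 on the logit scale; such fits are
flagged non-converged with missing p-values rather than penalised — the
scan stays a plain GLM.  Loci with fewer than 20 complete cases or a
monomorphic response are skipped with a reason.  Benjamini–Hochberg FDR is
applied within two strata — all autosomes pooled, and the Z chromosome
alone — and outliers are loci with q strictly below 0.05.

Anchors for the mismatch distance default to panel means from designated
parental reference data; absent that, individuals with q ≤ 0.05 / ≥ 0.95
serve as proxy panels.  Scanning all ~n²/2 pairs is deliberately not a
default; callers supply or subsample a pair list with a recorded seed.

## Enrichment

Linkage blocks span the positions of all same-chromosome loci with dosage
r² strictly above 0.5 against the focal locus.  Genes (1-based closed
intervals; BED converted on read) are assigned to blocks by ≥ 1 bp overlap.
The candidate-overlap test splits the `c` candidates into overlap vs
non-overlap with expected proportions `(a/b, 1−a/b)` — expectation
`e = (a/b)·c` — and computes a 1-df chi-square goodness-of-fit; an exact
binomial tail is reported alongside as a cross-check, since the two-category
and contingency constructions are not distinguishable from the convention
the result format implies.  The recombination contrast is a two-sided
Wilcoxon rank-sum test with midrank ties: exact enumeration when both
groups have at most 10 windows, otherwise the tie-corrected normal
approximation without continuity correction.

## Structural-variant suite

Local PCA runs in non-overlapping 100-kb windows (minimum 5 usable loci;
missing states mean-imputed per locus, PCA only).  Each window is summarised
by the top-2 eigenpairs of the individuals×individuals covariance
`X·Xᵀ/L_w`.  The distance between windows is the Frobenius norm between
rank-2 covariance reconstructions, evaluated through the inner-product
identity `d² = Σλ_A² + Σλ_B² − 2Σ_{k,l} λ_Ak λ_Bl (v_Ak·v_Bl)²`.  Window
distances are embedded with classical (Torgerson) MDS — double-centred
squared distances, top eigenpairs, negative eigenvalues clamped, axis sign
fixed so the first non-zero loading is positive — and k-means over the MDS
plane selects k (2–8) by maximum mean silhouette, ties to the smaller k.

Outlier windows have |z| > 1 on MDS1 (absolute value, because an MDS axis
sign is arbitrary; a signed mode is available), and maximal runs of at
least 10 genomically adjacent outlier windows become regions.  Region
genotyping is PCA over the region followed by k-means (k=3) on PC1;
clusters are relabelled 0/1/2 by increasing mean ancestry dosage in the
region, so the ends are putative homokaryotypes and the centre the putative
heterokaryotypes, whose region-restricted heterozygosity is expected
highest.  LD heatmaps filter on minor-state frequency (≥ 0.05, boundary
inclusive) and missingness, optionally thin to one locus per window, and
are computed separately for all samples and for the major-homokaryotype
subset: a real inversion elevates r² across the region in the full sample
but not among homokaryotypes, which recombine freely.

## Hi-C comparison

Contact matrices are symmetric dense arrays with a masked-bin set, read and
written as upper-triangle COO TSV with a JSON header.  The comparison order
is mask → balance → normalise → merge → ratio: coverage masking z-scores
`log(1+rowsum)` over all bins in a single pass (z < −1.5 or z > 5 masked;
statistics ignore the incoming mask, making the operation idempotent); ICE
balancing divides rows and columns by mean-normalised marginals until the
maximum relative deviation falls below 1e-5; the higher-coverage matrix is
scaled down to the lower total; bins are merged by summing factor×factor
blocks (a merged bin is masked only if all constituents were); and the map
is the entrywise log2 ratio, undefined where either side is zero at zero
pseudocount or either bin masked.  The balancing algorithm is ICE-style
iterative correction — the processing chain the package reproduces names
only the masking thresholds, and matrix balancing is the standard choice.

## Synthetic cohorts

Each individual carries two haplotypes simulated as two-state Markov
ancestry tracts along each chromosome.  A haplotype with inland proportion
`p` switches between gaps with probabilities `r·gap_Mb·p` (coastal→inland)
and `r·gap_Mb·(1−p)` (inland→coastal), the factor `r·gap` capped at 1; this
preserves the stationary proportion, and at `r·gap ≥ 1` consecutive loci
are independent.  Ancestry classes: coastal/inland parentals (both
haplotypes fixed), F1 (one of each), backcrosses (one fixed, one
recombinant at p=0.5), and later-generation admixed individuals whose `p`
is Beta-distributed with a mean solved from the configured cohort target
(default 0.77 inland, the hybrid-zone average) and a concentration
parameter.  Defaults describe the emulated study population: 900 birds,
~2,000 AIMs over five autosomes and the Z with block LD
(`tract_switch_rate` 0.5/Mb), mean inland ancestry 0.77.

Survival is logistic per transition (HY→SY, SY→ASY):
`logit = base + Σ β_het·het(locus) + Σ β_int·het(locus)·q +
Σ β_pair·d(pair) + Σ β_pair_q·d(pair)·q`, where `d` is the mismatch
distance at (0,0)/(2,2) anchors.  The ancestry-interaction coefficients let
selection strength depend on genome-wide ancestry, matching the epistatic
hypothesis the scans test.  Age classes are cross-sectional: each candidate
is assigned a prospective class (quota-weighted) and accepted only if its
survival draws reach it, so each class has exactly the conditional genotype
distribution of survivors and the classes are independent cohorts, not
recaptures.  Sex is 50/50 with no effect.  One root seed spawns separate
genotype and assignment streams; identical seeds give bit-identical output.

A planted inversion assigns each haplotype an orientation drawn from its
ancestry proportion.  In heterokaryotypes both haplotypes carry a single
constant ancestry across the interval (complete recombination suppression),
so every interval locus is heterozygous when the orientations differ —
producing the three-cluster PCA signal with maximal central-cluster
heterozygosity.  Homokaryotypes exchange freely within the region,
modelled as an 8% per-locus ancestry flux on recombinant haplotypes, which
keeps interval loci segregating (above the MAF filter) but mutually
uncorrelated within the homokaryotype subset.

Companion generators produce a two-valued recombination map (low rate with
log-normal noise inside the inversion, high outside) and toy Hi-C matrix
pairs sharing a Poisson distance-decay expectation `intensity/(1+|i−j|)`
over 60 bins of 10 kb, with an optional fold-amplified long-range contact
neighbourhood present in one matrix only.

## Validation scenarios and what they show

The emulated hybrid zone violates two assumptions of the scan model, and
the validation scenarios are chosen so that each property is tested where
it is defined:

* **Calibration** (no-selection cohort, n=400, 200 loci): the heterozygote
  probability is a parabola in ancestry (`≈2q(1−q)`), while the model's
  logit is monotone in q.  Over a cohort spanning both branches the mean
  model is misspecified and Wald p-values are conservative even under the
  null; over an inland-biased cohort without coastal-side classes the
  sampled range lies on the descending branch and the model is
  near-correctly specified.  The calibration cohort therefore uses the
  mixture {inland 0.10, backcross-inland 0.12, later 0.78} and unlinked
  loci (1 Mb spacing at switch rate 1/Mb), making the 200 tests independent
  as the binomial reference band requires.  Raw age- and interaction-term
  p-values are uniform there (KS) with the significant fraction inside the
  95% band around 0.05.

* **Recovery** (five het-selected loci; three epistatic pairs): in an
  inland-biased cohort, selection against heterozygosity at several loci
  unavoidably selects on ancestry composition itself (heterozygosity and
  ancestry are correlated at q̄=0.77), inducing a genome-wide age shift at
  every locus, while the target's own Wald z saturates near |z|≈3 for
  strong effects (the Hauck–Donner effect, compounded by the collinearity
  of the age and q×age columns when q is far from 0).  No effect size makes
  planted targets outrank that background.  Recovery is therefore validated
  on a balanced hybrid swarm (later-generation only, mean q=0.5,
  concentration 2) over an unlinked 400-locus panel, where the
  exposure–ancestry gradient vanishes: planted loci (β_het=−2) reach
  z≈−5 on the age term and occupy the top ranks, and planted pairs
  (β_pair_q=−6) lead the interaction-term ranking among 1,000 scanned
  pairs.  Passing these tests shows the scan machinery finds what its
  model can represent; it does not show that age-term rankings isolate
  individual targets in a strongly ancestry-biased zone, where block LD
  and composition shifts spread signal genome-wide — consistent with
  large significant fractions being a real feature of such scans.

* **Inversion** (n=300, one 6-Mb chromosome, 1,500 loci, 1.5-Mb planted
  inversion): background tracts are short (switch rate 20/Mb) so only the
  inversion creates window-scale structure.  The suite calls exactly one
  region covering the interval, genotypes karyotypes at ≥95% accuracy with
  the central cluster's region heterozygosity highest, and shows elevated
  LD across the region in all samples but not within the major
  homokaryotype cluster.

* **Hi-C**: an 8-fold planted contact at bins (10,40) survives the full
  pipeline as the most positive merged cell; twenty null pairs produce no
  2×2 block of merged cells with |log2 ratio| > 1.

What the generator does not emulate: genotyping error and read-level noise,
realistic coalescent tract-length distributions (a free-parameter Markov
switch rate stands in), hemizygosity of the Z in females, kinship between
sampled birds, and missing-call structure.  Conclusions about real data at
those margins require care beyond these tests.

## Numerical conventions

Strict inequalities at every published threshold (posterior > 0.9,
frequency difference > 0.5, r² > 0.5, q < 0.05, |z| > 1).  LD-prune
tie-breaking removes the lower-MAF member of an over-threshold pair, then
the later locus by position; pruning its own output is a fixed point.
K-means runs 25 restarts at a fixed seed.  Window distances clamp
numerically negative squared distances at a relative 1e-12.  MDS clamps
negative eigenvalues to zero.  All IRLS weights are floored at 1e-10.
Problem sizes in the validation suite (n=300–900 individuals, 200–1,500
loci, 1,000 pairs, 60-bin Hi-C grids) are the package's chosen desk-scale
study conditions; each scenario completes in seconds.
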