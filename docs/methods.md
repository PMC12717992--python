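# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerically delicate choices a maintainer should know
about.

## Data model

The central object is a `GenotypePanel`: a samples × sites matrix of
allele dosages in {0, 1, 2, MISSING} with per-site metadata (chromosome,
1-based position, ref/alt bases, ancestral allele, array quality class).
Dosages count ALT alleles as read from the VCF (`coding="alt"`) until
`polarize_to_ancestral` recodes them to derived-allele counts
(`coding="derived"`); stages that depend on ancestral state (load, iHS)
refuse alt-coded panels. MISSING is a negative sentinel and is never
imputed except where a stage requires a complete matrix (the RDA response
and neutral PCs use mean imputation). BED gene intervals are converted to
1-based inclusive coordinates on read; everything downstream is 1-based.

Sites with an unknown ancestral state are dropped at polarization but
retained for the allele-label-symmetric statistics (H_exp, F_ST, PCA),
which are computed on the unpolarized panel.

## Filtering and LD pruning

Site filters follow array-genotyping practice: non-indel biallelic SNPs,
quality class in {PolyHighResolution, MonoHighResolution, NoMinorHom},
missing fraction below a cap, optionally polymorphic. Filters are applied
in that fixed order and each site is charged to the first rule that
removes it, so the attrition counts sum to the number removed.

LD pruning windows by **variant count** (window 500, step 200, 5
iterations, r² cap 0.1) with a `window_unit="bp"` switch. The literature
on these arrays describes the window in bp while the routine actually
used windows by variant count; we default to the tool's semantics and
expose the ambiguity as an option. Within a window the later site of an
over-correlated pair is removed; missingness is handled pairwise when
computing genotype correlation.

## Diversity and inbreeding

Per-site H = 1 − p² − q² with p the within-population frequency among
non-missing calls; a site needs ≥ 2 called genotypes to contribute. The
population mean is a NaN-ignoring mean over **all** retained sites
(`segregating_only` gives the alternative); which convention a published
per-population H_exp used at population-monomorphic sites is usually
unstated, so the default is documented here rather than guessed silently.

Inbreeding uses the method-of-moments estimator
F = (O_hom − E_hom)/(N − E_hom) with the small-sample correction
E_het(site) = 2pq·n/(n−1) on the cohort's called allele number n — the
formula of the standard VCF toolchain, which does not print it. The
cohort is the sample's own population. F is NaN when the expected
heterozygous count is zero (monomorphic cohort).

Great-circle distances use the haversine formula with the IUGG mean Earth
radius 6371.0088 km. All gradient tests are Spearman (rank) correlations:
they are invariant to monotone transforms, which also makes the IBD test
blind to the Slatkin linearization (a useful internal consistency check).

## Hudson F_ST

Per-site numerator and denominator follow the Bhatia/Hudson estimator
(see README for the formulas); sites need ≥ 2 called alleles per
population, and by default each pair uses the sites segregating in the
union of the pair (`seg_scope="global"` switches to dataset-wide
segregating sites — the absolute values differ between the scopes, which
is why both exist). The overall estimate is the **ratio of sums**, never
the mean of per-site ratios; a constructed counterexample in the tests
pins this. The SE is a delete-one-block jackknife over contiguous blocks
of `block_size` variants (default 100,000); a single block yields a
finite F_ST with an undefined SE. Negative per-site numerators are kept
(the estimator is unbiased around zero); the reported long table carries
both the raw value and a zero-floored column for presentation.

Environmental distance standardizes each bioclim variable to mean 0 and
exactly unit (population) standard deviation before Euclidean distance,
so a two-population variable scales to ±1 and contributes 2 to their
distance. Affine rescaling of any raw variable is absorbed.

The IBD p-value is the plain Spearman p over upper-triangle pairs, as in
the analysis convention this package mirrors; pairs are not independent,
so a Mantel permutation variant is provided (`mantel_test`) and its use
logged. The cluster contrast is a two-sample Kolmogorov–Smirnov test of
within- vs between-cluster F_ST values; clusters need ≥ 2 populations.

## EHH / iHS

DH lines are fully homozygous, so dosages {0, 2} collapse to haplotypes
{0, 1} with no phasing step; a dosage of 1 is a hard error and sites with
missing calls in the panel are dropped. EHH at flanking site x is the
pair homozygosity of the partition of carrier haplotypes into classes
identical from the core through x, computed incrementally (O(n) per site
rather than all-pairs). The walk stops after the first point below
`ehh_cutoff` (default 0.05) or at the chromosome end.

iHH integrates EHH trapezoidally over bp, truncated at the last point at
or above the cutoff, with inter-site gaps capped at `max_gap` (200 kb).
iHS_raw = ln(iHH_A/iHH_D) with both-direction (left + right) integrals
per allele; negative values mean long derived haplotypes. Standardization
is within `n_bins` equal-width derived-frequency bins over [0, 1]
(default 100); sites whose curve hits a chromosome end while still above
the cutoff are edge-censored and excluded from standardization by
default. Defaults mirror the scan tool this analysis style uses
(cutoff 0.05, MAF 0.05, gap 200 kb), since publications typically do not
print them; candidate counts are sensitive to these choices.

Empirical p is rank(|iHS|)/N with average ranks for ties (deterministic,
order-free); the significance call is the dual rule p < 0.05 AND
|iHS| > 2. On standard-normal scores the expected significant fraction is
min(0.05, P(|Z|>2)) ≈ 0.0455, which the calibration test checks.
Nearest-gene annotation reports signed bp distance (0 inside a gene),
breaking exact ties toward the lower-coordinate gene.

## Partial RDA and forward selection

The RDA response is the individual-level centered, mean-imputed derived
dosage matrix, with population-level bioclim values broadcast to
individuals (a population-frequency response is available via
`genotype_response(level="population")`). Conditions are removed from
both response and predictors by OLS (intercept always included);
constrained variance is the squared norm of the response residuals'
projection onto an orthonormal basis of the predictor residuals (SVD,
rank-tolerant). For partial models the reported R² uses the
**conditioned** total (variance remaining after removing the
conditions); the common ordination-software convention divides by the
raw total instead — the two are proportional by the conditioned/raw SS
ratio, so model rankings and permutation p-values agree. Adjusted R² is
Ezekiel's 1 − (1−R²)(n−1)/(n−1−m) with m the post-residualization rank. p-values come from freely permuting rows
of the predictor residuals, p = (1+k)/(1+B) with B = 999 by default
(199 in the pipeline's default parameters for speed); a within-population
restricted scheme is a documented alternative for clustered rows.

Forward selection admits, at each step, the candidate with the largest
cumulative adjusted R² provided its marginal permutation p (conditional
on the selected set) is below alpha; selection ends when no candidate
passes or when the cumulative adjusted R² reaches the global-model
ceiling (the adjusted R² using every candidate). The ceiling-reaching
variable is **retained**: it passed its own permutation test, and
rejecting it would discard the last genuine predictor whenever noise
candidates dilute the global model — the boundary case where the naive
rule misfires. Near-collinear candidates (R² ≥ 0.99 on the selected set)
are skipped with a warning. Ties in adjusted R² beyond 1e-9 go to the
earlier-listed variable, keeping selection deterministic.

The four-model comparison fits the full model (climate + neutral PCs +
lat/lon as predictors) and the three pure models (one block as predictor,
the others as conditions), ranking by adjusted R². Because partials
overlap, no ordering between the full and pure models is asserted beyond
the nested-model bound on unadjusted R².

## Genetic load

total_load(i) = Σ_s GERP(s) × derived_dosage(i, s), joined strictly on
(chrom, pos); unscored sites are skipped with a count. Missing cells
contribute 0 — there is no per-sample rescaling by callable sites;
instead, samples above the 95th empirical quantile of missing fraction
are excluded (strict >, so a fully called panel excludes nobody), the
same two-part convention as the analysis this mirrors. Homozygous derived
genotypes count the score twice (dosage weighting); a presence/absence
mode exists for sensitivity analysis because published "sum of GERPs"
descriptions rarely pin this down. Highly deleterious alleles are derived
alleles at sites with GERP strictly greater than 5.

Fixed/segregating classification is group-relative on non-missing calls:
derived-fixed sites contribute 2×GERP to the group's fixed load,
segregating sites contribute dosage-weighted per-sample seg_load, and
with complete data total = fixed + segregating exactly (asserted).

## Synthetic generator

The generator is frequency-level: ancestral frequencies are drawn once
from Beta(0.8, 0.8) (an array-like U-shaped spectrum), each route edge
applies a binomial founder bottleneck (40 haploid founders) followed by
30 Wright–Fisher generations at deme size 200, and symmetric neighbour
migration (rate 0.03 along tree edges, ×0.1 between the two route
subtrees — the two-cluster structure) mixes frequencies for one edge's
worth of generations. Genotypes are drawn under inbreeding-adjusted
Hardy–Weinberg with F = 0.1 (open-pollinated landraces are mildly
inbred), with 0.2% missing calls. Defaults: 35 populations, 24
samples each, 5000 SNPs at 300 bp spacing on one chromosome, entry points
at (42.04, −8.64) and (49.57, 3.328). Coordinates advance north-east
(southern route) or east (northern route) per founding step with jitter,
so route depth and great-circle distance from the entry agree.

GERP scores go to a random 10% of sites: Gamma(2, 1) with a 3% point
mass above 5 (5 + Exp(1)); an optional coupling makes high-GERP derived
alleles rarer. Because a pure standing-variation serial-founder model
keeps expected load flat (drift is a frequency martingale), expansion
load is modelled by activating a few previously absent deleterious
variants per route edge at Beta(1, 4) founding frequencies
(`mutation_accumulation`, on by default) — a surfing proxy, not a
mutation-rate model. Sweeps are planted by pinning the focal derived
frequency in the focal population; the haplotype signature is created in
`make_dh_panel`, where carriers of the focal derived allele are
overwritten with one shared template across the core window with
probability equal to the sweep's final frequency (completeness), so a
completeness-1 sweep gives EHH ≡ 1 across the core.

Bioclim variables are intercept + a·lat + b·lon + Normal noise; three
variables carry strong planted gradients (a driest-quarter temperature
falling with latitude, precipitation seasonality rising eastward,
coldest-quarter precipitation falling eastward), the rest are weakly
structured. The coefficient truth is recorded for recovery tests.

What the generator does **not** emulate: background LD and recombination
maps (haplotypes are site-wise independent outside sweep cores, so EHH
decays faster than in real data and iHS standardization leans on the
planted contrast), ascertainment bias of array SNP discovery, genotyping
error, gene flow from outside the two routes, and selection other than
the planted sweeps. Passing recovery tests therefore demonstrates that
the estimators detect the structure they target at realistic effect
sizes, not that real-data candidate counts would be reproduced.

All randomness flows from one root seed through named substreams
(SeedSequence keyed by a CRC of the stage name), so stages are
individually reproducible and reruns are byte-identical.

## Problem sizes and numerics

The test suite and the acceptance script run desk-scale versions of every
experiment: 12–30 populations, 600–3000 sites, 80–400 DH lines, 20 seeds
per recovery experiment, 99–199 permutations per RDA test. These sizes
were chosen so each Monte-Carlo check has clear separation between signal
and its null (recovery rates sit at 19–20/20 with planted effects, and
null rates within binomial noise of nominal) while the whole suite stays
in the tens of seconds.

Degenerate inputs are handled by contract rather than silently: undefined
correlations (constant inputs) return NaN with a warning; F_ST with a
zero denominator, Slatkin at F = 1, and inbreeding with zero expected
heterozygosity are reported missing; empty filter results and empty
cluster pair sets raise with diagnostics. Floating-point tie-breaks that
could make output order- or noise-dependent (forward-selection ties,
|iHS| rank ties, nearest-gene ties) are all resolved by documented
deterministic rules.
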