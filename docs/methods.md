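# Methods

## The trait model

Phenotype: systolic blood pressure (SBP, mmHg). A diallelic trait locus
with allele frequency `p_d` shifts the mean of a normal distribution:
an individual with trait genotype `g` (copies of the trait allele, 0/1/2)
has latent SBP ~ Normal(mu_g, sigma). Individuals whose latent value
exceeds a treatment threshold `tau` are observed only as "affected" (on
antihypertensive medication); their numeric value is censored. The
likelihood contribution of one individual is therefore

* untreated with observed value x: the density phi((x - mu_g)/sigma)/sigma
  (observed values are treated as fully observed, not additionally
  censored below tau — the simplest consistent reading of a single
  threshold);
* treated: the exceedance P(X > tau | g) = 1 - Phi((tau - mu_g)/sigma);
* missing: 1.

This analyzes quantitative values of untreated individuals jointly with
the affected status of treated ones, with one shared threshold.

Before analysis, phenotypes are standardized by the mean and SD of the
observed (untreated) values; the integration grid is expressed in SD
units, making the default prior scale-free. Raw mmHg are accepted and
converted internally.

## The integration grid

The PPL/PPLD statistics integrate over trait-model parameters with a
proper finite prior (a tensor-product grid with uniform weights):

* `p_d` in {0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5};
* homozygote displacement |mu_DD - mu_dd| in {0.5, 1, 1.5, 2, 3} SD,
  in both orientations (either homozygote may be high — the grid is
  symmetric in which allele is protective);
* dominance: heterozygote at the low homozygote (recessive), midpoint
  (additive), or high homozygote (dominant);
* sigma in {0.5, 1} sample SD;
* tau at the {0.7, 0.8, 0.9, 0.95} sample quantiles of standardized
  untreated values (standard-normal quantiles when no data are supplied).

Genotype means are centered so each model has zero population mean under
Hardy–Weinberg, keeping the grid aligned with the standardized data. Any
proper prior is admissible here; the grid is fully configurable and can
be dumped (`ngla dump-grid`) for audit. `TraitGridConfig.coarse()` is a
64-point version of the same construction used for replicate studies and
scans where the full 1,680-point grid would be wasteful; it keeps both
sigma levels, because a grid pinned at sigma = 1 sample SD cannot fit
any displacement once a real locus contributes variance. Refining the
grid changes Bayes factors only marginally (tested).

## Pedigree likelihoods

Three exact engines, cross-validated against brute-force enumeration:

1. **Peeling** (Elston–Stewart, implemented as sum-product variable
   elimination with a min-degree order over per-individual latent states).
   States are ordered haplotype pairs — 4 states for one locus, 16 for
   the trait–marker pair — so phase is exact. All computations are
   batched over a leading model axis: an entire (trait grid x theta grid)
   batch peels in one pass, with the elimination schedule computed once
   per pedigree shape and reused. Every elimination rescales and tracks
   the log scale factor, so no likelihood is ever returned as zero by
   underflow alone; truly impossible data (Mendelian inconsistency)
   yield exact zero with a finite diagnosis, not an exception.
2. **Inheritance-vector HMM** (Lander–Green) for multipoint likelihoods.
   Meiosis bits index grandparental origin; transitions between loci
   flip each bit independently with the Haldane recombination fraction
   of the cM gap (no interference). Founder-phase symmetry is removed
   exactly by fixing one transmitted bit per founder with children,
   shrinking the state space by 2^(#founders-with-children). Emissions
   P(data at locus | vector) are computed per connected component of the
   founder-allele descent graph (exact summation over each component's
   allele assignments), cached per (family, marker) so scans over trait
   positions and overlapping subsamples reuse them. Families above a
   meiosis cap (default 16 meioses) are rejected with an explicit
   pointer to subsampling — exact full-chromosome multipoint on
   57-member pedigrees is out of scope by design; the pipeline's
   two-point fallback and marker subsampling cover that regime. Loops
   (inbreeding, intermarriage) are rejected rather than broken.
3. **Enumeration oracles**: direct sums over every joint assignment of
   per-individual multi-locus ordered haplotype pairs, vectorized in
   chunks and guarded to small problems. They share nothing with the
   fast engines beyond the penetrance definition and exist to verify
   them to 1e-12 relative error (a property-level test sweeps >= 200
   random pedigrees).

## PPL

At a marker, the Bayes factor integrates the likelihood ratio over the
trait grid and a grid on the recombination fraction theta:

    BF = sum_m sum_theta w_m w_theta L(data | theta, m) / L(data | 1/2, m)

with the theta grid {0, 0.01, ..., 0.05, 0.1, ..., 0.5} carrying
trapezoid weights for a uniform prior density on [0, 1/2]. The posterior
probability of linkage is PPL = pi*BF / (pi*BF + 1 - pi). The prior
pi = 0.02 is the value consistent with a published posterior/Bayes-factor
pair (68% from 104.125); it is configurable. Families combine by
multiplying Bayes factors before the single posterior update (sequential
updating). Posterior means of the trait parameters fall out of the same
computation by reweighting the grid with its posterior mass. Scans run
at LD-pruned markers so founder genotypes are approximately independent,
matching the two-point model; allele frequencies come from all genotyped
founders by default.

## PPLD

For fine-mapping, founder haplotypes over (trait locus, variant) follow
frequencies implied by a standardized LD coefficient d' (the raw D
scaled by its bound, so every d' in [-1, 1] is a valid simplex), with
tight linkage theta = 0. The Bayes factor integrates over the trait grid
and d' in {0, ±0.2, ±0.4, ±0.6, ±0.8, ±1} (uniform) against the d' = 0
null — which is "linked but unassociated", not a factorized null: with
tight linkage, marker data still inform shared descent of trait alleles
in multi-generation families even without LD. The prior probability of
LD, 0.0004 (0.04%), is interpreted as the single prior for "linked and
in LD" and absorbed into one update, so posterior 0.04 is a 100-fold
update. Unphased data are handled by summing over founder phase in the
peeling; no external phasing. Variants monomorphic in the analysis
founders report posterior = prior with a flag. The default analysis uses
the single selected family (frequencies from its founders); pooling over
families multiplies per-family likelihood ratios inside the integral.

## Subsample linkage (averaged LOD)

Dense panels violate inter-marker independence. The scan draws random
informative subsamples left-to-right: among markers in a look-ahead
window (8 cM) past the previous pick (minimum spacing 0.5 cM) whose
founder r² with it is at most 0.20, the next SNP is sampled with
probability proportional to founder heterozygosity 2p(1-p)
("informative" is operationalized as heterozygosity; no formula is
standard). r² is the squared Pearson correlation of founder dosages — a
phase-free composite estimator. The adjacent-r² cap is enforced at
construction and re-asserted on output, including across window gaps.

Per subsample, a fixed trait model (no integration) gives a LOD curve
log10 L(position)/L(unlinked) — exact multipoint for families within
the meiosis cap, a two-point approximation against the nearest selected
marker otherwise (logged per family). Curves sum over families, average
over subsamples (default 15), and the support interval is the 1-LOD drop
from the averaged maximum — the standard convention, adopted here as an
explicit assumption. The report includes the mean subsample
heterozygosity; with pool frequencies uniform on (0.2, 0.8) it comes out
near 43% (E[2p(1-p)] = 0.44).

## Variant QC and the filter-based approach

QC removes variants with founder minor-allele frequency below 0.01 or
Hardy–Weinberg exact-test p below 1e-4. The HWE test is the exact
conditional test (sum of heterozygote-count probabilities no larger than
the observed one, given allele counts), verified against brute-force
multinomial conditioning. MAF uses founders only — one shared
implementation for QC and FBA step 1 — to avoid double-counting
transmitted chromosomes; note that published MAFs computed sample-wide
would differ slightly.

FBA: (1) keep founder-MAF < 0.01 variants; (2) select n = 3 untreated
relatives over age 31 with observed SBP in the lowest quartile of the
eligible set, choosing the subset that minimizes the maximum pairwise
kinship coefficient (ties: lower kinship sum, then ID order) — "low SBP"
and "distant" are not standard terms, so both rules are explicit and
configurable; (3) keep variants with at least one minor allele in all
three (allele-state sharing, IBS, not IBD); (4) keep conservation score
(phastCons 44-way) >= 220, reading "threshold 220" as inclusive;
variants without a score are retained with a flag rather than silently
dropped. Counts telescope step to step and each removal is attributed
to exactly one step.

## Haplotype sharing

Rare variants (founder MAF <= cap) are grouped by exact carrier-set
equality; groups with >= 2 sites are haplotype clusters, ordered by site
count then position, annotated with their carrier families and whether
those fall inside a configured target set. With unphased (or imputed)
genotypes this is co-carriage, not proven phase — such haplotypes
deserve experimental confirmation. A Jaccard-tolerance mode exists but
defaults off: strict equality keeps the statistic exact and testable.

## The synthetic study generator

Defaults emulate a large Mexican-American-style family study of SBP:

* 20 loop-free multi-generation pedigrees of 20–60 members (founder
  couple; children marry in founders and reproduce — every nonfounder
  mates a married-in founder, which guarantees loop-freeness);
* 120 markers over 100 cM: LD blocks of 4 SNPs built from two pool
  haplotypes (pool frequency uniform on 0.2–0.8, per-site flip 0.006,
  giving within-block founder r² near 0.9 and mean heterozygosity near
  43%) plus 10% rare variants (frequency 0.002–0.01);
* a protective recessive trait locus at 54 cM: means (125, 125, 95) mmHg
  — homozygote displacement 2 SD with sigma = 15 — threshold 140 mmHg
  (the conventional hypertension treatment cut), trait-allele frequency
  0.2, observed in the panel as a sequence variant;
* treatment is deterministic above the threshold (mirroring the analysis
  model; a stochastic option exists for robustness checks — the
  pre-treatment mechanism of real treated individuals is unobservable,
  so the deterministic default is an explicit assumption);
* 38% of remaining phenotypes are set missing (the proportion
  unphenotyped in the motivating study);
* a 4-site rare haplotype written onto one founder chromosome in each of
  families "4" and "15", at physically clustered sites with negligible
  genetic distance from the trait locus (below map resolution, hence
  never recombining — which is what makes exact carrier-set recovery a
  sharp test);
* conservation scores: 15% of sites uniform on 220–400, the rest on
  0–200, with one haplotype site forced into the conserved range.

Gene dropping transmits founder haplotypes with Haldane recombination;
with `trait_locus_cm=None` the trait locus segregates fully unlinked
(the null configuration). Everything is reproducible from (config, seed).

What the generator does **not** emulate: realistic allele-frequency
spectra, genotyping or imputation error, covariate structure (age/sex
effects on SBP), repeated measures, and population stratification.
Passing tests therefore demonstrate internal correctness and calibration
of the statistics under the stated model, not robustness to those
real-data complications.

## Validation studies and problem sizes

* **Null calibration**: 200 replicates, two 20-member families each,
  60 markers, trait locus unlinked; PPL scanned at 8 LD-pruned markers,
  PPLD over the 44–64 cM region's variants, with the coarse grid, a
  7-point theta grid and a 5-point d' grid. Medians of per-replicate
  maxima stay within twice the respective priors.
* **Localization/recovery**: 50 replicates, eight families of 20–30
  members (the causal variant needs enough recessive homozygotes with
  observed phenotypes to be identifiable at all under 38% missingness —
  the size was fixed at design time on that power reasoning), 15
  subsamples, averaged-LOD support interval and PPLD rank of the causal
  variant among the region's records.

These sizes are the package's own validation design; the full-scale
defaults remain available and are what the examples use.

## Numerical choices

* Haldane map function throughout (consistency between generator and
  analysis); theta clipped to [0, 0.5].
* Trapezoid weights on the theta grid (uniform prior density); a
  degenerate one-point grid gets weight 1.
* Log-scale tracking after every elimination/forward step; -inf denotes
  exactly impossible data.
* Batched peeling chunks the model axis at 128 rows to bound memory.
* Ties in family selection go to the lowest family ID (numeric-aware);
  ties in carrier selection to lexicographic ID order; cluster ordering
  is (site count desc, leftmost position, first variant ID).
* Zero-distance markers share transmission exactly (no epsilon jitter).

## Known limitations

* Multipoint exactness is capped by meiosis count; very large families
  always go through the two-point fallback in the averaged-LOD scan.
* The PPL scan is two-point per marker (the published analyses used
  multipoint MCMC machinery for very large families; reimplementing that
  sampler is out of scope, and the subsample scan provides the
  robustness cross-check instead).
* X-linked models, imprinting, sex-specific maps, loop-breaking,
  covariate adjustment and population-based (case/control) LD components
  are not implemented.
* PPLD assumes the variant is typed in the analysis family; no
  imputation is performed.
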