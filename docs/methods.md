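# Methods

This note documents the models, defaults and design choices behind
`consangmap`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Pedigree coefficients

Kinship φ(i, j) — the probability that one allele sampled from each of two
individuals is identical by descent — is computed by the classical
recursion on parents, recursing onto the individual farther (by longest
parent chain) from the founders; φ(i, i) = (1 + F(i))/2 and the inbreeding
coefficient F(i) is the kinship of i's parents. Founders are assumed
mutually unrelated and non-inbred: deeper relatedness is modelled by
*adding ancestors* (as in the hypothetical-pedigree construction used for
the Druze family), never by assigning founder kinship. A parent recorded
as absent behaves as a unique unrelated founder. The recursion is exact;
tests verify it against exhaustive enumeration of inheritance vectors on
small pedigrees, including looped ones.

Affection is three-state (CD / UC / unaffected) so case sets can be
restricted by disease subtype, mirroring CD-only, UC-only and any-IBD
mapping runs. The FAM dialect encodes this in the sixth column
(1 unaffected, 2 CD, 3 UC, 0/−9 unknown).

## Array QC

Filters run in a fixed order — samples first (missingness > 5%), then
markers (missingness > 5%, Hardy–Weinberg exact P < 5×10⁻⁸, duplicate ids
keeping the first) — because a failing sample's missing calls must not
condemn markers. The HWE test is the exact conditional test on
heterozygote counts given allele counts, two-sided by probability-mass
ordering; it is checked against a rational-arithmetic enumeration oracle
and is conservative (attained type-I error below nominal), as exact
discrete tests are. HWE is computed on all retained samples by default:
the cohorts in view are a handful of small families genotyped in one
batch; a founders-only restriction is available via the `founders_only`
argument for users worried about within-family genotype correlation.

Sex is inferred from the homozygosity rate of common (MAF > 0.05)
non-pseudoautosomal X markers: ≥ 0.9 calls male, ≤ 0.8 female, between —
ambiguous. The deliberate gap avoids over-confident calls on noisy arrays.

Relatedness verification uses the robust pairwise estimator
φ̂ = (N_het,het − 2·N_opposite-hom)/(N_het(i) + N_het(j)), which conditions
on the pair's own heterozygosity and is therefore insensitive to
population structure. A pair is flagged discordant when
|observed − expected| exceeds 0.0442, the smallest boundary of the
powers-of-two degree ladder — i.e. a full degree-class shift. An absolute
band is used instead of comparing hard degree assignments because the
estimator is calibrated for outbred pairs and reads systematically low
when both members are inbred; in deeply consanguineous pedigrees a few
true multi-loop relationships (expected φ of 0.125–0.19 through several
paths) can still flag and should be reviewed manually rather than dropped.
A genuine sample swap (claimed siblings measuring as unrelated) deviates
by ~0.2 and is flagged unambiguously.

## Runs of homozygosity

The detector scans common markers (input MAF > 0.05; markers with no
reference frequency are used as given) per chromosome for maximal runs of
homozygous calls. Defaults: at least 50 homozygous markers spanning at
least 1 Mb — long enough to represent recent consanguinity and to exclude
chance identity-by-state — and `het_tolerance=0`. The zero default is a
deliberate stance: tolerating ("erasing") embedded heterozygous calls is
exactly the failure mode that manufactures false ROH near centromeres in
inbred families (a 49-marker stretch containing two genuine heterozygous
calls is not an autozygous run), so any error tolerance must be requested
explicitly. Missing calls are transparent — they neither break a run nor
count toward the 50-marker minimum — and an optional `max_missing_run`
converts long no-call stretches into hard breaks to guard low-density
regions.

Case-shared mapping (`shared_identical_regions`, the "genetic homogeneity"
mode) counts a marker only when *every* case is homozygous for the same
allele; two cases homozygous for opposite alleles is a hard break that no
tolerance absorbs. Region boundaries are the first/last homozygous
markers; length is `end_bp − start_bp` (this arithmetic reproduces the
published region lengths from their printed coordinates) and all reported
coordinates are 1-based inclusive GRCh37; BED input/output converts from/to
0-based half-open.

Control-overlap annotation runs the same detector on each unaffected
member and lists a control when one of its ROH covers at least 50% of the
case region (the fraction is a parameter; published tables do not define
overlap). Exclusion mode — dropping any region with control overlap — is
optional, preserving the possibility of incomplete penetrance.

The scanner is validated against a brute-force all-substrings oracle on
panels up to 500 markers across random parameters, and planted regions are
recovered with exact marker boundaries.

## Gene dropping

Meiosis follows the Haldane (no-interference) model: per chromosome the
crossover count is Poisson with mean equal to the map length in Morgans,
breakpoints uniform on the cM scale, starting haplotype equiprobable. No
interference is assumed because the target quantities (window-level
autozygosity probabilities) are insensitive to crossover clustering at the
1 cM scale, and the model is analytically checkable (P(intact gamete on
100 cM) = e⁻¹, verified). The default map is uniform 1 cM/Mb over the 22
GRCh37 autosomes (so chromosome 16 spans ~90.4 cM); any per-chromosome map
can be substituted. Sex chromosomes are excluded.

"Identically homozygous" for a pair over a window is operationalised
strictly: all four haplotypes carry one and the same founder-haplotype
label across the entire window. A relaxed mode (each individual autozygous,
possibly to different founders) is provided for sensitivity analysis and
is provably no less probable. Only the window's chromosome is simulated,
since under no interference other chromosomes are independent of the
window statistic; a single seeded generator drives all replicates, so a
fixed seed is bit-reproducible and the estimate comes with the binomial
Monte-Carlo standard error √(p̂(1−p̂)/n).

The Druze pedigree used for the headline simulation is a *reconstruction*:
the published pedigree figure is anonymised and the hypothetical pedigree
of the original simulation is not printed. The bundled topology encodes
the stated relationships — III-2 (CD) as offspring of a first-cousin
mating, IV-1 (UC) the proband's mother, III-3 (UC) an uncle — and places
the proband's parents as first cousins within III-2's sibship, consistent
with strong village endogamy. On this reconstruction 10,000 replicates
give an identically-homozygous probability of ≈ 0.003–0.004 for a 1 cM
chromosome-16 window, the same order as the originally reported 0.0021;
agreement beyond order of magnitude cannot be expected from a
reconstructed topology. Point-locus self-probabilities from the same
machinery agree exactly (within Monte-Carlo error) with the recursive
inbreeding coefficients, which is the cross-module parameter-recovery
check.

## Exome variant prioritisation

The cascade is order-fixed and idempotent:

1. site filter — SNPs with recalibration truth-tranche sensitivity ≤ 99.5,
   indels ≤ 99.0 (PASS-flagged records kept); recalibration is consumed as
   an input annotation (`TRANCHE` INFO or PASS), never computed;
2. genotype filter — calls become no-calls when GQ < 30, when a
   heterozygous call's allele depths deviate from 50:50 (χ², 1 df,
   P < 0.001), or when a het/hom-alt call has alternate depth < 3; absent
   metrics are uninformative rather than failing;
3. no-call filter — variants with a no-call rate ≥ 0.25 are dropped;
4. classification — frequency classes per population (common ≥ 5%;
   uncommon 1–5%; rare 0.1–1%; very rare ≤ 0.1%; an absent frequency means
   absent from that data set, i.e. 0) combined under the dual-population
   rule: the joint class is the *least rare* across required populations,
   so a Middle-East-specific reference can only demote, never rescue, a
   variant. Boundary points join the rarer class except at 5%, which is
   common. "Damaging" is deliberately permissive: any protein-truncating
   or splice-site consequence, or a missense called deleterious by *any*
   of SIFT (low-confidence counts as its base class), PolyPhen (possibly
   damaging counts) or CADD phred strictly above 20;
5. selection — homozygous-alternate, damaging, uncommon-or-rarer variants
   in the proband; then segregation ("all" affected siblings or a minimum
   count), homozygous-control annotation with optional any/majority
   control exclusion, and the deceased-parent rule: a parent cannot be
   homozygous-alternate if any genotyped descendant is homozygous
   reference.

Manual curation steps (protein function, expression, disease-browser
lookups) are represented as user-supplied annotation columns, not
automated.

## Enrichment

ROH gene-set enrichment conditions on the 2×2 margins and reports the
one-sided upper hypergeometric tail (the enrichment direction) with the
raw cross-product odds ratio; zero cells report OR 0 or ∞ with a flag, no
continuity correction. The default gene universe is 19,528 protein-coding
genes (overridable). With the published counts — 3 of 20 high-confidence
disease genes among 703 ROH genes — this gives OR 4.74 and P = 0.034. No
multiple-testing correction is applied, matching the exploratory design.
Homozygous-burden comparisons are restricted to full siblings, who expect
an equal autozygous genome fraction; comparing across pedigree positions
would confound inbreeding level with genotype.

## Synthetic data

The generator draws founder haplotype alleles independently per marker
(Bernoulli at a marker MAF ~ Uniform(0.05, 0.5), the ascertainment range
of common array content) and transmits them by gene dropping, so founders
conform to Hardy–Weinberg and relatives share exactly as the pedigree
dictates. Genotyping error (default 0.2%) is replacement with a random
population genotype; missingness defaults to 0.5%. Markers carry no
linkage disequilibrium: the analyses are run-based and frequency-based and
never exploit LD, so LD realism would add nothing to what the tests can
show. Planted shared-ROH regions force carriers homozygous-identical and
are insulated by one forced-heterozygous flanking marker per side so that
recovery with exact boundaries is well-defined; error and missingness
never touch planted markers. The default panel is 20,000 markers over four
synthetic chromosomes (desk-fast); `paper_scale_config()` provides a
250,000-marker panel over the 22 GRCh37 autosomes. The acceptance
simulations use 10,000 gene-dropping replicates (the original analysis
size); distribution-level test assertions use 1,000–10,000 replicates
with three-standard-error bands.

Variant tables plant candidates that satisfy every criterion and decoys
that each violate exactly one. One decoy needs a composite mechanism: the
allele-balance rule only applies to heterozygous calls, so a
case-genotype violation would simultaneously break the homozygosity
requirement; the allele-balance decoy therefore models a systematic
imbalance artefact in a quarter of the cohort, whose calls only the
balance rule no-calls, pushing the variant over the no-call-rate
threshold.

**What passing tests show — and don't.** Recovery of planted structure on
LD-free, error-controlled synthetic data demonstrates the correctness of
the algorithms and the internal consistency of the pipeline, not its
sensitivity on real arrays, where LD, batch effects, clustered genotype
errors and reference-panel mismatch all matter. The reconstructed
pedigrees are plausible topologies consistent with the described
relationships, not ground truth; quantities that depend on the full loop
structure (the window-sharing probability above all) inherit that
uncertainty.

## Numerical and degenerate-input conventions

Exact-test P-values use log-space probability mass with a 1+10⁻¹² slack on
the observed-mass comparison to absorb rounding; monomorphic markers
return P = 1. Genotype matrices are validated at construction (dosage
codes, strictly increasing positions within contiguous chromosome
blocks). Empty results are explicit errors where silence would mislead:
all samples removed, no qualifying X markers, zero array–exome overlap,
zero-length map, plant regions containing no markers. Gametes on
zero-length chromosomes transmit without recombination. Estimates from
zero successes report SE 0 rather than NaN.
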