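# Methods

## Scope and data model

`clonotrace` analyzes longitudinal clonal-hematopoiesis (CH) dynamics around
CAR T-cell infusion. All timestamps are integer days relative to infusion
(day 0); calendar dates must be converted on ingest. Observations are
(variant, day, compartment, alt reads, total depth) tuples over three
compartments — cfDNA, PBL, BM — and single-cell inputs are cells × amplicon
genotype matrices (0 = ref, 1 = het, 2 = hom, NA = missing) with a
pre-annotated lineage label and a per-cell CAR-vector flag. Lineage gating
and raw genotype calling are upstream of this package.

## Growth law

Clone cell fractions follow a logistic-capped exponential,
f(t) = f₀e^{rt}/(1 − f₀ + f₀e^{rt}) with r = ln2/T_d. Reported doubling
times in this setting do not come with a stated growth model; we use the
logistic form because a pure exponential violates f ≤ 1, while for small
clones it reduces to 2^{t/T_d} scaling (relative error < 10⁻³ at f ≈ 10⁻⁴).
The closed form is the exact solution of df/dt = r·f·(1 − f), verified
against numerical integration in the tests. Heterozygous clones are
observed at VAF = f/2; LOH clones at VAF = f. `T_d = "static"` or ±∞ means
no growth; negative T_d models contraction (|T_d| is a half-life). When
several independently growing clones of one patient would sum past
fraction 1 at some timepoint they are rescaled proportionally
(a shared-fraction cap); richer clonal interference is out of scope.

## Sequencing noise model

Total depth is Poisson around the configured mean (default 2800×,
matching de-duplicated ultra-deep capture panels). Alt reads are binomial
with success probability vaf + (1 − vaf)·error_rate, where error_rate
(default 10⁻⁴ per base) stands in for post-suppression background
substitutions; read-level error-suppression chemistry is not modeled. A
zero-depth draw is emitted as missing, never as VAF 0. cfDNA and BM VAFs
are the PBL VAF times a lognormal(0, σ) factor (default σ = 0.15), a
deliberately simple stand-in that reproduces the high inter-compartment
correlation seen in practice (Pearson r > 0.9 in simulation at n = 100)
without modeling fragmentomics; the true inter-compartment noise structure
is only known to us as a correlation, so this is a design choice, not an
inference.

## Detectability

A variant is detectable when alt ≥ 3 and the one-sided binomial tail
P(X ≥ alt | depth, error_rate) < 10⁻³. At 2800× this admits VAFs of roughly
0.2% and above — well below the conventional 2% clinical threshold — which
is the operating regime the analysis depends on. Both constants are
configurable.

## Selection test

For each variant trajectory with at least one observation at day ≤ 0 and
one at day ≥ 25, the earliest pre-infusion and latest post-infusion VAFs
are paired and log₂((vaf_post + ε)/(vaf_pre + ε)) computed with
ε = 0.001 (so undetected pre-infusion values give finite, large fold
changes). Genes with ≥ 3 paired variants are tested by a two-sided
one-sample Wilcoxon signed-rank against 0, with Benjamini–Hochberg
correction across the tested genes only. The Wilcoxon choice is ours — the
statistic used in the antecedent analyses is not restated here — and its
operating characteristics are established by simulation: on 200 fully
static cohorts of 40 patients the any-gene discovery rate at FDR 0.05 is
≤ 7% (measured 2–7% depending on seed), and a single gene doubling every
200 days against static competitors is flagged in ≥ 90% of cohorts
(measured 100%). All-zero fold changes give p = 1 by convention.

## Doubling-time estimation

Growth is estimated by OLS of log₂(VAF) on day over detectable
observations only; imputing undetectable points at the ε floor would
inflate slopes, so they are excluded instead. The slope is in doublings per
day (T_d = 1/slope; r = slope·ln 2); |slope| < 10⁻¹² reports T_d = ∞ and a
negative slope reports a negative T_d (half-life), with sign(T_d) =
sign(r). The fit is on VAF rather than clone fraction — identical in log
space for het clones below the logistic regime, biased long as VAF
approaches 0.5. Per-gene summaries take the median over variant-level
estimates restricted to expanding variants (slope > 0), with the all-clone
median reported alongside; genes not summarized individually pool into
"other". Recovery: median estimate within 20% of a 250-day truth across
200 simulated trajectories (2809×, 6 timepoints over 500 days); measured
recovery is within ~5%.

## Clonal competition

Within one patient and compartment, each trajectory's VAF change across the
shared observation window is called significant when the later exact 95%
interval separates from the earlier one. Competition is flagged when one
variant rises and another falls, both significantly; the dominant variant
is the largest significant riser.

## Single-cell clone architecture

Each distinct set of mutant amplicon calls among complete (NA-free) cells
defines a clone; groups below `min_cells` (default 2) fold into unassigned.
Cells with missing calls are assigned only when their observed calls match
exactly one called pattern — conservative under allelic dropout, so
ambiguous cells never seed or split clones. On NA-free matrices the caller
is provably the exact grouping (tested against a brute-force oracle).
Hierarchy edges are the transitive reduction of strict-subset relations
between clone variant sets, labeled age→DDR, DDR→age, sequential-TP53, or
other from the gene classes of ancestral vs gained mutations.

Lineage penetrance maps the eight lineage labels onto myeloid
{monocyte, other_myeloid, progenitor, erythroid} and lymphoid
{T_CD4, T_CD8, NK, B}; placing progenitors and erythroid cells on the
myeloid side is a judgment call and the map is configurable.

## CAR-vector enrichment

Among T cells, the expected number of CAR⁺ cells in a clone under
independence is N_T · p(CAR⁺|T) · p(clone|T); the enrichment ratio is
observed/expected with a two-sided Fisher exact test on the 2×2. Because
single CAR⁺ cells in a clone may represent sporadic integration, an
exclusive mode (`include_singletons=False`) zeroes singleton overlaps. In
the generator, the designated clone's CAR rate is E·p₀ and the out-of-clone
rate is compensated to p₀(1 − Eq)/(1 − q) (q = clone share of T cells) so
the marginal CAR⁺ T-cell rate stays p₀ and the observed/expected ratio
recovers E without the 1/(1 + (E−1)q) shrinkage a naive multiplier would
produce; configurations with E·q > 1 or E·p₀ > 1 are rejected as
infeasible. Recovery: median ratio within 25% of E ∈ {1.4, 4, 18} over 50
matrices of 60,000 cells (~20,000 T cells).

The CD4:CD8 skew odds ratio is the pooled 2×2
(CD4/CD8 × stratum⁺/stratum⁻); a Mantel–Haenszel per-patient stratified OR
is offered because cell-level observations within patients are not
independent. A cell-level random-effects model would be the fuller
treatment and is deliberately out of scope.

## Allelic dropout

ADO converts a het call to non-het with total probability `ado_rate`
(default 0.1); lost calls become ref or missing with equal probability, a
split chosen so the observed-het expectation is exactly
true_het·(1 − ado_rate). Doublets are not simulated.

## Cohort classification

Precedence: tMN (a morphologic/molecular myeloid-neoplasm diagnosis)
overrides everything; a cytopenic patient with a detectable CH variant at
VAF ≥ 2% (configurable) is CCUS; cytopenic otherwise is ICUS — so a patient
whose only clone sits at 1% VAF is ICUS even though the clone is real;
non-cytopenic carriers are CH_only. Labels are mutually exclusive by
construction. Gene–tMN association uses the 2×2 odds ratio with
Haldane–Anscombe 0.5 correction for zero cells, Woolf logit 95% CI, and
Fisher exact p; for a single binary predictor this is numerically the
logistic-regression OR, which it replaces because per-patient covariates
are not modeled here.

Printed percentages use round-half-away-from-zero to one decimal
(28/31 → 90.3%). Note 3/18 prints 16.7% under this convention (16.6% is a
truncation) and 22/29 prints 75.9%.

## Synthetic cohorts: what they do and do not show

Generator defaults mirror the study conditions: 40 patients; five CH genes
(*PPM1D* 159 d, *DNMT3A* 253 d, *TP53* 263 d, *TET2*/*ASXL1* 374 d
doubling times; one clone per gene per patient at 50% prevalence; initial
clone fractions 0.4–4%, i.e. VAF 0.2–2%); sampling at days −30, 0, 28, 90,
180, 365 at 2800× in cfDNA and PBL; single-cell matrices of 5,000 cells
with ADO 0.1 and 0.5% CAR⁺ T cells. Randomness is a single cohort seed with
per-patient child streams keyed by (seed, patient index), so any patient
subset reproduces byte-identically.

The generator emulates the statistical structure the estimators assume —
not real data. It does not model UMI/duplex chemistry, fragmentomics,
contaminating tumor DNA, doublets, germline variation, clonal interference
beyond a shared-fraction cap, or manual gating error in lineage labels.
Passing recovery tests therefore shows the estimators are correct and
calibrated under the stated model, not that the model captures every
feature of patient data.

## Numerical choices

Clopper–Pearson intervals from the beta-quantile form; logistic fractions
clamped to the open interval (0, 1) at float resolution; e^{rt} capped at
e⁷⁰⁰ to avoid overflow; duplicate observations at one (variant, day,
compartment) keep the higher-depth record; ties in VAF change count as
"not increased"; BH q-values verified against the step-up definition on an
exhaustive grid of p-vectors up to length 6. Simulation sizes in the test
and acceptance suites (200 cohorts for type-I, 100 for power, 50 seeds for
enrichment, 60,000-cell matrices) were chosen so each Monte-Carlo band is
several standard errors wide at single-CPU desk scale.

## Known limitations

Selection inference is gene-level, not clone-level; doubling times from
two-point trajectories are noisy and the expanding-only gene medians are
conditionally biased; LOH calling is threshold-based on VAF (no copy-number
input); CAR integration is modeled as a per-cell flag, not an insertion
site; and the CCUS threshold convention intentionally demotes real but
sub-threshold clones to ICUS.
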