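# Methods

This note documents the models and procedures implemented in `tigerpop`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used
throughout.

## Consensus genotyping and individual identification

Fecal-DNA microsatellite genotypes suffer three characteristic errors:
allelic dropout (one allele of a heterozygote fails to amplify,
producing a false homozygote), false alleles (a stepwise PCR artifact
scored as a novel size), and outright amplification failure. The
replication rule — a homozygote accepted after ≥ 3 identical replicates
(`min_hom`), a heterozygote after ≥ 2 (`min_het`) — exploits the fact
that dropout is the dominant error: observing the same heterozygote
twice is already strong evidence, while a homozygote must be seen three
times before dropout can be ruled out. When two conflicting genotypes
both reach their threshold, the locus is left *unresolved* rather than
settled by majority vote: favouring missing data over wrong data is the
conservative choice for downstream identity and assignment analyses.

A multilocus genotype is usable when ≥ 14 alleles (7 of 8 loci) are
confirmed. Samples whose usable genotypes differ at ≤ 1 allele position
(`max_mismatch`, counted over loci typed in both; loci missing in either
sample contribute nothing) are merged into one individual by
single-linkage. Allele-position counting was chosen over locus counting
because a one-allele difference is exactly what one uncorrected dropout
produces. Single-linkage can chain A~B~C with A≁C; such clusters are
still merged but flagged (`merge_conflict`), since the pairwise rule
alone cannot say which pair is the same animal.

Sex assignment uses Y-chromosome presence logic: DBY7 amplification in
any replicate (with a clean negative control) is male; ZFX amplification
with ≥ 3 DBY7-negative replicates and a successful positive control is
female (the positive control distinguishes true Y absence from PCR
failure). The threshold of three negative replicates matches the
replicate counts of the genotyping protocol and is configurable.

## Diversity statistics

* H_E uses Nei's small-sample correction `(2n/(2n−1))(1 − Σp²)`; the
  "unbiased" qualifier in the surrounding literature refers to this
  form.
* PIC = `1 − Σp² − Σ_{i<j} 2 p_i² p_j²`.
* P_ID (probability two unrelated HWE individuals share a genotype)
  `= 2(Σp²)² − Σp⁴`; P_ID(sibs) `= 0.25 + 0.5a₂ + 0.5a₂² − 0.25a₄`
  (a_k = Σp^k). The small-sample unbiased P_ID estimator is a
  polynomial in the number of sampled allele copies m = 2n; with m in
  that role its expectation over multinomial sampling equals the
  true-frequency P_ID exactly (verified by exhaustive enumeration in the
  test suite).
* Cumulative multilocus P_ID curves multiply per-locus values with loci
  ordered most-informative-first (ascending per-locus unbiased P_ID),
  the convention used for marker-panel power curves; the order is
  configurable.
* The HWE exact test is Monte-Carlo: the observed genotype array's
  conditional probability given its allele counts (Levene's
  distribution) is ranked among arrays obtained by shuffling the
  observed allele pool into random pairs. This scales to many alleles
  where full enumeration would not.
* LD between loci uses the log-likelihood-ratio G statistic on the
  two-locus genotype table with a permutation null.
* The null-allele screen replaces a full scoring-artifact diagnostic
  with two outputs: Brookfield's estimator r = (H_E − H_O)/(1 + H_E)
  and a homozygote-excess resampling p-value; a locus is flagged only
  when r > 0 *and* the excess is significant. Stutter and large-allele
  dropout are not separately modelled — a documented simplification.
* All Monte-Carlo p-values use (1 + hits)/(N + 1): never zero, and a
  valid test.
* Multiple testing uses Holm's sequential Bonferroni step-down
  (delegated to `statsmodels.stats.multitest`).

## Migrant detection

**Assignment likelihood.** An individual's log₁₀ likelihood under a
candidate population multiplies Hardy–Weinberg genotype probabilities
per locus from that population's sample allele proportions. Alleles
absent from the candidate population contribute `zero_freq = 0.01`, the
long-standing default of frequency-based assignment programs. When an
individual is scored against the population it was sampled in, it is
first removed from that sample (leave-one-out); critically, the removal
happens *once, to the frequency table*, so observed and simulated
likelihoods are computed on the same reference sample and the
Monte-Carlo p-values remain calibrated.

**Exclusion test.** 10,000 genotypes are simulated per candidate
population by drawing two alleles per locus with replacement from the
population's observed pool (restricted to the focal individual's typed
loci); p = (1 + #{simulated logL ≤ observed})/(N + 1), and a population
is excluded as origin at p < 0.05. With very small reference samples
this family of tests is anti-conservative for individuals carrying
alleles unseen in the reference pool (they are penalized at `zero_freq`
while simulants never are) — an inherent property of the method worth
remembering when reference samples shrink below ~10 individuals.

**First-generation migrants.** Λ = L_home/L_max over all candidate
populations; the null distribution of Λ comes from simulated residents
of the home population, and the migrant probability is 1 − residency p,
with a 0.95 flag threshold (equivalently α = 0.05).

**Admixture clustering.** The Gibbs sampler implements the admixture
model with *independent* cluster allele frequencies: allele-copy origins
z, cluster frequencies (Dirichlet(λ + counts), λ = 1), per-individual
membership Q (Dirichlet(α + copy counts)), and a Metropolis update of α
(uniform prior on (0, 10), proposal SD 0.025 — the standard width; a
larger proposal lets α run to large values before Q becomes informative,
which pins Q near uniform and can trap chains in the symmetric
no-structure mode). The correlated-frequency variant was deliberately
not implemented: at the strong-signal scale of desk analyses the
independent-frequency model selects the same K and separates the same
clusters, and it is substantially simpler. Model log-probability is
estimated as mean(logL) − var(logL)/2 over recorded sweeps.

**Evanno ΔK.** ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| /
SD_runs[L(K)], i.e. the second difference of the *run means*. Taking
per-run absolute second differences instead would upward-bias the
numerator at plateau K values (E|noise| > 0) and destabilize selection
at desk-scale chain lengths. ΔK is undefined at the K-range endpoints
and when the run-to-run SD is zero; the selected K maximizes ΔK over the
defined interior.

**Migrant-prior ancestry model.** With declared origins, each individual
is a priori resident with probability 1 − ν (default ν = 0.05) and
otherwise a migrant from another population g generations back
(g = 0..G, default G = 2, prior mass split uniformly). A g-generation
ancestor contributes one allele copy per locus from the source with
probability 2^(1−g) (both copies for g = 0). Hypotheses and population
frequencies are Gibbs-sampled jointly; an individual is flagged when
P(resident) < 0.5.

**Final classification.** F₀-flagged with one candidate locality ≠
sampling locality → MS; one candidate = sampling → MU; several (or zero)
candidates → a dual label, ordered MS/MU when the sampling locality
itself carries the top assignment probability and MU/MS otherwise (a
tie-ordering convention). Non-flagged individuals are "admixed" only
when their Q falls in the 0.4–0.6 window *and* the assignment is
undetermined in the strong sense of producing no candidate locality at
all; otherwise resident. Candidate localities are the non-excluded
populations within 0.1 of the top assignment probability (configurable),
which is what produces joint "China/Russia" entries.

## Genetic and geographic distance

Individual-level Nei's D_A treats each individual as a population of one
(pseudo-frequencies 1, or 0.5/0.5 at heterozygous loci). HL weights each
homozygous locus by its reference expected heterozygosity E_ℓ = 1 − Σp²,
`HL = Σ_hom E / (Σ_hom E + Σ_het E)`; IR = (2H − Σf)/(2N − Σf) over the
2N allele copies. Reference frequencies for HL/IR come from the pooled
sample including the focal individual (the indices' own convention).

Geographic distances are haversine great-circle kilometres (Earth radius
6371.0088 km); distance to the boundary polyline is the minimum over
segments in a per-segment local equirectangular projection. The
"boundary difference" predictor for a pair is |d_a − d_b| of the two
individuals' boundary distances.

Genetic distance is modelled against a geographic predictor with (i) a
Gamma GLM (log link) and (ii) a lognormal model (OLS on log D_A; zero
distances offset by 1e-6); AICs are made comparable by adding the log
Jacobian to the lognormal model. Because pairwise distances are not
independent observations, a Mantel permutation test (permuting
individual labels) is reported alongside the parametric fits rather than
instead of them.

## Spatial dispersal

Occurrences are projected with a local equirectangular projection
(reference latitude = bounding-box midpoint, origin = southwest corner)
and binned into 14-km square cells. A period's geometric center is the
unweighted mean of *occupied-cell centers* — presence/absence, so record
clustering within a cell cannot drag the center. Periods can be
cumulative (2003–05, 2003–08, …; the default, matching
occurrence-accumulation maps) or disjoint 3-year blocks (the last block
may be shorter, e.g. 2015–16). Dispersal speed is the mean ± sample SD
of consecutive-center great-circle steps; net displacement is
first-to-last. Note the two period modes answer different questions:
cumulative centers smooth the trajectory (each step dilutes new records
with all earlier ones), so their step speed *underestimates* the
per-period drift, while disjoint periods recover it — the parameter
recovery tests use disjoint mode. The longitude trend is OLS of center
longitude on period end-year; westward movement is a negative slope in
east-longitude degrees, and the signed slope is reported as-is.

## Synthetic-data generator

The generator emulates the study design the analysis assumes:

* Two demes ("China" west of a north–south boundary polyline, "Russia"
  east of it) with Balding–Nichols differentiation: ancestral
  frequencies ~ symmetric Dirichlet, deme frequencies ~
  Dirichlet(p(1−F)/F). Defaults: 8 loci, 5 alleles (allele ladder spaced
  4 size units so ±2 false alleles never collide with true alleles),
  F = 0.15, 12 individuals per deme, migrant fraction 0.13.
* Replicate amplification errors: locus missing with rate 0.05; at
  heterozygous loci each allele drops with rate 0.2 — *any* dropout
  event yields an apparent homozygote (when both copies drop, severe
  amplification imbalance leaves one of the two true alleles at random;
  total failure is governed by the missing rate), so the per-replicate
  false-homozygote probability is 1 − (1−d)² = 0.36 at d = 0.2; each
  reported allele copy is replaced by a ±2 stepwise artifact with rate
  0.05. Four initial replicates per sample, plus three more when any
  locus lacks a confirmed consensus — the adaptive protocol of
  noninvasive genotyping practice. The dropout and false-allele rates
  are plausible fecal-DNA values, not estimates from any particular
  dataset.
* Sex markers: ZFX amplifies in either sex (rate 0.98/replicate), DBY7
  only in males (0.9), clean controls.
* Occurrences: 77 records per year over 2003–2016 whose mean longitude
  translates by drift/3 km per year (default −12.83 km per 3-year
  interval, negative = westward) with 5-km isotropic scatter.
* The fixture written to disk is plain text: `replicates.csv`,
  `samples.csv` (per-sample collection metadata), `sex_markers.csv`,
  `occurrences.csv`, `boundary.geojson`, `genotypes.gen` (Genepop), and
  `truth.json` (generator ground truth, for tests only).

What the generator does *not* emulate: stutter peak shapes and
electropherogram-level artifacts, allele-frequency correlation between
demes beyond the Balding–Nichols draw, spatial genetic autocorrelation
within demes (coordinates are drawn independently of genotype), uneven
sampling effort, and landscape-driven movement. Tests passing on this
generator therefore validate the statistical machinery and its
calibration, not field-data idiosyncrasies such as scoring error or
spatial sampling bias.

## Reproducibility and numerical conventions

* Every stage seed derives from one master seed via
  `numpy.random.SeedSequence`; fixed config + seed ⇒ byte-identical
  output bundles (floats are written with fixed formats, JSON with
  sorted keys, no timestamps in outputs).
* Monte-Carlo sizes are configurable everywhere; the defaults are the
  full-scale analysis settings (exclusion/F₀ 10,000 simulants; admixture
  burn-in 100,000 / 1,000,000 sweeps, 10 runs per K, K = 1–10). The test
  suite and the packaged examples run scaled-down chains (burn-in
  2,000 / 10,000 sweeps for the K-selection study; a few hundred sweeps
  for fixture smoke runs), sizes chosen so the full suite completes in
  minutes while keeping every selection and calibration property
  stable.
* Degenerate inputs are flagged rather than silently computed:
  monomorphic loci are untestable for HWE (p = 1), H_E needs n ≥ 2,
  unbiased P_ID needs n ≥ 4, ΔK is undefined at endpoints and at zero
  run SD, an all-missing individual has undefined HL/IR.
* Ties in Monte-Carlo ranking count as hits (≤ / ≥ with a 1e-12
  tolerance), keeping p-values conservative.

## Known limitations

* The correlated-allele-frequency admixture variant is not implemented;
  for weakly differentiated populations it can detect structure at
  lower F than the independent model.
* Exclusion/F₀ tests lose calibration for reference samples below ~10
  individuals (novel-allele penalty; see above).
* The boundary-distance regression treats |d_a − d_b| as the pair
  predictor; other readings of "distance to the boundary" for pairs are
  possible.
* Individual-level D_A on few loci is coarse (many tied values), and the
  lognormal model needs the 1e-6 offset for identical genotypes.
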