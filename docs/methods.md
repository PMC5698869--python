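# Methods

`mmrkit` implements an endophenotype analysis chain for the late auditory
mismatch response (MMR): a synthetic study generator, an ERP reduction
pipeline, genotype QC, per-SNP association with FDR control, a polygenic
risk-score classifier comparison, and linear-model power calculations. This
note records the models, the defaults and why, the numerical conventions,
and what the synthetic data can and cannot show.

## Study design emulated by the generator

The simulated experiment is a passive two-block auditory oddball paradigm
with syllables /pa/ (266 ms) and /ga/ (409 ms). Each block presents 600
stimuli — 510 standards (85%) and 90 deviants (15%) — pseudorandomized so
that at least two standards separate consecutive deviants, with an
offset-to-onset inter-stimulus interval drawn uniformly from 1450–1750 ms.
Block 1 uses /ga/ as standard and /pa/ as deviant; block 2 swaps the
assignment. Deviant positions are drawn uniformly over all placements
satisfying the spacing constraint via a stars-and-bars bijection, so the
generator is exact, not rejection-based.

The cohort default is 67 children, with poor spellers defined as the lowest
decile of a spelling score and an independently drawn attention-deficit
(ADD) flag at the observed prevalence of 12/67.

## Signal model

Continuous EEG (default montage F3, Fz, F4, Cz, Pz, A1, A2 at 500 Hz) is
the sum of:

* **1/f background** per channel, scaled to a per-channel SD of 8 µV, plus
  a 1 µV 10 Hz rhythm with random phase. These values give single-trial
  variability typical of pediatric EEG while keeping clean trials far from
  the ±80 µV rejection bound.
* **A common evoked response** at every stimulus onset on all scalp
  channels (an N1-P2-like biphasic shape supported on 0–800 ms).
* **A deviant-only difference component** on the frontal channels, which is
  the quantity the pipeline must recover:
  * controls: two negativities, centred near 200 ms and ~480 ms (−1.5 µV);
  * poor spellers: a positivity rising to ~4.5 µV between 200 and 600 ms;
  * a genetic term: for each causal SNP, the configured µV-per-risk-allele
    shift times the subject's dosage, realized as a unit boxcar over
    300–600 ms so the shift moves the analysis window mean by exactly the
    configured amount (additivity by construction);
  * a subject-level Gaussian offset over the same window (SD 4 µV),
    providing the between-subject residual variance that sets realistic
    effect/noise ratios for n≈67 association tests.

  Default per-allele shifts are +3.0 (rs17819126), −1.8 (rs8053211), −1.5
  (rs2875891), −1.7 (rs3743204), −1.4 (rs16973771) and +1.6 (rs11100040)
  µV/allele — the magnitudes reported for these candidate SNPs.
* **Artifacts**: a configurable fraction of trials (default 20%) receives a
  ±150 µV boxcar of 200–400 ms on one scalp channel, placed inside the
  epoch window. The amplitude guarantees detection by the ±80 µV criterion,
  which makes rejection-recall testable as an exact count property.

ERP templates are supported on 0–800 ms; with onset-to-onset gaps of at
least 1716 ms no trial's response leaks into a neighbouring epoch, so the
noiseless generator→pipeline round trip is an identity (verified to
< 1e-9 µV with filtering disabled).

Genotypes are drawn per SNP from Hardy-Weinberg proportions (dosage ~
Binomial(2, p), risk allele oriented as the minor allele, frequencies
uniform on 0.10–0.45 unless specified), with uniform missingness (default
1%). The latent spelling score is `-sqrt(r²)·z(PRS) + sqrt(1−r²)·ε` with
r² = 0.07 by default — a modest genetic contribution to spelling chosen to
be realistic for a 20-SNP unweighted score; the poor-speller flag is the
empirical lowest decile.

All randomness derives from one root seed through `numpy.SeedSequence`
spawn keys (stream, subject, block), so any subject or block can be
regenerated independently.

## ERP reduction

Stage order follows the acquisition protocol: re-reference to the mastoid
average (A1, A2), 30 Hz low-pass at 500 Hz, decimation to 250 Hz, 0.5 Hz
high-pass, epoching, rejection, averaging.

* **Filters** are zero-phase windowed-sinc FIRs (Hamming; transition width
  one third of the cutoff), applied by symmetric convolution with reflect
  padding. The protocol's instrument-specific −3 dB points (26.27 Hz and
  0.501 Hz) are treated as validation metadata, not bit-match targets: the
  realized −3 dB point of each designed filter is measured from its
  frequency response, reported alongside the output, and asserted within
  ±10% of nominal. Filtering and resampling can be disabled for analytic
  round-trip tests.
* **Epochs** span [−200, 1250) ms around onset — half-open on the
  recording's grid, hence 363 samples at 250 Hz — baseline-corrected by the
  mean of [−200, 0) ms per channel. Standards directly following a deviant
  are excluded by design; events too close to a recording edge are flagged,
  not fatal. All time grids in the package are half-open, in ms relative to
  onset, with 0-based sample indexing.
* **Rejection** default is |x| > 80 µV anywhere in the epoch (an absolute
  bound makes the 200 ms sliding window immaterial); a peak-to-peak
  alternative (range > 160 µV within any 200 ms window) is configurable.
  Artifact-exclusion fractions are tracked per condition and compared with
  a paired t-test across subjects.
* **The late MMR** is the mean of the deviant-minus-standard difference
  wave over F3/Fz/F4 within [300, 600) ms, in µV. The default contrast
  pools both blocks (all valid deviants minus all retained standards);
  an identity-matched same-syllable contrast is available because the
  two-block design leaves the pooling choice genuinely open.
* **The sliding group test** tiles [0, 1200) ms into 375 windows of 3.2 ms
  and Welch-tests per-subject window means between groups (Welch because
  group sizes are very unequal, 14 vs 53 at study scale; Student's pooled
  variant is a config option). A 3.2 ms window is shorter than the 4 ms
  sample period, so windows are defined on the continuous axis and an
  empty window inherits the sample nearest its centre. This convention
  reproduces the 375-window count while remaining computable; it is a
  documented choice, not a claim about how the original count arose.

## Genetics

QC order is fixed: individual call rate (> 0.90) → SNP call rate (> 0.97)
→ MAF (> 0.05) → HWE (p > 0.05/m, Bonferroni with m = SNPs entering the
HWE stage). The default HWE test is the 1-df chi-square without continuity
correction; a conditional exact test is available. LD clumping is the
greedy PLINK-style procedure (index = smallest p among unassigned SNPs,
absorb r² ≥ 0.5 within 250 kb), with the index p-threshold set to 1.0
because a candidate panel — unlike a GWAS — should remain fully clumpable.
The packaged panel already lists the 25 independent candidate SNPs, so the
published 30→25 reduction (which needs population LD) is not recomputed.

Association is per-SNP OLS of MMR on risk-allele dosage (additive coding)
adjusted for poor spelling, two-sided t-tests, complete cases per SNP with
`n_used` recorded. ADD adjustment is assessed by re-fitting with the ADD
covariate and tabulating per-SNP beta/p deltas. Influence is screened by
Cook's distance with the conventional 4/n flag (no cutoff is prescribed by
the protocol; the threshold is config-exposed), refitting without flagged
observations and reporting the coefficient shift; an exact fit short-circuits
to zero distances to avoid 0/0. FDR is Benjamini-Hochberg step-up with the
universe m defaulting to the 25 candidate SNPs; the two MMR-replication
SNPs are analysed separately. The QQ envelope uses the Beta(i, m−i+1)
order-statistic quantiles at 95%.

The PRS is the unweighted sum of risk-allele dosages over panel SNPs with
a literature risk allele (20 of 25; which five are unscored is configurable
— the published identity of those five is in an unavailable supplement, so
the packaged choice is a synthetic stand-in). Missing dosages are imputed
with the per-SNP mean so every subject stays scoreable. Classifier
comparison fits three logistic models (MMR; PRS; MMR+PRS) by Newton/IRLS at
tolerance 1e-8 — perfect separation is flagged and probabilities still
returned — and reports ROC AUCs with DeLong CIs (bootstrap alternative),
plus continuous NRI and IDI with their standard asymptotic z-tests,
comparing MMR-alone (old) against the combined model (new). The DeLong
implementation is checked against R's pROC on a frozen instance; NRI/IDI
against hand enumerations.

## Power

For a 1-df SNP effect in a linear model, the normal approximation
`sqrt(λ) = z_{1−α/2} + z_{power}` is inverted and converted to explained
variance by `R² = λ/(λ + v)`. The published-figures preset v = 52 reproduces the
published detectable effect sizes exactly at α = .05 (13.1%) and α = .001
(24.7%) and gives 18.3% at α = .01 against a printed 18.2% — that 0.1-pp
discrepancy is documented, not asserted away. No single exact
noncentral-F configuration reproduces all three printed values, which is
why the preset is the normal approximation; the exact noncentral-F solver
is provided and agrees within 5% relative in the study's df regime. For
new analyses the study-design default is v = 64 (n = 67, intercept + SNP +
spelling covariate).

## Problem sizes used in tests

Statistical properties are verified at sizes chosen for statistical
resolution: type-I error over 2000 null cohorts of n=67; effect recovery
over 100 replicates each at 1.4 and 3.0 µV/allele with n=2000; QQ coverage
over 200 null scans of 25 SNPs; HWE calibration over 5000 SNPs of n=500;
AUC against brute-force pair counting on 1000 small instances. Waveform
round-trip and artifact-recall properties use blocks of 20–200 trials,
where they are exact count/identity checks independent of scale; the
end-to-end pipeline test uses 20 subjects with 30-stimulus blocks, a size
at which every stage still runs on every code path.

## Known limitations

* The generator is a measurement model, not a physiological one: no source
  geometry, no EOG/eye movements, no attention manipulation, no
  non-stationarity across the session. Passing tests certify the analysis
  chain's arithmetic and calibration, not its behaviour on real pediatric
  EEG.
* Risk-allele letters and the unscored-SNP identities in the packaged panel
  are synthetic placeholders; dosages are defined in risk-allele copies, so
  no computation depends on the letters.
* Genotypes are independent across SNPs (no LD), so clumping on simulated
  data is exercised through constructed r² matrices rather than emergent
  correlation.
* The published cohort results (AUC 0.78/0.63/0.85, NRI 0.72, IDI 0.08,
  the Table of per-SNP p-values) derive from an unreleased 67-child
  dataset; the package reproduces the statistics structurally on synthetic
  data and reproduces exactly those published numbers that are pure
  arithmetic on printed inputs (FDR of the printed p-values, window counts,
  block composition, power figures).
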