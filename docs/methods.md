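# Methods

This note documents the models, procedures and numerical choices behind the
package, and what the synthetic generator does and does not emulate.

## Data model and conventions

The substrate is a beta-value matrix β ∈ [0,1]^{P×S} (fraction methylated
per CpG per sample), with probes as rows. All genomic coordinates are
0-based half-open (BED convention); a probe belongs to a region when its
position lies in [start, end). Betas are stored as fractions; percentages
appear only in presentation. Missing betas stay missing (NaN) and are
excluded pairwise from every statistic — no imputation. An optional integer
coverage matrix, aligned cell-for-cell, accompanies sequencing-derived
("capture-mode") betas.

Cohorts are CC (community control), HD (Hodgkin disease) and TC (testicular
cancer); `timepoint_months == 0` is the pre-treatment baseline and
follow-ups come at 6-month intervals.

## Imprint QC and contamination

Germline ICRs give sperm a fixed fingerprint: paternally methylated ICRs
(H19-like) near β = 0.93, maternally methylated ones near β = 0.02, versus
≈0.5 in somatic tissue. For one sample with per-ICR observed means
`obs_i`, sperm expectations `s_i` and somatic expectations `m_i`, the
somatic admixture model `obs_i = (1−α)s_i + α m_i` has the least-squares
solution

    α̂ = Σ (s_i − obs_i)(s_i − m_i) / Σ (s_i − m_i)²,  clipped to [0,1].

Verdict logic: `clean` when α̂ < 0.1; otherwise `contaminated` when the
coefficient of variation of the per-ICR implied α's is < 0.5 (the deviation
is uniform, as true admixture must be) and `locus_anomaly` otherwise. Both
thresholds are design constants (configurable); the source analysis
described the reasoning qualitatively, and this estimator makes it testable.
On synthetic mixtures α̂ recovers the true fraction to well under 0.05 and
is monotone in it.

Outlier flagging computes centered-SVD principal components of the
samples × ICR-means table and flags robust z-scores (median/MAD, consistency
factor 1.4826) beyond 3.5 on the leading components. Components explaining
< 5% of total variance are skipped: when one aberrant sample absorbs nearly
all variance into PC1, the residual components are pure noise whose tiny
MAD would otherwise manufacture spurious outliers. Samples with α̂ above
threshold are flagged independently of the PCs. Flagged samples are
excluded from all downstream stages but retained, with reasons, in the QC
report.

## Baseline differential methylation

Probe filtering drops multi-mapped probes and probes whose overlapping SNP
has minor allele frequency strictly greater than 0.01 (a probe at exactly
the cutoff stays).

Per probe, a classical one-way fixed-effects ANOVA (equal-variance form,
matching base-R `aov`; Welch's form is deliberately not used) over the
baseline samples of the k=3 cohorts:
F = (SSB/(k−1)) / (SSW/(N−k)), p from the F distribution. Degenerate rows:
all values equal → F = 0, p = 1; zero residual variance with distinct
means → p = 0. Significance is raw p < 0.05 by default — replicating the
study design this mirrors — with Benjamini–Hochberg available as an opt-in
(`bh_correct`). The implementation is vectorised over probes and agrees
with `scipy.stats.f_oneway` to 1e-10.

Tukey–Kramer post hoc (valid at the unequal 7/7/6 cohort sizes):
q = |m̄_i − m̄_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)), adjusted p from the
studentized-range distribution with k groups and N−k df. When MSW = 0 the
adjusted p is 0 for unequal means and 1 for equal means (documented
convention). scipy's exact studentized-range quadrature costs ~10 ms per
point, so above 300 evaluations per (k, df) a cubic spline of log-SF on a
481-point q-grid over [0, 20] is built once and cached; its error is below
1e-6 in p (tested), and values beyond the grid fall back to the exact call.
Direction convention: differences are case minus control, so a negative
difference is hypomethylation in the cancer cohort.

Signature selection takes the k probes with smallest ANOVA p; ties break by
larger F, then lexicographic probe id, so selection is invariant to input
order. Clustering of samples over a probe set uses Euclidean distance with
average linkage (the common default for methylation-array heatmaps; the
choice is recorded in the run summary), cut into 3 clusters; purity is the
fraction of samples matching their cluster's majority cohort. A
random-probe control redraws equally sized probe sets to show the
separation is signature-specific.

Region comparisons compute per-sample means over a region's probes first,
then a two-sided unpaired equal-variance t-test or Mann–Whitney on those
means. Two identical constant groups get p = 1 (zero-variance guard) rather
than scipy's NaN.

## DMR merging

Each significant CpG is a 1-bp interval [pos, pos+1); intervals on one
chromosome merge when the gap to the next (next_start − prev_end) is at
most the merge distance (default 1000 bp) — BEDtools `merge -d` semantics,
verified against the bedtools CLI and a brute-force transitive-closure
oracle in the tests. Consequently positions 1,000 apart (gap 999) merge.
Output covers every input site exactly once; DMRs with one site are
singletons, multi-site DMRs are ranked by descending site count with ties
in genomic order. Per-group DMR means are unweighted averages of the member
probes' group means.

## Longitudinal dynamics

Array mode compares every follow-up with the same subject's baseline
(never with the previous follow-up); Δ = β_followup − β_baseline, and a CpG
is altered when Δ > 0.2 (hyper) or Δ < −0.2 (hypo), both strict, so a
change of exactly 0.2 does not count. The drift reference is the mean
altered count over CC subjects' 6/12/18-month follow-ups; fold change is
n_total / reference. Venn cells over a subject's follow-up sets are exact
membership-pattern counts (they partition the union); "persistent" is the
intersection of all follow-ups.

Capture mode has no baseline, so consecutive follow-ups are compared.
CpGs must reach ≥10× coverage in every sample (inclusive, reflecting the
"minimum tenfold" reading; `coverage_exclusive` restores a strict >).
Dynamic CpGs are those with reference mean methylation in [0.2, 0.8],
bounds inclusive; the reference mean is the mean over the analysed samples
(configurable to an external table). Alteration loads between two subjects
are compared with the 2×2 chi-squared with Yates continuity correction,
χ² = N(max(|ad−bc| − N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), 1 df.

## The synthetic generator

`simulate_cohort` emulates, per probe and sample:

* **Bimodal baseline profile.** A fraction (`dynamic_fraction`, default
  0.14 in array mode) of probes is *dynamic*: profile uniform on
  [0.2, 0.8], per-measurement Gaussian noise SD `dynamic_noise_sd`. The
  rest are *static*: profile uniform on [0.03, 0.17] or [0.83, 0.97]
  (half each), noise SD `static_noise_sd`. All betas are clipped to [0,1];
  the truncated-Gaussian-on-beta-scale noise model (rather than
  logit-normal) keeps every invariant directly testable in beta units.
* **ICRs.** Four 800-bp ICRs (one paternal at 0.93, three maternal at
  0.02, eight probes each) plus three candidate signature loci at
  intermediate methylation (a 21-CpG GDF2-like promoter at 0.55–0.75, a
  20-CpG SPON2-like region, an 8-CpG BASP1P1-like locus). Scattered probes
  are spread over 22 autosomes proportionally to (rounded) chromosome
  lengths; ~1% are flagged multi-mapped and ~2% carry a SNP MAF, so the
  probe filter has work to do; implanted effects avoid flagged probes.
* **Disease signatures** (present at every timepoint): TC −0.20 at the
  GDF2-like promoter; HD +0.15 / TC −0.10 at the SPON2-like region; −0.15
  in both cancer cohorts at the BASP1P1-like locus; and 250 dispersed
  dynamic CpGs per cancer cohort at ±0.15 (65% hypomethylated) — the
  substrate the top-500 clustering signature recovers.
* **Treatment pulse.** Each treated subject perturbs 2,900 dynamic CpGs
  (drawn from a shared pool of 2,900/0.25 so two subjects share ~25% of
  their sites) by 0.3 toward the beta midpoint at the 6-month follow-up,
  decaying geometrically (×0.25 per later timepoint); subjects listed as
  persisters keep the full pulse, emulating the rare patient altered out
  to 2 years. 2,900 ≈ 20 × the drift reference, reproducing the ~20-fold
  acute elevation.
* **Contamination** mixes a chosen sample with the somatic profile
  (expected somatic beta inside ICRs, the baseline profile elsewhere).
* **Capture mode** (defaults: 1,711,875 CpGs, 2 CC + 1 HD + 1 TC subjects
  at 12- and 18-month follow-ups, dynamic fraction 0.25) adds per-CpG
  negative-binomial coverage (mean 30, dispersion 5, so ~25–40% of CpGs
  fail the all-sample ≥10× filter), and gives treated subjects extra
  altered dynamic CpGs (0.76% of the universe, shifted by 0.25) emulating
  their elevated alteration load.

**Calibration constants.** The noise SDs are not measured values; they are
calibrated so the generator reproduces the study's headline rates.
Array mode: with dynamic fraction 0.14 over 385,553 probes, the
|Δ| > 0.2 drift count per control follow-up is ~385,553·0.14·P(|Δ|>0.2)
with Δ ~ N(0, √(2σ_d² + σ_drift²)); solving for ≈145 counts gives
σ_d = 0.046 with σ_drift = 0.015 (static probes contribute nothing at
σ_s = 0.01). Capture mode: σ_d = 0.08 makes ~7.7% of dynamic CpGs change
between follow-ups; the static SD was then chosen from a coarse grid, by
simulation (clipping at 0 suppresses static-probe changes below the
unclipped closed form), so the expected share of changes at dynamic CpGs is
closest to 82.9% — giving σ_s = 0.054 and a control alteration rate of
~2.3% of covered CpGs. Problem sizes used by the acceptance script are the
full study-scale defaults (385,553 and 1,711,875 CpGs); the test suite uses
proportionally reduced universes for the scale-invariant quantities.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-type (Infinium I/II) chemistry and
normalisation artefacts, batch effects, correlated noise along the genome
or between neighbouring CpGs, subject-level baseline offsets (noise is
independent per cell), CpG-density structure beyond the implanted loci,
genuine biological pathways behind signatures (sites are random), and
bisulfite-conversion error. Recovery results demonstrate the *pipeline's*
correctness on data matching its assumptions, not the biological findings
themselves.

## Reproducibility and degenerate inputs

All randomness in a run flows from one integer seed through a single
`numpy` Generator; identical (config, seed) gives bit-identical outputs,
and the pipeline's run summary records the seed and config snapshot
(timestamps are opt-in so default reruns are byte-identical). Degenerate
inputs are handled explicitly: empty regions summarise to NaN with a
warning; probes with fewer than two populated cohorts are skipped and
counted; zero significant probes yield missing percentages rather than
division errors; a zero chi-squared margin, an all-equal ICR expectation
vector, disjoint probe universes and a non-positive drift reference raise
named errors.

## Known limitations

* The contamination estimator assumes exactly two components (sperm +
  one somatic mixture) and known expectations; partial degradation or
  cell-type mixtures with non-0.5 ICR methylation will bias α̂.
* Raw p < 0.05 at ~385k tests implies ~19k false positives by design;
  the replicated analysis relies on top-k selection and region-level
  aggregation rather than FDR control (BH is available but off by
  default).
* Longitudinal counting is threshold-based; no mixed-model time-trend
  estimation is attempted.
* The studentized-range spline is accurate to ~1e-6 in p; exact quadrature
  is used automatically for small batches.
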