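# Methods

## Compartment model

Mature mRNA is produced in the nucleus at rate k_S, exported to the
cytoplasm with first-order rate constant k_E, and degraded exclusively in
the cytoplasm with rate constant k_D. Nuclear degradation and
non-mitotic re-import are assumed negligible; reads from alternative
isoforms are combined so each gene gets a single model.

Cell division mixes the compartments: while the nuclear envelope is down,
transcripts redistribute by volume. Averaged over an asynchronous
population with doubling time D, G1/S fraction F_G1S, G2/M fraction F_G2M,
mitosis fraction F_M and nucleus-to-cell diameter ratio r_nc, the
effective exchange rates are

    kf  = 2·r_nc³·(N0+C0)·(F_G1S + 2·F_G2M) / (D·C0)      (cyto → nuc)
    kf′ = 2·(F_G1S + 2·F_G2M − 2·F_M) / D                  (nuc → cyto)

kf depends on the gene's compartment partition and is computed from the
measured t = 0 abundances, then held fixed during fitting.

Quasi-steady state — per-gene pools growing as e^{gt} with g = ln2/D —
fixes the t = 0 balance. The pre-existing (unlabeled-at-t0) pools then
follow closed-form bi-exponential decay curves; the total pre-existing
pool is approximated as a single exponential with the overall turnover
rate k_T = k_D·C0/W0. When the fast exponent of a bi-exponential
coincides with k_T within 1e-12 the removable singularity is evaluated by
its analytic limit (amplitude·t·e^{−kT·t}).

Defaults (all times in minutes, rates per minute; hours only at reporting
boundaries): D = 1440, F_G1S = 0.2, F_G2M = 0.8, F_M = 1/24, r_nc = 0.8.

## Preprocessing

**Spike-in scaling.** Per sample, FPKM values are multiplied by the ratio
of experimental to spike-in mapped reads, making abundances comparable
across time points in a growing culture.

**Outlier exclusion.** For two transcriptomes that should agree (mock vs
4sU-treated; whole cells vs the sum of the fractions), the technical
dispersion around the diagonal is modeled on log10 abundance as
f(x) = m + n·e^{−px}, fitted to per-bin standard deviations of (y − x)
over equal-width abundance intervals (1000 by default, capped by data
density; bins with fewer than 5 points are dropped). A gene is excluded
when it exceeds twice the fitted dispersion on either side
(y > x + 2f(x) or x > y + 2f(y)). Evaluation of f clamps to the fitted
abundance range — the exponential term explodes below it and would
otherwise mask downward outliers of low-abundance genes. Whether the
intervals should be equal-width or equal-occupancy is an open choice;
equal-width is used (configurable).

**Labeling-bias correction.** A new transcript with Nu uridines escapes
capture with probability (1−pr)^Nu (per-uridine labeling probability
pr = 0.01), so the capture probability is F = 1 − (1−pr)^Nu, computed via
expm1/log1p. The measured "unlabeled" signal is the true pre-existing
pool plus the escaped share of new RNA; because the compartment total
grows as X0·e^{gt}, mass balance gives the exact inverse

    Xp(t) = [Xm(t) − (1−F)·X0·e^{gt}] / F

Genes with F ≤ 0.2 are excluded rather than corrected (the 1/F noise
amplification becomes extreme); noise-driven negative corrected values
are clamped to zero and counted.

## Noise and carry-over models

**Replicate noise.** Technical noise is over-dispersed and
mean-dependent. Per gene × condition, the spread across replicates is
measured as the standard deviation of log values, debiased by the
finite-sample factor c4 (at 2 replicates the raw sd underestimates the
true sigma by ~20%), lowess-smoothed against log10 mean (span 0.5), and
converted to a natural-scale CV via cv = √(e^{σ²} − 1). Evaluation
outside the fitted range clamps to the endpoints. The mapping CV = L(m)
supplies the weights of every downstream objective.

**Streptavidin carry-over.** A fraction U of labeled RNA survives the
pulldown, so the measured unlabeled bulk follows
W(t) = W0·e^{−kT·t} + U·W0·(e^{gt} − e^{−kT·t}) and decays to the plateau
U·W0·e^{gt}. (U, kT_bulk) are estimated from the bulk series by
Levenberg–Marquardt on the loss d = (1/n)·Σ(L(Wm)·log(Wm/W))², with U
constrained to [0, 1] and W0 pinned to the t = 0 measurement. The CV
enters the loss as a multiplicative weight on the log-ratio; the
statistically conventional inverse weighting is available via the
`weighting` switch (default `as_printed` keeps the multiplicative form).
U is a single global constant; only labeling escape is gene-specific.

## Per-gene fitting

Free parameters are (k_E, k_D, k_T) in log space (positivity by
construction). N0 and C0 are pinned to the t = 0 measurements, kf/kf′ are
precomputed, and k_S is derived post-fit from the nuclear balance
k_S = (g + k_E + kf′)·N0 − kf·C0. The stacked residual vector realizes
four components: per-point weighted log-ratios of the nuclear and
cytoplasmic curves, a cytoplasmic quasi-steady-state penalty
log((k_E+kf′)N0 / ((k_D+kf+g)C0)), and a turnover-consistency penalty
log(k_T·W0 / (k_D·C0)). The penalties act as soft constraints tying k_T
and k_D together through the steady state.

Initialization is deterministic: k_T from the slope of a log-linear
regression of (Nm+Cm) on t, k_D = k_T·W0/C0, k_E from the cytoplasmic
balance; an optional five-point geometric multi-start sits behind a
config flag. Zero-abundance time points are dropped from the residuals
(no pseudocounts); genes with more than two dropped points per fraction,
or zero t = 0 abundance, are excluded. Identical inputs and
configuration produce bit-identical outputs.

Goodness of fit is r² = 1 − SS_res/SS_tot per fraction on log10
abundances (matching the log-ratio objective); a gene is retained when
r² > 0.8 in both fractions of every replicate (the combination rule is
configurable; the threshold could equally be applied per replicate or
pooled — "all replicates" is the strict choice).

## Association statistics

Replicate estimates are combined per gene by geometric mean. Under
quasi-steady state without mitotic exchange the steady-state cytoplasmic
abundance decomposes additively:

    log C0 = log k_S + log(k_E/(k_E+g)) − log(k_D+g)

The share of each kinetic step in the genome-wide variance of log C0 is
its covariance with log C0 over var(log C0); shares sum to one exactly.
(With mitotic exchange the decomposition is only approximate; the
entangled term would be assigned to decay.)

Rate–feature relations are Spearman correlations plus the log-log OLS
slope. Bound-vs-unbound comparisons per RBP restrict to the top 70%
expressed genes, use two-sided Wilcoxon rank-sum tests (normal
approximation with tie correction) and Holm–Bonferroni adjustment across
label sets within each rate, significance at adjusted p < 0.01; the
family whose error rate is controlled is therefore one rate across its
label sets. Chromatin-state comparisons use one-way ANOVA on log rates
plus Tukey's HSD for all state pairs; states under 10 genes are merged
into "other" (and dropped if still undersized). The Pol II pausing index
is the TSS-window to gene-body signal ratio, missing when the body signal
is zero.

## Synthetic-data generator

The generator emulates the study design: 6 labeling time points (0, 30,
90, 180, 300, 450 min), nuclear + cytoplasmic fractions, 2 replicates,
per-sample spike factors (log-uniform in [0.5, 2]), mean-dependent
replicate noise, per-gene labeling escape and a global carry-over
U = 0.073.

Rates are log-normal with median k_E = 0.0083 min⁻¹ (5th–95th percentile
span 0.5 decades) and median k_D = 0.0140 min⁻¹ (0.9 decades); total
abundance W0 spans 5 decades (median 30 spike-normalized FPKM) so derived
transcription rates do too. The compartment partition, kf/kf′, k_T and
k_S are solved self-consistently (the partition fixed point
N0/C0 = (k_D + a + g)/(k_E + kf′ − a) with a = 2·r_nc³(F_G1S+2F_G2M)/D),
so every identity of the model holds exactly by construction.

The forward measurement model per compartment is
Xm = F·Xp + (1−F)·X0·e^{gt} + U·F·(X0/W0)·W4sU(t): true pre-existing RNA,
the escaped share of new RNA (making the bias correction its exact
inverse), and the carried-over share of captured new RNA apportioned by
quasi-steady-state compartment shares (new RNA is not modeled
compartmentally). Noise is multiplicative log-normal with natural-scale
sd = CV(mean), CV(m) = min(0.1 + 0.4/√m, 0.3) by default — the 0.1–0.3
replicate CV range of the real data. Uridine content is Nu = 0.3 × length
(a generator convention, not a measured value); transcript lengths are
log-normal (median 2 kb), optionally coupled to decay as k_D ∝ length^0.25
for planted-effect tests. Count-level output (for thinning studies) is
Poisson around FPKM-scaled expectations; down-sampling is binomial
thinning. All randomness flows through one seeded generator.

Planted anomalies for the outlier comparisons are systematic offsets of
5 local dispersions with random sign (an extra *noise* sd of that size
would be undetectable at the 2σ rule by construction).

## Validation studies and problem sizes

`nucflux.studies` packages the Monte-Carlo calibrations: the recovery and
down-sampling studies run with escape and carry-over off, isolating the
rate estimator (each correction has its own exact round-trip oracle);
the carry-over study generates bulk series from the single-k_T model the
estimator assumes. Default sizes — 500 genes for recovery, 150 for
down-sampling, 100 seeds for carry-over, 5000 genes for variance shares,
60/100 simulations for association power/size — give stable summary
statistics while the whole acceptance run stays around a minute on one
CPU.

## Known limitations

* The genome-summed bulk series mixes heterogeneous turnover rates; the
  single-k_T carry-over fit on such a sum overestimates U (slowly decaying
  genes dominate late time points and mimic a plateau). The pipeline
  reports this estimate as-is; the estimator itself is unbiased when its
  model holds.
* Carry-over is quantified but not subtracted from per-gene series (as in
  the study design), which flattens the late tail of slow, low-abundance
  genes and lowers their r²; retention consequently selects for
  fast-turnover, high-abundance genes more strongly in the noisy synthetic
  population than in the published data, whose detected gene set was
  already expression-filtered upstream.
* The synthetic generator draws genes independently; it does not emulate
  correlated biology (co-regulated modules, isoform structure,
  position-dependent coverage), so passing tests demonstrate estimator
  calibration under the assumed noise structure, not robustness to every
  feature of real libraries.
* Labeled fractions are not modeled or fitted jointly with the unlabeled
  ones; Bayesian uncertainty intervals are out of scope.
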