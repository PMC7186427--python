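# Methods

`fstgc` implements an imaging-genetics analysis of directed (effective)
connectivity over a ten-region frontal–striatum–thalamus pathway:
bivariate coefficient-based Granger causality per subject, a two-SNP
general linear model over the 90 directed connections at the group
level, covariate-adjusted volume contrasts, and Spearman brain–behavior
correlation — together with a synthetic cohort generator that plants
known genotype-dependent effects so every stage can be validated
end to end.

## The subject-level model

For an ordered pair of region time courses x(t), y(t) and q exogenous
processes z_j(t), the package fits the two-equation lag-p vector
autoregression by ordinary least squares on rows t = p+1…T:

    x(t) = α_x0 + Σᵢ α_xx,i x(t−i) + Σᵢ α_xy,i y(t−i) + Σⱼ β_x,j z_j(t) + ε_x(t)
    y(t) = α_y0 + Σᵢ α_yx,i x(t−i) + Σᵢ α_yy,i y(t−i) + Σⱼ β_y,j z_j(t) + ε_y(t)

Two directed measures are derived:

* **Signed path coefficient** — Σᵢ α_yx,i for x→y (a single coefficient
  at p = 1). This keeps its sign and is the "connection strength"
  carried into the group stage.
* **Residual-variance ratio** — F_XtoY = ln(Var ε_y,reduced / Var
  ε_y,full), where the reduced model omits x's lags; clipped at zero.

Model order defaults to p = 1 (configurable). Each region's series is
z-scored before fitting by default so path coefficients are comparable
across subjects; raw mode is available. `gca_matrix` fits all 90
ordered pairs of the ten-region pathway (diagonals are NaN).

A property worth knowing: bivariate Granger estimation marginalises
over the other eight regions, so a genuine shift in one directed
coupling also moves the lagged cross-covariance seen from the reverse
direction. In planted-effect simulations the reverse connection of the
planted pair is therefore sometimes flagged as well; this is a property
of the bivariate estimand, not a calibration failure (connections not
sharing the affected covariance stay clean).

## Time-series conditioning

The chain mirrors standard resting-state practice, in order: discard
the first k = 10 volumes; per-region linear detrend; ideal band-pass
(rectangular FFT mask) retaining 0.01–0.1 Hz with the DC bin removed; a
zero-phase Butterworth is offered as an option. Nuisance regression
removes the least-squares projection onto [intercept | covariates],
where the covariates are passed through the *same* detrend and
band-pass first — regressing unfiltered confounds on filtered data
would leave in-band confound signal behind (covariate columns
annihilated by the detrend, e.g. a linear drift regressor, are dropped).
With TR = 3 s the Nyquist frequency is ≈0.167 Hz; a band reaching above
it is rejected.

Head-motion exclusion removes subjects whose maximum translation or
rotation *exceeds* 1.5 mm / 1.5° (strictly greater: a subject exactly
at the threshold is kept).

## Genotype QC and subgrouping

Genotypes are unordered allele pairs ("GC" ≡ "CG", normalised sorted).
`hwe_test` offers the Pearson chi-square against p², 2pq, q²
expectations (df = 1) and the Levene–Haldane conditional exact test
(enumerating heterozygote counts given the allele counts). MAF is
(2·hom_minor + het) / (2n), with the minor allele chosen as the rarer.

`assign_subgroups` cross-classifies subjects by the two SNPs. Any
marginal genotype class with fewer than `min_group_size = 3` carriers
is removed with its carriers (the default of 3 reflects dropping a
two-subject class); because the group design treats each SNP as a
two-level factor, any surplus third class that survives the size rule
is likewise excluded. Fewer than two surviving joint cells is an error.

## Group inference

Per connection, the subject strengths are modelled as

    strength ~ 1 + snp1 + snp2 + snp1·snp2 + gender + age + edu

with the factors effect-coded (±1/2, reference genotype negative;
references: the common/ancestral homozygotes, GG for SNP1 and TT for
SNP2). Each family (SNP1 main, SNP2 main, interaction) is tested by the
full-versus-reduced residual-sum-of-squares F with one numerator degree
of freedom; effect coding makes the drop-one F a Type III main effect
(averaged over the other factor) even with the interaction in the
model. Benjamini–Hochberg FDR is applied *within each family* across
its 90 connections at q = 0.01. A Mann–Whitney U on covariate-adjusted
strengths accompanies every row as a robustness column (exact
enumeration when the pooled sample is ≤12 and tie-free, otherwise the
tie-corrected normal approximation with continuity correction); the
covariate adjustment takes its betas from the factor-including GLM so
factor-correlated covariate noise cannot absorb the group effect.

Degenerate designs follow a fixed policy: covariate columns collinear
with the rest are dropped with a warning; an interaction made
inestimable by an empty joint cell reports no evidence (F = 0, p = 1);
collinear factor columns are an error.

Connections with a flagged interaction get simple-effect contrasts:
within each level of one SNP the other SNP's genotypes are compared
(adjusted mean difference + Mann–Whitney), labelled "CG/GT vs. GG/GT"
style. Volume tests fit volume ~ intercept + group + gender + age + edu
per region and report the group coefficient's t, BH-corrected across
regions. The Spearman stage runs only for flagged connections, within
the genotype subsets defining the flag (the two marginal genotypes for
a main effect; the four joint cells for an interaction), against all
behavioral scales, with pairwise deletion of missing values, row
suppression below n = 3, and BH-FDR across the reported rows.

## The synthetic cohort

The generator's defaults emulate the study conditions: 55 subjects,
170 acquired volumes at TR = 3 s (160 analysed after the discard), two
biallelic SNPs with minor-allele frequencies 0.195 (SNP1, alleles G/C)
and 0.246 (SNP2, T/G) drawn under Hardy–Weinberg equilibrium — so the
rare homozygotes appear at their HWE rates and the exclusion rules have
something to exclude.

Each subject's signal is a stationary lag-1 VAR: diagonal 0.35 plus
weak (0.08–0.10) directed entries along the
cortico-striato-pallido-thalamo-cortical loop; every genotype-modified
matrix is checked for spectral radius < 1. Genotype effects are
`EffectSpec` entries adding a signed delta to one (target, source)
coefficient for non-reference carriers (or one joint cell for
interaction effects); the default map mirrors the reported pattern
(a SNP1 effect within bilateral dLPFC, a SNP2 effect on the descending
prefrontal–striatal path, an interaction on the ascending
pallidum–prefrontal path), each with delta 0.2. On top of the VAR
signal the generator adds a linear drift (amplitude 0.5 of signal sd)
and six smoothed-Gaussian pseudo-motion regressors (loading 0.3 of
signal sd) — magnitudes are the package's own choices; only the
regressor identities are dictated by the protocol. Generative model
order is fixed at 1; higher orders can be simulated via a custom
transition matrix.

Behavioral scales are population Gaussians (means/SDs at plausible
clinical values) except where a coupling ties a scale linearly to a
subject's *true* path coefficient. Because genotype shifts alone make
the true strength two-valued, connections referenced by a coupling
receive per-subject Gaussian jitter (sd 0.05) so that the Spearman
stage has a continuous substrate; connections without couplings keep
deterministic per-cell coefficients. Volumes are region-typical means
(cm³) with 5% noise and optional per-(region, genotype-cell) shifts.

Randomness is keyed, not sequential: the master seed spawns independent
substreams per subject and per behavioral scale
(`SeedSequence(entropy=seed, spawn_key=…)`), so growing the cohort
never reshuffles earlier subjects, and one seed reproduces the bundle
byte for byte.

What the generator does **not** emulate: hemodynamic convolution,
physiological noise spectra (cardiac/respiratory), spatial structure,
scanner artefacts, and genotype–covariate correlation. Passing tests
therefore demonstrate the statistical machinery is correct and
calibrated under the stated generative assumptions, not that the
original biological effects are reproduced — the patient fMRI
underlying the original tables is not available at any scale.

## Numerical choices

* All OLS fits use `numpy.linalg.lstsq`; rank-deficient nuisance
  designs fall back to the minimum-norm solution (residuals match the
  de-duplicated design).
* The ideal filter mask includes band edges with a 1e-15 Hz tolerance;
  the exact-HWE p-value sums probabilities ≤ the observed one with a
  1e-12 relative tolerance (the conventional tie rule).
* F statistics are clipped at 0 before the p-value; residual-ratio
  influences are clipped at 0.
* Volume t-tests report t = 0, p = 1 when the model fits perfectly
  (no residual variance), rather than 0/0.
* Tables are TSV, UTF-8, floats at 12 significant digits; every output
  round-trips through its reader at that precision. A run manifest
  records the config hash, seed and library versions.

## Problem sizes used in validation

Simulation-based checks run at: 200 subjects (T = 160) for
planted-coefficient recovery; 100 replicate cohorts of 60 subjects for
detection power at delta = 0.2 and 100 null cohorts for calibration at
q = 0.01; 2000 replicates for the null distribution of the
standardized cross coefficient; 200 mixed null/non-null replicates for
the empirical-FDR bound. Power properties for the volume and
simple-effect stages are demonstrated at 24 and 30 subjects per group
respectively, where the ≥0.8 detection bound holds with margin under
BH correction with a single true effect in the family.

## Known limitations

* Bivariate (not conditional) Granger causality: influences mediated by
  a third region are not partialled out, and a planted effect can
  surface in the reverse direction of the same pair.
* The ideal filter assumes the series is effectively periodic over the
  window; edge ringing is possible on short series.
* The GLM assumes homoscedastic Gaussian residuals across genotype
  cells; the Mann–Whitney column is the guard against gross violations.
* Behavioral couplings are linear with Gaussian noise; monotone
  nonlinear couplings are detectable by the Spearman stage but are not
  generated.
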