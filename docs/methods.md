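# Methods

This note documents the models, estimators and numerical choices behind
`nearzero`, and what the synthetic-data generator does and does not
emulate.

## Retentostat maintenance-energy model

A retentostat is a chemostat with full biomass retention. With dilution
rate D (h⁻¹), feed and residual glucose C_s,in and C_s (g L⁻¹),
maintenance coefficient m_s (given in mmol glucose g⁻¹ h⁻¹ and
converted with the anhydrous glucose molar mass 180.16 g mol⁻¹) and
maximum biomass yield Y_sx^max (g g⁻¹), the ideal biomass balance —
growth-rate-independent maintenance, no lysis, full viability — is

    dCx/dt = Ysx_max · (D·(Cs_in − Cs) − ms_g·Cx)

with closed-form solution Cx(t) = Cx_∞ + (Cx0 − Cx_∞)·e^(−k·t), where
k = ms_g·Ysx_max is the relaxation rate and Cx_∞ = D·(Cs_in − Cs)/ms_g
the biomass at which the whole substrate supply is spent on
maintenance. Defaults (D = 0.025 h⁻¹, Cs_in = 50 g L⁻¹, m_s = 0.50
mmol g⁻¹ h⁻¹, Y_sx^max = 0.097 g g⁻¹) describe anaerobic glucose-limited
cultivation; with them Cx_∞ ≈ 13.88 g L⁻¹ and k ≈ 0.0087 h⁻¹. The
initial biomass defaults to the steady state of a chemostat at μ = D,
computed with the maintenance-corrected (Pirt) yield
1/Y_obs = 1/Ysx_max + ms_g/D applied to the consumed substrate
C_s,in − C_s. C_s defaults to 0: measured residual glucose (≤ ~1 mM) is
three orders of magnitude below a 278 mM feed.

**Fitting.** Observed total-biomass series (which include non-viable
cells) are fitted with A·e^{B·t} + C by Nelder–Mead minimization of the
sum of squared residuals, initialized at C₀ = 1.05·max(Cx),
A₀ = Cx(0) − C₀, B₀ = −0.01 h⁻¹, with simplex tolerances 1e−10 and at
most 10 000 evaluations. Non-convergence returns best-so-far values
flagged `converged=False` rather than raising. Exactly constant series
are unidentifiable along A + C = const and are resolved to the flat
solution A = 0, C = mean. At least 4 points are required.

**Growth-rate reconstruction.** μ(t) = (A·B·e^{B·t})/(v(t)·Cx_fit(t)),
with viability v linearly interpolated between sampling points. Only
viable cells replicate; because no lysis is assumed, a negative fitted
derivative would imply μ < 0 and is instead reported as μ = 0 with a
`clipped` flag. Zero viability raises an error naming the time point.

**Glucose partition.** Maintenance flux m_s·Cx,viable and growth flux
μ·Cx,viable/Y_sx^max (g glucose L⁻¹ h⁻¹), fractions normalized by their
sum; the all-zero case is flagged degenerate instead of dividing by 0.

**Residual glucose.** For the generator's metadata a Monod relation is
inverted: qs = μ/(Y_sx^max·mw) + m_s, Cs = Ks·qs/(qs_max − qs). The
defaults qs_max = 15 mmol g⁻¹ h⁻¹ and Ks = 0.8 mM are package choices
keeping qs below saturation across the whole design; printed
residual-glucose anchors in the motivating experiments are mutually
inconsistent with any single Monod curve under this qs(μ) relation, so
only the structural properties (monotonicity, positive floor
Ks·m_s/(qs_max − m_s) as μ → 0) should be relied on.

## Expression preprocessing

Order: (1) global scaling — each array multiplied by
300/mean(all features on that array); idempotent; (2) flooring of
values below 12; (3) removal of genes whose across-array maximum is
below 20; (4) ORF selection; (5) for profile work, replicate collapsing
by arithmetic mean per (mode, growth rate, day) condition, columns
ordered by increasing growth rate, then division of each gene by its
across-condition mean (rows average 1, shapes comparable across
expression levels). Scaling precedes ORF selection because the array
mean is taken over all features, controls included. Housekeeping
stability is summarized as CV = sd/mean across all arrays with the
sample (n−1) standard deviation, appropriate for 2–3 replicates; CVs
below 0.20 indicate global scaling is safe (no massive mRNA-pool
shift).

## Differential expression over growth rate

Per gene, the full model regresses intensity on a natural cubic spline
in the covariate plus intercept; the null model is the intercept. The
default covariate is log₁₀ μ because the combined chemostat +
retentostat design spans 2.5 orders of magnitude in growth rate and the
profile shapes are transitions in log μ; retentostat day is available
as an alternative for pure time courses. The spline has df = 3 basis
columns, boundary knots at the covariate extremes and interior knots at
quantiles; replicates enter as independent samples sharing a covariate
value. F = [(RSS₀ − RSS₁)/(d₁ − d₀)]/[RSS₁/(n − d₁)] with d₁ the
realized rank of the design (a rank-deficient basis degrades gracefully
through the least-squares fit). A perfectly fitted gene (RSS₁ = 0)
reports F = +∞; a constant gene reports F = 0. F is invariant to affine
transformation of the profile.

The null permutes whole sample columns — the same B = 1000 seeded
permutations for every gene, preserving gene–gene correlation — and
p = (1 + #{F_perm ≥ F_obs})/(B + 1), which cannot return 0. For n small
enough that n! ≤ B the permutations are enumerated exhaustively. The
observed statistic is routed through the same indexed-copy code path as
the permuted ones so the identity permutation ties bit-exactly.

q-values follow the Storey procedure: π₀(λ) = #{p > λ}/(m(1 − λ)) on
λ = 0.05…0.90 (step 0.05), smoothed by a cubic polynomial evaluated at
λ = 0.90 and clamped to (0, 1]; an unstable estimate falls back to
π₀ = 1, making the q-values exactly Benjamini–Hochberg. Genes are
called at p < 0.01 with q reported alongside; any printed pairing of a
p cut-off with a particular q value is dataset-specific, not a
contract.

Because all genes share one permutation set, their p-values are
correlated: the *mean* type-I rate is exact (measured 0.0502 at the
0.05 level across seeds) but the variance of the per-dataset rejection
fraction is inflated by roughly half relative to independence.
Calibration experiments should therefore average a few replicate draws
rather than rely on a single one.

## Profile clustering

Distance d = 1 − Pearson r, in [0, 2]. Degenerate conventions: two
positive constants are at distance 0 (they mean-normalize to the same
flat profile), a constant against a varying profile is at distance 1.
Input rows are mean-normalized first, which is what makes labels
invariant to positive per-gene scaling. Lloyd iterations assign genes
to the nearest centroid (ties to the lowest index) and update each
centroid as the arithmetic mean of its members, re-mean-normalized to
stay on the profile scale; empty clusters are reseeded with the point
farthest from its current centroid. Seeding is distance-weighted
(k-means++-style with weight d), with 10 restarts and the best total
objective kept; everything is deterministic at a fixed seed. The mean
update is not mathematically guaranteed to decrease the 1 − r objective
(the correlation barycenter is the normalized mean of the z-scored
members, not of the raw profiles), so if an update step ever increases
the objective the iteration stops and keeps the previous, better state;
the reported objective history is therefore non-increasing by
construction, and the converged objective pairs the final labels with
their own centroids. k defaults to 7; no model selection for k is
attempted.

**Threshold detection.** For profiles expected to be "constant below a
threshold growth rate", every interior condition is tried as a
breakpoint of a flat-below / linear-above (in log₁₀ μ) model; the
breakpoint minimizing total SSE is kept if an F test (4 vs 2
parameters, α = 0.05) rejects the single-line alternative. Globally
flat or exactly log-linear profiles report no threshold. Smooth
logistic transitions do not necessarily trigger the detector — it
responds to genuinely flat-then-sloped geometry, not to any saturating
curve.

## Enrichment

Gene-set over-representation uses the exact hypergeometric upper tail
P(X ≥ k) for drawing n cluster genes from N analyzable genes of which K
are annotated, evaluated through the survival function (log-space
internals, stable at genome scale), with EF = (k/n)/(K/N). The universe
is the set of genes that survived preprocessing, not the whole genome.
Raw p is thresholded at 1e−6 by default; a within-collection Bonferroni
adjustment is reported alongside. Sets are restricted to the universe
on construction, empty sets dropped with a warning.

Motifs are IUPAC strings matched exactly (overlapping occurrences
counted via lookahead; an N in the sequence never matches; both strands
by default, via the reverse complement). The motif enrichment factor is
the cluster/universe hit-fraction ratio with a hypergeometric tail on
hit counts — the standard promoter-analysis definition, dimensionless,
equal to 1 when the cluster mirrors the universe. Promoters default to
800 bp upstream windows. No position-weight matrices, background Markov
models or motif discovery.

## Synthetic-data generator

The generator defines the study conditions the tests exercise:

- **Design**: 22 arrays, 9 conditions — chemostats at μ = 0.2, 0.1,
  0.05, 0.03, 0.025 h⁻¹ with 3/3/2/3/3 replicates and duplicate
  retentostat samples at days 2/9/16/22 with μ ≈ 0.0084, 0.0024,
  0.0011, 0.00063 h⁻¹.
- **Archetypes**: seven profile shapes as smooth logistic transitions
  in log₁₀ μ (midpoint, steepness, amplitude, baseline): rising-with-μ
  with a low-μ plateau, falling-with-μ with a plateau, glucose
  derepression at intermediate μ, a sharp retentostat-specific up-shift,
  a broad monotone stress shape, a retentostat-specific down-shift, and
  a near-zero-only dip (Gaussian in log μ). Responder amplitudes
  (240 on a baseline of 60, times a lognormal gene-specific scale)
  put effects well above 3× the replicate noise sd.
- **Noise**: multiplicative lognormal with unit mean at CV = 0.14, the
  typical reproducibility of replicate steady-state arrays;
  housekeeping genes at CV = 0.10 so they satisfy the CV < 0.20
  criterion; intensities scaled so the pre-noise array mean is 300.
- **Trajectories**: total biomass follows the closed-form trajectory
  exactly and the viable fraction decays as v_inf + (1 − v_inf)e^{−λt}
  (defaults v_inf = 0.8, λ = 0.005 h⁻¹ — stand-ins, configurable);
  viable biomass is v·Cx_total and the recorded truth μ is
  (dCx_total/dt)/(v·Cx_total). This construction keeps the noiseless
  fit-and-reconstruct round trip exact; it does not model the feedback
  of viability loss on substrate consumption.
- **Gene sets**: planted sets sample members without replacement with
  odds w for the target archetype vs 1 otherwise; decoys sample
  uniformly.
- **Promoters**: i.i.d. bases at GC 0.38 with one motif instance
  (random degenerate expansion, strand and offset) stamped per selected
  gene. In the default Bernoulli mode spontaneous background matches
  remain possible (~5% per 800 bp for an 8-mer with one two-fold
  degenerate position); the `exact` mode plants exact hit counts and
  resamples unstamped promoters to be motif-free, for experiments that
  must realize stated hit *rates* precisely.

What the generator does not emulate: probe-level array physics,
cross-hybridization, scanner saturation, condition-dependent noise,
correlated gene modules beyond the archetype means, or real genome
annotation structure. Passing planted-truth tests therefore
demonstrates that the estimators recover the structure they assume, at
realistic noise — not that real arrays satisfy those assumptions.

Known limitation: the df = 3 natural-spline F test has low power
(~13% at these settings) for the near-zero-only dip archetype, whose
signal is localized next to the covariate boundary where a natural
spline is constrained to be linear; raising df or using the time
covariate on the retentostat subseries recovers power.

## Problem sizes and reproducibility

Simulation-based checks use 100-replicate Monte-Carlo runs for
trajectory recovery, 500–2000 genes × 1000 permutations for test
calibration and planted-responder detection (pooled over 4–5 replicate
simulations, since the shared-permutation scheme inflates single-draw
variance), 2000 promoters for motif enrichment, and exhaustive
enumeration up to N = 12 (hypergeometric) and 2¹¹ bipartitions
(k-means) for oracle equivalence. All stochastic components take
explicit integer seeds; the pipeline fans one global seed into stable
per-stage child seeds via `numpy.random.SeedSequence`, and repeated
runs are byte-identical.
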