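# Methods

## Scope and data model

The package analyses a pairwise-coculture screen read out as total OD600
per well plus endpoint cytometry. The design it targets (and that the
generator emits) is 5 species × 3 strains; every strain as a monoculture
in biological triplicate, every unordered strain pair in quadruplicate;
OD600 every 30 min for 24 h (49 points); 10 000 gated cytometry events per
sample at T0 and T24. A "monoculture" is operationally a 50:50 mix of a
wild-type strain and its fluorescently tagged clone, so every well —
mono or co — contains two populations.

## Growth-curve kinetics

Each curve, truncated to the 24 h analysis window, is fitted with the
3-parameter logistic by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trf). Initial guesses: K₀ = max OD,
N₀₀ = max(first OD, 10⁻³), r₀ from the log-linear slope of the
sub-half-capacity points. Bounds: r ∈ (0, 10] h⁻¹, N0 ∈ (0, 3·maxOD],
K starting in (0, 3·maxOD] — when the optimum presses against the K
cap (an unsaturated curve carries its capacity outside it) the cap is
widened tenfold, up to 100·maxOD. Non-converged fits are retried from
5 multiplicatively jittered starts (fixed sub-seed) before being flagged;
flagged wells keep their direct measures (latency, maxOD) and drop the
model-based ones (r, AUC). A flat signal (max OD < 1.2 × initial, or a
fit collapsing onto K ≈ N0) is flagged non-growing.

Choices the data do not force, and what was decided:

* **AUC is the model integral**, evaluated in closed form (log-space, so
  late-saturating curves lose no precision); the empirical trapezoid is
  kept as a diagnostic column (`auc_trapezoid`). The two agree to <0.1%
  for any converged fit.
* **Latency interpolates linearly** between the samples bracketing the
  0.25 OD crossing, because the 30-min grid is coarse relative to
  replicate latency spreads; a step-mode flag returns the first
  above-threshold sample instead.
* Defaults: threshold 0.25 OD, window 24 h, no background subtraction
  (an optional constant offset exists, default 0).

## Monoculture variance structure

Species is a fixed effect, strain-within-species a random one. For the
balanced designs this screen produces, the mixed model is exactly testable
by the expected-mean-square nested ANOVA: the species F uses the
strain-within-species mean square as denominator, the strain F uses the
residual. This coincides with the REML mixed-model tests for balanced data
while being optimizer-free and exactly reproducible; with a single strain
per species the species test falls back to the residual denominator (and
then equals the classical one-way ANOVA, verified to 1e-10). Near-balanced
data are accepted with a logged warning; strongly unbalanced designs
should use a dedicated mixed-model fit instead. Species letter groups come
from Tukey–Kramer comparisons with the strain mean square as error (the
correct yardstick when strains are random draws) and an insert-and-absorb
compact letter display; α = 0.05.

## Interaction index and outcome classes

Id = (co − m̄)/m̄ with m̄ the mean of the two monoculture parameter means.
The classifier runs a fixed ladder at α = 0.05: (1) two-sided Welch t-test
of the coculture replicates against the replicate-paired monoculture
averages ((m1ᵢ+m2ᵢ)/2, i up to min(n1,n2) in replicate order — this
pairing preserves replicate count and variance scale; the source
experiments did not specify one); not significant → A. (2) One-sided
Welch against the higher-mean monoculture → B. (3) One-sided against the
lower-mean monoculture → C. (4) Otherwise D. All three p-values are
reported regardless of the branch taken. Welch rather than pooled-variance
tests because mono and co wells have different replicate numbers and noise
compositions; one-sided B/C gates because over/underyielding is
directional. No multiple-testing correction by default (each coculture is
a self-contained comparison, as in the original screens); a
Benjamini–Hochberg option re-gates case A per parameter. For latency the
index sign is inverted when translated into a biological direction.

## Matrix clustering and stability

The per-parameter strain×strain index matrix (symmetric, zero diagonal;
missing or duplicate pairs are errors) is clustered by complete-linkage
agglomeration on Euclidean distances between rows; row vectors include the
diagonal zero (an exclude-self flag exists; the effect is negligible and
both options are tested). k defaults to the number of species (5).
Cluster ids are renumbered deterministically by lexicographic strain
order.

Stability: B resamples of the strain set (`subset`: fraction 0.5 without
replacement; `bootstrap`: n with replacement), each re-clustered at k
(capped at the number of distinct strains drawn); each original cluster
scores the maximum Jaccard similarity between its drawn members and any
cluster of the resampled solution, **and scores 0 when none of its members
was drawn** — the dissolved-cluster convention of the reference bootmean
procedure. This convention matters: with a fixed dissimilarity matrix a
singleton can essentially never be absorbed under re-clustering, so
skipping absent clusters would certify every singleton as perfectly
stable. Counting absence as dissolution caps a singleton near its
inclusion probability (1 − (14/15)¹⁵ ≈ 0.64 under bootstrap resampling of
15 strains), which is exactly the behaviour that flags lone intermediate
strains as unstable. Mean Jaccard < 0.5 is reported as dissolved. The
merge tree is exported as Newick.

## Cytometry fold changes

Gate fractions of total events give relative abundances; fold change is
the T24 fraction over the T0 fraction per replicate (undefined at zero T0
share — flagged, not imputed). In a two-gate well the per-replicate fold
changes obey f_A·s_A0 + f_B·s_B0 = 1 exactly. The test against 1 is a
one-sample two-sided t-test on the raw fold-change scale (matching how
such screens report mean ± sd of raw fold changes); a log-scale option
tests log-fc against 0. No correction across the 210 strain-in-pair tests
by default.

## Synthetic study generator

Dynamics per well (two populations, total OD observed):

    dN_A/dt = r_A N_A (1 − (N_A + α_AB N_B)/K_A) − τ N_A N_B

and symmetrically for B; each population is held at its inoculum until its
lag elapses. Integration is fixed-step RK4 at Δt = 0.01 h, vectorised
across wells; lags snap to the integration grid so the growth switch-on
falls on a step boundary and every RK4 step sees a smooth right-hand side
(the decoupled limit then matches the logistic closed form to ~1e-12).

Parameters and defaults, chosen once:

* Species phenotypes seeded from observed wine-yeast monoculture
  kinetics: K (OD) / r (h⁻¹) = Sc 2.11/0.43, Lt 2.15/0.43, Td 2.11/0.33,
  Hu 1.62/0.30, Sb 1.42/0.17; lag 1.0 h for all.
* Strain level: multiplicative Normal(1, strain_cv) deviations on K, r,
  lag; strain_cv = 0.03.
* Inoculum: total N0 = 0.01 OD-equivalents, 50:50 split (0.005 per
  member); the OD-to-cell scale is a single constant since only relative
  dynamics matter.
* Noise: additive Gaussian OD noise σ = 0.02 per reading (clipped at 0);
  per-member replicate lag jitter sd 0.5 h, the order of observed
  within-strain latency spreads — this is what gives AUC replicate SDs of
  ~0.5–1.5 OD·h, matching reported magnitudes.
* Cytometry: multinomial draws of 10 000 events from the simulated
  population shares at t = 0 and 24 h (cocultures; a flag adds
  monoculture clone-pair samples).
* Seeding: one master seed; sub-streams via `SeedSequence` spawn keys —
  (0,) registry, (1, well) lag jitter + OD noise, (2, well) cytometry,
  (3, pair-hash) strain-pair coefficient jitter — so any single well is
  reproducible in isolation.

**The neutral null is full niche overlap**: α ≡ 1 with one shared
phenotype (K = 2.0, r = 0.40, lag 1.0) for all species. Two deliberate
subtleties: (i) independent growth (α = 0) is *not* neutral for a
total-OD readout — it stacks two carrying capacities and reads as
overyielding; (ii) even at α = 1, species-specific rates would drift the
coculture toward its faster member and away from the monoculture
midpoint, so a calibration null also requires exchangeable phenotypes.
Facilitation is planted as α < 1 (niche release), antagonism as α > 1
and/or τ > 0; τ is what produces genuine case-C underyielding, because
raised overlap alone mostly changes *who* wins, not the total. In the
species-block scenario the planted values are α = 1.5, τ = 0.25 for
Sc–Lt; α(Sc←Td) = 2.5, α(Td←Sc) = 1.2, τ = 0.25 for Sc–Td (that contest
settles quickly, so the pressure on the winner is raised asymmetrically);
α = 0.6 for every Sb pairing; ±5% per-strain-pair jitter on planted
coefficients. The truth manifest records every strain parameter, every
realized pair coefficient, the noise-free ("planted") AUC interaction
index per pair, and the intended sign.

What the generator does **not** emulate: mechanistic fermentation
chemistry (sugars, nitrogen, ethanol), oxygen, diauxie, evaporation or
drift, more-than-two-member consortia, or vendor file formats. Two known
realism gaps follow from the fixed inoculum scale: the slowest species
(Sb) does not saturate within 24 h in silico, so synthetic latencies keep
a species structure that real screens did not show; and Sb's simulated
abundance collapse in coculture is far deeper than observed (fold changes
~0.05 rather than ~0.5). Passing tests therefore demonstrate correctness
of the analysis chain under a controlled data-generating process, not
biological fidelity of any particular simulated number.

## Validation experiments and problem sizes

`codyn.validation` (driven by `scripts/acceptance.py` and mirrored in the
test suite) measures, per run: logistic recovery on 200 noiseless curves
spanning K ∈ [1, 2.5], r ∈ [0.15, 0.5], N0 ∈ [0.005, 0.02] plus 100
noisy curves at σ = 0.02; closed-form-AUC vs quadrature over all
converged fits; classifier null calibration over 5 independent full
designs (525 cocultures); planted ±30% AUC shifts over 210 cocultures
(exact by curve scaling) plus ×1.5/×0.5 extremes at low noise; cluster
recovery and bootstrap stability (B = 100) on a planted 5-block matrix
with uniform between-block separation 5× the within-block SD (uniform so
that scaling the separation scales every between-block mean difference
alike); fold-change recovery at planted T24 shares 1/3 and 2/3 with
10 000-event multinomials and a 1000-run null; nested-ANOVA power (200
runs at a 10σ species effect) and type-I rate (500 null runs); and the
full 465-well pipeline run twice for hash-identical determinism. These
sizes keep a complete validation run in the order of half a minute on one
CPU.

## Numerical conventions and degenerate inputs

Undefined quantities are NaN, never imputed (latency that never crosses,
r/AUC of failed fits, fold change at zero T0 share — the last raises and
is logged). Zero-variance t-test inputs: identical groups count as "no
evidence of difference" (p = 1), identically shifted groups as certain
difference (p = 0). Interaction records with a zero monoculture average
are flagged and skipped. The pipeline aborts with exit code 2 on input
errors and 3 on analysis errors; every output file carries the
configuration hash, outputs contain no timestamps, and a rerun with an
identical configuration is byte-identical.

## Known limitations

* Total-OD readout fundamentally cannot attribute an interaction to one
  member of the pair; the package classifies and quantifies, it does not
  attribute.
* The EMS nested ANOVA assumes (near-)balance; it warns rather than
  reweights when unbalanced.
* Exact Table-style outcome counts depend on test conventions (variant,
  sidedness, α) that published screens typically leave unstated; the
  defaults here are documented above and configurable.
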