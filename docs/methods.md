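# Methods

## Scope and model structure

The package quantifies kinetic inhibition of Cas12a:gRNA target recognition
by non-cognate nucleic acids at four levels: combinatorial occurrence
statistics of decoy sites in random pools, deterministic mass-action models
of the fluorescent trans-cleavage readout, summary statistics of
plate-reader traces, and a closed-form map from seed composition to the
measured slowdown. A synthetic-data layer generates every input the
pipeline needs, so all results here are computed, not transcribed.

## Sequence features

A spacer is a 20-nt RNA string over {A,C,G,U}; its seed is the 5′
(PAM-proximal) prefix, 8 nt by default (the biophysically canonical seed is
5–6 nt; the 8-nt window is the analysis convention and the length is a
parameter). DNA-alphabet input is rejected rather than silently
transliterated — an explicit `transcribe` (T→U) keeps sequence provenance
intentional. Composition counts partition each region exactly
(purines + pyrimidines = AU + GC = length) and fractions are stored as
`fractions.Fraction`, so the partition identities f_R + f_Y = 1 and
f_AU + f_GC = 1 hold exactly and composition tests never compare floats.

The 17-spacer benchmark panel ships as a fixture. Its printed seed-region
composition columns agree with direct counting for all 17 entries; the
printed full-spacer columns do not (11 of 17 rows disagree with counting
the printed sequences, one cell even sums to 21 for a 20-nt spacer). The
package treats the printed sequences as the source of truth and reports
counts computed from them; the test suite pins the discrepant rows at their
computed values so the inconsistency is recorded rather than silently
reproduced or silently corrected.

## Pool occurrence statistics

For an IUPAC motif of length ℓ (default TTTV, where V = {A,C,G}) under a
uniform base model, the per-window match probability is the product of
per-position allowed fractions: P(TTTV) = (1/4)³(3/4) = 3/256. In an L-nt
random region a duplex offers 2·(L − ℓ + 1) windows; by linearity of
expectation the expected occurrence count (overlaps included) is windows ×
probability, exactly — no Poisson or independence approximation is needed
for counts (probability of ≥ 1 occurrence is deliberately out of scope).

For PAM + m-nt seed-matching sites two window conventions exist:

* `printed` (default): 2·(L − m + 1)·P(PAM)·(1/4)^m — the headline-number
  convention, which does not subtract the PAM's own footprint;
* `strict`: 2·(L − m − ℓ + 1)·P(PAM)·(1/4)^m — every counted window fits
  entirely inside the random region, which is what a scanner measures.

At L = 168, m = 8, 200 nM pool the two give 11.5 and 11.2 pM — identical
for every practical purpose; the strict form backs the Monte-Carlo checks.

The oracle for all expectations is a brute-force scanner: both strands are
scanned in their own 5′→3′ orientation with an overlap-tolerant regex; each
hit optionally records how many bases immediately 3′ of the motif
reproduce the gRNA seed as DNA (the non-target strand of a protospacer
carries the spacer's own sequence). Coordinates are 0-based per strand;
minus-strand hits are not projected onto plus-strand coordinates.
Expectation formulas cover only the random core — designed flanks are
PAM-free by construction and that construction is *validated by scanning*,
never assumed.

## Kinetic models

Model 1 (no background), concentrations in nM, time in seconds:

    dC/dt = −k_ON,T·C·T          dT/dt = −k_ON,T·C·T
    dA/dt = +k_ON,T·C·T          dR/dt = −k2·A·R        dP/dt = +k2·A·R

with C = free effector, T = target duplex, A = activated effector,
R = intact reporter, P = cleaved reporter (the fluorescence proxy).
Activation is irreversible and lumps binding, R-loop formation and nuclease
activation into one second-order constant. Model 2 adds reversible
sequestration of the *free* effector by one effective background species at
the total pool concentration:

    dC/dt += −k_ON,B·C·B + k_OFF,B·D,   dB/dt = −(…),   dD/dt = +(…)

Nothing else: activated effector does not bind background, sequestered
effector does not activate, target binding is not reversible, and there is
no gRNA-loading step (Cas12a at 60 nM is limiting against 150 nM gRNA and
loading is taken as complete at t = 0).

Defaults follow the standard assay composition: 60 nM effector, 6.7 nM
target, 200 nM reporter, 200 nM dsDNA background where present. Rate
constants are supplied in SI units (M⁻¹s⁻¹ / s⁻¹) and scaled internally
(second-order × 10⁻⁹ for nM). Integration uses LSODA with rtol 10⁻⁸ and
atol 10⁻⁶ nM on the experimental grid (1 point/min, 16 h, 961 points);
linear conservation (R+P, C+A+D, T+A, B+D) holds to well below 10⁻⁶ nM.
The independent oracle in the test suite is an explicit fixed-step RK4
integrator at 0.01-s steps, written directly against the reaction scheme.

### Two-stage fitting

Stage 1 fits (k_ON,T, k2) to a background-free trace on the 0–200 nM
scale; stage 2 freezes them and fits (k_ON,B, k_OFF,B) on a background
trace. Rather than manual tuning, both stages use bounded least squares in
log₁₀-parameter space (second-order rates 10¹–10⁹ M⁻¹s⁻¹, first-order
10⁻⁶–10² s⁻¹) with 8 starts (geometric centre of the bounds plus 7
log-uniform draws from a seeded generator) and early termination once the
RMS residual drops below 10⁻³ nM. The finite-difference step is fixed at
10⁻³ in log space so the gradient stays well above the integrator-accuracy
floor; without this the optimizer stalls about 1 % from the optimum on
noiseless data.

Identifiability: once sequestration is near equilibrium the trace
constrains mainly K_D,eff = k_OFF,B/k_ON,B; the absolute rates enter
through the early-time equilibration transient and are therefore much more
weakly determined. `ratio_profile` scans the residual along the
constant-K_D,eff valley — on the reference trace the RMS residual stays
below ~1 nM across a 100-fold range of k_ON,B, while noiseless refits
still land on the generating rates to ≪ 1 % because the valley has a true
minimum there. On noisy real data the ratio, not the individual rates,
is the robust quantity.

## Trace analysis

Processing order is subtract-then-normalize: the per-time-point mean of
the negative-control (no-target) wells is subtracted from each sample
trace (a scalar-offset mode exists because a single "background value" is
an equally defensible reading); traces are then scaled so the plateau —
mean of the last 30 samples, configurable — equals 200 (the reporter
concentration in nM). Transiently negative values after subtraction are
kept, not clipped.

t₀.₅ is the earliest *sampled* time at which the trace strictly exceeds
50 % of its own full-record maximum — no interpolation, so the resolution
is the 1-min sampling interval, and the threshold uses the per-sample
maximum, not the normalization constant. The kinetic ratio for a condition
is the mean ± sd (ddof = 1) of all pairwise t₀.₅ ratios between the
with-background and without-background replicate groups (9 for
triplicates). The mean of pairwise ratios is not the ratio of means;
r(A,B)·r(B,A) = 1 only when all replicates agree exactly, and the test
suite pins that identity only in the zero-spread case. Ratio groups are
compared with a two-sided Welch t-test (Welch–Satterthwaite df); it is
undefined (error) when both groups have zero variance.

## Slowdown expression

r(f_R, f_U) = exp[exp(f_U) + f_U/(f_R − c)] with c = 1.0423962, where f_R
and f_U are seed purine and uracil fractions. For f_R ∈ [0,1] and c > 1
the denominator is negative, so the two f_U terms pull in opposite
directions; the direction of the net f_U dependence varies with f_R
(increasing over all of [0,1] at f_R = 0; at f_R = 0.5 the expression
*decreases* until f_U ≈ 0.61). Monotonicity is therefore exposed as a
grid-check utility, never asserted globally. Only the expression family is
implemented — the symbolic-regression search that produced it is not
reproducible from its description — and c is the single refittable
parameter, fitted by bounded scalar least squares on (1, 3] (deterministic;
xatol 10⁻¹⁰). Refit on noiseless self-generated benchmark points recovers
c to < 10⁻⁴; the expression ranks the uracil-rich, purine-poor gRNA 7 seed
(predicted r ≈ 3.7) above the purine-rich gRNA 14 seed (≈ 1.5).

## Synthetic data

The generators define the study conditions the rest of the package is
exercised against:

* dsDNA pools: 5′-P1–N168–P2-3′, uniform i.i.d. core. The real primer
  flanks are not printed anywhere usable, so the module ships its own
  20-nt PAM-free flanks (validated by scanning, overridable).
* ssRNA pools: fully random 183-nt strands, no flanks.
* Designed variants are built per contract and *validated with the
  scanner* (generator/validator separation): V1 = PAM + scrambled seed
  (no seed-prefix match ≥ 4 nt) + spacer-matching distal 12-mer; V2 =
  non-PAM 4-mer + full protospacer, zero PAM hits on either strand; V3 =
  PAM + exact 8-nt seed + non-complementary filler; V4 = eight PAMs at
  21-nt spacing with non-complementary filler. "Non-complementary" is
  operationalized as no shared 4-mer between either candidate strand and
  the spacer sequence (threshold configurable); fillers also exclude
  T/A triples so no strand gains an accidental PAM. Designs are
  rejection-sampled (bounded attempts) and spacers whose own sequence
  makes a contract unsatisfiable raise a design error. The exact filler
  architecture and V4 spacing are this package's own choices; only the
  constraint structure is fixed.
* Plates: per condition, 3 replicate wells (Model 1 without background,
  Model 2 with) plus 3 no-target negative controls, sampled each minute
  for 16 h. Noise model (invented, not instrument-derived): additive
  Gaussian noise of sd 2 nM-equivalent per point, a per-well uniform
  baseline offset on [0, 20], and mean-one lognormal jitter with CV 0.05
  on k_ON,T per replicate — chosen once to resemble the spread of
  technical triplicates. All sampling flows through a single seeded
  generator; equal seeds give byte-identical FASTA/CSV output.

Because the noise model is invented, passing end-to-end tests demonstrate
pipeline closure (the analysis recovers the direction and, noiselessly, the
generating constants) — not that real plate data have these error
characteristics. Real traces add photobleaching, plate-edge effects,
well-to-well crosstalk and non-Gaussian outliers, none of which are
emulated; the published per-gRNA ratio values themselves are only
obtainable from the deposited raw data.

## Numerical choices and limitations

* Integrator LSODA (stiffness-switching); tests that assert conservation
  to 10⁻⁶ nM tighten to rtol 10⁻¹⁰/atol 10⁻⁹ nM.
* Fit bounds and multi-start counts as above; fits are deterministic given
  the seed. The trans-cleavage constant k2 has no published value; where a
  concrete number is needed (simulation studies, the acceptance script)
  k2 = 10⁴ M⁻¹s⁻¹ is used, and in recovery exercises any fixed choice
  cancels between generation and refit.
* Half-times are grid-valued by design; sub-minute changes in kinetics are
  invisible to r. Mean-of-ratios vs ratio-of-means is documented above.
* Monte-Carlo cross-checks use 10,000 sampled 168-nt duplexes (standard
  error ≈ 0.02 on a mean of 3.87) — the scale at which the scanner is an
  effective oracle for the analytic expectations.
* The pool model treats all decoys as one averaged species at the total
  pool concentration; per-sequence heterogeneity, partial-match
  thermodynamics and genome-scale search are out of scope.
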