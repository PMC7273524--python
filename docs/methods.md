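# Methods

This note records the models, numerical choices, and known limitations
behind each stage of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic exercise-test ECG

The generator emulates a standardized bicycle-ergometer protocol:
15 s of rest, 360 s of exercise with gradually increasing workload, and
60 s of recovery, recorded on one lead at 500 Hz (2 ms resolution).

**RR profile.** Rest beats are laid at constant RR (default 1000 ms),
anchored to the end of the phase so a phase of duration D holds exactly
⌊D/RR⌋ beats. During exercise the RR interval ramps linearly from
`rr_rest` to `rr_peak` (default 600 ms); the workload-to-heart-rate
mapping of a ramped bicycle test is not standardized, and a linear ramp
is the simplest profile consistent with a monotone workload increase.
During recovery RR relaxes exponentially toward `rr_recovery` (default
900 ms) with a 20 s time constant, the classic mono-exponential shape
of early heart-rate recovery.

**Morphology.** Each beat is a stylized QRS-T: a narrow triphasic QRS
(Q, R, S Gaussian bumps of widths 6–7 ms) and a single Gaussian T wave
of half-width σ centered 260 ms after the R apex. The Gaussian T is the
load-bearing choice: under the tangent method the steepest descent of
A·exp(−(t−μ)²/2σ²) lies at μ+σ and the tangent there crosses baseline
at exactly μ+2σ, so the generated beat carries a closed-form
ground-truth Tpe = 2σ. The per-phase Tpe targets (defaults 62, 55,
60 ms, matching a population median resting Tpe of 62 ms with a modest
rate-dependent shortening) are encoded by per-beat σ following the same
normalized time profile as RR. Optional white noise and a 0.3 Hz
sinusoidal baseline wander complete the record.

**What it does not emulate:** 12-lead morphology, P waves, ectopy,
pedalling artifact, QT/Tpe hysteresis, and beat-to-beat morphology
variability. Passing the recovery tests therefore demonstrates that the
processing chain is unbiased and sampling-limited on well-behaved
morphology, not that it is robust to every pathology of real
stress-test recordings.

## ECG processing

* Band-limiting: 4th-order Butterworth low-pass at 50 Hz plus 2nd-order
  Butterworth high-pass at 0.5 Hz, both applied forward–backward
  (zero phase) so fiducials are not displaced. Orders are a
  conventional choice; only the cutoffs are dictated by the problem
  (mains/muscle noise above, baseline wander below).
* QRS detection: band-pass 5–25 Hz, squaring, 120 ms moving-average
  energy envelope, peaks above 0.2× the 99.5th envelope percentile with
  a 250 ms refractory period, refined to the absolute band-passed
  maximum. Any detector meeting the ≥99 % sensitivity/PPV property on
  the synthetic records would serve equally.
* Signal averaging: beats inside the window (rest = first 15 s of the
  rest phase; peak = last 15 s of exercise; recovery = 15 s centered
  50 s after exercise end — the window edges are a documented
  convention, since only the window length and the 50 s anchor are
  given) are aligned on the R apex and averaged. Beats correlating
  < 0.9 with the median template are excluded (ectopy/artifact guard;
  the threshold is a documented substitute for unavailable cohort QC
  rules). Fewer than 3 usable beats is a QC failure for that window.

## Delineation

Baseline is the median of the 40 ms preceding QRS onset; QRS bounds are
found by amplitude decay below 2 % of the R amplitude. The T apex is
the absolute extremum of the baseline-corrected signal in a window from
120 ms after the R apex to min(450 ms, 0.75·RR), refined by three-point
parabolic interpolation (so inverted T waves behave identically; for
biphasic T waves the larger-|amplitude| lobe defines the apex — a
documented limitation). T end is the tangent-method crossing; the
descending limb is followed only while the wave stays above 5 % of the
apex amplitude, which stops the search before any following deflection.
All fiducials are reported in ms as floats; on noise-free Gaussian
templates the end-to-end Tpe error is below one sample (2 ms) across
the physiological 40–120 ms range, with a small negative bias
(≈0.4 ms) from evaluating the discrete gradient at the steepest sample.

## Traits

Responses use positive RR-change magnitudes (ΔRRex = RR_rest − RR_peak,
ΔRRrec = RR_rec − RR_peak), so the responses themselves may be
negative; a non-positive ΔRR is a QC failure, never silently clipped.
The alternative signed convention is a one-line change at the call
site since the responses are plain quotients. The inverse-normal
transform uses ranks with the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)),
average ranks for ties. Plausibility bounds (Tpe ∈ [20, 200] ms,
RR ∈ [300, 2000] ms, configurable via YAML) stand in for cohort-level
phenotypic QC whose exact rules are not public; the rule is monotone in
the bounds.

## Association and variance components

Per-variant association is exact OLS via Frisch–Waugh residualization
(trait and dosages projected off the covariates + intercept), Wald
two-sided p from the t distribution with n − k − 1 df. On unrelated,
unstructured simulated individuals this is the correct desk-scale
analogue of the mixed-model machinery used at biobank scale — the mixed
model exists there to absorb relatedness and scale, both absent here by
construction. That scalability machinery is deliberately not
reproduced. Variants below 1 % MAF or monomorphic in the analyzed
samples are skipped; the effect allele is ALT as loaded, and allele
relabelling maps (β, EAF) → (−β, 1−EAF) with an identical p.

Conditional analysis adds the lead dosage to the covariates and tests
the candidate in the joint model; a candidate within r² > 1−1e−10 of
the lead is unidentifiable and is dropped with a flag at p = 1 (the
conservative report: it can never be declared independent).

Heritability is Haseman–Elston regression: products of standardized
trait values over individual pairs regressed (with intercept) on
off-diagonal GRM entries, GRM = ZZ′/m from column-standardized
dosages. Under the generating model E[y_i y_j | A] = h²·A_ij, so the
slope estimates h²; the bivariate form with symmetrized cross-trait
products estimates the genetic covariance and r_g = cov_g/√(v_a v_b).
Standard errors are delete-block jackknives over 20 individual blocks,
with the full ratio re-estimated per deleted block for r_g. At the
desk scale used in the acceptance run (n = 4,000, m = 2,000) the
jackknife SE is ≈ 2–3 percentage points for h² and ≈ 0.2 for r_g —
method-of-moments estimators are noisy at this size, which is why the
recovery criteria are stated in SE units. r_g is undefined (flagged)
when either genetic-variance estimate is non-positive.

The generator makes the *realized* quantities exact: genetic values are
rescaled to variance exactly h² and the second trait's genetic value is
built from an orthogonalized independent polygenic score so the
realized genetic correlation equals r_g to machine precision. Recovery
error in the tests is therefore attributable to the estimator alone.

## Multi-stage decisions

Loci: greedy, smallest p first, absorbing unassigned candidates
(p < 1×10⁻⁶) on the same chromosome within 500 kb of the lead. The
boundary convention is that exactly 500,000 bp is absorbed (≤ absorbs);
the partition and lead-minimality properties are tested. Replication
uses the exact threshold α/m (its 2-significant-figure rounding, e.g.
0.05/21 = 2.4×10⁻³, is reported for display) plus direction
concordance; full-dataset significance is p ≤ 5×10⁻⁸ inclusive and
excludes already-replicated loci. The secondary-signal rule is the
printed three-condition conjunction (p_sec < 10⁻⁶;
−log₁₀(p_lead)/−log₁₀(p_sec) < 1.5; −log₁₀(p_sec)/−log₁₀(p_cond) < 1.5)
and is monotone in p_cond. Sex-stratified scans drop sex from the
covariates; a variant is sex-specific if genome-wide significant in one
sex but not in the sex-adjusted combined scan.

Percent variance explained follows the two-model definition: residuals
from the covariate regression are fitted on the top ten genotype PCs
alone and on PCs + identified variants; PVE is the adjusted-R²
difference (duplicated variant columns dropped and flagged). Note a
property of this definition at small variant panels: with m variants,
k random PCs overlap the causal direction by ≈ k/m and absorb that
share into the baseline model, biasing the increment low; at realistic
panel sizes (m ≫ k) the effect is negligible, and the tests use
m = 500 so it stays below the Monte-Carlo error.

The tally reports replicated + additional lead SNVs, secondary signals,
totals, and round(100·PVE/h²) as an integer percent.

## Genetic risk score

Scores are weighted ALT-dosage sums with weights taken verbatim from
source summary statistics; missing calls are mean-imputed. The cutoff
scan fits logistic(outcome ~ standardized score) per cutoff on a
log-spaced grid (5×10⁻⁸ … 1, 20 points by default) in the training
split and keeps the smallest association p — the conventional criterion
for threshold optimization. Validation is a single logistic fit in the
held-out split; the stratified train/validation split fixes prevalence
across subsets by construction. Distance-based clumping is available
in principle but unnecessary for the default generators, which simulate
linkage equilibrium. The binary outcome follows a liability-threshold
model (standardized liability over the Φ⁻¹(1−prevalence) quantile;
default prevalence 0.6 %, the rarity of hard arrhythmic endpoints in a
healthy middle-aged cohort). Under a null outcome the two-step design
keeps the validation p uniform — asserted by simulation in the suite.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; there is no global
RNG state, and all generators are bit-reproducible given the seed. The
acceptance run uses n = 4,000 individuals × 2,000 variants for the
variance-components recoveries and 200 recordings for the ECG-chain
median — sizes at which the estimators' sampling error is honestly
reported alongside the estimates and each recovery completes in
seconds on one core. Null-calibration suites use smaller cohorts
(≈1,000–2,000 individuals) with 60–100 replicates.
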