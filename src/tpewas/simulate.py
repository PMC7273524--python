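"""Synthetic-data generators with known ground truth.

Everything downstream of this module — ECG processing, T-wave
delineation, trait assembly, association and risk-score analyses — is
exercised on data produced here, so each generator logs the truth it
embeds (per-beat Tpe, per-individual genetic values, causal effects).

The exercise-test generator emulates a bicycle-ergometer protocol:
15 s of rest, 6 min of exercise with gradually increasing workload, and
1 min of recovery without pedalling, recorded on a single lead at
500 Hz.  Heart rate rises linearly with workload during exercise and
relaxes exponentially during recovery; the T-wave is a Gaussian bump
whose width carries the ground-truth Tpeak-to-Tend (Tpe) interval in
closed form.

The genotype generator draws unrelated diploid individuals in
Hardy-Weinberg equilibrium and linkage equilibrium, builds quantitative
traits with a chosen narrow-sense heritability h2 (optionally two
traits with genetic correlation rg), and draws a rare binary outcome
under a liability-threshold model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import EcgRecording, PhaseAnnotation
from .exceptions import InvalidParameterError

__all__ = [
    "ExerciseProtocol",
    "BeatTemplate",
    "GeneticArchitecture",
    "SimulatedEcg",
    "GenotypeCohort",
    "simulate_ecg",
    "simulate_cohort",
    "simulate_covariates",
    "simulate_binary_outcome",
]

#: Nominal distance (ms) from QRS onset to the R apex in the template.
QRS_ONSET_TO_R_MS = 40.0

#: Recovery heart-rate relaxation time constant (s).
RECOVERY_TAU_S = 20.0


@dataclass(frozen=True)
class ExerciseProtocol:
    """Timing and heart-rate targets of the exercise stress test.

    Defaults follow the standard bicycle protocol: 15 s rest, 6 min of
    exercise, 1 min recovery.  ``rr_rest``/``rr_peak``/``rr_recovery``
    are the RR intervals (ms) at rest, at peak exercise, and the
    asymptote approached during recovery.
    """

    rest_duration: float = 15.0
    exercise_duration: float = 360.0
    recovery_duration: float = 60.0
    rr_rest: float = 1000.0
    rr_peak: float = 600.0
    rr_recovery: float = 900.0

    def __post_init__(self):
        for name in ("rest_duration", "exercise_duration", "recovery_duration"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0 < self.rr_peak < self.rr_rest):
            raise InvalidParameterError("require 0 < rr_peak < rr_rest")
        if not (self.rr_peak < self.rr_recovery):
            raise InvalidParameterError("require rr_peak < rr_recovery")

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.exercise_duration + self.recovery_duration

    @property
    def delta_rr_ex(self) -> float:
        """Magnitude of the rest -> peak-exercise RR change (ms)."""
        return self.rr_rest - self.rr_peak

    @property
    def delta_rr_rec(self) -> float:
        """Magnitude of the peak-exercise -> recovery RR change (ms)."""
        return self.rr_recovery - self.rr_peak

    def phases(self) -> list[PhaseAnnotation]:
        r, e = self.rest_duration, self.exercise_duration
        return [
            PhaseAnnotation("rest", 0.0, r),
            PhaseAnnotation("exercise", r, r + e),
            PhaseAnnotation("recovery", r + e, r + e + self.recovery_duration),
        ]


@dataclass(frozen=True)
class BeatTemplate:
    """Stylized QRS-T morphology used to synthesize beats.

    The QRS is a narrow triphasic complex (Q, R, S Gaussian bumps); the
    T wave is a single Gaussian of half-width ``t_sigma`` centered
    ``t_center_offset`` ms after QRS onset.  For a Gaussian T the
    tangent-method T-end lands at mu + 2 sigma, so the ground-truth Tpe
    is exactly ``2 * t_sigma`` — this closed form is what makes the
    template useful as a delineation oracle.
    """

    qrs_amplitude: float = 1.0  # mV
    t_amplitude: float = 0.3  # mV
    t_center_offset: float = 300.0  # ms from QRS onset
    t_sigma: float = 31.0  # ms

    def __post_init__(self):
        if self.t_sigma <= 0:
            raise InvalidParameterError("t_sigma must be > 0")
        if self.t_amplitude == 0:
            raise InvalidParameterError("t_amplitude must be nonzero")

    @property
    def tpe_true(self) -> float:
        """Closed-form Tpeak-to-Tend interval (ms) of the Gaussian T."""
        return 2.0 * self.t_sigma


@dataclass
class SimulatedEcg:
    """A synthetic recording plus the per-beat ground truth behind it."""

    recording: EcgRecording
    truth: pd.DataFrame  # columns: time_s, phase, rr_ms, tpe_ms
    protocol: ExerciseProtocol
    template: BeatTemplate
    tpe_by_phase: tuple[float, float, float]

    def truth_tpe(self, phase: str) -> float:
        """Ground-truth Tpe (ms) at the named protocol landmark."""
        idx = {"rest": 0, "peak": 1, "recovery": 2}[phase]
        return self.tpe_by_phase[idx]


def _beat_times_and_profiles(
    protocol: ExerciseProtocol, tpe_by_phase: tuple[float, float, float]
) -> pd.DataFrame:
    """Place beats along the protocol and attach per-beat RR / Tpe truth.

    Rest beats are laid out at constant RR (the first at RR/2 so the
    rest phase holds exactly ``floor(duration / RR)`` beats); exercise
    RR ramps linearly from rr_rest to rr_peak; recovery RR relaxes
    exponentially toward rr_recovery with a 20 s time constant.  The
    ground-truth Tpe follows the same normalized time profile.
    """
    p = protocol
    tpe_rest, tpe_peak, tpe_rec = tpe_by_phase
    rows: list[tuple[float, str, float, float]] = []

    # Rest beats anchored to the end of the phase so the phase holds
    # exactly floor(duration / RR) beats for any RR.
    rr_s = p.rr_rest / 1000.0
    n_rest = int(np.floor(p.rest_duration / rr_s))
    first = p.rest_duration - rr_s / 2.0 - (n_rest - 1) * rr_s
    t = first
    for _ in range(n_rest):
        rows.append((t, "rest", p.rr_rest, tpe_rest))
        t += rr_s
    # continue from the last rest beat into exercise
    ex0, ex1 = p.rest_duration, p.rest_duration + p.exercise_duration
    rec1 = ex1 + p.recovery_duration

    def rr_at(time_s: float) -> float:
        if time_s < ex0:
            return p.rr_rest
        if time_s < ex1:
            f = (time_s - ex0) / p.exercise_duration
            return p.rr_rest + (p.rr_peak - p.rr_rest) * f
        dt = time_s - ex1
        return p.rr_recovery - (p.rr_recovery - p.rr_peak) * np.exp(-dt / RECOVERY_TAU_S)

    def tpe_at(time_s: float) -> float:
        if time_s < ex0:
            return tpe_rest
        if time_s < ex1:
            f = (time_s - ex0) / p.exercise_duration
            return tpe_rest + (tpe_peak - tpe_rest) * f
        dt = time_s - ex1
        return tpe_rec - (tpe_rec - tpe_peak) * np.exp(-dt / RECOVERY_TAU_S)

    while t < rec1:
        phase = "rest" if t < ex0 else ("exercise" if t < ex1 else "recovery")
        rows.append((t, phase, rr_at(t), tpe_at(t)))
        t += rr_at(t) / 1000.0

    return pd.DataFrame(rows, columns=["time_s", "phase", "rr_ms", "tpe_ms"])


def simulate_ecg(
    protocol: ExerciseProtocol | None = None,
    template: BeatTemplate | None = None,
    tpe_by_phase: tuple[float, float, float] = (62.0, 55.0, 60.0),
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
    fs: float = 500.0,
    seed: int = 0,
) -> SimulatedEcg:
    """Synthesize one exercise-test ECG with known per-beat Tpe.

    Parameters
    ----------
    tpe_by_phase:
        Ground-truth Tpe (ms) at rest, peak exercise, and recovery; the
        per-beat T width is ``tpe / 2`` (Gaussian closed form).
    noise_sd:
        White-noise standard deviation in mV.
    wander_amp:
        Amplitude (mV) of a 0.3 Hz sinusoidal baseline wander.
    """
    protocol = protocol or ExerciseProtocol()
    template = template or BeatTemplate(t_sigma=tpe_by_phase[0] / 2.0)
    if fs <= 0:
        raise InvalidParameterError(f"fs must be > 0, got {fs}")
    if any(v <= 0 for v in tpe_by_phase):
        raise InvalidParameterError("tpe_by_phase entries must be > 0")

    rng = np.random.default_rng(seed)
    beats = _beat_times_and_profiles(protocol, tpe_by_phase)

    n = int(round(protocol.total_duration * fs))
    x = np.zeros(n)
    t_axis = np.arange(n) / fs

    def add_gauss(center_s: float, amp: float, sigma_ms: float):
        sigma_s = sigma_ms / 1000.0
        lo = max(0, int((center_s - 5 * sigma_s) * fs))
        hi = min(n, int((center_s + 5 * sigma_s) * fs) + 1)
        if hi <= lo:
            return
        tt = t_axis[lo:hi] - center_s
        x[lo:hi] += amp * np.exp(-0.5 * (tt / sigma_s) ** 2)

    a = template.qrs_amplitude
    for time_s, _, _, tpe_ms in beats.itertuples(index=False):
        # triphasic QRS around the R apex
        add_gauss(time_s - 0.025, -0.15 * a, 6.0)
        add_gauss(time_s, a, 7.0)
        add_gauss(time_s + 0.025, -0.20 * a, 6.0)
        # Gaussian T: width carries the ground-truth Tpe
        t_center = time_s + (template.t_center_offset - QRS_ONSET_TO_R_MS) / 1000.0
        add_gauss(t_center, template.t_amplitude, tpe_ms / 2.0)

    if wander_amp > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        x += wander_amp * np.sin(2 * np.pi * 0.3 * t_axis + phase0)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)

    rec = EcgRecording(samples=x, fs=fs, phases=protocol.phases())
    return SimulatedEcg(
        recording=rec,
        truth=beats,
        protocol=protocol,
        template=template,
        tpe_by_phase=tuple(tpe_by_phase),
    )


# ---------------------------------------------------------------------------
# genotypes and quantitative traits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticArchitecture:
    """Generating model for a genotype cohort and its traits.

    ``h2`` is the narrow-sense heritability (fraction of trait variance
    from additive genetic values); ``rg`` the genetic correlation
    between the two generated traits.  ``causal_effects``, if given,
    are fixed per-variant effects in trait-SD units per standardized
    allele applied to the first trait on top of the polygenic
    background.
    """

    n_individuals: int = 4000
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.156
    rg: float = 0.0
    causal_effects: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.h2 <= 1.0):
            raise InvalidParameterError(f"h2 must lie in [0, 1], got {self.h2}")
        if abs(self.rg) > 1.0:
            raise InvalidParameterError(f"|rg| must be <= 1, got {self.rg}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidParameterError(f"maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_individuals < 2 or self.n_variants < 1:
            raise InvalidParameterError("need >= 2 individuals and >= 1 variant")


@dataclass
class GenotypeCohort:
    """Individuals x variants hard-call dosage matrix with metadata.

    ``dosages`` holds ALT-allele counts in {0, 1, 2}; ``variants`` has
    one row per variant (snv_id, chrom, pos, ref, alt, eaf).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise InvalidParameterError("dosage matrix shape mismatch")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        """Effect (ALT) allele frequency per variant on current samples."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        eaf = self.eaf()
        return np.minimum(eaf, 1.0 - eaf)

    def standardized(self) -> np.ndarray:
        """Column-standardized dosage matrix (mean 0, unit variance)."""
        g = self.dosages.astype(float)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (g - mu) / sd

    def subset(self, sample_mask: np.ndarray) -> "GenotypeCohort":
        mask = np.asarray(sample_mask)
        return GenotypeCohort(
            dosages=self.dosages[mask],
            variants=self.variants.copy(),
            sample_ids=self.sample_ids[mask],
        )

    def column(self, snv_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["snv_id"] == snv_id]
        if len(idx) == 0:
            raise KeyError(f"variant {snv_id!r} not in cohort")
        return self.dosages[:, int(idx[0])].astype(float)


def _variant_frame(m: int, mafs: np.ndarray) -> pd.DataFrame:
    # spread variants round-robin over 22 autosomes, 2 Mb apart, so
    # linkage-equilibrium variants also fall in distinct distance loci
    chrom = 1 + (np.arange(m) % 22)
    pos = 1 + (np.arange(m) // 22) * 2_000_000
    return pd.DataFrame(
        {
            "snv_id": [f"snv{j:05d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "eaf": mafs,
        }
    )


def simulate_cohort(
    arch: GeneticArchitecture,
) -> tuple[GenotypeCohort, pd.DataFrame]:
    """Draw a genotype cohort and two quantitative traits.

    Genotypes are Binomial(2, MAF) per variant (Hardy-Weinberg,
    linkage equilibrium).  Trait A is built as fixed causal effects (if
    any) plus a polygenic background over all variants; its realized
    genetic value is rescaled to variance exactly ``h2`` so the
    generating heritability is exact in-sample.  Trait B carries an
    independent polygenic value combined with trait A's so the realized
    genetic correlation equals ``rg`` exactly; residuals are independent
    Gaussian with variance ``1 - h2``.

    Returns the cohort and a trait table with columns
    ``id, trait_a, trait_b, genetic_a, genetic_b``.
    """
    rng = np.random.default_rng(arch.seed)
    n, m = arch.n_individuals, arch.n_variants
    mafs = rng.uniform(arch.maf_range[0], arch.maf_range[1], size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    cohort = GenotypeCohort(
        dosages=dosages,
        variants=_variant_frame(m, mafs),
        sample_ids=np.array([f"id{i:06d}" for i in range(n)]),
    )

    z = cohort.standardized()

    def polygenic() -> np.ndarray:
        u = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
        return z @ u

    def scale_to(g: np.ndarray, var: float) -> np.ndarray:
        sd = g.std()
        if sd == 0 or var == 0:
            return np.zeros_like(g)
        return g * (np.sqrt(var) / sd)

    if arch.causal_effects is not None:
        beta = np.asarray(arch.causal_effects, dtype=float)
        if beta.shape != (m,):
            raise InvalidParameterError("causal_effects must have one entry per variant")
        if float(beta @ beta) > arch.h2 + 1e-8:
            raise InvalidParameterError(
                f"nominal fixed-effect variance {float(beta @ beta):.4f} exceeds h2={arch.h2}"
            )
        g_fixed = z @ beta
        var_fixed = float(np.var(g_fixed))
        g_a = g_fixed + scale_to(polygenic(), max(arch.h2 - var_fixed, 0.0))
        g_a = scale_to(g_a, arch.h2) if arch.h2 > 0 else np.zeros(n)
    else:
        g_a = scale_to(polygenic(), arch.h2)

    # independent polygenic value, orthogonalized against g_a so the
    # realized genetic correlation is exactly rg
    g_ind = polygenic()
    if arch.h2 > 0 and g_a.std() > 0:
        ga_c = g_a - g_a.mean()
        g_ind = g_ind - (g_ind @ ga_c) / (ga_c @ ga_c) * ga_c
    g_ind = scale_to(g_ind, arch.h2)
    g_b = arch.rg * g_a + np.sqrt(max(1.0 - arch.rg**2, 0.0)) * g_ind

    e_sd = np.sqrt(max(1.0 - arch.h2, 0.0))
    trait_a = g_a + rng.normal(0.0, e_sd, size=n)
    trait_b = g_b + rng.normal(0.0, e_sd, size=n)

    traits = pd.DataFrame(
        {
            "id": cohort.sample_ids,
            "trait_a": trait_a,
            "trait_b": trait_b,
            "genetic_a": g_a,
            "genetic_b": g_b,
        }
    )
    return cohort, traits


def simulate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Draw a plausible covariate table (sex, age, BMI, smoking,
    diabetes, genotyping-array indicator) for ``n`` individuals.

    Covariates are independent of genotypes; association models adjust
    for them so the adjustment machinery is exercised without changing
    the generating heritability.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.uniform(40, 70, size=n),
            "bmi": rng.normal(27.0, 4.0, size=n),
            "smoking": rng.binomial(1, 0.1, size=n),
            "diabetes": rng.binomial(1, 0.05, size=n),
            "array": rng.binomial(1, 0.5, size=n),
        }
    )


def simulate_binary_outcome(
    cohort: GenotypeCohort,
    weights: np.ndarray,
    prevalence: float = 0.006,
    seed: int = 0,
) -> np.ndarray:
    """Draw a rare binary outcome under a liability-threshold model.

    The liability is the weighted standardized-dosage score plus unit
    Gaussian noise; individuals whose standardized liability exceeds the
    normal quantile at ``1 - prevalence`` are cases, so the empirical
    prevalence matches the target within binomial error.  The default
    prevalence (0.6%) matches a rare arrhythmic endpoint in a healthy
    middle-aged population.
    """
    from scipy.stats import norm

    if not (0.0 < prevalence < 1.0):
        raise InvalidParameterError(f"prevalence must lie in (0, 1), got {prevalence}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (cohort.n_variants,):
        raise InvalidParameterError("weights must have one entry per variant")
    rng = np.random.default_rng(seed)
    n = cohort.n_individuals
    liability = rng.normal(0.0, 1.0, size=n)
    if np.any(w != 0):
        liability = liability + cohort.standardized() @ w
    sd = liability.std()
    if sd > 0:
        liability = (liability - liability.mean()) / sd
    thr = norm.ppf(1.0 - prevalence)
    return (liability > thr).astype(int)
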