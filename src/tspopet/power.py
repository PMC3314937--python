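"""Population simulation and sample-size calculation for TSPO PET studies.

Two study designs are covered, both at 90% power and two-sided alpha 0.05 by
default:

* within-subject (longitudinal): each simulated subject is scanned at a
  control TSPO density and again after a 50% or 400% Bmax increase (K1 and k2
  fixed within subject); the paired t-test sample size is computed from the
  mean and SD of the per-subject change in estimated BP_ND.

* between-subject (disease characterisation): independent control and
  diseased cohorts are simulated, either within one binding class (class
  known a priori; Welch two-sample t-test) or as an ethnic-group mixture of
  HABs/MABs/LABs with fixed class proportions (class unknown; the mixture is
  not normal, so the t-test sample size is corrected by the Pitman
  asymptotic relative efficiency of the Mann-Whitney U test).

Group moments always come from the *estimated* BP_ND of fitted noisy TACs,
not from the generative values, so measurement noise propagates into the
sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import stats

from ._expsum import ExpSum
from .kinetics import (
    FrameSchedule,
    InputFunction,
    NoiseModel,
    TimeActivityCurve,
    add_noise,
    apply_decay,
    default_schedule,
    synth_input,
)
from .estimation import DEFAULT_NOISE_SCALE, bp_from_fits, fit_1tc
from .ligands import (
    BindingClass,
    LigandRecord,
    PhysiologicalConstants,
    PopulationFrequencies,
)
from .prediction import CONTROL, DiseaseState, binding_potential, predict_kinetics

__all__ = [
    "VariabilitySpec",
    "PowerSettings",
    "SimulatedSubject",
    "ClassPopulation",
    "MixturePopulation",
    "StudyResult",
    "paired_power",
    "paired_sample_size",
    "welch_power",
    "welch_sample_size",
    "mannwhitney_sample_size",
    "simulate_class_population",
    "simulate_mixture",
    "within_subject_result",
    "between_known_result",
    "between_unknown_result",
]


@dataclass(frozen=True)
class VariabilitySpec:
    """Inter-subject coefficients of variation on K1, k2 and Bmax."""

    cv_k1: float = 0.10
    cv_k2: float = 0.10
    cv_bmax: float = 0.25

    def __post_init__(self):
        if min(self.cv_k1, self.cv_k2, self.cv_bmax) < 0:
            raise ValueError("CVs must be >= 0")

    @classmethod
    def within_subject(cls) -> "VariabilitySpec":
        return cls(0.10, 0.10, 0.25)

    @classmethod
    def between_subject(cls) -> "VariabilitySpec":
        return cls(0.10, 0.20, 0.25)


@dataclass(frozen=True)
class PowerSettings:
    """Target power, significance level and the Pitman A.R.E. used to convert
    a t-test sample size into a Mann-Whitney one (3/pi: Wilcoxon vs t under
    normality)."""

    power: float = 0.90
    alpha: float = 0.05
    are_constant: float = 3.0 / math.pi

    def __post_init__(self):
        if not 0 < self.alpha < self.power < 1:
            raise ValueError("require 0 < alpha < power < 1")
        if not self.are_constant > 0:
            raise ValueError("are_constant must be > 0")


# ---------------------------------------------------------------------------
# sample-size solvers (noncentral t)
# ---------------------------------------------------------------------------

def _nct_power(tcrit: float, df: float, ncp: float) -> float:
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral t underflows to NaN in the far tail; it is zero there
    upper = 0.0 if not np.isfinite(upper) else upper
    lower = 0.0 if not np.isfinite(lower) else lower
    return float(upper + lower)


def paired_power(n: int, mean_delta: float, sd_delta: float,
                 alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test with n pairs."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = math.sqrt(n) * abs(mean_delta) / sd_delta
    return _nct_power(stats.t.ppf(1 - alpha / 2, df), df, ncp)


def paired_sample_size(
    mean_delta: float,
    sd_delta: float,
    settings: PowerSettings | None = None,
    n_max: int = 100000,
) -> int:
    """Smallest number of paired subjects with paired-t power >= target."""
    settings = settings or PowerSettings()
    if mean_delta == 0:
        raise ValueError("no finite sample size for zero mean difference")
    if not sd_delta > 0:
        return 2
    n = 2
    while n <= n_max:
        if paired_power(n, mean_delta, sd_delta, settings.alpha) >= settings.power:
            return n
        n += 1
    raise RuntimeError(f"sample size exceeds {n_max}")


def welch_power(n: int, mean_diff: float, sd1: float, sd2: float,
                alpha: float = 0.05) -> float:
    """Power of the two-sided Welch t-test with n subjects per group."""
    if n < 2:
        return 0.0
    v1, v2 = sd1**2 / n, sd2**2 / n
    df = (v1 + v2) ** 2 / (v1**2 / (n - 1) + v2**2 / (n - 1))
    ncp = abs(mean_diff) / math.sqrt(v1 + v2)
    return _nct_power(stats.t.ppf(1 - alpha / 2, df), df, ncp)


def welch_sample_size(
    mean_diff: float,
    sd_control: float,
    sd_disease: float,
    settings: PowerSettings | None = None,
    n_max: int = 100000,
) -> int:
    """Smallest per-group n (equal allocation) with Welch power >= target."""
    settings = settings or PowerSettings()
    if mean_diff == 0:
        raise ValueError("no finite sample size for zero group difference")
    if not (sd_control > 0 and sd_disease > 0):
        raise ValueError("group SDs must be > 0")
    n = 2
    while n <= n_max:
        if welch_power(n, mean_diff, sd_control, sd_disease,
                       settings.alpha) >= settings.power:
            return n
        n += 1
    raise RuntimeError(f"sample size exceeds {n_max}")


def mannwhitney_sample_size(welch_n: int,
                            settings: PowerSettings | None = None) -> int:
    """Mann-Whitney U sample size via the Pitman A.R.E. correction:
    ceil(t-test n / A.R.E.)."""
    settings = settings or PowerSettings()
    return math.ceil(welch_n / settings.are_constant)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSubject:
    """One simulated subject: drawn kinetics plus per-state BP_ND estimates."""

    cls: BindingClass
    k1: float
    k2: float
    bmax_factor: float
    bp_nd_estimates: Mapping[float, float]  # bmax multiplier -> estimate


@dataclass(frozen=True)
class ClassPopulation:
    """Simulated subjects of a single binding class.

    ``bp_hat[m]`` holds the estimated BP_ND of every subject at Bmax
    multiplier ``m``; within one subject the same K1/k2/Bmax draw underlies
    every state (only measurement noise is re-drawn per scan).
    """

    ligand: str
    cls: BindingClass
    multipliers: tuple[float, ...]
    k1: np.ndarray
    k2: np.ndarray
    bmax_factor: np.ndarray
    bp_true: Mapping[float, np.ndarray]
    bp_hat: Mapping[float, np.ndarray]
    n_truncated: int = 0
    n_resampled: int = 0

    @property
    def n(self) -> int:
        return self.k1.size

    def subjects(self) -> Iterator[SimulatedSubject]:
        for i in range(self.n):
            yield SimulatedSubject(
                cls=self.cls,
                k1=float(self.k1[i]),
                k2=float(self.k2[i]),
                bmax_factor=float(self.bmax_factor[i]),
                bp_nd_estimates={m: float(self.bp_hat[m][i])
                                 for m in self.multipliers},
            )

    def delta_bp(self, multiplier: float) -> np.ndarray:
        """Per-subject change in estimated BP_ND relative to control."""
        return self.bp_hat[multiplier] - self.bp_hat[1.0]


@dataclass(frozen=True)
class MixturePopulation:
    """A fixed-proportion mixture of binding classes scanned at one or more
    disease states.

    The same subjects (same K1/k2/Bmax draws) underlie every state; only the
    Bmax multiplier and the per-scan measurement noise differ, mirroring the
    "one population, healthy and diseased groups" design.
    """

    ligand: str
    ethnicity: str
    multipliers: tuple[float, ...]
    cls: np.ndarray  # per-subject BindingClass
    bp_hat: Mapping[float, np.ndarray]

    @property
    def n(self) -> int:
        return self.cls.size

    def mean(self, multiplier: float) -> float:
        x = self.bp_hat[multiplier]
        return float(np.mean(x[np.isfinite(x)]))

    def sd(self, multiplier: float) -> float:
        x = self.bp_hat[multiplier]
        return float(np.std(x[np.isfinite(x)], ddof=1))


@dataclass(frozen=True)
class StudyResult:
    """Sample-size output row (the quantities behind a study-design table)."""

    design: str  # within | between_known | between_unknown
    ligand: str
    group: str  # binding class or ethnicity
    increase: float  # fractional Bmax increase (0.5 or 4.0)
    mean_effect: float
    sd_control: float | None
    sd_disease: float | None
    sd_delta: float | None
    n_required: int
    extras: dict = field(default_factory=dict)


def _truncated_factors(rng: np.random.Generator, cv: float, n: int):
    """N(1, cv) factors truncated at zero by resampling; returns factors and
    the number of rejected draws."""
    if cv == 0:
        return np.ones(n), 0
    x = rng.normal(1.0, cv, n)
    n_trunc = 0
    while True:
        bad = x <= 0
        k = int(bad.sum())
        if k == 0:
            return x, n_trunc
        n_trunc += k
        x[bad] = rng.normal(1.0, cv, k)


def _estimate_bp_once(
    k1: float,
    k2: float,
    bp: float,
    input_fn: InputFunction,
    v_b: float,
    schedule: FrameSchedule,
    isotope,
    noise: NoiseModel,
    rng: np.random.Generator,
    max_retries: int = 5,
):
    """Simulate one scan (noisy total + ND TAC), fit both, return the BP_ND
    estimate and how many noise re-draws a fit failure forced."""
    k2_app = k2 / (1.0 + bp)
    blood = input_fn.blood_expsum.scale(v_b)
    total_es = input_fn.plasma_expsum.convolve_exp(k2_app).scale((1 - v_b) * k1) + blood
    nd_es = input_fn.plasma_expsum.convolve_exp(k2).scale((1 - v_b) * k1) + blood
    total = TimeActivityCurve(schedule,
                              total_es.frame_means(schedule.starts, schedule.ends),
                              isotope)
    nd = TimeActivityCurve(schedule,
                           nd_es.frame_means(schedule.starts, schedule.ends),
                           isotope)
    total_raw = apply_decay(total, "uncorrect")
    nd_raw = apply_decay(nd, "uncorrect")
    for retry in range(max_retries + 1):
        t_fit = fit_1tc(apply_decay(add_noise(total_raw, noise, rng), "correct"),
                        input_fn, v_b)
        n_fit = fit_1tc(apply_decay(add_noise(nd_raw, noise, rng), "correct"),
                        input_fn, v_b)
        try:
            return bp_from_fits(t_fit, n_fit), retry
        except ValueError:
            continue
    return np.nan, max_retries


def simulate_class_population(
    record: LigandRecord,
    cls: BindingClass,
    variability: VariabilitySpec | None = None,
    multipliers: Sequence[float] = (1.0, 1.5, 5.0),
    n: int = 1000,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    input_fn: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    constants: PhysiologicalConstants | None = None,
) -> ClassPopulation:
    """Simulate-and-fit a population of one binding class at several states.

    Each subject draws K1, k2 and Bmax factors (truncated-at-zero normal with
    the configured CVs); states share the subject's draws, and every scan gets
    fresh measurement noise.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    variability = variability or VariabilitySpec.within_subject()
    noise = noise if noise is not None else NoiseModel(DEFAULT_NOISE_SCALE)
    input_fn = input_fn or synth_input()
    schedule = schedule or default_schedule()
    constants = constants or PhysiologicalConstants()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    kp = predict_kinetics(record, constants)
    bp0 = kp.bp_nd[cls]
    isotope = record.properties.isotope

    f_k1, trunc_k1 = _truncated_factors(rng, variability.cv_k1, n)
    f_k2, trunc_k2 = _truncated_factors(rng, variability.cv_k2, n)
    f_bm, trunc_bm = _truncated_factors(rng, variability.cv_bmax, n)
    k1 = kp.k1 * f_k1
    k2 = kp.k2 * f_k2

    multipliers = tuple(float(m) for m in multipliers)
    bp_true = {m: bp0 * f_bm * m for m in multipliers}
    bp_hat = {m: np.empty(n) for m in multipliers}
    n_resampled = 0
    for i in range(n):
        for m in multipliers:
            est, retries = _estimate_bp_once(
                k1[i], k2[i], bp_true[m][i], input_fn, constants.v_b,
                schedule, isotope, noise, rng,
            )
            n_resampled += retries
            bp_hat[m][i] = est
    return ClassPopulation(
        ligand=record.name,
        cls=cls,
        multipliers=multipliers,
        k1=k1,
        k2=k2,
        bmax_factor=f_bm,
        bp_true=bp_true,
        bp_hat=bp_hat,
        n_truncated=trunc_k1 + trunc_k2 + trunc_bm,
        n_resampled=n_resampled,
    )


def _mixture_counts(freqs: PopulationFrequencies, n: int) -> dict[BindingClass, int]:
    """Fixed class counts by largest remainder; classes rounding to zero are
    dropped (with the proportions renormalized implicitly by the fixed n)."""
    raw = {c: freqs.proportions[c] * n for c in BindingClass}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(BindingClass, key=lambda c: raw[c] - counts[c], reverse=True):
        if short <= 0:
            break
        counts[c] += 1
        short -= 1
    return counts


def simulate_mixture(
    record: LigandRecord,
    frequencies: PopulationFrequencies,
    variability: VariabilitySpec | None = None,
    multipliers: Sequence[float] = (1.0, 1.5),
    n: int = 1000,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    **kwargs,
) -> MixturePopulation:
    """Simulate a population containing all binding classes at fixed
    proportions, scanned at each Bmax multiplier.

    Class counts are frequency * n (largest-remainder rounding) and, since
    the subjects are shared, automatically identical in the control and
    diseased groups; a class whose count rounds to zero is omitted with a
    warning.
    """
    variability = variability or VariabilitySpec.between_subject()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    multipliers = tuple(float(m) for m in multipliers)
    counts = _mixture_counts(frequencies, n)
    cls_arr: list[BindingClass] = []
    bp_arr = {m: [] for m in multipliers}
    for cls in BindingClass:
        k = counts[cls]
        if k == 0:
            if frequencies.proportions[cls] > 0:
                import warnings

                warnings.warn(
                    f"{frequencies.ethnicity}: class {cls.value} count rounds "
                    f"to 0 at n={n}; omitted",
                    RuntimeWarning,
                    stacklevel=2,
                )
            continue
        pop = simulate_class_population(
            record, cls, variability, multipliers=multipliers,
            n=k, noise=noise, seed=rng, **kwargs,
        )
        cls_arr += [cls] * k
        for m in multipliers:
            bp_arr[m].append(pop.bp_hat[m])
    return MixturePopulation(
        ligand=record.name,
        ethnicity=frequencies.ethnicity,
        multipliers=multipliers,
        cls=np.array(cls_arr, dtype=object),
        bp_hat={m: np.concatenate(v) for m, v in bp_arr.items()},
    )


# ---------------------------------------------------------------------------
# study results
# ---------------------------------------------------------------------------

def within_subject_result(
    population: ClassPopulation,
    multiplier: float,
    settings: PowerSettings | None = None,
) -> StudyResult:
    """Paired-design sample size from a within-subject class population."""
    settings = settings or PowerSettings()
    delta = population.delta_bp(multiplier)
    delta = delta[np.isfinite(delta)]
    mean_d = float(np.mean(delta))
    sd_d = float(np.std(delta, ddof=1))
    return StudyResult(
        design="within",
        ligand=population.ligand,
        group=population.cls.value,
        increase=multiplier - 1.0,
        mean_effect=mean_d,
        sd_control=None,
        sd_disease=None,
        sd_delta=sd_d,
        n_required=paired_sample_size(mean_d, sd_d, settings),
    )


def _group_moments(bp: np.ndarray) -> tuple[float, float]:
    bp = bp[np.isfinite(bp)]
    return float(np.mean(bp)), float(np.std(bp, ddof=1))


def between_known_result(
    population: ClassPopulation,
    multiplier: float,
    settings: PowerSettings | None = None,
) -> StudyResult:
    """Welch sample size per group when binding class is known a priori.

    Control and diseased group moments come from the same simulated
    population evaluated at control and elevated Bmax.
    """
    settings = settings or PowerSettings()
    mean_c, sd_c = _group_moments(population.bp_hat[1.0])
    mean_d, sd_d = _group_moments(population.bp_hat[multiplier])
    diff = mean_d - mean_c
    return StudyResult(
        design="between_known",
        ligand=population.ligand,
        group=population.cls.value,
        increase=multiplier - 1.0,
        mean_effect=diff,
        sd_control=sd_c,
        sd_disease=sd_d,
        sd_delta=None,
        n_required=welch_sample_size(diff, sd_c, sd_d, settings),
    )


def between_unknown_result(
    mixture: MixturePopulation,
    multiplier: float,
    settings: PowerSettings | None = None,
) -> StudyResult:
    """Mann-Whitney (A.R.E.-corrected Welch) sample size per group for a
    mixed-class cohort comparison."""
    settings = settings or PowerSettings()
    mean_c, sd_c = _group_moments(mixture.bp_hat[1.0])
    mean_d, sd_d = _group_moments(mixture.bp_hat[multiplier])
    diff = mean_d - mean_c
    welch_n = welch_sample_size(diff, sd_c, sd_d, settings)
    return StudyResult(
        design="between_unknown",
        ligand=mixture.ligand,
        group=mixture.ethnicity,
        increase=multiplier - 1.0,
        mean_effect=diff,
        sd_control=sd_c,
        sd_disease=sd_d,
        sd_delta=None,
        n_required=mannwhitney_sample_size(welch_n, settings),
        extras={"welch_n": welch_n},
    )
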