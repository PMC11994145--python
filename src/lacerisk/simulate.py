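"""Seeded synthetic admission cohorts with known ground truth.

The registry data the pipeline targets are not public, so the generator
emulates the two printed cohort structures — trauma (young, 85% male,
almost all emergency, near-zero comorbidity) and general surgery (older,
mixed acuity, comorbidity mean 1.56) — and plants dictionary surface
forms inside template free text so every pipeline stage has an exact
oracle: ``gold_cci`` equals the planted condition weights (after synonym
dedup and severity dominance) plus age points, and keyword extraction
recovers it on 100% of records.

The 30-day outcome is drawn from a logistic model on the actually
computed LACE total (plus one covariate), with the intercept calibrated
by bisection so the expected prevalence matches the cohort target; the
readmission models fit downstream are therefore correctly specified and
parameter-recovery checks are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .dictionary import SentimentDictionary, build_default_dictionary, normalize_text
from .extract import age_points, match_conditions
from .lace import lace_total
from .records import AGE_MAX, AGE_MIN, PatientRecord, records_to_frame

__all__ = [
    "CohortProfile",
    "TRAUMA_PROFILE",
    "GENERAL_PROFILE",
    "get_profile",
    "generate_cohort",
    "generate_cohort_frame",
    "generate_history_text",
    "calibrate_intercept",
]


def nb_dispersion(mean: float, sd: float) -> float:
    """Negative-binomial size r from a target mean and SD (var > mean)."""
    var = sd * sd
    if var <= mean:
        raise ValueError("negative binomial needs var > mean")
    return mean * mean / (var - mean)


@dataclass(frozen=True)
class CohortProfile:
    """Generator parameters for one cohort.

    ``condition_rate`` (mean planted conditions per record, Poisson) may
    be None, in which case it is derived so the expected total CCI —
    planted weights plus age points under the cohort's age distribution —
    matches ``target_cci_mean``.
    """

    name: str
    n: int
    target_prevalence: float
    age_mean: float
    age_sd: float
    prop_male: float
    prop_emergency: float
    los_mean: float
    los_dispersion: float       # negative-binomial size r
    ed_visit_rate: float        # Poisson mean of prior-6-month ED visits
    target_cci_mean: float
    condition_rate: float | None = None
    lace_slope: float = 0.0     # true log-odds per LACE point
    covariate: str | None = None  # "sex" (male=1) | "age" | None
    covariate_slope: float = 0.0
    ed_mode: str = "binary"
    threshold: int = 10
    obfuscation_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for p, label in ((self.target_prevalence, "target_prevalence"),
                         (self.prop_male, "prop_male"),
                         (self.prop_emergency, "prop_emergency"),
                         (self.obfuscation_rate, "obfuscation_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be strictly inside (0, 1)")


#: Built-in profiles reproducing the printed cohort characteristics:
#: mean age / SD, sex and acuity mix, LOS moments, comorbidity-score mean,
#: unplanned prevalence, and the reported LACE log-odds slopes (trauma 0.11
#: with sex covariate 0.52; general 0.15 with age covariate -0.004).
TRAUMA_PROFILE = CohortProfile(
    name="trauma", n=12_590, target_prevalence=804 / 12_590,
    age_mean=33.91, age_sd=12.26, prop_male=0.85, prop_emergency=0.95,
    los_mean=1.76, los_dispersion=nb_dispersion(1.76, 2.18),
    ed_visit_rate=0.35, target_cci_mean=0.2,
    lace_slope=0.11, covariate="sex", covariate_slope=0.52,
)

GENERAL_PROFILE = CohortProfile(
    name="general", n=19_120, target_prevalence=2_192 / 19_120,
    age_mean=49.33, age_sd=17.44, prop_male=0.47, prop_emergency=0.49,
    los_mean=3.04, los_dispersion=nb_dispersion(3.04, 2.08),
    ed_visit_rate=0.75, target_cci_mean=1.56,
    lace_slope=0.15, covariate="age", covariate_slope=-0.004,
)

_PROFILES = {"trauma": TRAUMA_PROFILE, "general": GENERAL_PROFILE}


def get_profile(name: str, **overrides) -> CohortProfile:
    """A built-in profile by name, optionally with field overrides."""
    try:
        base = _PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(_PROFILES)}")
    return replace(base, **overrides) if overrides else base


# -- age distribution ------------------------------------------------------

def _age_sampler_loc(mean: float, sd: float) -> float:
    """Location of the [18, 100]-truncated normal whose TRUNCATED mean is
    ``mean`` (truncation would otherwise inflate young cohorts' means)."""

    def trunc_mean(loc: float) -> float:
        a, b = (AGE_MIN - loc) / sd, (AGE_MAX - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(brentq(lambda m: trunc_mean(m) - mean, mean - 4 * sd, mean + sd,
                        xtol=1e-10))


def _expected_age_points(loc: float, sd: float) -> float:
    """E[age points] under the truncated-normal age law: one point per
    completed decade past 40, so band [40+10k, 50+10k) scores k."""
    a, b = (AGE_MIN - loc) / sd, (AGE_MAX - loc) / sd
    dist = truncnorm(a, b, loc=loc, scale=sd)
    total = 0.0
    k = 1
    while 40 + 10 * k < AGE_MAX:
        lo, hi = 40 + 10 * k, min(50 + 10 * k, AGE_MAX)
        total += k * (dist.cdf(hi) - dist.cdf(lo))
        k += 1
    return total


def _derive_condition_rate(profile: CohortProfile,
                           dictionary: SentimentDictionary) -> float:
    loc = _age_sampler_loc(profile.age_mean, profile.age_sd)
    age_part = _expected_age_points(loc, profile.age_sd)
    mean_weight = float(np.mean([e.weight for e in dictionary]))
    needed = max(0.0, profile.target_cci_mean - age_part)
    return needed / mean_weight


# -- free-text generation --------------------------------------------------

#: Neutral clinical-style filler; screened so no phrase (nor any
#: concatenation across phrase boundaries) matches a dictionary surface form.
DISTRACTORS: tuple[str, ...] = (
    "presented to the unit", "complains of abdominal pain",
    "two day history of vomiting", "fall from standing height",
    "assault with blunt object", "involved in motor vehicle collision",
    "right lower limb swelling", "generalised body weakness",
    "headache for one week", "non smoker", "occasional alcohol use",
    "lives with family", "previously well", "no regular medication",
    "seen at referring clinic", "wound on left forearm",
    "pain controlled on analgesia", "vitals stable on arrival",
    "booked for review", "awaiting imaging",
)

_OPENERS: tuple[str, ...] = (
    "Patient", "54 year old patient", "Referred patient", "Walk-in patient",
)

_OBFUSCATED_PHRASES: tuple[str, ...] = (
    "longstanding undisclosed medical condition",
    "chronic illness managed elsewhere",
    "significant past medical history per old notes",
)


def _screen_distractors(dictionary: SentimentDictionary) -> None:
    """Assert the filler vocabulary cannot fire the matcher, even across
    adjacent phrases."""
    joined = " . ".join((*_OPENERS, *DISTRACTORS, *_OBFUSCATED_PHRASES))
    stuck = " ".join((*_OPENERS, *DISTRACTORS, *_OBFUSCATED_PHRASES))
    for blob in (joined, stuck):
        hits = match_conditions(normalize_text(blob), dictionary)
        if hits:
            raise AssertionError(
                f"distractor vocabulary matches dictionary entries: {hits}"
            )


def generate_history_text(
    conditions: Sequence[str],
    rng: np.random.Generator,
    dictionary: SentimentDictionary | None = None,
    obfuscation_rate: float = 0.0,
) -> str:
    """Build a clinical-style history embedding the given canonical
    conditions (one randomly chosen surface form each) in neutral filler.

    With probability ``obfuscation_rate`` per condition the surface form is
    replaced by an unmatchable paraphrase — the condition still counts in
    the gold score, emulating expert readers catching phrasing the keyword
    matcher cannot (the source of machine-vs-expert discordance).
    """
    if dictionary is None:
        dictionary = build_default_dictionary()
    parts: list[str] = [str(rng.choice(_OPENERS)),
                        str(rng.choice(DISTRACTORS))]
    for name in conditions:
        entry = dictionary.by_canonical(name)  # KeyError on unknown condition
        if obfuscation_rate > 0 and rng.random() < obfuscation_rate:
            parts.append("known " + str(rng.choice(_OBFUSCATED_PHRASES)))
        else:
            form = entry.surface_forms[rng.integers(len(entry.surface_forms))]
            parts.append("known " + form)
    parts.append(str(rng.choice(DISTRACTORS)))
    return ". ".join(parts) + "."


# -- outcome calibration ---------------------------------------------------

def calibrate_intercept(
    target_prevalence: float,
    linear_predictor: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Bisection for the intercept alpha such that
    mean(expit(alpha + eta)) equals the target prevalence.

    The mean is strictly increasing in alpha, so bisection converges; the
    bracket is widened automatically before raising.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    eta = np.asarray(linear_predictor, dtype=float)

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta))) - target_prevalence

    lo, hi = -30.0, 30.0
    for _ in range(8):
        if f(lo) < 0 < f(hi):
            break
        lo, hi = lo * 2, hi * 2
    else:
        raise ValueError("target prevalence unreachable at any intercept")

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) <= tol:
            return mid
        if val < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- cohort generation -----------------------------------------------------

def generate_cohort(
    profile: CohortProfile,
    seed: int | None = None,
    dictionary: SentimentDictionary | None = None,
) -> list[PatientRecord]:
    """Generate one fully seeded synthetic cohort.

    Reproducible: the same profile and seed give byte-identical records.
    ``seed`` overrides ``profile.seed``; one of the two must be set for a
    reproducibility guarantee (None falls back to OS entropy).
    """
    if dictionary is None:
        dictionary = build_default_dictionary()
    _screen_distractors(dictionary)
    use_seed = seed if seed is not None else profile.seed
    rng = np.random.default_rng(use_seed)
    n = profile.n

    # demographics and structured LACE inputs
    loc = _age_sampler_loc(profile.age_mean, profile.age_sd)
    a, b = (AGE_MIN - loc) / profile.age_sd, (AGE_MAX - loc) / profile.age_sd
    ages = truncnorm.rvs(a, b, loc=loc, scale=profile.age_sd, size=n,
                         random_state=rng)
    ages = np.round(ages, 2)
    male = rng.random(n) < profile.prop_male
    emergency = rng.random(n) < profile.prop_emergency
    r = profile.los_dispersion
    los = rng.negative_binomial(r, r / (r + profile.los_mean), size=n)
    ed_visits = rng.poisson(profile.ed_visit_rate, size=n)

    # planted comorbid conditions and history text
    rate = (profile.condition_rate if profile.condition_rate is not None
            else _derive_condition_rate(profile, dictionary))
    concepts = dictionary.canonical_conditions
    n_counts = np.minimum(rng.poisson(rate, size=n), len(concepts))
    conditions_per_record: list[list[str]] = []
    texts: list[str] = []
    gold: list[int] = []
    for i in range(n):
        k = int(n_counts[i])
        if k:
            idx = rng.choice(len(concepts), size=k, replace=False)
            conds = [concepts[j] for j in sorted(idx)]
        else:
            conds = []
        conditions_per_record.append(conds)
        texts.append(generate_history_text(
            conds, rng, dictionary, profile.obfuscation_rate))
        gold.append(dictionary.score_conditions(conds) + age_points(float(ages[i])))

    # LACE through the real scoring chain on the gold CCI
    totals = np.array([
        lace_total(
            int(los[i]), "emergency" if emergency[i] else "elective",
            gold[i], int(ed_visits[i]),
            ed_mode=profile.ed_mode, threshold=profile.threshold,
        ).total
        for i in range(n)
    ])

    # outcome: logistic in the LACE total plus the profile covariate
    if profile.covariate == "sex":
        cov = male.astype(float)
    elif profile.covariate == "age":
        cov = ages.astype(float)
    elif profile.covariate is None:
        cov = np.zeros(n)
    else:
        raise ValueError(f"unknown covariate {profile.covariate!r}")
    eta = profile.lace_slope * totals + profile.covariate_slope * cov
    alpha = calibrate_intercept(profile.target_prevalence, eta)
    unplanned = rng.random(n) < expit(alpha + eta)

    return [
        PatientRecord(
            patient_id=f"{profile.name}-{i:06d}",
            cohort=profile.name if profile.name in ("trauma", "general") else "general",
            age=float(ages[i]),
            sex="male" if male[i] else "female",
            admission_type="emergency" if emergency[i] else "elective",
            los_days=int(los[i]),
            ed_visits_6mo=int(ed_visits[i]),
            history_text=texts[i],
            outcome="unplanned_readmission" if unplanned[i] else "other",
            gold_cci=gold[i],
        )
        for i in range(n)
    ]


def generate_cohort_frame(
    profile: CohortProfile,
    seed: int | None = None,
    dictionary: SentimentDictionary | None = None,
) -> pd.DataFrame:
    """Like :func:`generate_cohort`, as a DataFrame."""
    return records_to_frame(generate_cohort(profile, seed=seed,
                                            dictionary=dictionary))
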