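"""Synthetic cohorts with the statistical structure of a PIT-tag validation study.

The generator emulates a river monitoring setup: smolts are measured and
tagged on seaward migration, a subset of returning adults is recaptured,
and scales are read by several independent readers.  Defaults are
calibrated to the published summary statistics of a western-Norwegian
river cohort:

* smolt length ~ truncated normal, mean 13.73 cm, 5%/95% quantiles
  12.00/15.56 cm (sd 1.08 cm reproduces these), hard bounds 11.5-17.0 cm;
* sea-age pmf {1: 126/254, 2: 105/254, 3: 19/254, 4: 4/254}
  (mean 1.61 years); freshwater-age pmf concentrated on 2-3 years
  ({2: 38/81, 3: 40/81} with one fish each at 1, 4 and 5);
* freshwater age known (via parent identification) for a Bernoulli(81/254)
  subset of fish;
* readers misclassify by exactly +-1 year with small class-specific
  probabilities, and abstain ("unreadable") at reader-specific rates.

Scale geometry follows a latent linear rule S(L) = kappa * beta * (L - L0)
for body length L > L0, where L0 is the body length at which the scale
starts to form.  With L0 = 0 the Lea-Dahl proportionality assumption
holds exactly and back-calculation is an identity; with L0 > 0 the
generator deliberately violates the through-origin assumption, producing
the characteristic slope-above-1 bias of back-calculated smolt length on
measured smolt length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError
from .io import FishRecord, ReaderAgeEstimate, ScaleRadiiMeasurement

__all__ = [
    "TruncNormalSpec",
    "CohortConfig",
    "ReaderProfile",
    "ScaleGeometryConfig",
    "default_reader_profiles",
    "generate_cohort",
    "simulate_scale_radii",
    "simulate_reader_estimates",
]

DEFAULT_FW_AGE_PMF: dict[int, float] = {1: 1 / 81, 2: 38 / 81, 3: 40 / 81, 4: 1 / 81, 5: 1 / 81}
DEFAULT_SEA_AGE_PMF: dict[int, float] = {1: 126 / 254, 2: 105 / 254, 3: 19 / 254, 4: 4 / 254}


@dataclass(frozen=True)
class TruncNormalSpec:
    mean: float
    sd: float
    lower: float
    upper: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigError(f"{name}: sd {self.sd} < 0")
        if not self.lower < self.upper:
            raise ConfigError(f"{name}: bounds [{self.lower}, {self.upper}] not ordered")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


def _check_pmf(pmf: Mapping[int, float], name: str) -> None:
    if abs(sum(pmf.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {sum(pmf.values())}, not 1")
    if any(p < 0 for p in pmf.values()):
        raise ConfigError(f"{name}: negative probability")
    if any(a < 1 or a > 5 for a in pmf):
        raise ConfigError(f"{name}: ages must lie in 1..5")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated cohort."""

    n_fish: int = 254
    smolt_length_dist: TruncNormalSpec = TruncNormalSpec(13.73, 1.08, 11.5, 17.0)
    fw_age_pmf: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_FW_AGE_PMF))
    sea_age_pmf: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_SEA_AGE_PMF))
    #: per sea-age (mean cm, sd cm) of adult length, truncated to [40, 120]
    adult_length_by_sea_age: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {
            1: (56.5, 4.0), 2: (78.5, 5.0), 3: (93.0, 6.0), 4: (103.0, 6.0), 5: (108.0, 5.0),
        }
    )
    #: W = a * L^b * lognormal(sd) with L in cm, W in kg
    weight_allometry: tuple[float, float, float] = (1.0e-5, 3.0, 0.1)
    smolt_year_range: tuple[int, int] = (2016, 2021)
    sex_ratio: float = 0.5  # probability female
    #: probability that both parents were identified, i.e. fw truth known
    fw_known_prob: float = 81 / 254
    seed: int = 0

    def validate(self) -> None:
        if self.n_fish < 1:
            raise ConfigError(f"n_fish {self.n_fish} < 1")
        self.smolt_length_dist.validate("smolt_length_dist")
        _check_pmf(self.fw_age_pmf, "fw_age_pmf")
        _check_pmf(self.sea_age_pmf, "sea_age_pmf")
        for age in self.sea_age_pmf:
            if self.sea_age_pmf[age] > 0 and age not in self.adult_length_by_sea_age:
                raise ConfigError(f"no adult length distribution for sea-age {age}")
        for age, (m, s) in self.adult_length_by_sea_age.items():
            if s < 0:
                raise ConfigError(f"adult_length_by_sea_age[{age}]: sd {s} < 0")
        if not self.smolt_year_range[0] <= self.smolt_year_range[1]:
            raise ConfigError("smolt_year_range not ordered")
        if not 0 <= self.sex_ratio <= 1 or not 0 <= self.fw_known_prob <= 1:
            raise ConfigError("sex_ratio and fw_known_prob must be probabilities")

    def sea_age_expectation(self) -> float:
        """Expected sea-age under the configured pmf."""
        return float(sum(a * p for a, p in self.sea_age_pmf.items()))


@dataclass(frozen=True)
class ReaderProfile:
    """Error and abstention behaviour of one scale reader.

    Misclassifications are always exactly +-1 year with equal direction
    probability (at true age 1 the error is forced to +1, since age 0 is
    impossible for a returning adult).
    """

    reader_id: str
    #: probability of a +-1 sea-age error, per class {"1SW", "MSW"}
    sea_misclass_prob_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"1SW": 0.01, "MSW": 0.05}
    )
    fw_misclass_prob: float = 0.28
    fw_unreadable_prob: float = 1 / 3
    smolt_length_unreadable_prob: float = 0.1
    #: multiplicative lognormal sd on each radius increment
    radius_noise_sd: float = 0.03

    def validate(self) -> None:
        probs = [
            *self.sea_misclass_prob_by_class.values(),
            self.fw_misclass_prob,
            self.fw_unreadable_prob,
            self.smolt_length_unreadable_prob,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError(f"reader {self.reader_id!r}: probability outside [0, 1]")
        if set(self.sea_misclass_prob_by_class) != {"1SW", "MSW"}:
            raise ConfigError(
                f"reader {self.reader_id!r}: sea_misclass_prob_by_class needs keys 1SW, MSW"
            )
        if self.radius_noise_sd < 0:
            raise ConfigError(f"reader {self.reader_id!r}: radius_noise_sd < 0")


def default_reader_profiles() -> list[ReaderProfile]:
    """Three readers mimicking the study's reader pool.

    All three read sea-age; only the first two read freshwater age (the
    third abstains always); smolt-length abstention rates 8/248, 61/248
    and 111/248 follow the published per-reader counts.
    """
    return [
        ReaderProfile("R1", fw_misclass_prob=0.23, fw_unreadable_prob=1 / 3,
                      smolt_length_unreadable_prob=8 / 248),
        ReaderProfile("R2", fw_misclass_prob=0.33, fw_unreadable_prob=1 / 3,
                      smolt_length_unreadable_prob=61 / 248),
        ReaderProfile("R3", fw_misclass_prob=0.28, fw_unreadable_prob=1.0,
                      smolt_length_unreadable_prob=111 / 248),
    ]


@dataclass(frozen=True)
class ScaleGeometryConfig:
    """Latent linear scale-radius geometry S(L) = kappa * beta * (L - L0)."""

    formation_length: float = 9.0   # L0, cm; 0 makes Lea-Dahl exact
    radius_per_cm: float = 0.04     # beta, mm of radius per cm of body length
    per_fish_radius_sd: float = 0.08  # lognormal sd of kappa
    #: fraction of the final sea-winter growth increment completed at
    #: capture; 1.0 places the last annulus exactly at the scale edge
    plus_growth_fraction: float = 1.0

    def validate(self) -> None:
        if self.formation_length < 0:
            raise ConfigError(f"formation_length {self.formation_length} < 0")
        if self.radius_per_cm <= 0:
            raise ConfigError(f"radius_per_cm {self.radius_per_cm} <= 0")
        if self.per_fish_radius_sd < 0:
            raise ConfigError("per_fish_radius_sd < 0")
        if not 0 < self.plus_growth_fraction <= 1:
            raise ConfigError("plus_growth_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_ages(pmf: Mapping[int, float], n: int, rng: np.random.Generator) -> np.ndarray:
    ages = np.array(sorted(pmf), dtype=int)
    probs = np.array([pmf[a] for a in ages], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(ages, size=n, p=probs)


def generate_cohort(config: CohortConfig | None = None) -> list[FishRecord]:
    """Draw a cohort of known-sea-age fish; reproducible given ``config.seed``."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fish

    smolt_years = rng.integers(cfg.smolt_year_range[0], cfg.smolt_year_range[1] + 1, size=n)
    sea_ages = _draw_ages(cfg.sea_age_pmf, n, rng)
    fw_ages = _draw_ages(cfg.fw_age_pmf, n, rng)
    fw_known = rng.random(n) < cfg.fw_known_prob
    smolt_lengths = np.round(cfg.smolt_length_dist.rvs(n, rng), 1)
    sexes = np.where(rng.random(n) < cfg.sex_ratio, "F", "M")

    # adult lengths: one vectorized truncated-normal draw per sea-age class
    adult_lengths = np.empty(n)
    for age in np.unique(sea_ages):
        mean_l, sd_l = cfg.adult_length_by_sea_age[int(age)]
        mask = sea_ages == age
        spec = TruncNormalSpec(mean_l, sd_l, 40.0, 120.0)
        adult_lengths[mask] = spec.rvs(int(mask.sum()), rng)
    adult_lengths = np.round(adult_lengths, 1)

    a, b, wsd = cfg.weight_allometry
    weights = a * adult_lengths ** b
    if wsd > 0:
        weights = weights * np.exp(rng.normal(0.0, wsd, size=n))
    weights = np.round(weights, 2)

    records: list[FishRecord] = []
    for i in range(n):
        sea_age = int(sea_ages[i])
        records.append(
            FishRecord(
                fish_id=f"F{i + 1:04d}",
                smolt_year=int(smolt_years[i]),
                return_year=int(smolt_years[i]) + sea_age,
                smolt_length=float(smolt_lengths[i]),
                adult_length=float(adult_lengths[i]),
                adult_weight=float(weights[i]),
                sex=str(sexes[i]),
                parent_return_year=(
                    int(smolt_years[i]) - int(fw_ages[i]) - 1 if fw_known[i] else None
                ),
            )
        )
    return records


def _latent_fw_age(
    fish: FishRecord, rng: np.random.Generator, pmf: Mapping[int, float]
) -> int:
    """True freshwater age when known, else an independent latent draw.

    Fish with unknown freshwater truth never enter a freshwater-age
    analysis, so the latent draw only shapes nuisance structure (annulus
    counts, estimates that downstream code ignores).
    """
    if fish.true_fw_age is not None:
        return fish.true_fw_age
    return int(_draw_ages(pmf, 1, rng)[0])


def simulate_scale_radii(
    cohort: Sequence[FishRecord],
    geometry: ScaleGeometryConfig | None = None,
    profiles: Sequence[ReaderProfile] | None = None,
    seed: int = 0,
    latent_fw_age_pmf: Mapping[int, float] | None = None,
) -> list[ScaleRadiiMeasurement]:
    """Simulate per-reader scale-radius measurements for every fish.

    The latent body-length trajectory places winter marks by linear
    interpolation: freshwater winters between the formation length L0 and
    the smolt length, sea winters between the smolt length and the adult
    length, in equal per-winter increments.  Each reader perturbs every
    radius *increment* with independent multiplicative lognormal noise,
    which preserves the strictly-increasing annulus order by
    construction.  With zero noise and L0 = 0 the downstream Lea-Dahl
    back-calculation recovers every length exactly.
    """
    geom = geometry or ScaleGeometryConfig()
    geom.validate()
    profs = list(profiles) if profiles is not None else default_reader_profiles()
    for p in profs:
        p.validate()
    pmf = dict(latent_fw_age_pmf) if latent_fw_age_pmf is not None else dict(DEFAULT_FW_AGE_PMF)
    _check_pmf(pmf, "latent_fw_age_pmf")
    rng = np.random.default_rng(seed)

    out: list[ScaleRadiiMeasurement] = []
    for fish in cohort:
        if fish.smolt_length is None or fish.adult_length is None:
            continue
        l_smolt, l_adult = fish.smolt_length, fish.adult_length
        if geom.formation_length >= l_smolt:
            raise ConfigError(
                f"formation_length {geom.formation_length} >= smolt length "
                f"{l_smolt} of fish {fish.fish_id!r}"
            )
        kappa = math.exp(rng.normal(0.0, geom.per_fish_radius_sd)) if geom.per_fish_radius_sd else 1.0
        scale = kappa * geom.radius_per_cm

        fw_age = _latent_fw_age(fish, rng, pmf)
        sea_age = fish.true_sea_age
        # body lengths at each winter mark, freshwater then sea
        fw_marks = [
            geom.formation_length + (l_smolt - geom.formation_length) * k / fw_age
            for k in range(1, fw_age + 1)
        ]
        step = (l_adult - l_smolt) / (sea_age - 1 + geom.plus_growth_fraction)
        sea_marks = [l_smolt + step * m for m in range(1, sea_age + 1)]
        mark_lengths = fw_marks + sea_marks
        true_radii = [scale * (L - geom.formation_length) for L in mark_lengths]
        true_total = scale * (l_adult - geom.formation_length)
        smolt_idx = fw_age - 1  # smolt mark is the last freshwater annulus

        for prof in profs:
            # noise the increments, keep order
            bounds = true_radii + [true_total]
            incs = np.diff([0.0] + bounds)
            if prof.radius_noise_sd > 0:
                incs = incs * np.exp(rng.normal(0.0, prof.radius_noise_sd, size=incs.size))
            radii = np.cumsum(incs)
            annuli = tuple(float(r) for r in radii[:-1])
            total = float(radii[-1])
            smolt_mark: float | None = annuli[smolt_idx]
            if rng.random() < prof.smolt_length_unreadable_prob:
                smolt_mark = None
            out.append(
                ScaleRadiiMeasurement(
                    fish_id=fish.fish_id,
                    reader_id=prof.reader_id,
                    total_radius=total,
                    smolt_mark_radius=smolt_mark,
                    annulus_radii=annuli,
                )
            )
    return out


def simulate_reader_estimates(
    cohort: Sequence[FishRecord],
    profiles: Sequence[ReaderProfile] | None = None,
    seed: int = 0,
    latent_fw_age_pmf: Mapping[int, float] | None = None,
) -> list[ReaderAgeEstimate]:
    """Simulate per-reader age calls: +-1 errors and abstentions.

    With a class-specific probability the sea-age is shifted by one year
    (direction symmetric; +1 forced at true age 1); freshwater age is
    unreadable with the reader's abstention probability and otherwise
    shifted by one year with the reader's freshwater error probability.
    """
    profs = list(profiles) if profiles is not None else default_reader_profiles()
    for p in profs:
        p.validate()
    pmf = dict(latent_fw_age_pmf) if latent_fw_age_pmf is not None else dict(DEFAULT_FW_AGE_PMF)
    _check_pmf(pmf, "latent_fw_age_pmf")
    rng = np.random.default_rng(seed)

    out: list[ReaderAgeEstimate] = []
    for fish in cohort:
        sea_true = fish.true_sea_age
        sea_class = "1SW" if sea_true == 1 else "MSW"
        fw_true = _latent_fw_age(fish, rng, pmf)
        for prof in profs:
            sea_est = sea_true
            if rng.random() < prof.sea_misclass_prob_by_class[sea_class]:
                sea_est = _shift_one(sea_true, rng)
            if rng.random() < prof.fw_unreadable_prob:
                fw_est: int | None = None
            else:
                fw_est = fw_true
                if rng.random() < prof.fw_misclass_prob:
                    fw_est = _shift_one(fw_true, rng)
            out.append(
                ReaderAgeEstimate(
                    fish_id=fish.fish_id,
                    reader_id=prof.reader_id,
                    fw_age_est=fw_est,
                    sea_age_est=sea_est,
                )
            )
    return out


def _shift_one(age: int, rng: np.random.Generator) -> int:
    """A +-1 error, direction symmetric, forced upward at age 1."""
    if age == 1:
        return 2
    return age + (1 if rng.random() < 0.5 else -1)
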