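"""Ageing precision statistics: PE, agreement, bootstrap CIs, Chang CV, APE.

The headline accuracy statistic is the percent of incorrectly classified
ages (PE), which weights every misclassification equally irrespective of
the true age — appropriate when nearly all fish fall in a narrow age
range, where the classical CV/APE indices would over-weight errors on
young fish.  Abstentions ("unreadable") are excluded from both the
numerator and the denominator: accuracy is computed over produced
estimates only.

Confidence intervals are nonparametric bootstrap percentile intervals.
The resampling unit is the *fish*, never the individual read: all of a
fish's reader estimates move together because they derive from the same
scale.  Quantiles use linear interpolation of the empirical distribution
(numpy's default, Hyndman-Fan type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import UndefinedStatisticError

__all__ = [
    "PrecisionResult",
    "percent_error",
    "percent_agreement",
    "bootstrap_ci",
    "chang_cv",
    "ape",
    "classwise_misclassification",
]


@dataclass(frozen=True)
class PrecisionResult:
    """A point estimate (percent) with an optional bootstrap interval."""

    statistic_name: str  # PE, agreement, CV or APE
    point_value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_units: int = 0
    b_resamples: int = 0

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None and self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")


def percent_error(
    true_ages: Sequence[int],
    est_ages: Sequence[int | None],
) -> float:
    """PE: 100 x (number of estimates differing from truth) / readable pairs.

    ``est_ages`` is aligned with ``true_ages``; ``None`` entries
    (unreadable) are dropped from numerator and denominator alike.
    Raises :class:`UndefinedStatisticError` when no pair is readable.
    """
    if len(true_ages) != len(est_ages):
        raise ValueError("true_ages and est_ages must be aligned")
    n = wrong = 0
    for t, e in zip(true_ages, est_ages):
        if e is None:
            continue
        n += 1
        wrong += t != e
    if n == 0:
        raise UndefinedStatisticError("PE undefined: no readable (true, estimate) pairs")
    return 100.0 * wrong / n


def percent_agreement(true_ages: Sequence[int], est_ages: Sequence[int | None]) -> float:
    """Percent agreement, the complement of :func:`percent_error`."""
    return 100.0 - percent_error(true_ages, est_ages)


def bootstrap_ci(
    statistic: Callable[[Sequence], float],
    units: Sequence,
    b: int = 1000,
    seed: int | np.random.Generator | None = None,
    quantiles: tuple[float, float] = (2.5, 97.5),
    max_redraws_per_resample: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``statistic`` over resampled units.

    ``units`` is any sequence (typically one entry per fish carrying that
    fish's reads); each of the ``b`` resamples draws ``len(units)`` units
    with replacement and re-evaluates the statistic.  A resample on which
    the statistic is undefined (raises
    :class:`~ageval.errors.UndefinedStatisticError`, e.g. an
    all-unreadable draw) is redrawn, up to a hard cap per resample.
    """
    if len(units) == 0:
        raise UndefinedStatisticError("bootstrap undefined on an empty unit list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(units)
    arr = units if isinstance(units, np.ndarray) else None
    values = np.empty(b)
    for k in range(b):
        for attempt in range(max_redraws_per_resample + 1):
            idx = rng.integers(0, n, size=n)
            sample = arr[idx] if arr is not None else [units[i] for i in idx]
            try:
                values[k] = statistic(sample)
                break
            except UndefinedStatisticError:
                continue
        else:
            raise UndefinedStatisticError(
                f"statistic undefined on {max_redraws_per_resample} consecutive resamples"
            )
    lo, hi = np.percentile(values, quantiles)
    return float(lo), float(hi)


def _per_fish_dispersion(
    readings: Sequence[Sequence[float]],
    references: Sequence[float | None] | None,
    kind: str,
) -> float:
    if references is not None and len(references) != len(readings):
        raise ValueError("references must align with readings")
    terms = []
    for j, vals in enumerate(readings):
        vals = [v for v in vals if v is not None]
        if len(vals) < 2:
            continue  # a single reading carries no dispersion information
        x = np.asarray(vals, dtype=float)
        ref = references[j] if references is not None else None
        if ref is None:
            ref = float(x.mean())
        if ref <= 0:
            raise UndefinedStatisticError(f"reference length {ref} <= 0 for fish index {j}")
        if kind == "cv":
            terms.append(x.std(ddof=1) / ref)
        else:  # ape
            terms.append(float(np.mean(np.abs(x - ref))) / ref)
    if not terms:
        raise UndefinedStatisticError("no fish with >= 2 readings")
    return 100.0 * float(np.mean(terms))


def chang_cv(
    readings: Sequence[Sequence[float]],
    references: Sequence[float | None] | None = None,
) -> float:
    """Chang's coefficient of variation for repeated measurements, percent.

    Per fish j with r_j >= 2 readings: sd_j / ref_j, where sd uses the
    r_j - 1 denominator and ref_j is the true length when supplied
    (``references[j]`` not None) and the reader mean otherwise; the CV is
    100 times the mean of these ratios over fish.  Fish with fewer than
    two readings are excluded.
    """
    return _per_fish_dispersion(readings, references, "cv")


def ape(
    readings: Sequence[Sequence[float]],
    references: Sequence[float | None] | None = None,
) -> float:
    """Beamish-Fournier average percent error, same reference convention as CV."""
    return _per_fish_dispersion(readings, references, "ape")


def classwise_misclassification(
    true_ages: Sequence[int],
    estimates_by_reader: Mapping[str, Sequence[int | None]],
    classing: Mapping[int, str],
) -> dict[str, dict[str, float | int]]:
    """Per age-class misclassified-fish counts.

    A fish counts as misclassified when at least one reader produced a
    readable estimate differing from the truth.  Returns, per class, the
    misclassified count, the total fish count, and the exact percent
    fraction 100 * misclassified / total.
    """
    for t in true_ages:
        if t not in classing:
            raise ValueError(f"classing does not cover observed age {t}")
    per_class: dict[str, dict[str, float | int]] = {}
    for j, t in enumerate(true_ages):
        cls = classing[t]
        entry = per_class.setdefault(cls, {"n_misclassified": 0, "n_fish": 0, "percent": 0.0})
        entry["n_fish"] += 1
        wrong = any(
            ests[j] is not None and ests[j] != t for ests in estimates_by_reader.values()
        )
        entry["n_misclassified"] += int(wrong)
    for entry in per_class.values():
        entry["percent"] = 100.0 * entry["n_misclassified"] / entry["n_fish"]
    return per_class
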