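"""Lea-Dahl back-calculation and bias analyses of back-calculated smolt length.

The Lea-Dahl method assumes body length proportional to scale radius
throughout life, so the length at any earlier mark t is
L_t = L_c * S_t / S_c, with L_c the length at capture, S_t the radius at
the mark and S_c the total scale radius.  When scales begin to form at a
positive body length the proportionality is violated and back-calculated
smolt lengths are biased: too short for small smolts, too long for large
ones — visible as a regression slope above 1 of back-calculated on
measured smolt length.

Three bias analyses are provided, mirroring standard practice:
a paired t-test of the mean difference, a sign chi-square of the
under/over split, and an OLS regression with a t-test of the slope
against 1 (the slope against 0 is also reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError
from .io import FishRecord, ScaleRadiiMeasurement

__all__ = [
    "BackCalcResult",
    "BiasAnalysisResult",
    "lea_dahl_length",
    "backcalculate_cohort",
    "sign_chisquare",
    "smolt_length_bias",
    "reader_mean_smolt_bc",
]

logger = logging.getLogger(__name__)


def lea_dahl_length(s_t: float, s_c: float, l_c: float) -> float:
    """Length at mark t: L_t = L_c * S_t / S_c (radii mm, lengths cm)."""
    if s_t <= 0 or s_c <= 0 or l_c <= 0:
        raise ValidationError(f"nonpositive input to Lea-Dahl: s_t={s_t}, s_c={s_c}, l_c={l_c}")
    if s_t > s_c * (1 + 1e-12):
        raise ValidationError(f"annulus radius s_t={s_t} exceeds total radius s_c={s_c}")
    return l_c * s_t / s_c


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated lengths at every mark of one reader's scale."""

    fish_id: str
    reader_id: str
    lengths_at_marks: tuple[float, ...]  # cm, one per annulus, in radius order
    smolt_length_bc: float | None  # cm; None when the smolt mark was unreadable


def backcalculate_cohort(
    radii: Sequence[ScaleRadiiMeasurement],
    fish: Sequence[FishRecord],
) -> tuple[list[BackCalcResult], list[str]]:
    """Apply Lea-Dahl at the smolt mark and every annulus of every scale.

    Fish without an adult length cannot be back-calculated.  Per-scale
    problems are collected (and logged) rather than fatal; the second
    return value lists them.
    """
    by_id = {f.fish_id: f for f in fish}
    results: list[BackCalcResult] = []
    problems: list[str] = []
    for m in radii:
        rec = by_id.get(m.fish_id)
        if rec is None:
            problems.append(f"radii for unknown fish {m.fish_id!r}")
            continue
        if rec.adult_length is None:
            problems.append(f"fish {m.fish_id!r}: no adult length, cannot back-calculate")
            continue
        try:
            lengths = tuple(
                lea_dahl_length(r, m.total_radius, rec.adult_length) for r in m.annulus_radii
            )
            smolt_bc = (
                lea_dahl_length(m.smolt_mark_radius, m.total_radius, rec.adult_length)
                if m.smolt_mark_radius is not None
                else None
            )
        except ValidationError as exc:
            problems.append(f"fish {m.fish_id!r} reader {m.reader_id!r}: {exc}")
            continue
        results.append(
            BackCalcResult(
                fish_id=m.fish_id,
                reader_id=m.reader_id,
                lengths_at_marks=lengths,
                smolt_length_bc=smolt_bc,
            )
        )
    for p in problems:
        logger.warning("back-calculation skipped: %s", p)
    return results, problems


def reader_mean_smolt_bc(results: Sequence[BackCalcResult]) -> dict[str, float]:
    """Per fish, the mean back-calculated smolt length over readers that gave one."""
    acc: dict[str, list[float]] = {}
    for r in results:
        if r.smolt_length_bc is not None:
            acc.setdefault(r.fish_id, []).append(r.smolt_length_bc)
    return {fid: float(np.mean(v)) for fid, v in acc.items()}


def sign_chisquare(n_under: int, n_over: int) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of an under/over split against a fair coin.

    chi2 = (n_under - E)^2/E + (n_over - E)^2/E with E = (n_under + n_over)/2,
    df = 1.  Returns (chi2, df, p).
    """
    total = n_under + n_over
    if total == 0:
        raise UndefinedStatisticError("sign test undefined: no non-tied pairs")
    e = total / 2.0
    chi2 = (n_under - e) ** 2 / e + (n_over - e) ** 2 / e
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


@dataclass(frozen=True)
class BiasAnalysisResult:
    """Paired-t, sign chi-square and slope analyses of back-calculated bias."""

    n: int
    mean_diff: float  # cm, back-calculated minus measured
    t_stat: float
    t_df: int
    t_p: float
    n_under: int  # back-calculated shorter than measured
    n_over: int
    n_ties: int
    chisq: float
    chisq_df: int
    chisq_p: float
    slope: float
    intercept: float
    slope_se: float
    slope_t_vs1: float
    slope_p_vs1: float
    slope_t_vs0: float
    slope_p_vs0: float
    slope_t_df: int


def smolt_length_bias(
    measured: Sequence[float],
    backcalc: Sequence[float],
) -> BiasAnalysisResult:
    """Run all three bias analyses on aligned per-fish length pairs.

    ``measured`` and ``backcalc`` are the trap-measured and
    back-calculated smolt lengths of the same fish (for pooled analyses
    pass the per-fish reader means, see :func:`reader_mean_smolt_bc`).
    Ties are excluded from the sign chi-square and reported.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(backcalc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and backcalc must be aligned 1-d sequences")
    n = x.size
    if n < 3:
        raise UndefinedStatisticError(f"bias analysis needs >= 3 fish, got {n}")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero variance in measured lengths: regression undefined")

    diffs = y - x
    if np.ptp(diffs) == 0 and diffs[0] == 0:
        # back-calculated identically equals measured: no paired dispersion
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_1samp(diffs, 0.0)
    n_under = int(np.sum(diffs < 0))
    n_over = int(np.sum(diffs > 0))
    n_ties = n - n_under - n_over
    if n_under + n_over == 0:
        # all ties: the sign test carries no information
        chi2, chi_df, chi_p = float("nan"), 1, float("nan")
    else:
        chi2, chi_df, chi_p = sign_chisquare(n_under, n_over)

    fit = stats.linregress(x, y)
    df = n - 2

    def _slope_t(delta: float) -> float:
        if fit.stderr == 0:
            return 0.0 if delta == 0 else float("inf") * np.sign(delta)
        return delta / fit.stderr

    t_vs1 = _slope_t(fit.slope - 1.0)
    p_vs1 = 2.0 * stats.t.sf(abs(t_vs1), df)
    t_vs0 = _slope_t(fit.slope)

    return BiasAnalysisResult(
        n=n,
        mean_diff=float(diffs.mean()),
        t_stat=float(t_stat),
        t_df=n - 1,
        t_p=float(t_p),
        n_under=n_under,
        n_over=n_over,
        n_ties=n_ties,
        chisq=chi2,
        chisq_df=chi_df,
        chisq_p=chi_p,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        slope_t_vs1=float(t_vs1),
        slope_p_vs1=float(p_vs1),
        slope_t_vs0=float(t_vs0),
        slope_p_vs0=float(fit.pvalue),
        slope_t_df=df,
    )
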