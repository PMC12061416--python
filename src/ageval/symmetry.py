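"""Agreement tables and chi-square tests of symmetry for directional age bias.

A true-vs-estimated contingency table is symmetric in expectation when
readers are as likely to under- as to over-estimate.  Three classical
chi-square statistics probe departures from symmetry:

* ``mcnemar`` — pools all above- vs all below-diagonal mass into one
  2-cell comparison: chi2 = (A - B)^2 / (A + B), df = 1;
* ``bowker`` — per symmetric cell pair (i < j):
  chi2 = sum (n_ij - n_ji)^2 / (n_ij + n_ji), df = number of pairs with
  n_ij + n_ji > 0;
* ``evans_hoenig`` — pools cells by off-diagonal distance d = |i - j|:
  chi2 = sum_d (A_d - B_d)^2 / (A_d + B_d) over distances with mass,
  df = number of such distances.

All variants reduce to the same statistic when a single cell pair holds
all the off-diagonal mass.  No continuity correction is applied.  The
test is undefined on a table with no off-diagonal counts (perfect
agreement carries no information about directionality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = ["AgreementTable", "SymmetryTestResult", "build_agreement_table", "symmetry_test"]

VARIANTS = ("mcnemar", "evans_hoenig", "bowker")


@dataclass(frozen=True)
class AgreementTable:
    """Square contingency table of true (rows) vs estimated (columns) age."""

    ages: tuple[int, ...]
    counts: np.ndarray  # shape (k, k), nonnegative integers

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.ages)
        if c.shape != (k, k):
            raise ValueError(f"counts shape {c.shape} does not match {k} ages")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"ages": list(self.ages), "counts": self.counts.tolist()}


@dataclass(frozen=True)
class SymmetryTestResult:
    variant: str
    chi2: float
    df: int
    p: float  # upper-tail chi-square probability


def build_agreement_table(
    true_ages: Sequence[int],
    est_ages: Sequence[int | None],
) -> AgreementTable:
    """Tally readable (true, estimate) pairs into a square table.

    The age axis is the sorted union of observed true and estimated
    values; unreadable estimates are dropped.  Raises on empty input.
    """
    if len(true_ages) != len(est_ages):
        raise ValueError("true_ages and est_ages must be aligned")
    pairs = [(t, e) for t, e in zip(true_ages, est_ages) if e is not None]
    if not pairs:
        raise UndefinedStatisticError("no readable pairs to tabulate")
    ages = tuple(sorted({a for p in pairs for a in p}))
    index = {a: i for i, a in enumerate(ages)}
    counts = np.zeros((len(ages), len(ages)), dtype=np.int64)
    for t, e in pairs:
        counts[index[t], index[e]] += 1
    return AgreementTable(ages=ages, counts=counts)


def symmetry_test(table: AgreementTable, variant: str = "evans_hoenig") -> SymmetryTestResult:
    """Run one symmetry-test variant on an agreement table.

    Raises :class:`UndefinedStatisticError` when every off-diagonal count
    is zero.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant {variant!r} not in {VARIANTS}")
    c = np.asarray(table.counts, dtype=float)
    k = c.shape[0]
    off_total = c.sum() - np.trace(c)
    if off_total == 0:
        raise UndefinedStatisticError(
            "symmetry test undefined: perfect agreement (no off-diagonal counts)"
        )

    if variant == "mcnemar":
        above = sum(c[i, j] for i in range(k) for j in range(i + 1, k))
        below = sum(c[j, i] for i in range(k) for j in range(i + 1, k))
        chi2 = (above - below) ** 2 / (above + below)
        df = 1
    elif variant == "bowker":
        chi2 = 0.0
        df = 0
        for i in range(k):
            for j in range(i + 1, k):
                tot = c[i, j] + c[j, i]
                if tot > 0:
                    chi2 += (c[i, j] - c[j, i]) ** 2 / tot
                    df += 1
    else:  # evans_hoenig: pool by off-diagonal distance
        chi2 = 0.0
        df = 0
        for d in range(1, k):
            above = sum(c[i, i + d] for i in range(k - d))
            below = sum(c[i + d, i] for i in range(k - d))
            tot = above + below
            if tot > 0:
                chi2 += (above - below) ** 2 / tot
                df += 1
    p = float(stats.chi2.sf(chi2, df))
    return SymmetryTestResult(variant=variant, chi2=float(chi2), df=df, p=p)
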