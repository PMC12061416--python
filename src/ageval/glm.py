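"""Binomial GLMs of reader misclassification probability with AIC selection.

The response for each fish is 1 when at least one reader produced a
readable age estimate differing from the truth, and 0 when every
readable estimate was correct — abstentions are not errors.  True ages
are aggregated into two classes before modelling (sea: 1SW vs MSW;
freshwater: 1-2 vs 3-5 years) because older fish are scarce.

Models are binomial with a logit link, fitted by IRLS (statsmodels).
All-subsets model selection ranks every admissible combination of
candidate terms by AIC; an interaction is only admitted alongside both
of its main effects (marginality), and exact AIC ties go to the model
with fewer coefficients.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ConvergenceError, ValidationError
from .io import FishRecord, ReaderAgeEstimate

__all__ = [
    "MisclassResponse",
    "GlmFit",
    "build_misclassification_response",
    "build_design_matrix",
    "fit_binomial_glm",
    "all_subsets_aic",
    "SEA_TERMS",
    "FW_TERMS",
]

logger = logging.getLogger(__name__)

#: candidate covariates of the sea-age and freshwater-age accuracy models
SEA_TERMS = ("age_class", "smolt_year", "smolt_length", "adult_length", "sex")
FW_TERMS = ("age_class", "smolt_year", "smolt_length", "sex")

INTERACTION_SEP = ":"


@dataclass(frozen=True)
class MisclassResponse:
    fish_id: str
    response: int  # 1 = at least one reader wrong, 0 = all readable reads correct
    which: str  # "sea" or "fw"


def build_misclassification_response(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    which: str,
) -> pd.DataFrame:
    """Fish-level misclassification responses with modelling covariates.

    Returns one row per fish with known truth and at least one readable
    estimate: columns ``fish_id``, ``response``, ``age_class`` (sea: 1SW
    vs MSW; fw: 1-2 vs 3-5 years), ``smolt_year``, ``smolt_length``,
    ``adult_length``, ``sex``.  Fish with unknown truth or no readable
    estimate are excluded (a logged count).
    """
    if which not in ("sea", "fw"):
        raise ValueError("which must be 'sea' or 'fw'")
    ests: dict[str, list[int]] = {f.fish_id: [] for f in fish}
    for r in reads:
        val = r.sea_age_est if which == "sea" else r.fw_age_est
        if val is not None and r.fish_id in ests:
            ests[r.fish_id].append(val)

    rows = []
    n_excluded = 0
    for f in fish:
        truth = f.true_sea_age if which == "sea" else f.true_fw_age
        readable = ests[f.fish_id]
        if truth is None or not readable:
            n_excluded += 1
            continue
        if which == "sea":
            age_class = "1SW" if truth == 1 else "MSW"
        else:
            age_class = "1-2" if truth <= 2 else "3-5"
        rows.append(
            {
                "fish_id": f.fish_id,
                "response": int(any(e != truth for e in readable)),
                "age_class": age_class,
                "smolt_year": f.smolt_year,
                "smolt_length": f.smolt_length,
                "adult_length": f.adult_length,
                "sex": f.sex,
            }
        )
    if n_excluded:
        logger.info(
            "%d of %d fish excluded from %s-age response (unknown truth or no readable read)",
            n_excluded, len(fish), which,
        )
    if not rows:
        raise ValidationError(f"no fish usable for the {which}-age response")
    return pd.DataFrame(rows)


def build_design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Dummy-coded design matrix (with intercept) for the given terms.

    Categorical terms (``age_class``, ``sex``, ``smolt_year``) are coded
    against their first sorted level — for smolt year, the earliest year.
    An interaction term ``a:b`` multiplies the coded columns of its two
    components.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}

    def coded(term: str) -> dict[str, np.ndarray]:
        if term in ("age_class", "sex"):
            levels = sorted(data[term].astype(str).unique())
            return {
                f"{term}[{lv}]": (data[term].astype(str) == lv).to_numpy(float)
                for lv in levels[1:]
            }
        if term == "smolt_year":
            levels = sorted(data[term].astype(int).unique())
            return {
                f"smolt_year[{lv}]": (data[term].astype(int) == lv).to_numpy(float)
                for lv in levels[1:]
            }
        if term in data.columns:
            return {term: data[term].to_numpy(float)}
        raise ValueError(f"unknown term {term!r}")

    for term in terms:
        if INTERACTION_SEP in term:
            a, b = term.split(INTERACTION_SEP, 1)
            for na, ca in coded(a).items():
                for nb, cb in coded(b).items():
                    cols[f"{na}:{nb}"] = ca * cb
        else:
            cols.update(coded(term))
    X = pd.DataFrame(cols, index=data.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError(f"design matrix for terms {list(terms)} is rank deficient")
    return X


@dataclass(frozen=True)
class GlmFit:
    """One fitted binomial logit model."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    aic: float
    n: int
    converged: bool = True
    degenerate: bool = False  # perfect separation / boundary fit

    def __post_init__(self) -> None:
        if not self.degenerate:
            k = len(self.coefficients)
            if abs(self.aic - (2 * k - 2 * self.loglik)) > 1e-8:
                raise ValueError("AIC identity 2k - 2*loglik violated")


def fit_binomial_glm(
    data: pd.DataFrame,
    terms: Sequence[str] = (),
    response: str = "response",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit a binomial logit model of ``response`` on the given terms.

    Rows with a missing value in any used column are dropped.  Raises
    :class:`ConvergenceError` after ``maxiter`` IRLS iterations without
    convergence; a perfectly separated (boundary) fit is returned with
    ``degenerate=True`` and a warning rather than an exception.
    """
    used = {response}
    for t in terms:
        used.update(t.split(INTERACTION_SEP))
    sub = data.dropna(subset=[c for c in used if c in data.columns])
    y = sub[response].to_numpy(float)
    X = build_design_matrix(sub, terms)
    if len(sub) <= X.shape[1]:
        raise ValidationError(
            f"n={len(sub)} rows cannot support {X.shape[1]} coefficients"
        )

    degenerate = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=maxiter, tol=tol)
    except (PerfectSeparationError, PerfectSeparationWarning):
        logger.warning("perfect separation for terms %s; fit flagged degenerate", list(terms))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=maxiter)
        degenerate = True
    if not getattr(res, "converged", True) and not degenerate:
        raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations for {list(terms)}")
    if not degenerate and np.abs(res.params).max() > 15:
        # quasi-separation: coefficients diverging toward the boundary
        logger.warning("quasi-separation suspected for terms %s", list(terms))
        degenerate = True

    names = list(X.columns)
    return GlmFit(
        terms=tuple(terms),
        coefficients={n: float(v) for n, v in zip(names, res.params)},
        standard_errors={n: float(v) for n, v in zip(names, res.bse)},
        loglik=float(res.llf),
        aic=float(res.aic),
        n=int(len(sub)),
        converged=bool(getattr(res, "converged", True)),
        degenerate=degenerate,
    )


def _rank_key(fit: GlmFit) -> tuple[float, int]:
    """Ranking key: AIC rounded to 1e-9 (ties go to fewer coefficients)."""
    return (round(fit.aic / 1e-9) * 1e-9, len(fit.coefficients))


def all_subsets_aic(
    data: pd.DataFrame,
    candidates: Sequence[str],
    interaction: tuple[str, str] | None = None,
    response: str = "response",
) -> tuple[GlmFit, pd.DataFrame]:
    """Fit every admissible subset of candidate terms; pick the lowest AIC.

    With an ``interaction`` (a, b), models containing both main effects
    are additionally fitted with the a:b term (marginality is enforced:
    the interaction never appears without its mains).  Subsets that fail
    to converge or are degenerate are recorded in the returned table but
    excluded from the ranking.  Ties within 1e-9 of AIC go to the model
    with fewer coefficients.
    """
    if len(candidates) > 12:
        raise ValueError("all-subsets enumeration capped at 12 candidate terms")
    subsets: list[tuple[str, ...]] = []
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            subsets.append(combo)
            if interaction and interaction[0] in combo and interaction[1] in combo:
                subsets.append(combo + (f"{interaction[0]}{INTERACTION_SEP}{interaction[1]}",))

    rows = []
    fits: list[GlmFit] = []
    for terms in subsets:
        try:
            fit = fit_binomial_glm(data, terms, response=response)
            ok = not fit.degenerate
        except Exception as exc:  # rank deficiency, convergence failure, ...
            rows.append({"terms": " + ".join(terms) or "1", "k": None, "loglik": None,
                         "aic": None, "status": f"failed: {exc}"})
            continue
        rows.append({
            "terms": " + ".join(terms) or "1",
            "k": len(fit.coefficients),
            "loglik": fit.loglik,
            "aic": fit.aic,
            "status": "ok" if ok else "degenerate",
        })
        if ok:
            fits.append(fit)
    if not fits:
        raise ConvergenceError("no candidate model could be fitted")
    best = min(fits, key=_rank_key)
    table = pd.DataFrame(rows).sort_values(
        "aic", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return best, table
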