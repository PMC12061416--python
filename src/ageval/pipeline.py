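"""End-to-end orchestration: simulate or load a cohort, analyze, report.

A single top-level seed is expanded into independent per-stage streams
by fixed integer labels (cohort generation, radii, reader estimates,
bootstrap), so stages are reproducible independently of one another.
Reports are plain JSON-serializable dicts whose blocks map one-to-one
onto the analysis modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .backcalc import backcalculate_cohort, reader_mean_smolt_bc, smolt_length_bias
from .errors import ConfigError, UndefinedStatisticError
from .glm import FW_TERMS, SEA_TERMS, all_subsets_aic, build_misclassification_response
from .io import FishRecord, ReaderAgeEstimate, ScaleRadiiMeasurement, load_cohort, write_cohort
from .precision import (
    ape,
    bootstrap_ci,
    chang_cv,
    classwise_misclassification,
    percent_error,
)
from .symmetry import VARIANTS, build_agreement_table, symmetry_test
from .synthetic import (
    CohortConfig,
    ReaderProfile,
    ScaleGeometryConfig,
    TruncNormalSpec,
    default_reader_profiles,
    generate_cohort,
    simulate_reader_estimates,
    simulate_scale_radii,
)

__all__ = [
    "stage_seed",
    "configs_from_dict",
    "simulate_cohort_files",
    "precision_report",
    "symmetry_report",
    "backcalc_report",
    "glm_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_STAGE_LABELS = {"cohort": 1, "radii": 2, "reads": 3, "bootstrap": 4}


def stage_seed(seed: int, stage: str) -> int:
    """A per-stage child seed (< 2^31) derived from the top-level seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_LABELS[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# config plumbing
# ---------------------------------------------------------------------------

def _truncnormal_from(d: Mapping[str, Any]) -> TruncNormalSpec:
    return TruncNormalSpec(
        mean=float(d["mean"]), sd=float(d["sd"]),
        lower=float(d["lower"]), upper=float(d["upper"]),
    )


def configs_from_dict(
    sim: Mapping[str, Any], seed: int
) -> tuple[CohortConfig, ScaleGeometryConfig, list[ReaderProfile]]:
    """Build the three simulation configs from a nested (YAML) mapping."""
    c = dict(sim.get("cohort", {}))
    if "smolt_length_dist" in c:
        c["smolt_length_dist"] = _truncnormal_from(c["smolt_length_dist"])
    for pmf_key in ("fw_age_pmf", "sea_age_pmf"):
        if pmf_key in c:
            c[pmf_key] = {int(k): float(v) for k, v in c[pmf_key].items()}
    if "adult_length_by_sea_age" in c:
        c["adult_length_by_sea_age"] = {
            int(k): tuple(v) for k, v in c["adult_length_by_sea_age"].items()
        }
    if "weight_allometry" in c:
        c["weight_allometry"] = tuple(c["weight_allometry"])
    if "smolt_year_range" in c:
        c["smolt_year_range"] = tuple(c["smolt_year_range"])
    c.setdefault("seed", stage_seed(seed, "cohort"))
    cohort_cfg = CohortConfig(**c)

    geom_cfg = ScaleGeometryConfig(**sim.get("geometry", {}))
    readers = sim.get("readers")
    if readers is None:
        profiles = default_reader_profiles()
    else:
        profiles = [ReaderProfile(**r) for r in readers]
    return cohort_cfg, geom_cfg, profiles


def simulate_cohort_files(
    out_dir: str | Path,
    sim: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate a full cohort and write fish.csv / reads.csv / radii.csv."""
    cohort_cfg, geom_cfg, profiles = configs_from_dict(sim or {}, seed)
    fish = generate_cohort(cohort_cfg)
    radii = simulate_scale_radii(
        fish, geom_cfg, profiles, seed=stage_seed(seed, "radii"),
        latent_fw_age_pmf=cohort_cfg.fw_age_pmf,
    )
    reads = simulate_reader_estimates(
        fish, profiles, seed=stage_seed(seed, "reads"),
        latent_fw_age_pmf=cohort_cfg.fw_age_pmf,
    )
    return write_cohort(out_dir, fish, reads, radii)


# ---------------------------------------------------------------------------
# analysis blocks
# ---------------------------------------------------------------------------

def _truth(fish: FishRecord, which: str) -> int | None:
    return fish.true_sea_age if which == "sea" else fish.true_fw_age


def _pooled_pairs(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    which: str,
) -> tuple[list[int], list[int | None]]:
    """Aligned (true, estimate) pairs pooled over readers, truth-known fish only."""
    truth = {f.fish_id: _truth(f, which) for f in fish}
    true_out: list[int] = []
    est_out: list[int | None] = []
    for r in reads:
        t = truth.get(r.fish_id)
        if t is None:
            continue
        true_out.append(t)
        est_out.append(r.sea_age_est if which == "sea" else r.fw_age_est)
    return true_out, est_out


def _fish_units(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    which: str,
) -> np.ndarray:
    """Per-fish (wrong, readable) read counts — the bootstrap resampling unit."""
    truth = {f.fish_id: _truth(f, which) for f in fish}
    acc: dict[str, list[int]] = {}
    for r in reads:
        t = truth.get(r.fish_id)
        est = r.sea_age_est if which == "sea" else r.fw_age_est
        if t is None or est is None:
            continue
        wrong, readable = acc.setdefault(r.fish_id, [0, 0])
        acc[r.fish_id] = [wrong + (est != t), readable + 1]
    return np.array(list(acc.values()), dtype=float).reshape(-1, 2)


def _pe_from_units(units: np.ndarray) -> float:
    readable = units[:, 1].sum()
    if readable == 0:
        raise UndefinedStatisticError("no readable reads in resample")
    return 100.0 * units[:, 0].sum() / readable


def _agreement_block(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    which: str,
    b: int,
    rng: np.random.Generator,
) -> dict[str, Any]:
    true_ages, est_ages = _pooled_pairs(fish, reads, which)
    pe = percent_error(true_ages, est_ages)
    units = _fish_units(fish, reads, which)
    lo, hi = bootstrap_ci(_pe_from_units, units, b=b, seed=rng)
    per_reader = {}
    for rid in sorted({r.reader_id for r in reads}):
        sub = [r for r in reads if r.reader_id == rid]
        t, e = _pooled_pairs(fish, sub, which)
        try:
            per_reader[rid] = {
                "pe": percent_error(t, e),
                "agreement": 100.0 - percent_error(t, e),
                "n_readable": sum(x is not None for x in e),
            }
        except UndefinedStatisticError:
            per_reader[rid] = {"pe": None, "agreement": None, "n_readable": 0}
    n_readable = sum(x is not None for x in est_ages)
    return {
        "pe": pe,
        "agreement": 100.0 - pe,
        "agreement_ci": [100.0 - hi, 100.0 - lo],
        "pe_ci": [lo, hi],
        "n_fish": int(units.shape[0]),
        "n_readable_pairs": n_readable,
        "b_resamples": b,
        "unreadable_convention": "excluded from numerator and denominator",
        "per_reader": per_reader,
    }


def precision_report(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    radii: Sequence[ScaleRadiiMeasurement] | None = None,
    b: int = 1000,
    seed: int | None = None,
) -> dict[str, Any]:
    """PE/agreement with bootstrap CIs, classwise misclassification, and
    smolt-length CV/APE when radii are supplied."""
    rng = np.random.default_rng(seed)
    out: dict[str, Any] = {
        "sea": _agreement_block(fish, reads, "sea", b, rng),
        "fw": None,
        "smolt_length": None,
    }

    # classwise sea-age misclassification (1SW vs MSW)
    known = [f for f in fish if any(r.fish_id == f.fish_id for r in reads)]
    ests_by_reader: dict[str, list[int | None]] = {}
    for rid in sorted({r.reader_id for r in reads}):
        by_fish = {r.fish_id: r.sea_age_est for r in reads if r.reader_id == rid}
        ests_by_reader[rid] = [by_fish.get(f.fish_id) for f in known]
    max_age = max((f.true_sea_age for f in known), default=1)
    classing = {a: ("1SW" if a == 1 else "MSW") for a in range(1, max_age + 1)}
    out["sea"]["classwise"] = classwise_misclassification(
        [f.true_sea_age for f in known], ests_by_reader, classing
    )

    if any(f.true_fw_age is not None for f in fish):
        try:
            out["fw"] = _agreement_block(fish, reads, "fw", b, rng)
        except UndefinedStatisticError:
            logger.info("freshwater agreement undefined: no readable reads on known-age fish")

    if radii:
        from .backcalc import backcalculate_cohort  # local alias for clarity

        results, _ = backcalculate_cohort(radii, fish)
        bc: dict[str, list[float]] = {}
        for r in results:
            if r.smolt_length_bc is not None:
                bc.setdefault(r.fish_id, []).append(r.smolt_length_bc)
        measured = {f.fish_id: f.smolt_length for f in fish if f.smolt_length is not None}
        ids = [fid for fid in bc if fid in measured and len(bc[fid]) >= 2]
        if ids:
            readings = [bc[fid] for fid in ids]
            refs = [measured[fid] for fid in ids]
            cv = chang_cv(readings, refs)
            idx = {fid: i for i, fid in enumerate(ids)}
            units = np.arange(len(ids))
            lo, hi = bootstrap_ci(
                lambda u: chang_cv([readings[i] for i in u], [refs[i] for i in u]),
                units, b=b, seed=rng,
            )
            out["smolt_length"] = {
                "cv": cv,
                "cv_ci": [lo, hi],
                "ape": ape(readings, refs),
                "n_fish": len(ids),
                "b_resamples": b,
                "reference": "measured smolt length",
            }
    return out


def symmetry_report(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    which: str,
    per_reader: bool = False,
) -> dict[str, Any]:
    """Pooled agreement table and all symmetry-test variants."""
    true_ages, est_ages = _pooled_pairs(fish, reads, which)
    table = build_agreement_table(true_ages, est_ages)
    out: dict[str, Any] = {"which": which, "table": table.to_dict(), "tests": {}}
    for variant in VARIANTS:
        try:
            res = symmetry_test(table, variant)
            out["tests"][variant] = {"chi2": res.chi2, "df": res.df, "p": res.p}
        except UndefinedStatisticError:
            out["tests"][variant] = None
    if per_reader:
        out["per_reader"] = {}
        for rid in sorted({r.reader_id for r in reads}):
            sub = [r for r in reads if r.reader_id == rid]
            t, e = _pooled_pairs(fish, sub, which)
            try:
                tab = build_agreement_table(t, e)
                res = symmetry_test(tab, "evans_hoenig")
                out["per_reader"][rid] = {
                    "table": tab.to_dict(),
                    "evans_hoenig": {"chi2": res.chi2, "df": res.df, "p": res.p},
                }
            except UndefinedStatisticError:
                out["per_reader"][rid] = None
    return out


def backcalc_report(
    fish: Sequence[FishRecord],
    radii: Sequence[ScaleRadiiMeasurement],
) -> dict[str, Any]:
    """Pooled (reader-mean) and per-reader bias analyses of smolt length."""
    results, problems = backcalculate_cohort(radii, fish)
    measured = {f.fish_id: f.smolt_length for f in fish if f.smolt_length is not None}

    def bias_dict(pairs: list[tuple[float, float]]) -> dict[str, Any] | None:
        if len(pairs) < 3:
            return None
        m, bcv = zip(*pairs)
        try:
            return dataclasses.asdict(smolt_length_bias(m, bcv))
        except UndefinedStatisticError as exc:
            logger.warning("bias analysis undefined: %s", exc)
            return None

    pooled_bc = reader_mean_smolt_bc(results)
    pooled_pairs = [(measured[f], bc) for f, bc in pooled_bc.items() if f in measured]
    out: dict[str, Any] = {
        "pooled": bias_dict(pooled_pairs),
        "pooled_averaging": "reader_mean",
        "per_reader": {},
        "n_problems": len(problems),
    }
    for rid in sorted({r.reader_id for r in results}):
        pairs = [
            (measured[r.fish_id], r.smolt_length_bc)
            for r in results
            if r.reader_id == rid and r.smolt_length_bc is not None and r.fish_id in measured
        ]
        out["per_reader"][rid] = bias_dict(pairs)
    return out


def glm_report(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate],
    which: str,
    include_interaction: bool = False,
) -> dict[str, Any]:
    """All-subsets AIC selection for the misclassification model."""
    data = build_misclassification_response(fish, reads, which)
    candidates = SEA_TERMS if which == "sea" else FW_TERMS
    interaction = ("age_class", "adult_length") if (include_interaction and which == "sea") else None
    best, table = all_subsets_aic(data, candidates, interaction=interaction)
    return {
        "which": which,
        "n": best.n,
        "best": {
            "terms": list(best.terms),
            "coefficients": best.coefficients,
            "standard_errors": best.standard_errors,
            "loglik": best.loglik,
            "aic": best.aic,
        },
        "model_table": table.to_dict(orient="records"),
        "events": int(data["response"].sum()),
    }


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Simulate (or load) a cohort and run every analysis stage.

    ``config`` needs either a ``simulate`` block (cohort / geometry /
    readers mappings) or a ``data`` block with a cohort directory, plus
    an integer ``seed`` and an optional ``analysis`` block
    (``bootstrap_b``, ``glm_interaction``).
    """
    seed = int(config.get("seed", 0))
    analysis = dict(config.get("analysis", {}))
    b = int(analysis.get("bootstrap_b", 1000))

    if "simulate" in config and "data" in config:
        raise ConfigError("config must not contain both 'simulate' and 'data'")
    if "simulate" in config:
        cohort_cfg, geom_cfg, profiles = configs_from_dict(config["simulate"] or {}, seed)
        fish = generate_cohort(cohort_cfg)
        radii = simulate_scale_radii(
            fish, geom_cfg, profiles, seed=stage_seed(seed, "radii"),
            latent_fw_age_pmf=cohort_cfg.fw_age_pmf,
        )
        reads = simulate_reader_estimates(
            fish, profiles, seed=stage_seed(seed, "reads"),
            latent_fw_age_pmf=cohort_cfg.fw_age_pmf,
        )
        source: dict[str, Any] = {"simulated": True, "n_fish": cohort_cfg.n_fish}
    elif "data" in config:
        fish, reads, radii = load_cohort(config["data"]["dir"])
        source = {"simulated": False, "dir": str(config["data"]["dir"])}
    else:
        raise ConfigError("config needs a 'simulate' or a 'data' block")

    report: dict[str, Any] = {
        "provenance": {
            "package": "ageval",
            "version": __version__,
            "seed": seed,
            "source": source,
            "bootstrap_b": b,
        },
        "precision": precision_report(
            fish, reads, radii, b=b, seed=stage_seed(seed, "bootstrap")
        ),
        "symmetry": {
            "sea": symmetry_report(fish, reads, "sea", per_reader=True),
            "fw": (
                symmetry_report(fish, reads, "fw", per_reader=True)
                if any(f.true_fw_age is not None for f in fish) else None
            ),
        },
        "backcalc": backcalc_report(fish, radii) if radii else None,
        "glm": {
            "sea": glm_report(fish, reads, "sea",
                              include_interaction=bool(analysis.get("glm_interaction", False))),
            "fw": glm_report(fish, reads, "fw"),
        },
    }
    # every value must survive a JSON round trip (schema stability)
    json.dumps(report, allow_nan=True)
    return report
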