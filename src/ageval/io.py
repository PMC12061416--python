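"""Domain types, CSV persistence, and deterministic age derivations.

The data model mirrors a known-age validation study of salmon scale
reading: each fish is PIT-tagged as a smolt (so the year of seaward
migration is known), recaptured as a returning adult (so sea-age is the
simple difference of calendar years), and — for a subset with both
parents genetically identified — has a known freshwater age derived from
the parents' return year.  Several independent readers then estimate the
same ages from a single scale per fish, and may abstain ("unreadable").

Conventions
-----------
* An unreadable / abstained estimate is ``None`` in memory and an empty
  cell on disk — never 0 or -1, because an abstention is informative and
  must not collide with a numeric age.
* Years are plain 4-digit calendar years; the only arithmetic on them is
  subtraction.
* Units: body lengths in cm (0.1 cm precision), weights in kg (0.01 kg),
  scale radii in mm (0.001 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "FishRecord",
    "ReaderAgeEstimate",
    "ScaleRadiiMeasurement",
    "derive_sea_age",
    "derive_freshwater_age",
    "load_cohort",
    "write_cohort",
    "validate_cohort",
]

#: plausible measurement bounds, cm (overridable per call)
SMOLT_LENGTH_BOUNDS = (10.0, 20.0)
ADULT_LENGTH_BOUNDS = (40.0, 120.0)

_SEXES = ("M", "F", "unknown")


# ---------------------------------------------------------------------------
# age derivations
# ---------------------------------------------------------------------------

def derive_sea_age(smolt_year: int, return_year: int, fish_id: str | None = None) -> int:
    """Sea-age in years: the return year minus the smolt (seaward migration) year.

    Raises :class:`ValidationError` if ``return_year <= smolt_year`` (a
    returning adult must have spent at least one winter at sea).
    """
    if return_year <= smolt_year:
        who = f" for fish {fish_id!r}" if fish_id else ""
        raise ValidationError(
            f"return_year {return_year} must exceed smolt_year {smolt_year}{who}"
        )
    return return_year - smolt_year


def derive_freshwater_age(
    smolt_year: int, parent_return_year: int, fish_id: str | None = None
) -> int:
    """Freshwater age: smolt year minus the parents' return year minus 1.

    Offspring hatch the year after their parents spawned, so a fish that
    smolted in 2016 with parents returning in 2013 hatched in 2014 and
    spent 2 years in the river.  A result below 1 year is an impossible
    life history and raises :class:`ValidationError`.
    """
    age = smolt_year - parent_return_year - 1
    if age < 1:
        who = f" for fish {fish_id!r}" if fish_id else ""
        raise ValidationError(
            f"freshwater age {age} < 1 from smolt_year {smolt_year}, "
            f"parent_return_year {parent_return_year}{who}"
        )
    return age


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FishRecord:
    """One tagged fish with its measured sizes and (derived) true ages."""

    fish_id: str
    smolt_year: int
    return_year: int
    smolt_length: float | None  # cm, measured at the smolt trap
    adult_length: float | None  # cm, measured on return
    adult_weight: float | None  # kg
    sex: str = "unknown"
    parent_return_year: int | None = None

    @property
    def true_sea_age(self) -> int:
        return derive_sea_age(self.smolt_year, self.return_year, self.fish_id)

    @property
    def true_fw_age(self) -> int | None:
        """Freshwater age, known only when both parents were identified."""
        if self.parent_return_year is None:
            return None
        return derive_freshwater_age(self.smolt_year, self.parent_return_year, self.fish_id)

    def validate(
        self,
        smolt_length_bounds: tuple[float, float] = SMOLT_LENGTH_BOUNDS,
        adult_length_bounds: tuple[float, float] = ADULT_LENGTH_BOUNDS,
    ) -> None:
        fid = self.fish_id
        # property accessors raise on year inconsistencies
        self.true_sea_age
        self.true_fw_age
        if self.sex not in _SEXES:
            raise ValidationError(f"fish {fid!r}: sex {self.sex!r} not in {_SEXES}")
        lo, hi = smolt_length_bounds
        if self.smolt_length is not None and not (lo <= self.smolt_length <= hi):
            raise ValidationError(
                f"fish {fid!r}: smolt_length {self.smolt_length} outside [{lo}, {hi}] cm"
            )
        lo, hi = adult_length_bounds
        if self.adult_length is not None and not (lo <= self.adult_length <= hi):
            raise ValidationError(
                f"fish {fid!r}: adult_length {self.adult_length} outside [{lo}, {hi}] cm"
            )
        if (
            self.smolt_length is not None
            and self.adult_length is not None
            and self.adult_length <= self.smolt_length
        ):
            raise ValidationError(
                f"fish {fid!r}: adult_length {self.adult_length} <= smolt_length "
                f"{self.smolt_length}"
            )
        if self.adult_weight is not None and self.adult_weight <= 0:
            raise ValidationError(f"fish {fid!r}: adult_weight {self.adult_weight} <= 0")


@dataclass(frozen=True)
class ReaderAgeEstimate:
    """One reader's freshwater- and sea-age calls for one fish.

    ``None`` means the reader deemed the scale unreadable for that age.
    """

    fish_id: str
    reader_id: str
    fw_age_est: int | None
    sea_age_est: int | None

    def validate(self) -> None:
        for name, val in (("fw_age_est", self.fw_age_est), ("sea_age_est", self.sea_age_est)):
            if val is not None and (not isinstance(val, int) or val < 1):
                raise ValidationError(
                    f"fish {self.fish_id!r} reader {self.reader_id!r}: "
                    f"{name}={val!r} must be a positive integer or unreadable"
                )


@dataclass(frozen=True)
class ScaleRadiiMeasurement:
    """One reader's radius measurements on one fish's scale.

    ``annulus_radii`` are the distances (mm) from the scale centre to each
    winter mark, freshwater marks first then sea marks, strictly
    increasing.  ``smolt_mark_radius`` is the radius at the circulus that
    ends the freshwater phase; ``None`` when the reader abstained from
    placing it.
    """

    fish_id: str
    reader_id: str
    total_radius: float  # mm, scale centre to edge
    smolt_mark_radius: float | None
    annulus_radii: tuple[float, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        fid, rid = self.fish_id, self.reader_id
        if self.total_radius <= 0:
            raise ValidationError(f"fish {fid!r} reader {rid!r}: total_radius <= 0")
        prev = 0.0
        for r in self.annulus_radii:
            if not (prev < r <= self.total_radius + 1e-12):
                raise ValidationError(
                    f"fish {fid!r} reader {rid!r}: annulus radii must be strictly "
                    f"increasing and <= total_radius ({self.annulus_radii}, "
                    f"S_c={self.total_radius})"
                )
            prev = r
        if self.smolt_mark_radius is not None:
            if not (0 < self.smolt_mark_radius <= self.total_radius + 1e-12):
                raise ValidationError(
                    f"fish {fid!r} reader {rid!r}: smolt_mark_radius "
                    f"{self.smolt_mark_radius} outside (0, S_c]"
                )
            # sea annuli are those beyond the smolt mark; the first of them
            # must not precede the smolt mark
            sea = [r for r in self.annulus_radii if r > self.smolt_mark_radius - 1e-12]
            if sea and sea[0] < self.smolt_mark_radius - 1e-12:
                raise ValidationError(
                    f"fish {fid!r} reader {rid!r}: smolt mark beyond first sea annulus"
                )


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

FISH_COLUMNS = [
    "fish_id", "smolt_year", "return_year", "smolt_length_cm",
    "adult_length_cm", "adult_weight_kg", "sex", "parent_return_year",
]
READS_COLUMNS = ["fish_id", "reader_id", "fw_age_est", "sea_age_est"]
RADII_COLUMNS = [
    "fish_id", "reader_id", "total_radius_mm", "smolt_mark_radius_mm",
    "annulus_radii_mm",
]


def _fmt(value: float | int | None, ndec: int | None = None) -> str:
    if value is None:
        return ""
    if ndec is None:
        return str(value)
    return f"{value:.{ndec}f}"


def _opt_int(raw: str, where: str) -> int | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError as exc:
        raise SchemaError(f"{where}: expected integer, got {raw!r}") from exc


def _opt_float(raw: str, where: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise SchemaError(f"{where}: expected number, got {raw!r}") from exc


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def write_cohort(
    out_dir: str | Path,
    fish: Iterable[FishRecord],
    reads: Iterable[ReaderAgeEstimate] = (),
    radii: Iterable[ScaleRadiiMeasurement] = (),
) -> dict[str, Path]:
    """Write fish.csv / reads.csv / radii.csv into ``out_dir``.

    Lengths are written at 0.1 cm, weights at 0.01 kg and radii at
    0.001 mm precision; unreadable values become empty cells.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = [
        {
            "fish_id": f.fish_id,
            "smolt_year": f.smolt_year,
            "return_year": f.return_year,
            "smolt_length_cm": _fmt(f.smolt_length, 1),
            "adult_length_cm": _fmt(f.adult_length, 1),
            "adult_weight_kg": _fmt(f.adult_weight, 2),
            "sex": f.sex,
            "parent_return_year": _fmt(f.parent_return_year),
        }
        for f in fish
    ]
    paths["fish"] = out / "fish.csv"
    pd.DataFrame(rows, columns=FISH_COLUMNS).to_csv(paths["fish"], index=False)

    rows = [
        {
            "fish_id": r.fish_id,
            "reader_id": r.reader_id,
            "fw_age_est": _fmt(r.fw_age_est),
            "sea_age_est": _fmt(r.sea_age_est),
        }
        for r in reads
    ]
    paths["reads"] = out / "reads.csv"
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(paths["reads"], index=False)

    rows = [
        {
            "fish_id": m.fish_id,
            "reader_id": m.reader_id,
            "total_radius_mm": _fmt(m.total_radius, 3),
            "smolt_mark_radius_mm": _fmt(m.smolt_mark_radius, 3),
            "annulus_radii_mm": ";".join(f"{r:.3f}" for r in m.annulus_radii),
        }
        for m in radii
    ]
    paths["radii"] = out / "radii.csv"
    pd.DataFrame(rows, columns=RADII_COLUMNS).to_csv(paths["radii"], index=False)
    return paths


def load_cohort(
    in_dir: str | Path,
    validate: bool = True,
) -> tuple[list[FishRecord], list[ReaderAgeEstimate], list[ScaleRadiiMeasurement]]:
    """Load a cohort directory written by :func:`write_cohort`.

    Empty cells decode to ``None`` (unreadable / unknown).  With
    ``validate`` (default) every record's invariants are checked and a
    :class:`ValidationError` naming the offending fish is raised on the
    first violation; row counts are otherwise preserved exactly.
    """
    src = Path(in_dir)
    fish_path, reads_path, radii_path = src / "fish.csv", src / "reads.csv", src / "radii.csv"
    if not fish_path.exists():
        raise SchemaError(f"{fish_path} not found")

    fish: list[FishRecord] = []
    for i, row in _read_csv(fish_path, FISH_COLUMNS[:7]).iterrows():
        where = f"fish.csv row {i}"
        smolt_year = _opt_int(row["smolt_year"], where)
        return_year = _opt_int(row["return_year"], where)
        if smolt_year is None or return_year is None:
            raise SchemaError(f"{where}: smolt_year and return_year are mandatory")
        fish.append(
            FishRecord(
                fish_id=row["fish_id"].strip(),
                smolt_year=smolt_year,
                return_year=return_year,
                smolt_length=_opt_float(row["smolt_length_cm"], where),
                adult_length=_opt_float(row["adult_length_cm"], where),
                adult_weight=_opt_float(row["adult_weight_kg"], where),
                sex=row["sex"].strip() or "unknown",
                parent_return_year=_opt_int(row.get("parent_return_year", ""), where),
            )
        )

    reads: list[ReaderAgeEstimate] = []
    if reads_path.exists():
        for i, row in _read_csv(reads_path, READS_COLUMNS).iterrows():
            where = f"reads.csv row {i}"
            reads.append(
                ReaderAgeEstimate(
                    fish_id=row["fish_id"].strip(),
                    reader_id=row["reader_id"].strip(),
                    fw_age_est=_opt_int(row["fw_age_est"], where),
                    sea_age_est=_opt_int(row["sea_age_est"], where),
                )
            )

    radii: list[ScaleRadiiMeasurement] = []
    if radii_path.exists():
        for i, row in _read_csv(radii_path, RADII_COLUMNS).iterrows():
            where = f"radii.csv row {i}"
            total = _opt_float(row["total_radius_mm"], where)
            if total is None:
                raise SchemaError(f"{where}: total_radius_mm is mandatory")
            raw = row["annulus_radii_mm"].strip()
            annuli = tuple(
                float(tok) for tok in raw.split(";") if tok.strip() != ""
            ) if raw else ()
            radii.append(
                ScaleRadiiMeasurement(
                    fish_id=row["fish_id"].strip(),
                    reader_id=row["reader_id"].strip(),
                    total_radius=total,
                    smolt_mark_radius=_opt_float(row["smolt_mark_radius_mm"], where),
                    annulus_radii=annuli,
                )
            )

    if validate:
        validate_cohort(fish, reads, radii)
    return fish, reads, radii


def validate_cohort(
    fish: Sequence[FishRecord],
    reads: Sequence[ReaderAgeEstimate] = (),
    radii: Sequence[ScaleRadiiMeasurement] = (),
) -> None:
    """Check every record invariant plus cross-table referential integrity."""
    seen = set()
    for f in fish:
        if f.fish_id in seen:
            raise ValidationError(f"duplicate fish_id {f.fish_id!r}")
        seen.add(f.fish_id)
        f.validate()
    for r in reads:
        r.validate()
        if r.fish_id not in seen:
            raise ValidationError(f"reads: unknown fish_id {r.fish_id!r}")
    for m in radii:
        m.validate()
        if m.fish_id not in seen:
            raise ValidationError(f"radii: unknown fish_id {m.fish_id!r}")
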