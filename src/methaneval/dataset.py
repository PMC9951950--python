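"""Domain types and CSV I/O for paired observed/simulated animal records and diet compositions.

The canonical on-disk format is UTF-8 CSV with a header row and '.' as the
decimal mark. Column names for the records file are configurable through a
*dialect* map (``{canonical_name: file_column_name}``) because upstream data
sources use no fixed naming convention.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DietLookupError,
    ParseError,
    ValidationError,
)

#: Tolerance (percentage points) for composition closure checks. Published
#: composition tables are rounded, so fractions may overshoot 100 slightly and
#: the tabulated NSC may differ from the by-difference value.
NSC_TOLERANCE = 0.15

RECORD_COLUMNS = (
    "animal_id",
    "diet_id",
    "period",
    "bw_kg",
    "dmi_obs",
    "dmi_sim",
    "ch4_obs",
    "ch4_sim",
)

_MEASUREMENTS = ("dmi_obs", "dmi_sim", "ch4_obs", "ch4_sim")

UNITS = {"dmi": "kg DM/d", "ch4": "L/d"}


@dataclass(frozen=True)
class AnimalRecord:
    """One animal x diet observation with its paired model predictions.

    Measurement fields may be ``None`` when that variable was not recorded;
    the record then remains usable for the other variable.
    """

    animal_id: str
    diet_id: str
    period: int
    bw_kg: float
    dmi_obs: float | None = None
    dmi_sim: float | None = None
    ch4_obs: float | None = None
    ch4_sim: float | None = None

    def __post_init__(self) -> None:
        if not self.bw_kg > 0:
            raise ValidationError(
                f"record ({self.animal_id}, {self.diet_id}): bw_kg must be > 0, got {self.bw_kg}"
            )
        for name in _MEASUREMENTS:
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(
                    f"record ({self.animal_id}, {self.diet_id}): {name} must be strictly positive, got {value}"
                )


@dataclass(frozen=True)
class DietComposition:
    """Nutritional composition of one forage diet, all fractions as % of DM."""

    diet_id: str
    cp: float
    ndf: float
    nsc: float
    ee: float
    ash: float
    ivdmd: float
    leucaena: bool = False
    leucaena_species: str | None = None

    def __post_init__(self) -> None:
        for name in ("cp", "ndf", "nsc", "ee", "ash", "ivdmd"):
            value = getattr(self, name)
            if not 0 < value < 100:
                raise ValidationError(
                    f"diet {self.diet_id}: {name}={value} outside (0, 100)"
                )

    def check_closure(self, tolerance: float = NSC_TOLERANCE) -> None:
        """Raise unless the five fractions sum to at most 100 (plus rounding slack).

        Enforced on dataset ingestion, not construction: one-at-a-time
        sensitivity substitutions legitimately break closure.
        """
        total = self.cp + self.ndf + self.nsc + self.ee + self.ash
        if total > 100 + tolerance:
            raise ValidationError(
                f"diet {self.diet_id}: fractions sum to {total:.2f} > 100"
            )

    def check_nsc_consistency(self, tolerance: float = NSC_TOLERANCE) -> None:
        """Raise unless the tabulated NSC agrees with the by-difference value."""
        derived = derive_nsc(self.cp, self.ndf, self.ee, self.ash)
        if abs(derived - self.nsc) > tolerance:
            raise ValidationError(
                f"diet {self.diet_id}: nsc={self.nsc} inconsistent with "
                f"by-difference value {derived:.2f} (tolerance {tolerance})"
            )


@dataclass
class PairedSeries:
    """Aligned observed/simulated vectors; the object every statistic consumes."""

    o: np.ndarray
    s: np.ndarray
    group: np.ndarray
    variable: str
    units: str = ""

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.group = np.asarray(self.group)
        if not (len(self.o) == len(self.s) == len(self.group)):
            raise ValidationError(
                f"o, s and group must have equal length; got "
                f"{len(self.o)}, {len(self.s)}, {len(self.group)}"
            )
        if len(self.o) < 1:
            raise ValidationError("paired series must contain at least one pair")
        if not np.all(self.o > 0):
            bad = int(np.flatnonzero(~(self.o > 0))[0])
            raise ValidationError(
                f"observed values must be strictly positive (index {bad})"
            )

    def __len__(self) -> int:
        return len(self.o)

    def subset(self, mask: np.ndarray) -> "PairedSeries":
        mask = np.asarray(mask, dtype=bool)
        return PairedSeries(
            self.o[mask], self.s[mask], self.group[mask], self.variable, self.units
        )


def derive_nsc(cp: float, ndf: float, ee: float, ash: float) -> float:
    """Non-structural carbohydrate by difference: 100 - ash - cp - ndf - ee.

    Organic matter is 100 - ash; NSC is the organic matter not accounted for
    by protein, fiber or fat.
    """
    for name, value in (("cp", cp), ("ndf", ndf), ("ee", ee), ("ash", ash)):
        if not 0 < value < 100:
            raise ValidationError(f"{name}={value} outside (0, 100)")
    nsc = 100.0 - ash - cp - ndf - ee
    if nsc <= 0:
        raise ValidationError(
            f"derived NSC {nsc:.2f} <= 0: composition inconsistent "
            f"(cp={cp}, ndf={ndf}, ee={ee}, ash={ash})"
        )
    return nsc


def _parse_float(raw: str, column: str, row: int, required: bool) -> float | None:
    raw = raw.strip() if raw is not None else ""
    if raw == "":
        if required:
            raise ParseError(f"row {row}: missing value for '{column}'", row=row)
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise ParseError(
            f"row {row}: non-numeric value {raw!r} for '{column}'", row=row
        ) from exc
    if not math.isfinite(value):
        raise ParseError(f"row {row}: non-finite value for '{column}'", row=row)
    return value


def read_records(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[AnimalRecord]:
    """Read and validate animal records from CSV.

    ``dialect`` maps canonical column names (see :data:`RECORD_COLUMNS`) to the
    names actually used in the file; unmapped columns keep their canonical name.
    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    dialect = dict(dialect or {})
    unknown = set(dialect) - set(RECORD_COLUMNS)
    if unknown:
        raise ConfigurationError(f"dialect maps unknown columns: {sorted(unknown)}")
    colmap = {canon: dialect.get(canon, canon) for canon in RECORD_COLUMNS}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canon in ("animal_id", "diet_id", "period", "bw_kg"):
            if colmap[canon] not in header:
                raise ConfigurationError(
                    f"{path}: required column '{colmap[canon]}' (for {canon}) not found"
                )
        records: list[AnimalRecord] = []
        seen: set[tuple[str, str]] = set()
        for i, row in enumerate(reader, start=1):
            animal_id = (row.get(colmap["animal_id"]) or "").strip()
            diet_id = (row.get(colmap["diet_id"]) or "").strip()
            if not animal_id or not diet_id:
                raise ParseError(f"row {i}: empty animal_id or diet_id", row=i)
            key = (animal_id, diet_id)
            if key in seen:
                raise ValidationError(
                    f"row {i}: duplicate (animal_id, diet_id) = {key}"
                )
            seen.add(key)
            period_raw = (row.get(colmap["period"]) or "").strip()
            try:
                period = int(period_raw)
            except ValueError as exc:
                raise ParseError(
                    f"row {i}: non-integer period {period_raw!r}", row=i
                ) from exc
            bw = _parse_float(row.get(colmap["bw_kg"], ""), "bw_kg", i, required=True)
            values = {
                name: _parse_float(
                    row.get(colmap[name], ""), name, i, required=False
                )
                for name in _MEASUREMENTS
            }
            try:
                records.append(
                    AnimalRecord(
                        animal_id=animal_id,
                        diet_id=diet_id,
                        period=period,
                        bw_kg=bw,
                        **values,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_records(
    records: Iterable[AnimalRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records to CSV (inverse of :func:`read_records`) at full precision."""
    dialect = dict(dialect or {})
    colmap = {canon: dialect.get(canon, canon) for canon in RECORD_COLUMNS}
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([colmap[c] for c in RECORD_COLUMNS])
        for rec in records:
            writer.writerow(
                [
                    rec.animal_id,
                    rec.diet_id,
                    rec.period,
                    repr(rec.bw_kg),
                ]
                + [
                    "" if getattr(rec, m) is None else repr(getattr(rec, m))
                    for m in _MEASUREMENTS
                ]
            )


_DIET_COLUMNS = (
    "diet_id",
    "cp",
    "ndf",
    "nsc",
    "ee",
    "ash",
    "ivdmd",
    "leucaena",
    "leucaena_species",
)


def read_diets(path: str | Path) -> list[DietComposition]:
    """Read diet compositions from CSV (columns: diet_id, cp, ndf, nsc, ee, ash, ivdmd, leucaena[, leucaena_species])."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _DIET_COLUMNS[:8]:
            if col not in header:
                raise ConfigurationError(f"{path}: required column '{col}' not found")
        diets = []
        for i, row in enumerate(reader, start=1):
            leuc_raw = (row.get("leucaena") or "").strip().lower()
            if leuc_raw not in {"true", "false", "1", "0", "yes", "no"}:
                raise ParseError(
                    f"row {i}: leucaena flag {leuc_raw!r} not boolean", row=i
                )
            species = (row.get("leucaena_species") or "").strip() or None
            try:
                diets.append(
                    DietComposition(
                        diet_id=row["diet_id"].strip(),
                        cp=_parse_float(row["cp"], "cp", i, True),
                        ndf=_parse_float(row["ndf"], "ndf", i, True),
                        nsc=_parse_float(row["nsc"], "nsc", i, True),
                        ee=_parse_float(row["ee"], "ee", i, True),
                        ash=_parse_float(row["ash"], "ash", i, True),
                        ivdmd=_parse_float(row["ivdmd"], "ivdmd", i, True),
                        leucaena=leuc_raw in {"true", "1", "yes"},
                        leucaena_species=species,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
    ids = [d.diet_id for d in diets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate diet_id values")
    for d in diets:
        d.check_closure()
    return diets


def write_diets(diets: Iterable[DietComposition], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DIET_COLUMNS)
        for d in diets:
            writer.writerow(
                [
                    d.diet_id,
                    repr(d.cp),
                    repr(d.ndf),
                    repr(d.nsc),
                    repr(d.ee),
                    repr(d.ash),
                    repr(d.ivdmd),
                    str(d.leucaena).lower(),
                    d.leucaena_species or "",
                ]
            )


def default_diets() -> list[DietComposition]:
    """The six packaged tropical forage diet compositions."""
    ref = resources.files("methaneval.data").joinpath("diets.csv")
    with resources.as_file(ref) as p:
        return read_diets(p)


def to_paired(
    records: Sequence[AnimalRecord],
    variable: str,
    diets: Sequence[DietComposition],
) -> PairedSeries:
    """Assemble the paired observed/simulated series for ``variable`` ('dmi' or 'ch4').

    Group labels are the leucaena flag of each record's diet.
    """
    if variable not in UNITS:
        raise ConfigurationError(f"variable must be 'dmi' or 'ch4', got {variable!r}")
    if not records:
        raise ValidationError("empty record set")
    by_id = {d.diet_id: d for d in diets}
    o, s, group = [], [], []
    for rec in records:
        diet = by_id.get(rec.diet_id)
        if diet is None:
            raise DietLookupError(
                f"record ({rec.animal_id}, {rec.diet_id}): unknown diet_id"
            )
        obs = getattr(rec, f"{variable}_obs")
        sim = getattr(rec, f"{variable}_sim")
        if obs is None or sim is None:
            raise ValidationError(
                f"record ({rec.animal_id}, {rec.diet_id}): missing {variable} measurement"
            )
        o.append(obs)
        s.append(sim)
        group.append(diet.leucaena)
    return PairedSeries(
        np.array(o), np.array(s), np.array(group, dtype=bool), variable, UNITS[variable]
    )
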