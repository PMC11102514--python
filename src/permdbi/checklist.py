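"""Species checklists scored with the Dragonfly Biotic Index (DBI).

The DBI assigns each odonate species a score from 0 (widespread habitat
generalist) to 9 (restricted, threatened, highly sensitive specialist),
computed as the sum of three subindices — geographic distribution, IUCN
threat status and sensitivity to disturbance — each scored 0–3.

This module holds the checklist data model (:class:`SpeciesRecord`,
:class:`ChecklistPool`), CSV readers/writers, a synthetic pool generator
emulating a Central-European-like regional species pool, and the
occupancy-based calibration of the probability-weight base ``x`` used by
the permutation machinery.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesRecord",
    "ChecklistPool",
    "ChecklistLoad",
    "OccupancyRecord",
    "OccupancyTable",
    "CalibrationReport",
    "ChecklistError",
    "ChecklistParseError",
    "ChecklistValidationError",
    "normalize_name",
    "read_checklist",
    "write_checklist",
    "read_occupancy",
    "synthetic_pool",
    "synthetic_pool_target_counts",
    "calibrate_weight_base",
    "recommend_base_from_class_means",
]

#: Canonical checklist CSV column names.
CHECKLIST_COLUMNS = ("species", "dbi_d", "dbi_t", "dbi_s", "dbi")

_WS_RUN = re.compile(r"\s+")


class ChecklistError(ValueError):
    """Base class for checklist problems."""


class ChecklistParseError(ChecklistError):
    """Malformed CSV (missing columns, non-numeric cells)."""


class ChecklistValidationError(ChecklistError):
    """Structurally valid CSV whose content violates DBI invariants."""


def normalize_name(name: str) -> str:
    """Normalization key for species-name matching.

    Trims leading/trailing whitespace, collapses internal whitespace runs
    to single spaces and casefolds.  The original spelling is preserved in
    the records; only comparisons use this key.
    """
    return _WS_RUN.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class SpeciesRecord:
    """One checklist entry: a species and its DBI scores.

    Subindices may all be ``None`` for total-only checklists; when present
    each must lie in {0,1,2,3} and sum to ``dbi_total``.
    """

    name: str
    dbi_total: int
    dbi_distribution: int | None = None
    dbi_threat: int | None = None
    dbi_sensitivity: int | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ChecklistValidationError("species name must be non-empty")
        if not (0 <= int(self.dbi_total) <= 9):
            raise ChecklistValidationError(
                f"{self.name!r}: total DBI {self.dbi_total} outside 0-9"
            )
        subs = (self.dbi_distribution, self.dbi_threat, self.dbi_sensitivity)
        present = [s for s in subs if s is not None]
        if present and len(present) != 3:
            raise ChecklistValidationError(
                f"{self.name!r}: subindices must be all present or all absent"
            )
        for s in present:
            if not (0 <= int(s) <= 3):
                raise ChecklistValidationError(
                    f"{self.name!r}: subindex {s} outside 0-3"
                )
        if present and sum(present) != self.dbi_total:
            raise ChecklistValidationError(
                f"{self.name!r}: total {self.dbi_total} != "
                f"sum of subindices {sum(present)}"
            )

    @property
    def has_subindices(self) -> bool:
        return self.dbi_distribution is not None

    @property
    def key(self) -> str:
        return normalize_name(self.name)


@dataclass(frozen=True)
class ChecklistPool:
    """A validated regional species pool.

    Serves both as the lookup table resolving field samples to DBI scores
    and as the universe from which random communities are assembled.
    Species names must be unique after normalization.
    """

    records: tuple[SpeciesRecord, ...]
    region_label: str = "unnamed pool"

    def __post_init__(self) -> None:
        if not self.records:
            raise ChecklistValidationError("pool must contain at least one species")
        seen: dict[str, str] = {}
        dupes = []
        for rec in self.records:
            if rec.key in seen:
                dupes.append(f"{seen[rec.key]!r} / {rec.name!r}")
            seen[rec.key] = rec.name
        if dupes:
            raise ChecklistValidationError(
                "duplicate species names after normalization: " + "; ".join(dupes)
            )
        object.__setattr__(
            self, "_index", {rec.key: rec for rec in self.records}
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._index

    def lookup(self, name: str) -> SpeciesRecord:
        key = normalize_name(name)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"species {name!r} not in pool {self.region_label!r}") from None

    def score(self, name: str) -> int:
        return self.lookup(name).dbi_total

    def totals(self) -> np.ndarray:
        """Total DBI score per species, in checklist order."""
        return np.array([r.dbi_total for r in self.records], dtype=np.int64)

    def names(self) -> list[str]:
        return [r.name for r in self.records]


@dataclass(frozen=True)
class ChecklistLoad:
    """Result of reading a checklist: the validated pool plus exclusions."""

    pool: ChecklistPool
    excluded: tuple[str, ...] = ()

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _parse_score(cell: str | None, *, line: int, col: str) -> int | None:
    if cell is None:
        return None
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "N/A", "NAN"}:
        return None
    try:
        value = float(cell)
    except ValueError:
        raise ChecklistParseError(
            f"line {line}: column {col!r} has non-numeric value {cell!r}"
        ) from None
    if value != int(value):
        raise ChecklistParseError(
            f"line {line}: column {col!r} has non-integer value {cell!r}"
        )
    return int(value)


def read_checklist(
    path: str | Path,
    *,
    region_label: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> ChecklistLoad:
    """Read a species checklist CSV into a validated :class:`ChecklistPool`.

    The expected dialect is UTF-8, comma-separated, with a header row using
    the canonical column names ``species, dbi_d, dbi_t, dbi_s, dbi``.  A
    total-only checklist (``species, dbi``) is accepted; subindex-dependent
    operations are then unavailable.  ``columns`` may remap canonical names
    to the file's header names.

    Rows whose total score cannot be determined (blank total and blank or
    incomplete subindices) are excluded from the pool and reported in
    :attr:`ChecklistLoad.excluded` — missing scores are never imputed.

    Raises
    ------
    ChecklistParseError
        Malformed CSV: missing required header columns or non-numeric cells
        (the message names the offending line).
    ChecklistValidationError
        Out-of-range scores, total inconsistent with the subindices, or
        duplicate species names (the message names the offending species).
    """
    path = Path(path)
    colmap = dict(zip(CHECKLIST_COLUMNS, CHECKLIST_COLUMNS))
    if columns:
        colmap.update(columns)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if colmap["species"] not in header:
            raise ChecklistParseError(
                f"{path}: missing species column {colmap['species']!r}"
            )
        has_subs = all(colmap[c] in header for c in ("dbi_d", "dbi_t", "dbi_s"))
        has_total = colmap["dbi"] in header
        if not has_subs and not has_total:
            raise ChecklistParseError(
                f"{path}: need either a total column {colmap['dbi']!r} or all "
                f"three subindex columns"
            )

        records: list[SpeciesRecord] = []
        excluded: list[str] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            name = (row.get(colmap["species"]) or "").strip()
            if not name:
                excluded.append(f"<blank name at line {lineno}>")
                continue
            subs = None
            if has_subs:
                raw = [
                    _parse_score(row.get(colmap[c]), line=lineno, col=colmap[c])
                    for c in ("dbi_d", "dbi_t", "dbi_s")
                ]
                subs = raw if all(s is not None for s in raw) else None
            total = (
                _parse_score(row.get(colmap["dbi"]), line=lineno, col=colmap["dbi"])
                if has_total
                else None
            )
            if total is None and subs is not None:
                total = sum(subs)
            if total is None:
                excluded.append(name)
                continue
            try:
                records.append(
                    SpeciesRecord(
                        name=name,
                        dbi_total=total,
                        dbi_distribution=subs[0] if subs else None,
                        dbi_threat=subs[1] if subs else None,
                        dbi_sensitivity=subs[2] if subs else None,
                    )
                )
            except ChecklistValidationError as exc:
                problems.append(str(exc))
        if problems:
            raise ChecklistValidationError(
                f"{path}: invalid records: " + "; ".join(problems)
            )

    pool = ChecklistPool(tuple(records), region_label=region_label or path.stem)
    return ChecklistLoad(pool=pool, excluded=tuple(excluded))


def write_checklist(pool: ChecklistPool, path: str | Path) -> None:
    """Write a pool back to the canonical checklist CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CHECKLIST_COLUMNS)
        for rec in pool:
            writer.writerow(
                [
                    rec.name,
                    "" if rec.dbi_distribution is None else rec.dbi_distribution,
                    "" if rec.dbi_threat is None else rec.dbi_threat,
                    "" if rec.dbi_sensitivity is None else rec.dbi_sensitivity,
                    rec.dbi_total,
                ]
            )


# ---------------------------------------------------------------------------
# Synthetic pool generation
# ---------------------------------------------------------------------------

def synthetic_pool_target_counts(n_species: int, decay: float = 2.0) -> np.ndarray:
    """Deterministic species counts per total DBI value 0–9.

    One species is reserved at every value (so all ten totals are always
    represented); the remainder is apportioned by largest remainder to
    quotas proportional to ``decay**-value``.  For ``decay > 1`` the
    resulting counts are non-increasing in the DBI value, mirroring the
    rarity gradient of real regional pools (high scorers are scarce).
    """
    if n_species < 10:
        raise ValueError("n_species must be >= 10 to cover all DBI totals 0-9")
    if decay <= 0:
        raise ValueError("decay must be positive")
    counts = np.ones(10, dtype=np.int64)
    spare = n_species - 10
    weights = decay ** -np.arange(10, dtype=float)
    quota = spare * weights / weights.sum()
    counts += np.floor(quota).astype(np.int64)
    remainder = quota - np.floor(quota)
    short = n_species - int(counts.sum())
    # ties in the remainders resolve toward lower (commoner) DBI values
    for v in np.argsort(-remainder, kind="stable")[:short]:
        counts[v] += 1
    return counts


def _split_total(total: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Random split of a total DBI score into three subindices in 0–3."""
    while True:
        d = int(rng.integers(max(0, total - 6), min(3, total) + 1))
        rest = total - d
        t_lo, t_hi = max(0, rest - 3), min(3, rest)
        t = int(rng.integers(t_lo, t_hi + 1))
        s = rest - t
        if 0 <= s <= 3:
            return d, t, s


def synthetic_pool(
    n_species: int = 68,
    seed: int = 0,
    decay: float = 2.0,
    region_label: str = "synthetic Central-European-like pool",
) -> ChecklistPool:
    """Generate a synthetic regional species pool.

    Emulates a Central-European-like checklist: by default 68 scored
    species whose frequency decreases with the total DBI value roughly by
    a factor of ``decay`` per score step (default 2).  Every total value
    0–9 is represented by at least one species, so communities of any
    composition class can be assembled.  Names are synthetic placeholders;
    subindices are drawn randomly among the valid splits of each total.
    Deterministic for a fixed ``(n_species, seed, decay)``.
    """
    counts = synthetic_pool_target_counts(n_species, decay)
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for value in range(10):
        for _ in range(int(counts[value])):
            i += 1
            d, t, s = _split_total(value, rng)
            records.append(
                SpeciesRecord(
                    name=f"Simulicium sp{i:03d}",
                    dbi_total=value,
                    dbi_distribution=d,
                    dbi_threat=t,
                    dbi_sensitivity=s,
                )
            )
    return ChecklistPool(tuple(records), region_label=region_label)


# ---------------------------------------------------------------------------
# Occupancy-based calibration of the weight base x
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyRecord:
    name: str
    quadrats_occupied: int
    dbi_distribution: int

    def __post_init__(self) -> None:
        if self.quadrats_occupied < 0:
            raise ChecklistValidationError(
                f"{self.name!r}: negative quadrat count"
            )
        if not (0 <= self.dbi_distribution <= 3):
            raise ChecklistValidationError(
                f"{self.name!r}: distribution subindex outside 0-3"
            )


@dataclass(frozen=True)
class OccupancyTable:
    """Quadrat-occupancy counts per species with the distribution subindex."""

    rows: tuple[OccupancyRecord, ...]

    def __post_init__(self) -> None:
        if not any(r.quadrats_occupied > 0 for r in self.rows):
            raise ChecklistValidationError(
                "occupancy table needs at least one species with a positive count"
            )

    def __len__(self) -> int:
        return len(self.rows)


def read_occupancy(path: str | Path) -> OccupancyTable:
    """Read an occupancy CSV with columns ``species, quadrats, dbi_d``."""
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "quadrats", "dbi_d"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ChecklistParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            q = _parse_score(row.get("quadrats"), line=lineno, col="quadrats")
            d = _parse_score(row.get("dbi_d"), line=lineno, col="dbi_d")
            if q is None or d is None:
                raise ChecklistParseError(f"{path}: line {lineno}: blank cell")
            rows.append(
                OccupancyRecord(
                    name=(row.get("species") or "").strip(),
                    quadrats_occupied=q,
                    dbi_distribution=d,
                )
            )
    return OccupancyTable(tuple(rows))


@dataclass(frozen=True)
class CalibrationReport:
    """Occupancy-rate calibration of the probability-weight base ``x``.

    ``class_means`` holds the mean occupancy rate per distribution-subindex
    class 0, 1 and 2 (class 3 is excluded: range-edge species whose
    occupancy confounds the relationship); ``ratios`` the successive
    rate ratios R1/R0 and R2/R1; ``x_exact`` the reciprocal of their
    geometric mean; ``x_recommended`` that value rounded to the nearest
    integer (the weight function uses an integer base by convention).
    """

    class_means: dict[int, float]
    ratios: tuple[float, float]
    x_exact: float
    x_recommended: int


def recommend_base_from_class_means(
    class_means: Sequence[float],
) -> CalibrationReport:
    """Derive the weight base ``x`` from mean occupancy rates of classes 0–2.

    The weight function ``P(DBI) = x**-DBI`` presumes occupancy falls by a
    constant factor ``1/x`` per unit of the distribution subindex; the
    geometric mean of the successive class-mean ratios estimates that
    factor, and its reciprocal, rounded to the nearest integer, is the
    recommended base.
    """
    if len(class_means) != 3:
        raise ValueError("need mean occupancy rates for classes 0, 1 and 2")
    r0, r1, r2 = (float(v) for v in class_means)
    if min(r0, r1, r2) <= 0:
        raise ValueError("class mean occupancy rates must be positive")
    ratios = (r1 / r0, r2 / r1)
    gmean = math.sqrt(ratios[0] * ratios[1])
    x_exact = 1.0 / gmean
    x_recommended = int(math.floor(x_exact + 0.5))
    return CalibrationReport(
        class_means={0: r0, 1: r1, 2: r2},
        ratios=ratios,
        x_exact=x_exact,
        x_recommended=x_recommended,
    )


def calibrate_weight_base(occ: OccupancyTable) -> CalibrationReport:
    """Calibrate the weight base ``x`` from quadrat-occupancy counts.

    Each species' occupancy rate is its occupied-quadrat count divided by
    the count of the most common species in the table.  Rates are averaged
    within distribution-subindex classes 0, 1 and 2 (class-3 species are
    dropped before averaging) and passed to
    :func:`recommend_base_from_class_means`.
    """
    max_count = max(r.quadrats_occupied for r in occ.rows)
    by_class: dict[int, list[float]] = {0: [], 1: [], 2: []}
    for rec in occ.rows:
        if rec.dbi_distribution in by_class:
            by_class[rec.dbi_distribution].append(rec.quadrats_occupied / max_count)
    empty = [c for c, vals in by_class.items() if not vals]
    if empty:
        raise ChecklistValidationError(
            f"occupancy table has no species in distribution class(es) {empty}"
        )
    means = [float(np.mean(by_class[c])) for c in (0, 1, 2)]
    return recommend_base_from_class_means(means)
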