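"""Community resolution and the two classical DBI aggregates.

A site sample is a list of (species, abundance) observations.  Resolution
matches the names against a scored checklist pool, coerces abundances to
presence/absence and collapses duplicates; the aggregates are then

* ``DBI_sum`` — the sum of the DBI scores of all member species, and
* ``DBI_mean`` — that sum divided by species richness.

Both are computed from presence/absence only: the DBI is a qualitative
scoring method, so abundance magnitudes never enter the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .checklist import ChecklistPool, normalize_name

__all__ = [
    "Community",
    "ResolutionReport",
    "ResolutionError",
    "resolve_community",
    "dbi_sum",
    "dbi_mean",
    "read_community_matrix",
    "communities_from_matrix",
]


class ResolutionError(ValueError):
    """Raised when a raw sample cannot be resolved against the pool."""


@dataclass(frozen=True)
class Community:
    """A resolved set of distinct species from a pool (one site sample)."""

    members: frozenset[str]  # normalized name keys
    source_site: str = "site"

    def __post_init__(self) -> None:
        if not self.members:
            raise ResolutionError(
                f"community {self.source_site!r} is empty after resolution"
            )

    @property
    def richness(self) -> int:
        return len(self.members)

    def display_names(self, pool: ChecklistPool) -> list[str]:
        """Member names in the pool's original spelling, checklist order."""
        return [r.name for r in pool if r.key in self.members]


@dataclass(frozen=True)
class ResolutionReport:
    """Bookkeeping from :func:`resolve_community`."""

    unmatched: tuple[str, ...] = ()
    zero_abundance: tuple[str, ...] = ()
    duplicates_collapsed: int = 0


def resolve_community(
    raw: Iterable[tuple[str, Real]],
    pool: ChecklistPool,
    *,
    strict: bool = True,
    site_label: str = "site",
) -> tuple[Community, ResolutionReport]:
    """Resolve raw (species, abundance) observations into a :class:`Community`.

    Abundances greater than zero are coerced to presence; zero-abundance
    entries are dropped (they encode absence in a community matrix).
    Duplicate names collapse to a single member.  Names match under the
    checklist normalization (whitespace/case-insensitive).

    In strict mode any observed name missing from the pool raises a
    :class:`ResolutionError` listing all unmatched names; in lenient mode
    unmatched names are dropped and listed in the report.  Non-numeric
    abundances always raise — treating them as absence would silently
    corrupt richness.
    """
    raw = list(raw)
    if not raw:
        raise ResolutionError(f"sample {site_label!r} contains no observations")

    members: set[str] = set()
    unmatched: list[str] = []
    zero_abund: list[str] = []
    n_dup = 0
    for name, abundance in raw:
        if not isinstance(abundance, Real):
            raise ResolutionError(
                f"sample {site_label!r}: non-numeric abundance {abundance!r} "
                f"for {name!r}"
            )
        if pd.isna(abundance) or float(abundance) < 0:
            raise ResolutionError(
                f"sample {site_label!r}: invalid abundance {abundance!r} for {name!r}"
            )
        if float(abundance) == 0.0:
            zero_abund.append(name)
            continue
        key = normalize_name(name)
        if key not in pool:
            unmatched.append(name)
            continue
        if key in members:
            n_dup += 1
        members.add(key)

    if unmatched and strict:
        raise ResolutionError(
            f"sample {site_label!r}: species not in pool "
            f"{pool.region_label!r}: {sorted(set(unmatched))}"
        )
    if not members:
        raise ResolutionError(
            f"sample {site_label!r} is empty after resolution"
        )
    report = ResolutionReport(
        unmatched=tuple(unmatched),
        zero_abundance=tuple(zero_abund),
        duplicates_collapsed=n_dup,
    )
    return Community(frozenset(members), source_site=site_label), report


def dbi_sum(community: Community, pool: ChecklistPool) -> int:
    """Sum of the DBI scores of all community members."""
    index = {r.key: r.dbi_total for r in pool}
    try:
        return sum(index[key] for key in community.members)
    except KeyError as exc:
        raise ResolutionError(
            f"community {community.source_site!r} member {exc.args[0]!r} "
            f"not in pool {pool.region_label!r}"
        ) from None


def dbi_mean(community: Community, pool: ChecklistPool) -> float:
    """DBI_sum divided by species richness, at full precision.

    Display rounding (2 decimals by convention) is the caller's job.
    """
    return dbi_sum(community, pool) / community.richness


# ---------------------------------------------------------------------------
# Community-matrix I/O
# ---------------------------------------------------------------------------

def read_community_matrix(
    path: str | Path,
    *,
    species_as_rows: bool = False,
) -> pd.DataFrame:
    """Read a site x species community matrix CSV.

    The default orientation is one site per row: the first column holds the
    site label and the remaining columns are species names with abundance
    (or 0/1 presence) cells.  ``species_as_rows=True`` reads the transposed
    layout (species in the first column, one site per column).
    """
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    if df.empty or df.shape[1] == 0:
        raise ResolutionError(f"{path}: community matrix has no data")
    if species_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def communities_from_matrix(
    matrix: pd.DataFrame,
    pool: ChecklistPool,
    *,
    strict: bool = True,
) -> list[tuple[Community, ResolutionReport]]:
    """Resolve every row of a site x species matrix against a pool."""
    out = []
    for site, row in matrix.iterrows():
        raw = [(str(sp), ab) for sp, ab in row.items()]
        out.append(
            resolve_community(raw, pool, strict=strict, site_label=str(site))
        )
    return out
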