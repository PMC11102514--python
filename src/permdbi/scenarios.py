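"""Simulated community scenarios for comparing DBI aggregation methods.

The scenario engine assembles archetypal communities from a scored pool
using four DBI bands — 'A' species (DBI 8–9, restricted/endangered/very
sensitive), 'B' (4–5), 'C' (2–3) and 'D' (0–1, ubiquitous generalists) —
at four richness tiers: small (2), medium (10), large (20, or 21 for the
mixed large-'A'-plus-one-'B' case) and giant (38).  Thirteen default
scenarios span pure-band communities of each size plus a giant mixed
community of 20 'A' and 18 'D' species.

Real pools rarely hold 20 species of DBI 8–9, so band *depletion* occurs:
once a band is exhausted the builder substitutes unused species with the
nearest DBI values beyond the boundary just crossed (downward for the
high bands A/B/C, which are filled from the top of the band; upward for
D, which is filled from the bottom).  Every substitution is recorded so
reported sums can be traced back to pool composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .checklist import ChecklistPool
from .indices import Community, dbi_mean, dbi_sum
from .permutation import (
    DEFAULT_N_PERM,
    WeightScheme,
    permutational_potential,
)

__all__ = [
    "BANDS",
    "ScenarioSpec",
    "Substitution",
    "ScenarioResult",
    "build_scenario",
    "evaluate_scenarios",
    "default_scenarios",
    "specs_from_config",
    "results_to_frame",
]

#: DBI value range (inclusive) per composition band.
BANDS: dict[str, tuple[int, int]] = {
    "A": (8, 9),
    "B": (4, 5),
    "C": (2, 3),
    "D": (0, 1),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated scenario: a label and ordered (band, count) blocks."""

    label: str
    blocks: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for band, count in self.blocks:
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r} (expected A/B/C/D)")
            if count < 1:
                raise ValueError(f"block count must be positive, got {count}")

    @property
    def richness(self) -> int:
        return sum(count for _, count in self.blocks)


@dataclass(frozen=True)
class Substitution:
    """Species taken from outside a requested band during depletion."""

    band: str
    used_value: int
    count: int


@dataclass(frozen=True)
class ScenarioResult:
    """One evaluated scenario row: metrics plus per-metric ranks."""

    label: str
    richness: int
    dbi_sum: int
    dbi_mean: float
    potential: float
    rank_sum: int
    rank_mean: int
    rank_potential: int
    substitutions: tuple[Substitution, ...] = ()


def _band_fill_values(band: str) -> list[int]:
    """Preferred DBI values for a band: in-band extreme-first, then the
    depletion sequence beyond the boundary crossed by the fill direction."""
    lo, hi = BANDS[band]
    if band == "D":
        in_band = list(range(lo, hi + 1))          # 0, 1 (bottom-up)
        overflow = list(range(hi + 1, 10))         # 2..9 upward
    else:
        in_band = list(range(hi, lo - 1, -1))      # top of band downward
        overflow = list(range(lo - 1, -1, -1))     # below the band, downward
        overflow += list(range(hi + 1, 10))        # last resort: above
    return in_band + overflow


def build_scenario(
    spec: ScenarioSpec, pool: ChecklistPool
) -> tuple[Community, tuple[Substitution, ...]]:
    """Deterministically assemble a scenario community from a pool.

    Each block is filled greedily with unused pool species at the band's
    preferred DBI values (extreme-first; ties within a value broken by
    checklist order).  When a band is depleted the nearest values beyond
    the crossed boundary substitute, and every substituted (band, value,
    count) triple is recorded.
    """
    if spec.richness > len(pool):
        raise ValueError(
            f"scenario {spec.label!r} needs {spec.richness} species but pool "
            f"{pool.region_label!r} has {len(pool)}"
        )
    by_value: dict[int, list[str]] = {v: [] for v in range(10)}
    for rec in pool:
        by_value[rec.dbi_total].append(rec.key)
    cursors = {v: 0 for v in range(10)}

    members: list[str] = []
    subs: dict[tuple[str, int], int] = {}
    for band, count in spec.blocks:
        lo, hi = BANDS[band]
        needed = count
        for value in _band_fill_values(band):
            while needed and cursors[value] < len(by_value[value]):
                members.append(by_value[value][cursors[value]])
                cursors[value] += 1
                needed -= 1
                if not (lo <= value <= hi):
                    key = (band, value)
                    subs[key] = subs.get(key, 0) + 1
            if not needed:
                break
        if needed:
            raise ValueError(
                f"scenario {spec.label!r}: pool exhausted with {needed} "
                f"species of band {band!r} still unfilled"
            )
    substitutions = tuple(
        Substitution(band=b, used_value=v, count=c)
        for (b, v), c in sorted(subs.items())
    )
    return Community(frozenset(members), source_site=spec.label), substitutions


def _dense_rank_desc(values: Sequence[float]) -> list[int]:
    """1-based dense ranks, descending (1 = most valuable; ties share)."""
    ranks = pd.Series(values).rank(method="dense", ascending=False)
    return [int(r) for r in ranks]


def evaluate_scenarios(
    specs: Sequence[ScenarioSpec],
    pool: ChecklistPool,
    n_perm: int = DEFAULT_N_PERM,
    scheme: WeightScheme | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[ScenarioResult]:
    """Build and score every scenario; rank the set on each metric.

    Ranks are dense and descending (rank 1 = highest value) and are
    computed on the full-precision metrics, never on display-rounded
    values.  Output order matches input order.
    """
    scheme = scheme or WeightScheme()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for spec in specs:
        community, subs = build_scenario(spec, pool)
        total = dbi_sum(community, pool)
        mean = dbi_mean(community, pool)
        pot = permutational_potential(
            community, pool, n_perm=n_perm, scheme=scheme, rng=rng
        ).potential
        rows.append((spec, community, subs, total, mean, pot))

    rank_sum = _dense_rank_desc([r[3] for r in rows])
    rank_mean = _dense_rank_desc([r[4] for r in rows])
    rank_pot = _dense_rank_desc([r[5] for r in rows])
    return [
        ScenarioResult(
            label=spec.label,
            richness=community.richness,
            dbi_sum=total,
            dbi_mean=mean,
            potential=pot,
            rank_sum=rs,
            rank_mean=rm,
            rank_potential=rp,
            substitutions=subs,
        )
        for (spec, community, subs, total, mean, pot), rs, rm, rp in zip(
            rows, rank_sum, rank_mean, rank_pot
        )
    ]


def default_scenarios() -> list[ScenarioSpec]:
    """The thirteen standard scenarios.

    Richness tiers: giant 38, large 20 (21 when a 'B' species supplements
    a pure-'A' community), medium 10, small 2.
    """
    return [
        ScenarioSpec("giant com. (20 'A' sp. + 18 'D' sp.)", (("A", 20), ("D", 18))),
        ScenarioSpec("giant com. of 'D' sp.", (("D", 38),)),
        ScenarioSpec("large com. of 'A' sp. + 1 'B' sp.", (("A", 20), ("B", 1))),
        ScenarioSpec("large com. of 'A' sp.", (("A", 20),)),
        ScenarioSpec("large com. of 'C' sp.", (("C", 20),)),
        ScenarioSpec("large com. of 'D' sp.", (("D", 20),)),
        ScenarioSpec("medium com. of 'A' sp.", (("A", 10),)),
        ScenarioSpec("medium com. of 'B' sp.", (("B", 10),)),
        ScenarioSpec("medium com. of 'C' sp.", (("C", 10),)),
        ScenarioSpec("medium com. of 'D' sp.", (("D", 10),)),
        ScenarioSpec("small com. of 'A' sp.", (("A", 2),)),
        ScenarioSpec("small com. of 'B' sp.", (("B", 2),)),
        ScenarioSpec("small com. of 'C' sp.", (("C", 2),)),
    ]


def specs_from_config(data: Sequence[Mapping]) -> list[ScenarioSpec]:
    """Build scenario specs from parsed config data (e.g. a YAML list).

    Each entry is a mapping with a ``label`` and ``blocks``, the latter a
    list of ``[band, count]`` pairs, e.g.::

        - label: my mixed community
          blocks: [[A, 5], [D, 5]]
    """
    specs = []
    for entry in data:
        try:
            label = str(entry["label"])
            blocks = tuple(
                (str(band), int(count)) for band, count in entry["blocks"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed scenario entry {entry!r}: {exc}") from exc
        specs.append(ScenarioSpec(label, blocks))
    return specs


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tabulate scenario results (one row per scenario)."""
    return pd.DataFrame(
        {
            "scenario": [r.label for r in results],
            "richness": [r.richness for r in results],
            "dbi_sum": [r.dbi_sum for r in results],
            "dbi_mean": [r.dbi_mean for r in results],
            "potential": [r.potential for r in results],
            "rank_sum": [r.rank_sum for r in results],
            "rank_mean": [r.rank_mean for r in results],
            "rank_potential": [r.rank_potential for r in results],
            "substitutions": [
                "; ".join(
                    f"{s.band}->DBI{s.used_value}x{s.count}"
                    for s in r.substitutions
                )
                for r in results
            ],
        }
    )
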