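"""Stability diagnostics for the permutational DBI potential.

The potential is a Monte-Carlo estimate, so its value fluctuates between
runs.  To judge whether sites remain discriminable despite that noise,
the diagnostic recomputes the potential many times per site (default 100
repetitions of 10,000 permutations each), then compares the resulting
per-site distributions with pairwise two-sample Kolmogorov–Smirnov tests,
Bonferroni-adjusted over all site pairs.  Pairs whose distributions are
degenerate at the same point (e.g. two sites saturated at potential 1.0
on every repetition) are flagged as indistinguishable directly, because
the asymptotic KS test is uninformative for zero-variance samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .checklist import ChecklistPool
from .indices import Community
from .permutation import (
    DEFAULT_N_PERM,
    WeightScheme,
    permutational_potential,
)

__all__ = [
    "PotentialDistribution",
    "StabilityReport",
    "repeat_potential",
    "ks_two_sample",
    "stability_report",
]

DEFAULT_REPS = 100


@dataclass(frozen=True)
class PotentialDistribution:
    """Repeated potential values for one site."""

    site_label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"{self.site_label!r}: no repetitions")
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValueError(f"{self.site_label!r}: potential outside [0, 1]")

    @property
    def reps(self) -> int:
        return len(self.values)

    def is_degenerate(self) -> bool:
        """All repetitions landed on a single value."""
        return len(set(self.values)) == 1


@dataclass(frozen=True)
class StabilityReport:
    """Pairwise KS comparison of per-site potential distributions.

    ``pairwise`` is a long-format table with one row per unordered site
    pair: KS statistic ``D``, raw two-sided p-value, Bonferroni-adjusted
    p-value (``min(1, p * n_comparisons)``), a ``degenerate_equal`` flag
    and the ``indistinct`` verdict at the chosen ``alpha``.
    """

    pairwise: pd.DataFrame
    n_comparisons: int
    alpha: float

    @property
    def indistinct_pairs(self) -> list[tuple[str, str]]:
        flagged = self.pairwise[self.pairwise["indistinct"]]
        return list(zip(flagged["site_i"], flagged["site_j"]))


def repeat_potential(
    community: Community,
    pool: ChecklistPool,
    reps: int = DEFAULT_REPS,
    n_perm: int = DEFAULT_N_PERM,
    scheme: WeightScheme | None = None,
    seed: int | None = None,
) -> PotentialDistribution:
    """Compute the potential ``reps`` times with independent permutations.

    Child RNG streams are spawned deterministically from the master seed
    (one per repetition), so a fixed seed reproduces the distribution
    exactly while repetitions remain statistically independent.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scheme = scheme or WeightScheme()
    streams = np.random.SeedSequence(seed).spawn(reps)
    values = tuple(
        permutational_potential(
            community,
            pool,
            n_perm=n_perm,
            scheme=scheme,
            rng=np.random.default_rng(stream),
        ).potential
        for stream in streams
    )
    return PotentialDistribution(site_label=community.source_site, values=values)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    ``D`` is the supremum absolute difference between the two empirical
    distribution functions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def stability_report(
    dists: Sequence[PotentialDistribution],
    alpha: float = 0.05,
) -> StabilityReport:
    """All-pairs KS comparison with Bonferroni correction.

    A pair is flagged ``indistinct`` when its Bonferroni-adjusted p-value
    is not below ``alpha``, or when both distributions are degenerate at
    the same point (the KS p-value carries no information there).  Raw and
    adjusted p-values are both reported so users can apply a different
    threshold.
    """
    if len(dists) < 2:
        raise ValueError("need at least two site distributions")
    n = len(dists)
    n_comparisons = n * (n - 1) // 2
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            di, dj = dists[i], dists[j]
            degenerate_equal = (
                di.is_degenerate()
                and dj.is_degenerate()
                and di.values[0] == dj.values[0]
            )
            D, p = ks_two_sample(di.values, dj.values)
            p_adj = min(1.0, p * n_comparisons)
            rows.append(
                {
                    "site_i": di.site_label,
                    "site_j": dj.site_label,
                    "D": D,
                    "p": p,
                    "p_adj": p_adj,
                    "degenerate_equal": degenerate_equal,
                    "indistinct": degenerate_equal or p_adj >= alpha,
                }
            )
    return StabilityReport(
        pairwise=pd.DataFrame(rows), n_comparisons=n_comparisons, alpha=alpha
    )
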