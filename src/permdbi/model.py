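"""Model/Results interface for whole-survey DBI assessments.

:class:`DBIAssessment` wraps a scored pool plus one or more resolved
communities — typically a whole site x species survey matrix — and
``fit()`` computes, per site, the classical aggregates (DBI_sum,
DBI_mean) and the Monte-Carlo permutational DBI potential.  The returned
:class:`DBIAssessmentResults` carries the per-site table, Monte-Carlo
standard errors, tie diagnostics and a formatted ``summary()``.

This is a thin facade: the statistical machinery lives in
:mod:`permdbi.indices` and :mod:`permdbi.permutation`, which remain
usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .checklist import ChecklistPool, read_checklist
from .indices import (
    Community,
    ResolutionReport,
    communities_from_matrix,
    dbi_mean,
    dbi_sum,
    read_community_matrix,
)
from .permutation import (
    DEFAULT_N_PERM,
    PotentialResult,
    WeightScheme,
    permutational_potential,
    simulate_null_sums,
)

__all__ = ["DBIAssessment", "DBIAssessmentResults"]


class DBIAssessment:
    """DBI assessment of a set of communities against a regional pool.

    Parameters
    ----------
    pool
        Validated species checklist providing the DBI scores and the
        permutation universe.
    communities
        Resolved site samples to assess.
    resolution_reports
        Optional per-site resolution bookkeeping (unmatched names etc.),
        carried through to the results for reporting.
    """

    def __init__(
        self,
        pool: ChecklistPool,
        communities: Sequence[Community],
        resolution_reports: Sequence[ResolutionReport] | None = None,
    ) -> None:
        if not communities:
            raise ValueError("need at least one community to assess")
        self.pool = pool
        self.communities = list(communities)
        self.resolution_reports = (
            list(resolution_reports) if resolution_reports is not None else None
        )

    @classmethod
    def from_matrix(
        cls,
        pool: ChecklistPool,
        matrix: pd.DataFrame,
        *,
        strict: bool = True,
    ) -> "DBIAssessment":
        """Build from a site x species abundance/presence matrix."""
        resolved = communities_from_matrix(matrix, pool, strict=strict)
        return cls(
            pool,
            [c for c, _ in resolved],
            resolution_reports=[r for _, r in resolved],
        )

    @classmethod
    def from_csv(
        cls,
        checklist_path: str | Path,
        matrix_path: str | Path,
        *,
        strict: bool = True,
        species_as_rows: bool = False,
    ) -> "DBIAssessment":
        """Build from a checklist CSV and a community-matrix CSV."""
        load = read_checklist(checklist_path)
        matrix = read_community_matrix(matrix_path, species_as_rows=species_as_rows)
        model = cls.from_matrix(load.pool, matrix, strict=strict)
        model.checklist_excluded = load.excluded
        return model

    def fit(
        self,
        n_perm: int = DEFAULT_N_PERM,
        base_x: float = 2.0,
        seed: int | None = None,
        mid_p: bool = False,
    ) -> "DBIAssessmentResults":
        """Compute all per-site statistics.

        One RNG, seeded with ``seed``, is threaded through the sites in
        order, so a fixed seed reproduces the whole table exactly.
        """
        scheme = WeightScheme(base_x=base_x)
        rng = np.random.default_rng(seed)
        potentials = [
            permutational_potential(
                c, self.pool, n_perm=n_perm, scheme=scheme, rng=rng, mid_p=mid_p
            )
            for c in self.communities
        ]
        return DBIAssessmentResults(self, scheme, potentials, seed=seed)


@dataclass
class DBIAssessmentResults:
    """Fitted per-site DBI statistics with Monte-Carlo diagnostics."""

    model: DBIAssessment
    scheme: WeightScheme
    potentials: list[PotentialResult]
    seed: int | None = None

    @property
    def table(self) -> pd.DataFrame:
        """Per-site results at full precision."""
        pool = self.model.pool
        rows = []
        for community, pot in zip(self.model.communities, self.potentials):
            rows.append(
                {
                    "site": community.source_site,
                    "richness": community.richness,
                    "dbi_sum": dbi_sum(community, pool),
                    "dbi_mean": dbi_mean(community, pool),
                    "potential": pot.potential,
                    "potential_se": pot.mc_standard_error,
                    "n_equal": pot.n_equal,
                    "n_perm": pot.n_permutations,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table.

        DBI_mean is displayed to 2 decimals and the potential to 3, the
        conventional reporting precisions; the underlying table keeps
        full precision.
        """
        pool = self.model.pool
        df = self.table.copy()
        df["dbi_mean"] = df["dbi_mean"].map(lambda v: f"{v:.2f}")
        df["potential"] = df["potential"].map(lambda v: f"{v:.3f}")
        df["potential_se"] = df["potential_se"].map(lambda v: f"{v:.4f}")
        lines = [
            "Dragonfly Biotic Index assessment",
            "=" * 72,
            f"pool: {pool.region_label} ({len(pool)} scored species)",
            f"weight base x = {self.scheme.base_x:g}   "
            f"n_perm = {self.potentials[0].n_permutations}   "
            f"seed = {self.seed}",
            "-" * 72,
            df.to_string(index=False),
            "=" * 72,
        ]
        return "\n".join(lines)

    def simulate_null_sums(
        self, site: str, n_perm: int | None = None, seed: int | None = None
    ) -> np.ndarray:
        """Fresh null DBI_sum draws for one site (for diagnostics/plots)."""
        for community, pot in zip(self.model.communities, self.potentials):
            if community.source_site == site:
                return simulate_null_sums(
                    self.model.pool,
                    community.richness,
                    n_perm or pot.n_permutations,
                    self.scheme,
                    np.random.default_rng(seed),
                )
        raise KeyError(f"unknown site {site!r}")

    def plot_null_ecdf(self, site: str, ax=None, seed: int | None = 0):
        """ECDF of null DBI_sums for one site with the observed sum marked.

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt

        for community, pot in zip(self.model.communities, self.potentials):
            if community.source_site == site:
                break
        else:
            raise KeyError(f"unknown site {site!r}")
        sums = self.simulate_null_sums(site, seed=seed)
        if ax is None:
            _, ax = plt.subplots()
        xs = np.sort(sums)
        ax.step(xs, np.arange(1, xs.size + 1) / xs.size, where="post",
                label="null DBI_sum ECDF")
        ax.axvline(pot.actual_sum, color="crimson", ls="--",
                   label=f"observed sum = {pot.actual_sum}")
        ax.set_xlabel("DBI_sum of random same-richness community")
        ax.set_ylabel("cumulative fraction")
        ax.set_title(f"{site}: potential = {pot.potential:.3f}")
        ax.legend()
        return ax

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
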