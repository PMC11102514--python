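from __future__ import annotations

import pytest

from permdbi import ChecklistPool, SpeciesRecord, synthetic_pool


def pool_from_totals(totals, prefix="sp"):
    """Build a total-only pool with the given DBI scores, checklist order."""
    records = tuple(
        SpeciesRecord(name=f"{prefix}{i:03d}", dbi_total=int(v))
        for i, v in enumerate(totals)
    )
    return ChecklistPool(records, region_label="test pool")


@pytest.fixture
def tiny_pool():
    """Four species scoring 0, 1, 2, 3 — small enough for the exact oracle."""
    return pool_from_totals([0, 1, 2, 3])


@pytest.fixture(scope="session")
def ce_pool():
    """Central-European-like synthetic pool: 68 scored species, rarity decay 2."""
    return synthetic_pool(n_species=68, seed=1, decay=2.0)
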