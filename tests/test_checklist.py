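"""Checklist data model, CSV I/O, synthetic pools and weight calibration."""

from __future__ import annotations

import csv

import numpy as np
import pytest

from permdbi import (
    ChecklistParseError,
    ChecklistPool,
    ChecklistValidationError,
    OccupancyRecord,
    OccupancyTable,
    SpeciesRecord,
    calibrate_weight_base,
    read_checklist,
    read_occupancy,
    recommend_base_from_class_means,
    synthetic_pool,
    write_checklist,
)
from permdbi.checklist import normalize_name, synthetic_pool_target_counts


def _write_csv(path, rows, header=("species", "dbi_d", "dbi_t", "dbi_s", "dbi")):
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


class TestSpeciesRecord:
    def test_total_must_match_subindex_sum(self):
        with pytest.raises(ChecklistValidationError, match="badsp"):
            SpeciesRecord("badsp", dbi_total=9, dbi_distribution=3,
                          dbi_threat=3, dbi_sensitivity=2)

    @pytest.mark.parametrize("total", [-1, 10])
    def test_total_range(self, total):
        with pytest.raises(ChecklistValidationError):
            SpeciesRecord("sp", dbi_total=total)

    @pytest.mark.parametrize("sub", [-1, 4])
    def test_subindex_range(self, sub):
        with pytest.raises(ChecklistValidationError):
            SpeciesRecord("sp", dbi_total=max(sub, 0) + 0,
                          dbi_distribution=sub, dbi_threat=0, dbi_sensitivity=0)

    def test_all_valid_score_combinations_accepted(self):
        for d in range(4):
            for t in range(4):
                for s in range(4):
                    rec = SpeciesRecord("sp", dbi_total=d + t + s,
                                        dbi_distribution=d, dbi_threat=t,
                                        dbi_sensitivity=s)
                    assert 0 <= rec.dbi_total <= 9


class TestReadChecklist:
    def test_blank_totals_excluded_and_reported(self, tmp_path):
        """A 73-row checklist with 5 unscored species yields a 68-species pool."""
        rows = [[f"sp{i:03d}", "", "", "", i % 10] for i in range(68)]
        rows += [[f"unscored{i}", "", "", "", ""] for i in range(5)]
        path = tmp_path / "cl.csv"
        _write_csv(path, rows)
        load = read_checklist(path)
        assert len(load.pool) == 68
        assert load.n_excluded == 5
        assert all(name.startswith("unscored") for name in load.excluded)

    def test_single_zero_species(self, tmp_path):
        path = tmp_path / "cl.csv"
        _write_csv(path, [["only sp", 0, 0, 0, 0]])
        load = read_checklist(path)
        assert len(load.pool) == 1
        assert load.pool.records[0].dbi_total == 0
        assert load.n_excluded == 0

    def test_inconsistent_total_names_species(self, tmp_path):
        path = tmp_path / "cl.csv"
        _write_csv(path, [["ok sp", 1, 1, 1, 3], ["bad sp", 3, 3, 2, 9]])
        with pytest.raises(ChecklistValidationError, match="bad sp"):
            read_checklist(path)

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "cl.csv"
        _write_csv(path, [["Aeshna  cyanea", "", "", "", 3],
                          ["aeshna cyanea", "", "", "", 3]])
        with pytest.raises(ChecklistValidationError, match="duplicate"):
            read_checklist(path)

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "cl.csv"
        _write_csv(path, [["sp1", "", "", "", "three"]])
        with pytest.raises(ChecklistParseError, match="line 2"):
            read_checklist(path)

    def test_total_only_checklist_accepted(self, tmp_path):
        path = tmp_path / "cl.csv"
        _write_csv(path, [["sp1", 4], ["sp2", 0]], header=("species", "dbi"))
        load = read_checklist(path)
        assert [r.dbi_total for r in load.pool] == [4, 0]
        assert not load.pool.records[0].has_subindices

    def test_total_computed_from_subindices_when_blank(self, tmp_path):
        path = tmp_path / "cl.csv"
        _write_csv(path, [["sp1", 1, 2, 3, ""]])
        load = read_checklist(path)
        assert load.pool.records[0].dbi_total == 6

    def test_round_trip(self, tmp_path):
        pool = synthetic_pool(n_species=15, seed=3)
        out = tmp_path / "out.csv"
        write_checklist(pool, out)
        back = read_checklist(out).pool
        assert back.records == pool.records


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [("  Aeshna   cyanea ", "aeshna cyanea"),
         ("AESHNA CYANEA", "aeshna cyanea"),
         ("a\tb", "a b")],
    )
    def test_normalize_name(self, raw, expected):
        assert normalize_name(raw) == expected


class TestSyntheticPool:
    def test_covers_all_totals_with_rarity_gradient(self):
        pool = synthetic_pool(n_species=68, seed=1)
        totals = pool.totals()
        assert len(pool) == 68
        present = set(totals.tolist())
        assert present == set(range(10))
        assert (totals == 0).sum() > (totals == 9).sum()

    def test_minimum_size_is_one_per_value(self):
        pool = synthetic_pool(n_species=10, seed=99)
        assert sorted(pool.totals().tolist()) == list(range(10))

    def test_deterministic_for_fixed_arguments(self):
        a = synthetic_pool(n_species=30, seed=7, decay=1.5)
        b = synthetic_pool(n_species=30, seed=7, decay=1.5)
        assert a.records == b.records

    def test_too_small_pool_rejected(self):
        with pytest.raises(ValueError):
            synthetic_pool(n_species=9, seed=0)

    @pytest.mark.parametrize("n,decay", [(68, 2.0), (25, 1.5), (200, 3.0)])
    def test_target_counts_non_increasing_for_decay_above_one(self, n, decay):
        counts = synthetic_pool_target_counts(n, decay)
        assert counts.sum() == n
        assert (counts >= 1).all()
        assert (np.diff(counts) <= 0).all()

    def test_records_satisfy_subindex_invariants(self):
        pool = synthetic_pool(n_species=40, seed=5)
        for rec in pool:
            assert rec.dbi_total == (rec.dbi_distribution + rec.dbi_threat
                                     + rec.dbi_sensitivity)


def _occupancy_for_means():
    """Counts whose class-mean occupancy rates are exactly 0.80/0.38/0.18.

    Most common species occupies 100 quadrats; a class-3 species is
    included to check it is excluded from the calibration.
    """
    rows = [
        OccupancyRecord("c0a", 100, 0),
        OccupancyRecord("c0b", 60, 0),
        OccupancyRecord("c1a", 38, 1),
        OccupancyRecord("c2a", 18, 2),
        OccupancyRecord("c3a", 90, 3),
    ]
    return OccupancyTable(tuple(rows))


class TestCalibration:
    def test_published_class_means_recommend_base_two(self):
        report = calibrate_weight_base(_occupancy_for_means())
        assert report.class_means[0] == pytest.approx(0.80)
        assert report.class_means[1] == pytest.approx(0.38)
        assert report.class_means[2] == pytest.approx(0.18)
        assert report.ratios[0] == pytest.approx(0.475)
        assert report.ratios[1] == pytest.approx(0.18 / 0.38)
        assert report.x_recommended == 2

    def test_uniform_occupancy_gives_base_one(self):
        rows = tuple(OccupancyRecord(f"s{c}", 50, c) for c in (0, 1, 2))
        report = calibrate_weight_base(OccupancyTable(rows))
        assert all(m == pytest.approx(1.0) for m in report.class_means.values())
        assert report.x_recommended == 1

    def test_quartering_occupancy_gives_base_four(self):
        report = recommend_base_from_class_means([1.0, 0.25, 0.0625])
        assert report.ratios == (pytest.approx(0.25), pytest.approx(0.25))
        assert report.x_exact == pytest.approx(4.0)
        assert report.x_recommended == 4

    def test_missing_class_rejected(self):
        rows = (OccupancyRecord("a", 10, 0), OccupancyRecord("b", 5, 1))
        with pytest.raises(ChecklistValidationError, match=r"\[2\]"):
            calibrate_weight_base(OccupancyTable(rows))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ChecklistValidationError):
            OccupancyTable((OccupancyRecord("a", 0, 0),))

    def test_read_occupancy_csv(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "species,quadrats,dbi_d\na,100,0\nb,38,1\nc,18,2\n",
            encoding="utf-8",
        )
        report = calibrate_weight_base(read_occupancy(path))
        assert report.x_recommended == 2
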