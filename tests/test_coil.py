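"""Coil-library operations: mesostates, basins, culls, propensities."""

import numpy as np
import pytest

from dsekit.coil import (BasinDefinition, DEFAULT_BASINS, ResidueRecord,
                         assign_basin, assign_mesostate, basin_propensities,
                         cull, rama_histogram, read_records, records_to_frame)
from dsekit.synthetic import generate_dihedral_records


def rec(aa="A", phi=-75.0, psi=145.0, ss="coil", seg="s1", pos=1, seglen=4):
    return ResidueRecord(aa=aa, phi=phi, psi=psi, ss_label=ss, segment_id=seg,
                         position_in_segment=pos, segment_length=seglen)


class TestMesostate:
    def test_origin_and_last_bins(self):
        assert assign_mesostate(-180.0, -180.0) == 0
        assert assign_mesostate(179.0, 179.0) == 143

    def test_partition_of_the_plane(self):
        grid = np.arange(-180.0, 180.0, 1.0)
        seen = set()
        for phi in grid[::7]:
            for psi in grid[::7]:
                idx = assign_mesostate(phi, psi)
                assert 0 <= idx <= 143
                seen.add(idx)
        assert len(seen) == 144

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            assign_mesostate(180.0, 0.0)


class TestBasins:
    def test_ppii_and_alpha_centres(self):
        assert assign_basin(-75.0, 145.0) == "ppii"
        assert assign_basin(-64.0, -41.0) == "alpha"

    def test_outside_all_boxes(self):
        assert assign_basin(10.0, 10.0) == "other"

    def test_overlapping_definitions_rejected(self):
        bad = (BasinDefinition("a", (-100, 0), (-100, 0)),
               BasinDefinition("b", (-50, 50), (-50, 50)))
        with pytest.raises(ValueError, match="overlap"):
            assign_basin(-20.0, -20.0, bad)

    def test_default_basins_disjoint(self):
        points = [(-75, 145), (-64, -41), (-150, 150), (60, 40)]
        labels = [assign_basin(p, s) for p, s in points]
        assert labels == ["ppii", "alpha", "beta", "alpha_L"]


class TestCull:
    RECORDS = ([rec(ss="helix") for _ in range(4)]
               + [rec(ss="sheet") for _ in range(2)]
               + [rec(ss="turn")]
               + [rec(ss="coil") for _ in range(3)])

    def test_counting_example(self):
        assert len(cull(self.RECORDS, "no_ss")) == 4
        assert len(cull(self.RECORDS, "no_ss_turns")) == 3

    def test_short_segment_dropped_at_internal_level(self):
        records = [rec(seg="s", pos=1, seglen=3) for _ in range(1)]
        assert cull(records, "internal_coil") == []

    def test_terminal_residues_removed(self):
        records = [rec(pos=0, seglen=4), rec(pos=1, seglen=4),
                   rec(pos=3, seglen=4)]
        assert len(cull(records, "full")) == 1

    def test_monotone_subsets(self):
        records = generate_dihedral_records(
            400, {"ppii": 0.4, "alpha": 0.3, "other": 0.3},
            ss_profile={"helix": 0.3, "sheet": 0.1, "turn": 0.2, "coil": 0.4},
            seed=5)
        sizes = [len(cull(records, lv))
                 for lv in ("full", "no_ss", "no_ss_turns", "internal_coil")]
        assert sizes[0] >= sizes[1] >= sizes[2] >= sizes[3] > 0

    def test_empty_input(self):
        assert cull([], "no_ss_turns") == []

    def test_missing_annotation_at_internal_level(self):
        with pytest.raises(ValueError, match="segment"):
            cull([rec(seg="")], "internal_coil")


class TestBasinPropensities:
    def test_pure_ppii_records(self):
        records = [rec(aa=aa) for aa in "ACDP" for _ in range(3)]
        table = basin_propensities(records)
        assert (table["ppii"] == 1.0).all()

    def test_empty_input(self):
        assert basin_propensities([]).empty

    def test_rows_sum_to_one_and_absent_aa_not_reported(self):
        records = [rec(aa="A"), rec(aa="A", phi=-64, psi=-41), rec(aa="G",
                                                                   phi=10,
                                                                   psi=10)]
        table = basin_propensities(records)
        assert set(table.index) == {"A", "G"}
        sums = table.drop(columns="n").sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_generator_weights_recovered(self):
        weights = {"ppii": 0.5, "alpha": 0.3, "other": 0.2}
        records = generate_dihedral_records(10_000, weights, seed=42)
        table = basin_propensities(records)
        overall = (table.drop(columns="n").mul(table["n"], axis=0).sum()
                   / table["n"].sum())
        for label, w in weights.items():
            sigma = np.sqrt(w * (1 - w) / 10_000)
            assert abs(overall[label] - w) < 3 * sigma, label

    def test_ppii_dominates_culled_synthetic_library(self):
        """After removing secondary structure and turns, PPII ranks first in
        a library whose coil population favours PPII."""
        records = generate_dihedral_records(
            4000, {"ppii": 0.45, "alpha": 0.25, "beta": 0.15, "other": 0.15},
            ss_profile={"helix": 0.3, "sheet": 0.15, "turn": 0.1,
                        "coil": 0.45}, seed=7)
        table = basin_propensities(cull(records, "no_ss_turns"))
        overall = (table.drop(columns="n").mul(table["n"], axis=0).sum()
                   / table["n"].sum())
        assert overall.idxmax() == "ppii"


class TestRamaHistogram:
    def test_counts_conserved(self):
        records = generate_dihedral_records(100, {"ppii": 1.0}, seed=1)
        assert rama_histogram(records).sum() == 100

    def test_single_record_single_cell(self):
        grid = rama_histogram([rec(phi=-65.0, psi=135.0)])
        assert grid.sum() == 1
        assert grid[int((-65 + 180) // 10), int((135 + 180) // 10)] == 1

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            rama_histogram([rec()], bin_deg=7.0)


def test_read_records_round_trip(tmp_path):
    records = [rec(aa="A"), rec(aa="G", phi=-64.0, psi=-41.0, ss="turn")]
    path = tmp_path / "records.csv"
    records_to_frame(records).to_csv(path, index=False)
    back = read_records(path)
    assert back == records
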