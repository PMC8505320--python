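"""Census domain model, gap policies, abundance derivation and long-format I/O."""

from __future__ import annotations

import io

import numpy as np
import pytest

from indbeta import (
    Census,
    CensusWarning,
    GapPolicyError,
    apply_gap_policy,
    read_long_format,
    to_abundance_matrix,
    write_long_format,
)
from indbeta.census import write_wide_occupancy

from conftest import random_census


def _read(text: str, **kw) -> Census:
    return read_long_format(io.StringIO(text), **kw)


class TestReadLongFormat:
    def test_direct_transcription(self):
        c = _read("individual_id,species_id,time_unit\ni1,s1,1\ni1,s1,2\ni2,s1,1\n")
        assert c.units == ("1", "2")
        assert dict(zip(c.ids, map(tuple, c.occupancy))) == {"i1": (1, 1), "i2": (1, 0)}

    def test_species_conflict_first_appearance_wins(self):
        with pytest.warns(CensusWarning, match="first appearance"):
            c = _read("individual_id,species_id,time_unit\ni1,s1,1\ni1,s2,2\n")
        assert c.species == ("s1",)

    def test_empty_stream_is_an_error(self):
        with pytest.raises(ValueError, match="no records"):
            _read("individual_id,species_id,time_unit\n")

    def test_duplicate_rows_deduplicated_with_warning(self):
        with pytest.warns(CensusWarning, match="duplicate"):
            c = _read("individual_id,species_id,time_unit\ni1,s1,1\ni1,s1,1\ni1,s1,2\n")
        assert c.occupancy.tolist() == [[1, 1]]

    def test_numeric_unit_ordering(self):
        c = _read("individual_id,species_id,time_unit\ni1,s1,10\ni1,s1,2\n")
        assert c.units == ("2", "10")

    def test_iso_date_unit_ordering(self):
        c = _read(
            "individual_id,species_id,time_unit\n"
            "i1,s1,2005-01-15\ni1,s1,1995-06-01\n"
        )
        assert c.units == ("1995-06-01", "2005-01-15")

    def test_unorderable_units_require_explicit_order(self):
        text = "individual_id,species_id,time_unit\ni1,s1,spring\ni1,s1,fall\n"
        with pytest.raises(ValueError, match="unit_order"):
            _read(text)
        c = _read(text, unit_order=["spring", "fall"])
        assert c.units == ("spring", "fall")

    def test_custom_column_names_and_delimiter(self):
        c = _read("tag\tsp\tyear\nA\toak\t1990\nA\toak\t1995\n",
                  delimiter="\t", individual_col="tag", species_col="sp",
                  time_col="year")
        assert c.ids == ("A",) and c.species == ("oak",)


class TestGapPolicy:
    def _gapped(self) -> Census:
        return Census((1, 2, 3), ("g1", "ok"), ("s1", "s1"),
                      np.array([[1, 0, 1], [1, 1, 0]], dtype=np.int8))

    def test_fill_closes_internal_gap(self):
        c = apply_gap_policy(self._gapped(), "fill")
        assert c.occupancy.tolist() == [[1, 1, 1], [1, 1, 0]]

    def test_strict_names_the_offender(self):
        with pytest.raises(GapPolicyError, match="g1"):
            apply_gap_policy(self._gapped(), "strict")

    def test_events_leaves_vectors_alone(self):
        c = apply_gap_policy(self._gapped(), "events")
        assert c.occupancy.tolist() == [[1, 0, 1], [1, 1, 0]]

    def test_contiguous_census_unchanged_under_any_policy(self):
        c = Census((1, 2, 3), ("a",), ("s1",), np.array([[1, 1, 0]], dtype=np.int8))
        for policy in ("strict", "fill", "events"):
            assert apply_gap_policy(c, policy) is c

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            apply_gap_policy(self._gapped(), "ignore")


class TestAbundanceMatrix:
    def test_five_individual_example(self, five_individual_census):
        m = to_abundance_matrix(five_individual_census)
        counts = {sp: tuple(row) for sp, row in zip(m.species, m.counts)}
        assert counts == {"s1": (2, 2), "s2": (1, 0), "s3": (0, 1)}
        assert m.I_j.tolist() == [3, 3]
        assert m.I_T == 5
        assert m.T_AB == 6
        assert m.S_j.tolist() == [2, 2]
        assert m.S_T == 3

    def test_single_individual(self):
        c = Census((1, 2), ("i1",), ("s1",), np.array([[1, 1]], dtype=np.int8))
        m = to_abundance_matrix(c)
        assert m.counts.tolist() == [[1, 1]] and m.I_T == 1

    def test_conspecifics_with_disjoint_occupancy_pool_in_species_row(self):
        c = Census((1, 2), ("i1", "i2"), ("s1", "s1"),
                   np.array([[1, 0], [0, 1]], dtype=np.int8))
        assert to_abundance_matrix(c).counts.tolist() == [[1, 1]]

    @pytest.mark.parametrize("seed", range(5))
    def test_totals_consistency_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c = random_census(rng)
        m = to_abundance_matrix(c)
        assert int(m.I_j.sum()) == m.T_AB == int(c.occupancy.sum())
        assert m.I_T == c.n_individuals
        perm = rng.permutation(c.n_individuals)
        shuffled = Census(c.units, tuple(c.ids[i] for i in perm),
                          tuple(c.species[i] for i in perm), c.occupancy[perm])
        m2 = to_abundance_matrix(shuffled)
        assert {sp: tuple(r) for sp, r in zip(m.species, m.counts)} == \
               {sp: tuple(r) for sp, r in zip(m2.species, m2.counts)}


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_read_write_identity_on_random_censuses(self, seed):
        c = random_census(np.random.default_rng(seed))
        buf = io.StringIO()
        write_long_format(c, buf)
        buf.seek(0)
        back = read_long_format(buf)
        assert tuple(map(str, c.units)) == back.units
        assert c.ids == back.ids and c.species == back.species
        assert (c.occupancy == back.occupancy).all()

    def test_all_zero_unit_preserved_via_units_header(self):
        c = Census((1, 2, 3), ("i1",), ("s1",),
                   np.array([[1, 1, 0]], dtype=np.int8))
        buf = io.StringIO()
        write_long_format(c, buf)
        assert buf.getvalue().startswith("#units=1,2,3\n")
        buf.seek(0)
        back = read_long_format(buf)
        assert back.units == ("1", "2", "3")
        assert back.occupancy.tolist() == [[1, 1, 0]]

    def test_species_label_containing_delimiter_is_quoted(self):
        c = Census((1, 2), ("i1",), ("Quercus, sp.",),
                   np.array([[1, 1]], dtype=np.int8))
        buf = io.StringIO()
        write_long_format(c, buf)
        buf.seek(0)
        assert read_long_format(buf).species == ("Quercus, sp.",)

    def test_wide_occupancy_export(self, five_individual_census):
        buf = io.StringIO()
        write_wide_occupancy(five_individual_census, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "individual_id\tspecies_id\t1\t2"
        assert lines[1] == "i1\ts1\t1\t1"
        assert len(lines) == 6


class TestCensusValidation:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="unique"):
            Census((1, 2), ("a", "a"), ("s", "s"), np.ones((2, 2), dtype=np.int8))

    def test_rejects_all_zero_individual(self):
        with pytest.raises(ValueError, match="all-zero"):
            Census((1, 2), ("a",), ("s",), np.zeros((1, 2), dtype=np.int8))

    def test_rejects_non_binary_occupancy(self):
        with pytest.raises(ValueError, match="0 or 1"):
            Census((1, 2), ("a",), ("s",), np.array([[2, 0]]))

    def test_rejects_single_unit_and_duplicate_units(self):
        with pytest.raises(ValueError, match="two units"):
            Census((1,), ("a",), ("s",), np.ones((1, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="duplicate"):
            Census((1, 1), ("a",), ("s",), np.ones((1, 2), dtype=np.int8))
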