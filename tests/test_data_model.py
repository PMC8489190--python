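import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anonlattice import (Lattice, lattice_size, neighbors, read_dataset,
                         read_hierarchy, validate_hierarchy)
from anonlattice.data_model import GeneralizationHierarchy, ParseError, Role

from conftest import random_instance


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadDataset:
    def test_basic_parse_with_roles(self, tmp_path):
        p = write(tmp_path, "d.csv", "a,b\n1,x\n2,y\n")
        ds = read_dataset(p, roles={"a": "quasi_identifying"})
        assert ds.n_records == 2
        assert ds.attributes[0].role is Role.QUASI_IDENTIFYING
        assert list(ds.frame["a"]) == ["1", "2"]

    def test_ragged_row_cites_row_number(self, tmp_path):
        p = write(tmp_path, "d.csv", "a,b\n1,x\n2,y,z\n")
        with pytest.raises(ParseError, match="row 2"):
            read_dataset(p)

    def test_header_only_is_empty_dataset(self, tmp_path):
        p = write(tmp_path, "d.csv", "a,b\n")
        ds = read_dataset(p)
        assert ds.n_records == 0

    def test_duplicate_header_rejected(self, tmp_path):
        p = write(tmp_path, "d.csv", "a,a\n1,2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_dataset(p)

    def test_role_for_unknown_attribute_rejected(self, tmp_path):
        p = write(tmp_path, "d.csv", "a,b\n1,x\n")
        with pytest.raises(ParseError, match="unknown"):
            read_dataset(p, roles={"zzz": "insensitive"})

    def test_unlisted_attributes_default_insensitive(self, tmp_path):
        p = write(tmp_path, "d.csv", "a,b\n1,x\n")
        ds = read_dataset(p)
        assert all(a.role is Role.INSENSITIVE for a in ds.attributes)


class TestReadHierarchy:
    def test_sex_hierarchy(self, tmp_path):
        p = write(tmp_path, "sex.csv", "male;*\nfemale;*\n")
        h = read_hierarchy(p)
        assert h.height == 1
        assert h.leaves == {"male", "female"}
        assert set(h.mapping(1).values()) == {"*"}

    def test_single_column_identity_hierarchy(self, tmp_path):
        p = write(tmp_path, "h.csv", "x\ny\n")
        h = read_hierarchy(p)
        assert h.height == 0

    def test_duplicate_leaf_with_conflicting_parent_rejected(self, tmp_path):
        p = write(tmp_path, "h.csv", "34;30-39\n34;40-49\n")
        with pytest.raises(ParseError):
            read_hierarchy(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = write(tmp_path, "h.csv", "a;b\nc\n")
        with pytest.raises(ParseError, match="ragged"):
            read_hierarchy(p)


class TestValidateHierarchy:
    def test_valid_hierarchy_empty_report(self):
        h = GeneralizationHierarchy("sex", (("male", "*"), ("female", "*")))
        assert validate_hierarchy(h, {"male", "female"}) == []

    def test_missing_observed_value_named(self):
        h = GeneralizationHierarchy("sex", (("male", "*"), ("female", "*")))
        report = validate_hierarchy(h, {"male", "unknown"})
        assert any("unknown" in v for v in report)

    def test_duplicate_leaf_named(self):
        h = GeneralizationHierarchy("x", (("a", "*"), ("a", "*")))
        report = validate_hierarchy(h)
        assert any("duplicate" in v and "'a'" in v for v in report)

    def test_composition_consistency_random_hierarchies(self):
        # applying level l then the l -> l+1 mapping equals applying level l+1
        rng = np.random.default_rng(42)
        for _ in range(20):
            ds = random_instance(rng, max_records=30)
            for attr in ds.quasi_identifiers:
                h = attr.hierarchy
                assert validate_hierarchy(h) == []
                for level in range(h.height):
                    step = {row[level]: row[level + 1] for row in h.table}
                    for leaf in h.leaves:
                        assert step[h.mapping(level)[leaf]] == \
                            h.mapping(level + 1)[leaf]


class TestLattice:
    def test_empty_product(self):
        assert lattice_size([]) == 1

    def test_against_enumeration_oracle(self):
        # explicit enumeration of all level vectors, incl. the [3,1,5,3,1] case
        rng = np.random.default_rng(0)
        heights_cases = [[3, 1, 5, 3, 1]] + [
            list(rng.integers(0, 5, size=rng.integers(1, 6)))
            for _ in range(10)]
        for heights in heights_cases:
            enumerated = sum(1 for _ in itertools.product(
                *(range(h + 1) for h in heights)))
            assert lattice_size(heights) == enumerated
        assert lattice_size([3, 1, 5, 3, 1]) == 384

    def test_exact_big_integer_arithmetic(self):
        # 31 attributes of height 3 : product must not overflow or round
        assert lattice_size([3] * 31) == 4 ** 31

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            lattice_size([2, -1])

    def test_neighbor_examples(self):
        lat = Lattice((2, 1))
        assert neighbors((2, 1), lat, "up") == []
        assert neighbors((0, 0), lat, "up") == [(1, 0), (0, 1)]
        assert neighbors((1, 1), lat, "down") == [(0, 1), (1, 0)]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=5).flatmap(
        lambda hs: st.tuples(
            st.just(tuple(hs)),
            st.tuples(*(st.integers(0, h) for h in hs)))))
    def test_neighbors_antisymmetric(self, case):
        heights, g = case
        lat = Lattice(heights)
        for up in neighbors(g, lat, "up"):
            assert g in neighbors(up, lat, "down")
        for down in neighbors(g, lat, "down"):
            assert g in neighbors(down, lat, "up")
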