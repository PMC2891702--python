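from __future__ import annotations

import itertools

import pytest

from spliceseek import (
    EnumerationParams,
    FragmentIndex,
    PspClass,
    SpliceIndex,
    Substrate,
    classify,
    count_products,
    enumerate_pcp,
    enumerate_psp,
    sequence_of,
)
from spliceseek.enumeration import label_deltas_of

from .conftest import oracle_counts, oracle_fragments


def make_idx(sub: Substrate, i, j, k, n) -> SpliceIndex:
    return SpliceIndex(FragmentIndex(i, j), FragmentIndex(k, n), sub, sub)


class TestSubstrate:
    def test_rejects_short(self):
        with pytest.raises(ValueError):
            Substrate("x", "A")

    def test_rejects_noncanonical(self):
        with pytest.raises(ValueError):
            Substrate("x", "ACDZ")

    def test_rejects_label_out_of_range(self):
        with pytest.raises(ValueError):
            Substrate("x", "ACDE", {9: 6.0})


class TestEnumeratePcp:
    def test_four_mer(self, tiny):
        got = enumerate_pcp(tiny, EnumerationParams(l_ext=2))
        assert [(f.i, f.j) for f in got] == [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]

    def test_minimal(self):
        got = enumerate_pcp(Substrate("x", "AC"), EnumerationParams(l_ext=2))
        assert [(f.i, f.j) for f in got] == [(1, 2)]

    def test_thirteen_mer_count(self, sub13):
        # sum over lengths 2..13 of (13 - m + 1) = 78
        assert len(enumerate_pcp(sub13, EnumerationParams(l_ext=2))) == 78

    @pytest.mark.parametrize("L,l_ext", [(5, 1), (7, 2), (9, 3)])
    def test_matches_oracle(self, L, l_ext):
        sub = Substrate("s", "ACDEFGHIK"[:L])
        got = [(f.i, f.j) for f in enumerate_pcp(sub, EnumerationParams(l_ext=l_ext))]
        assert got == oracle_fragments(L, l_ext)

    def test_l_ext_beyond_length_warns_empty(self):
        with pytest.warns(UserWarning):
            got = enumerate_pcp(Substrate("x", "ACD"), EnumerationParams(l_ext=4))
        assert got == []


class TestClassify:
    def test_reverse_pair(self, sub23):
        # second fragment entirely upstream of the first
        idx = make_idx(sub23, 15, 18, 1, 5)
        assert sequence_of(idx) == "YPEWVSRQL"
        assert classify(idx) is PspClass.CIS_REVERSE

    def test_normal_pair(self, sub23):
        idx = make_idx(sub23, 3, 4, 15, 23)
        assert sequence_of(idx) == "RQYPEWTEAQR"
        assert classify(idx) is PspClass.CIS_NORMAL

    def test_self_pair_is_trans(self, sub23):
        idx = make_idx(sub23, 1, 5, 1, 5)
        assert sequence_of(idx) == "VSRQLVSRQL"
        assert classify(idx) is PspClass.TRANS

    def test_overlap_is_trans(self, sub23):
        assert classify(make_idx(sub23, 1, 6, 4, 9)) is PspClass.TRANS

    def test_cross_substrate_is_trans(self, sub13):
        other = Substrate("other", sub13.sequence, {3: 6.02013})
        idx = SpliceIndex(FragmentIndex(1, 3), FragmentIndex(8, 13), sub13, other)
        assert classify(idx) is PspClass.TRANS

    def test_adjacent_keeps_substrate_order(self, tiny):
        # k = j + 1: sequence-identical to a cleavage product, classed cis_normal
        assert classify(make_idx(tiny, 1, 2, 3, 4)) is PspClass.CIS_NORMAL


class TestEnumeratePsp:
    def test_four_mer_classes(self, tiny):
        got = list(enumerate_psp(tiny, EnumerationParams(l_ext=2)))
        by_class = {c: [] for c in PspClass}
        for idx, cls in got:
            by_class[cls].append(idx.ijkn)
        assert by_class[PspClass.CIS_NORMAL] == []
        assert by_class[PspClass.CIS_REVERSE] == [(3, 4, 1, 2)]
        # oracle: 36 ordered pairs, 1 native-adjacent excluded, 1 reverse
        assert len(by_class[PspClass.TRANS]) == oracle_counts(4, 2)["trans"]

    def test_thirteen_mer_against_oracle(self, sub13):
        expect = oracle_counts(13, 2)
        got = {c: 0 for c in PspClass}
        for _, cls in enumerate_psp(sub13, EnumerationParams(l_ext=2)):
            got[cls] += 1
        assert got[PspClass.CIS_NORMAL] == expect["cis_normal"] == 495
        assert got[PspClass.CIS_REVERSE] == expect["cis_reverse"]
        assert got[PspClass.TRANS] == expect["trans"]

    def test_native_adjacent_flag(self, tiny):
        default = list(enumerate_psp(tiny, EnumerationParams(l_ext=2)))
        with_adj = list(enumerate_psp(tiny, EnumerationParams(l_ext=2, include_native_adjacent=True)))
        assert len(with_adj) - len(default) == oracle_counts(4, 2)["adjacent"]

    def test_cross_only_all_trans(self, sub13):
        heavy = Substrate("heavy", sub13.sequence, {3: 6.02013, 8: 0.99703})
        pairs = list(enumerate_psp([sub13, heavy], EnumerationParams(l_ext=2), cross_only=True))
        assert pairs
        assert all(cls is PspClass.TRANS for _, cls in pairs)
        assert len(pairs) == 2 * 78 * 78

    def test_class_subset(self, sub13):
        only_rev = EnumerationParams(l_ext=2, classes=frozenset({PspClass.CIS_REVERSE}))
        got = list(enumerate_psp(sub13, only_rev))
        assert len(got) == oracle_counts(13, 2)["cis_reverse"]
        assert all(cls is PspClass.CIS_REVERSE for _, cls in got)

    def test_deterministic_and_lexicographic(self, sub13):
        params = EnumerationParams(l_ext=2)
        a = [idx.ijkn for idx, _ in enumerate_psp(sub13, params)]
        b = [idx.ijkn for idx, _ in enumerate_psp(sub13, params)]
        assert a == b == sorted(a)

    def test_duplicate_ids_rejected(self, sub13):
        with pytest.raises(ValueError):
            list(enumerate_psp([sub13, sub13], EnumerationParams()))


class TestCountProducts:
    def test_tiny(self):
        c = count_products(4, 2)
        assert (c.n_pcp, c.n_all_pairs) == (6, 36)

    def test_thirteen_mer(self):
        c = count_products(13, 2)
        o = oracle_counts(13, 2)
        assert c.n_pcp == 78
        assert c.n_cis_normal == o["cis_normal"] == 495
        assert c.n_cis_reverse == o["cis_reverse"]

    def test_degenerate(self):
        c = count_products(2, 2)
        assert (c.n_pcp, c.n_cis_normal, c.n_cis_reverse) == (1, 0, 0)
        assert count_products(1, 2).n_pcp == 0

    @pytest.mark.parametrize("L", range(4, 17))
    @pytest.mark.parametrize("l_ext", [1, 2, 3])
    def test_closed_form_equals_oracle(self, L, l_ext):
        c = count_products(L, l_ext)
        o = oracle_counts(L, l_ext)
        assert c.n_pcp == o["pcp"]
        assert c.n_cis_normal == o["cis_normal"]
        assert c.n_cis_reverse == o["cis_reverse"]
        assert c.n_trans == o["trans"]
        assert c.n_native_adjacent == o["adjacent"]
        # partition of all ordered pairs
        assert c.n_cis_normal + c.n_cis_reverse + c.n_trans + c.n_native_adjacent == c.n_all_pairs


class TestInvariants:
    @pytest.mark.parametrize("L,l_ext", [(6, 1), (9, 2), (12, 3)])
    def test_partition_exactly_one_class(self, L, l_ext):
        sub = Substrate("s", "ACDEFGHIKLMNPQRS"[:L])
        params = EnumerationParams(l_ext=l_ext, include_native_adjacent=True)
        seen = {}
        for idx, cls in enumerate_psp(sub, params):
            assert idx.ijkn not in seen
            seen[idx.ijkn] = cls
        n_pcp = len(enumerate_pcp(sub, params))
        assert len(seen) == n_pcp * n_pcp

    @pytest.mark.parametrize("L,l_ext", [(8, 2), (11, 2), (10, 3)])
    def test_reverse_symmetry(self, L, l_ext):
        # swapping fragment order maps gap>=1 cis_normal pairs onto cis_reverse
        sub = Substrate("s", "ACDEFGHIKLMNPQRS"[:L])
        params = EnumerationParams(l_ext=l_ext)
        normals, reverses = set(), set()
        for idx, cls in enumerate_psp(sub, params):
            if cls is PspClass.CIS_NORMAL:
                normals.add(idx.ijkn)
            elif cls is PspClass.CIS_REVERSE:
                reverses.add(idx.ijkn)
        swapped = {(k, n, i, j) for (i, j, k, n) in normals}
        assert swapped <= reverses
        assert len(reverses) >= len(normals)


class TestSequenceOf:
    def test_fragment(self, sub23):
        assert sequence_of(FragmentIndex(1, 5), sub23) == "VSRQL"

    def test_lengths(self, sub13):
        for i, k in itertools.product(range(1, 5), range(5, 9)):
            idx = make_idx(sub13, i, i + 1, k, k + 1)
            assert len(sequence_of(idx)) == 4

    def test_label_deltas_reindexed(self, sub13):
        heavy = Substrate("h", sub13.sequence, {3: 6.0, 8: 1.0})
        idx = SpliceIndex(FragmentIndex(1, 3), FragmentIndex(8, 13), heavy, heavy)
        assert label_deltas_of(idx) == {3: 6.0, 4: 1.0}
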