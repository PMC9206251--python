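"""The four queries: worked examples on the demonstration matrix and
equivalence of the secure path with the plaintext scan oracle."""

import random

import pytest

from privgst.data_io import HaplotypeDataset, QueryString, generate_synthetic
from privgst.gst_core import build_trie
from privgst.query_engine import (
    EncryptedQuery,
    MatchSpan,
    build_server_bundle,
    default_smm_floor,
    execute_query,
    make_query_tokens,
    plaintext_oracle,
)
from privgst.rmt_hash import Salt, rmt_hash_string
from privgst.secure_index import EncryptionContext


class TestMakeTokens:
    def test_em_single_token_matches_stored_path(self, table1, salt, ctx,
                                                 table1_bundle):
        eq = make_query_tokens(QueryString("100010"), "em", salt, ctx,
                               m=table1.m)
        assert len(eq.tokens) == 1
        stored = {n.ciphertext for n in table1_bundle.egst.nodes}
        assert eq.tokens[0].ciphertext in stored

    def test_smm_substring_enumeration(self, salt, ctx):
        eq = make_query_tokens(QueryString("1101"), "smm", salt, ctx)
        assert [t.length for t in eq.tokens] == [4, 3, 3]
        assert eq.floor == 3  # ceil((4+1)/2)

    def test_single_symbol_esm(self, salt, ctx):
        eq = make_query_tokens(QueryString("1"), "esm", salt, ctx)
        assert len(eq.tokens) == 1 and eq.tokens[0].length == 1

    def test_query_longer_than_m_rejected(self, salt, ctx):
        with pytest.raises(ValueError):
            make_query_tokens(QueryString("0101"), "em", salt, ctx, m=3)

    def test_tsmm_threshold_bounds(self, salt, ctx):
        with pytest.raises(ValueError):
            make_query_tokens(QueryString("0101"), "tsmm", salt, ctx, t=5)

    def test_tokens_contain_no_plaintext(self, salt, ctx):
        eq = make_query_tokens(QueryString("110110"), "smm", salt, ctx)
        for token in eq.tokens:
            assert b"110110" not in token.ciphertext

    def test_default_floor(self):
        assert default_smm_floor(4) == 3
        assert default_smm_floor(6) == 4
        assert default_smm_floor(1) == 1


class TestWorkedExamples:
    def run(self, bundle, table1, salt, ctx, kind, qs, t=None):
        eq = make_query_tokens(QueryString(qs), kind, salt, ctx, t=t,
                               m=table1.m)
        return execute_query(bundle, eq, ctx, m=table1.m)

    def test_exact_match(self, table1, salt, ctx, table1_bundle):
        res = self.run(table1_bundle, table1, salt, ctx, "em", "100010")
        assert res.records() == [1]
        assert res.matches == [MatchSpan(1, 1, 6)]

    def test_exact_substring_match(self, table1, salt, ctx, table1_bundle):
        res = self.run(table1_bundle, table1, salt, ctx, "esm", "111")
        assert res.records() == [2]

    def test_set_maximal_match(self, table1, salt, ctx, table1_bundle):
        res = self.run(table1_bundle, table1, salt, ctx, "smm", "1101")
        assert res.records() == [2, 3, 4, 5]
        # matched substrings are 1101, 110, 101, 101 respectively
        best = {sid: max(s.length for s in res.matches if s.seq_id == sid)
                for sid in res.records()}
        assert best == {2: 4, 3: 3, 4: 3, 5: 3}

    def test_threshold_set_maximal_match(self, table1, salt, ctx,
                                         table1_bundle):
        res = self.run(table1_bundle, table1, salt, ctx, "tsmm", "1011", t=3)
        assert res.records() == [2, 4, 5]
        rec2 = [s for s in res.matches if s.seq_id == 2]
        assert rec2[0].j1 == 3  # record 2's match starts at position 3
        rec4 = [s for s in res.matches if s.seq_id == 4]
        assert rec4 == [MatchSpan(4, 2, 5)]  # whole query from position 2

    def test_em_shorter_than_m_misses(self, table1, salt, ctx, table1_bundle):
        res = self.run(table1_bundle, table1, salt, ctx, "em", "111")
        assert res.status == "miss"


class TestOracle:
    def test_examples(self, table1):
        assert plaintext_oracle(table1, QueryString("100010"), "em").records() == [1]
        assert plaintext_oracle(table1, QueryString("111"), "esm").records() == [2]
        assert plaintext_oracle(table1, QueryString("1101"), "smm").records() == [2, 3, 4, 5]
        assert plaintext_oracle(table1, QueryString("1011"), "tsmm", t=3).records() == [2, 4, 5]

    def test_absent_floor_length_misses(self, table1):
        res = plaintext_oracle(table1, QueryString("111111"), "tsmm", t=6)
        assert res.status == "miss"


class TestEquivalence:
    def _random_case(self, rng):
        n, m = rng.randint(1, 10), rng.randint(2, 12)
        ds = generate_synthetic(n, m, seed=rng.randint(0, 2**30))
        qlen = rng.randint(1, m)
        qs = "".join(rng.choice("01") for _ in range(qlen))
        kind = rng.choice(["em", "esm", "smm", "tsmm"])
        t = rng.randint(1, qlen) if kind == "tsmm" else None
        return ds, qs, kind, t

    def test_secure_equals_oracle_on_randoms(self, salt, ctx):
        rng = random.Random(99)
        bundles = {}
        for _ in range(120):
            ds, qs, kind, t = self._random_case(rng)
            key = ds.records
            if key not in bundles:
                bundles[key] = build_server_bundle(build_trie(ds), salt, ctx)
            eq = make_query_tokens(QueryString(qs), kind, salt, ctx, t=t,
                                   m=ds.m)
            res = execute_query(bundles[key], eq, ctx, m=ds.m)
            oracle = plaintext_oracle(ds, QueryString(qs), kind, t=t)
            assert res == oracle, (kind, qs, t, ds.records)

    def test_em_hit_implies_esm_hit(self, salt, ctx):
        ds = generate_synthetic(4, 6, seed=3, planted=[("010101", 2, 1)])
        bundle = build_server_bundle(build_trie(ds), salt, ctx)
        em = execute_query(bundle, make_query_tokens(
            QueryString("010101"), "em", salt, ctx, m=6), ctx, m=6)
        esm = execute_query(bundle, make_query_tokens(
            QueryString("010101"), "esm", salt, ctx, m=6), ctx, m=6)
        assert em.status == "hit"
        assert esm.status == "hit"
        assert set(em.records()) <= set(esm.records())

    def test_tsmm_monotone_in_threshold(self, salt, ctx):
        ds = generate_synthetic(8, 10, seed=17)
        bundle = build_server_bundle(build_trie(ds), salt, ctx)
        qs = QueryString("0110101")
        prev = None
        for t in range(1, 8):
            res = execute_query(bundle, make_query_tokens(
                qs, "tsmm", salt, ctx, t=t, m=ds.m), ctx, m=ds.m)
            recs = set(res.records())
            if prev is not None:
                assert recs <= prev
            prev = recs

    def test_tsmm_full_threshold_equals_esm(self, salt, ctx):
        ds = generate_synthetic(6, 8, seed=23, planted=[("1011", 3, 2)])
        bundle = build_server_bundle(build_trie(ds), salt, ctx)
        q = QueryString("1011")
        tsmm = execute_query(bundle, make_query_tokens(
            q, "tsmm", salt, ctx, t=4, m=ds.m), ctx, m=ds.m)
        esm = execute_query(bundle, make_query_tokens(
            q, "esm", salt, ctx, m=ds.m), ctx, m=ds.m)
        assert sorted(tsmm.matches) == sorted(esm.matches)

    def test_key_mismatch_is_universal_miss(self, table1, salt, table1_bundle):
        other = EncryptionContext(key=bytes(range(1, 17)), iv=bytes(16))
        eq = make_query_tokens(QueryString("111"), "esm", salt, other,
                               m=table1.m)
        res = execute_query(table1_bundle, eq, other, m=table1.m)
        assert res.status == "miss"

    def test_smm_iteration_bounded_by_substring_count(self, salt, ctx):
        q = QueryString("110101")
        eq = make_query_tokens(q, "smm", salt, ctx)
        floor = default_smm_floor(6)
        max_subs = sum(6 - L + 1 for L in range(floor, 7))
        assert len(eq.tokens) <= max_subs
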