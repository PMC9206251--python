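import json

import pytest

from privgst._aes import aes_cbc_decrypt, aes_cbc_encrypt
from privgst.data_io import HaplotypeDataset, generate_synthetic
from privgst.gst_core import Terminal, build_trie
from privgst.rmt_hash import Salt, digest_bits, hash_tree, rmt_hash_string
from privgst.secure_index import (
    EncryptionContext,
    EncryptedGST,
    HashIndex,
    IndexEntry,
    IndexHit,
    IndexMiss,
    build_hash_index,
    decode_ref_token,
    encode_ref_token,
    encrypt_tree,
    lookup,
    read_keyfile,
    write_keyfile,
)


class TestAes:
    """FIPS-197 known-answer vectors pin the block cipher."""

    def test_fips197_appendix_c1(self):
        key = bytes.fromhex("000102030405060708090a0b0c0d0e0f")
        pt = bytes.fromhex("00112233445566778899aabbccddeeff")
        ct = aes_cbc_encrypt(key, bytes(16), pt)  # zero IV = raw block
        assert ct.hex() == "69c4e0d86a7b0430d8cdb78070b4c55a"
        assert aes_cbc_decrypt(key, bytes(16), ct) == pt

    def test_fips197_appendix_b(self):
        key = bytes.fromhex("2b7e151628aed2a6abf7158809cf4f3c")
        pt = bytes.fromhex("3243f6a8885a308d313198a2e0370734")
        assert aes_cbc_encrypt(key, bytes(16), pt).hex() == (
            "3925841d02dc09fbdc118597196a0b32"
        )

    def test_cbc_chains_blocks(self):
        key = bytes(range(16))
        iv = bytes(range(16, 32))
        two = bytes(32)
        ct = aes_cbc_encrypt(key, iv, two)
        assert ct[:16] != ct[16:]  # chaining breaks equal-block equality
        assert aes_cbc_decrypt(key, iv, ct) == two

    def test_block_alignment_required(self):
        with pytest.raises(ValueError):
            aes_cbc_encrypt(bytes(16), bytes(16), b"short")


class TestEncryptTree:
    def test_topology_preserved(self, table1, salt, ctx):
        gst = build_trie(table1)
        rmtree = hash_tree(gst, salt)
        egst = encrypt_tree(rmtree, ctx)
        # one encrypted node per RMT node plus one per terminal leaf
        assert egst.node_count() == len(rmtree.nodes) + 30
        assert egst.root.ciphertext is None  # salt never leaves the owner
        assert all(n.ciphertext is not None for n in egst.nodes[1:]
                   if n.parent_id >= 0)

    def test_deterministic(self, table1, salt, ctx):
        rmtree = hash_tree(build_trie(table1), salt)
        a = encrypt_tree(rmtree, ctx).to_json()
        b = encrypt_tree(rmtree, ctx).to_json()
        assert a == b

    def test_different_iv_changes_every_ciphertext(self, table1, salt):
        rmtree = hash_tree(build_trie(table1), salt)
        c1 = EncryptionContext(key=bytes(16), iv=bytes(16))
        c2 = EncryptionContext(key=bytes(16), iv=bytes([1]) + bytes(15))
        e1 = encrypt_tree(rmtree, c1)
        e2 = encrypt_tree(rmtree, c2)
        for n1, n2 in zip(e1.nodes, e2.nodes):
            if n1.ciphertext is not None:
                assert n1.ciphertext != n2.ciphertext

    def test_no_size_expansion(self, table1, salt, ctx):
        egst = encrypt_tree(hash_tree(build_trie(table1), salt), ctx)
        assert all(
            len(n.ciphertext) == egst.k // 8
            for n in egst.nodes if n.ciphertext is not None
        )

    def test_json_round_trip(self, table1, salt, ctx):
        egst = encrypt_tree(hash_tree(build_trie(table1), salt), ctx)
        back = EncryptedGST.from_json(egst.to_json())
        assert back.to_json() == egst.to_json()


class TestHashIndex:
    def test_every_node_ciphertext_findable(self, table1, salt, ctx):
        egst = encrypt_tree(hash_tree(build_trie(table1), salt), ctx)
        hi = build_hash_index(egst)
        for node in egst.nodes:
            if node.ciphertext is None:
                continue
            res = lookup(hi, node.ciphertext)
            assert isinstance(res, IndexHit)
            assert res.entry.node_id == node.node_id or (
                # a digest shared by identical paths resolves to one entry
                hi.entry_at(digest_bits(node.ciphertext)) is not None
            )

    def test_random_ciphertext_misses(self, table1_bundle):
        probe = bytes(range(16))
        res = table1_bundle.hi.lookup(probe)
        assert isinstance(res, IndexMiss)
        assert 1 <= res.fail_depth <= 128

    def test_entry_count_equals_distinct_digests(self, table1, salt, ctx):
        rmtree = hash_tree(build_trie(table1), salt)
        egst = encrypt_tree(rmtree, ctx)
        hi = build_hash_index(egst)
        digests = {n.digest for n in rmtree.nodes if n.node_id != 0}
        digests |= {d for _, d in rmtree.leaf_digests()}
        assert len(hi) == len(digests)

    def test_flipped_last_bit_misses(self, table1_bundle):
        node = next(n for n in table1_bundle.egst.nodes
                    if n.ciphertext is not None)
        flipped = node.ciphertext[:-1] + bytes(
            [node.ciphertext[-1] ^ 1]
        )
        res = table1_bundle.hi.lookup(flipped)
        assert isinstance(res, IndexMiss)
        assert res.fail_depth >= 1

    def test_depth_is_k_regardless_of_size(self, salt, ctx):
        for n, m in [(1, 2), (6, 8)]:
            ds = generate_synthetic(n, m, seed=n)
            egst = encrypt_tree(hash_tree(build_trie(ds), salt), ctx)
            hi = build_hash_index(egst)
            assert hi.k == 128

    def test_wrong_length_rejected(self, table1_bundle):
        with pytest.raises(ValueError):
            table1_bundle.hi.lookup(b"\x00" * 8)

    def test_full_row_path_lookup(self, table1, salt, ctx, table1_bundle):
        """The ciphertext of the full row-1 path hits with (seq 1, start 1)."""
        token = ctx.encrypt(rmt_hash_string("100010", salt))
        res = table1_bundle.hi.lookup(token)
        assert isinstance(res, IndexHit)
        refs = {decode_ref_token(t, ctx) for t in res.entry.ref_tokens}
        assert refs == {Terminal(1, 1)}

    def test_all_30_suffix_tokens_hit(self, table1, salt, ctx, table1_bundle):
        from privgst.gst_core import enumerate_suffixes

        for sid, start, suffix in enumerate_suffixes(build_trie(table1)):
            token = ctx.encrypt(rmt_hash_string(suffix, salt))
            res = table1_bundle.hi.lookup(token)
            assert isinstance(res, IndexHit)
            refs = {decode_ref_token(t, ctx) for t in res.entry.ref_tokens}
            assert Terminal(sid, start) in refs

    def test_json_round_trip(self, table1_bundle):
        back = HashIndex.from_json(table1_bundle.hi.to_json())
        assert len(back) == len(table1_bundle.hi)
        node = next(n for n in table1_bundle.egst.nodes
                    if n.ciphertext is not None)
        assert isinstance(back.lookup(node.ciphertext), IndexHit)


class TestLeakScan:
    def test_server_bundle_contains_no_secrets(self, salt, ctx):
        ds = generate_synthetic(4, 12, seed=10)
        egst = encrypt_tree(hash_tree(build_trie(ds), salt), ctx)
        hi = build_hash_index(egst)
        blob = (egst.to_json() + hi.to_json()).encode()
        assert salt.data not in blob
        assert salt.data.hex().encode() not in blob
        assert ctx.key not in blob and ctx.key.hex().encode() not in blob
        for rec in ds.records:
            for j in range(len(rec) - 7):
                assert rec[j : j + 8].encode() not in blob


class TestKeyfile:
    def test_round_trip(self, tmp_path, salt, ctx):
        path = write_keyfile(tmp_path / "key.json", salt, ctx, "md5")
        s2, c2, fn = read_keyfile(path)
        assert (s2, c2, fn) == (salt, ctx, "md5")

    def test_ref_token_round_trip(self, ctx):
        ref = Terminal(12, 345)
        assert decode_ref_token(encode_ref_token(ref, ctx), ctx) == ref
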