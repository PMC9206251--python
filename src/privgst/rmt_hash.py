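"""Reverse-Merkle (top-down) hashing of strings and suffix trees.

A classical Merkle tree hashes leaves upward; here digests flow downward:
the root carries a secret random SALT and every child digest is

    d(child) = H( d(parent) || H(symbol) )

so a node's digest depends only on the SALT and the root-to-node symbol
path.  A leaf ending suffix ``(i, j)`` additionally folds in a typed
terminator, so equal suffix strings from different records still receive
distinct leaf digests carrying the positional payload needed by
position-aware queries.

Byte-level encodings (the schematic ``h(AB)`` is pinned here for bit-exact
reproducibility):

* a single symbol hashes as its one-byte ASCII encoding;
* ``H(x || y)`` is the hash of the concatenation of the two k-bit byte
  strings;
* the terminator for suffix (seq_id, start) hashes as ``b"$<id>:<start>"``;
* the SALT has the digest length k/8 bytes and IS the root digest.

MD5 (k = 128) is the default; SHA-256 (k = 256) is selectable, and every
structural invariant is digest-length agnostic.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

from .gst_core import GST, CompressedGST, GSTNode, Terminal

__all__ = [
    "HASH_FUNCTIONS",
    "Salt",
    "RMTNode",
    "RMTree",
    "rmt_hash_string",
    "hash_tree",
    "digest_bits",
    "bits_to_bytes",
    "terminal_bytes",
]

HASH_FUNCTIONS = {"md5": 128, "sha256": 256}


def _h(data: bytes, hash_fn: str) -> bytes:
    return hashlib.new(hash_fn, data).digest()


@dataclass(frozen=True)
class Salt:
    """Secret k-bit byte array seeding the root.  Shared owner<->researcher,
    withheld from the server; never serialized into server-side artifacts."""

    data: bytes

    @classmethod
    def generate(cls, hash_fn: str = "md5") -> "Salt":
        return cls(secrets.token_bytes(HASH_FUNCTIONS[hash_fn] // 8))

    def check(self, hash_fn: str) -> None:
        want = HASH_FUNCTIONS[hash_fn] // 8
        if len(self.data) != want:
            raise ValueError(
                f"salt must be {want} bytes for {hash_fn}, got {len(self.data)}"
            )


def terminal_bytes(ref: Terminal) -> bytes:
    return b"$%d:%d" % (ref.seq_id, ref.start)


def rmt_hash_string(s: str, salt: Salt, hash_fn: str = "md5") -> bytes:
    """Fold the symbols of ``s`` through the top-down chain:
    d0 = salt; d_i = H(d_{i-1} || H(s_i)).  Returns d_{|s|}."""
    if not s:
        raise ValueError("string must be non-empty")
    salt.check(hash_fn)
    d = salt.data
    for sym in s:
        if len(sym.encode("ascii", "replace")) != 1:
            raise ValueError(f"symbol {sym!r} is not a 1-byte symbol")
        d = _h(d + _h(sym.encode("ascii"), hash_fn), hash_fn)
    return d


class RMTNode:
    __slots__ = ("node_id", "parent_id", "depth", "digest", "children",
                 "terminal_leaves")

    def __init__(self, node_id, parent_id, depth, digest):
        self.node_id = node_id
        self.parent_id = parent_id
        self.depth = depth
        self.digest = digest
        self.children: List[int] = []
        # (Terminal, leaf digest) pairs for suffixes ending at this node
        self.terminal_leaves: List[Tuple[Terminal, bytes]] = []


class RMTree:
    """A GST mirror in which every node carries its k-bit top-down digest.

    Node 0 is the root and carries the SALT itself; it therefore must never
    leave the owner's side.
    """

    def __init__(self, hash_fn: str, k: int):
        self.hash_fn = hash_fn
        self.k = k
        self.nodes: List[RMTNode] = []

    @property
    def root(self) -> RMTNode:
        return self.nodes[0]

    def iter_nodes(self) -> Iterator[RMTNode]:
        return iter(self.nodes)

    def leaf_digests(self) -> List[Tuple[Terminal, bytes]]:
        """Flat export of all terminal-leaf digests ("kept separately for
        incoming queries")."""
        out = []
        for node in self.nodes:
            out.extend(node.terminal_leaves)
        return out


def hash_tree(gst, salt: Salt, hash_fn: str = "md5") -> RMTree:
    """Digest every node of the trie view of ``gst`` top-down.

    Each node at depth d on the path of suffix (i, j) receives exactly
    ``rmt_hash_string`` of the first d symbols of that suffix; each suffix
    terminator becomes an extra leaf digest folding in its positional
    payload.
    """
    if isinstance(gst, CompressedGST):
        gst = gst.to_trie()
    if not isinstance(gst, GST):
        raise TypeError(
            "hash_tree requires a trie or a compressed tree with a "
            "per-symbol expansion iterator"
        )
    salt.check(hash_fn)
    k = HASH_FUNCTIONS[hash_fn]
    tree = RMTree(hash_fn, k)
    root = RMTNode(0, -1, 0, salt.data)
    tree.nodes.append(root)
    stack = [(gst.root, root)]
    while stack:
        src, dst = stack.pop()
        for ref in sorted(src.leaf_refs):
            leaf_digest = _h(dst.digest + _h(terminal_bytes(ref), hash_fn),
                             hash_fn)
            dst.terminal_leaves.append((ref, leaf_digest))
        for sym in sorted(src.children):
            child_src = src.children[sym]
            digest = _h(dst.digest + _h(sym.encode("ascii"), hash_fn), hash_fn)
            child = RMTNode(len(tree.nodes), dst.node_id, dst.depth + 1,
                            digest)
            tree.nodes.append(child)
            dst.children.append(child.node_id)
            stack.append((child_src, child))
    return tree


def digest_bits(digest: bytes) -> str:
    """Big-endian bit string ('0'/'1' characters, MSB of byte 0 first);
    stable across platforms."""
    return "".join(f"{byte:08b}" for byte in digest)


def bits_to_bytes(bits: str) -> bytes:
    if len(bits) % 8:
        raise ValueError("bit length must be a multiple of 8")
    return bytes(int(bits[i : i + 8], 2) for i in range(0, len(bits), 8))
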