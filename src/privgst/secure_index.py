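"""Deterministic encryption of RMT digests and the server-side Hash Index.

The data owner encrypts every non-root node digest with AES-128-CBC under a
key/IV pair shared only with the researcher.  The IV is fixed per
deployment: identical plaintext digests must yield identical ciphertexts or
the server could never match query tokens.  This is a deliberate,
ECB-style determinism leak accepted by the design (documented in the
methods note); the security goal is that a breached server bundle reveals
neither the salt nor any plaintext symbol, not ciphertext indistinguishability.

The Hash Index (HI) is a binary tree of fixed logical depth k over the
*ciphertext* bits: every stored ciphertext occupies a root-to-leaf path of
exactly k bit edges, and the leaf references the GST node and the suffix
positions reachable through it.  Physically the index is a sorted table of
bit strings with prefix queries — a compressed radix realization of the
same logical tree; the oblivious protocol walks the logical bit view.
"""

from __future__ import annotations

import base64
import json
import secrets
from dataclasses import dataclass
from bisect import bisect_left
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Tuple, Union

from ._aes import BLOCK, aes_cbc_decrypt, aes_cbc_encrypt
from .gst_core import Terminal
from .rmt_hash import HASH_FUNCTIONS, RMTree, Salt, bits_to_bytes, digest_bits

__all__ = [
    "EncryptionContext",
    "ENode",
    "EncryptedGST",
    "IndexEntry",
    "IndexHit",
    "IndexMiss",
    "HashIndex",
    "encrypt_tree",
    "build_hash_index",
    "lookup",
    "encode_ref_token",
    "decode_ref_token",
    "write_keyfile",
    "read_keyfile",
]


@dataclass(frozen=True)
class EncryptionContext:
    """AES-128-CBC key material shared owner<->researcher, withheld from the
    server.  Deterministic by construction (fixed IV)."""

    key: bytes
    iv: bytes
    cipher: str = "aes-128-cbc"

    def __post_init__(self):
        if len(self.key) != 16:
            raise ValueError(f"key must be 16 bytes, got {len(self.key)}")
        if len(self.iv) != 16:
            raise ValueError(f"iv must be 16 bytes, got {len(self.iv)}")

    @classmethod
    def generate(cls) -> "EncryptionContext":
        return cls(key=secrets.token_bytes(16), iv=secrets.token_bytes(16))

    def encrypt(self, plaintext: bytes) -> bytes:
        return aes_cbc_encrypt(self.key, self.iv, plaintext)

    def decrypt(self, ciphertext: bytes) -> bytes:
        return aes_cbc_decrypt(self.key, self.iv, ciphertext)


# --- keyfile: salt + key + iv, owner- and researcher-side only -------------

def write_keyfile(path, salt: Salt, ctx: EncryptionContext,
                  hash_fn: str = "md5") -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "format": "privgst-keyfile",
        "version": 1,
        "hash_fn": hash_fn,
        "salt": salt.data.hex(),
        "key": ctx.key.hex(),
        "iv": ctx.iv.hex(),
    }))
    return path


def read_keyfile(path) -> Tuple[Salt, EncryptionContext, str]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "privgst-keyfile":
        raise ValueError(f"{path} is not a privgst keyfile")
    return (
        Salt(bytes.fromhex(doc["salt"])),
        EncryptionContext(bytes.fromhex(doc["key"]), bytes.fromhex(doc["iv"])),
        doc.get("hash_fn", "md5"),
    )


# --- reference tokens: opaque to the server, decryptable by the researcher --

def encode_ref_token(ref: Terminal, ctx: EncryptionContext) -> bytes:
    raw = b"%d:%d" % (ref.seq_id, ref.start)
    if len(raw) > BLOCK:
        raise ValueError("reference does not fit one block")
    return ctx.encrypt(raw.ljust(BLOCK, b"\x00"))


def decode_ref_token(token: bytes, ctx: EncryptionContext) -> Terminal:
    raw = ctx.decrypt(token).rstrip(b"\x00")
    sid, start = raw.split(b":")
    return Terminal(int(sid), int(start))


# --- encrypted tree ---------------------------------------------------------

class ENode:
    """EncryptedGST node: topology + ciphertext, no plaintext symbols.

    The root's ciphertext is ``None``: its digest is the SALT, which must
    never reach the server even under encryption.  Terminal leaves carry
    their encrypted suffix reference as an opaque token.
    """

    __slots__ = ("node_id", "parent_id", "depth", "ciphertext", "children",
                 "ref_tokens")

    def __init__(self, node_id, parent_id, depth, ciphertext,
                 ref_tokens=()):
        self.node_id = node_id
        self.parent_id = parent_id
        self.depth = depth
        self.ciphertext = ciphertext
        self.children: List[int] = []
        self.ref_tokens: Tuple[bytes, ...] = tuple(ref_tokens)


class EncryptedGST:
    def __init__(self, k: int, cipher: str = "aes-128-cbc"):
        self.k = k
        self.cipher = cipher
        self.nodes: List[ENode] = []

    @property
    def root(self) -> ENode:
        return self.nodes[0]

    def node_count(self) -> int:
        return len(self.nodes)

    def to_json(self) -> str:
        return json.dumps({
            "format": "privgst-egst",
            "version": 1,
            "k": self.k,
            "cipher": self.cipher,
            "nodes": [
                [
                    n.node_id,
                    n.parent_id,
                    n.depth,
                    base64.b64encode(n.ciphertext).decode()
                    if n.ciphertext is not None else None,
                    [base64.b64encode(t).decode() for t in n.ref_tokens],
                ]
                for n in self.nodes
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "EncryptedGST":
        doc = json.loads(text)
        if doc.get("format") != "privgst-egst" or doc.get("version") != 1:
            raise ValueError("not a version-1 privgst encrypted tree")
        out = cls(doc["k"], doc["cipher"])
        for node_id, parent_id, depth, ct, tokens in doc["nodes"]:
            node = ENode(
                node_id, parent_id, depth,
                base64.b64decode(ct) if ct is not None else None,
                [base64.b64decode(t) for t in tokens],
            )
            out.nodes.append(node)
            if parent_id >= 0:
                out.nodes[parent_id].children.append(node_id)
        return out


def encrypt_tree(rmtree: RMTree, ctx: EncryptionContext) -> EncryptedGST:
    """Encrypt every non-root digest; topology preserved node-for-node.

    Terminal leaves of the RMT become explicit child nodes of the path node
    they terminate, so the encrypted tree's node count equals (trie nodes)
    + (suffix count), with neither salt nor symbols present anywhere.
    """
    want = rmtree.k // 8
    egst = EncryptedGST(rmtree.k, ctx.cipher)
    id_map: Dict[int, int] = {}
    for node in rmtree.iter_nodes():
        if len(node.digest) != want:
            raise ValueError("digest length inconsistent with k")
        parent = id_map.get(node.parent_id, -1)
        enode = ENode(
            len(egst.nodes), parent, node.depth,
            ctx.encrypt(node.digest) if node.node_id != 0 else None,
        )
        id_map[node.node_id] = enode.node_id
        egst.nodes.append(enode)
        if parent >= 0:
            egst.nodes[parent].children.append(enode.node_id)
        for ref, leaf_digest in node.terminal_leaves:
            leaf = ENode(
                len(egst.nodes), enode.node_id, node.depth + 1,
                ctx.encrypt(leaf_digest),
                ref_tokens=[encode_ref_token(ref, ctx)],
            )
            egst.nodes.append(leaf)
            enode.children.append(leaf.node_id)
    return egst


# --- hash index -------------------------------------------------------------

class IndexEntry(NamedTuple):
    node_id: int          # EncryptedGST node this ciphertext belongs to
    depth: int            # that node's depth in the GST
    ref_tokens: tuple     # opaque suffix references reachable through it


class IndexHit(NamedTuple):
    entry: IndexEntry


class IndexMiss(NamedTuple):
    fail_depth: int       # 1-based depth of the first failing bit


class HashIndex:
    """Fixed-depth (k) binary tree over ciphertext bits.

    Entries live at depth exactly k; :meth:`lookup` is the plain bit-walk
    and :meth:`children_at` exposes the logical per-level child structure
    used by the oblivious protocol.
    """

    def __init__(self, k: int):
        self.k = k
        self._entries: Dict[str, IndexEntry] = {}
        self._keys: List[str] = []
        self._sorted = True

    # -- construction

    def insert(self, ciphertext: bytes, entry: IndexEntry) -> None:
        bits = digest_bits(ciphertext)
        if len(bits) != self.k:
            raise ValueError(f"ciphertext must be {self.k} bits")
        prior = self._entries.get(bits)
        if prior is not None:
            # identical path strings legitimately share a digest: merge refs
            merged = tuple(dict.fromkeys(prior.ref_tokens + entry.ref_tokens))
            self._entries[bits] = prior._replace(ref_tokens=merged)
            return
        self._entries[bits] = entry
        self._keys.append(bits)
        self._sorted = False

    def _key_list(self) -> List[str]:
        if not self._sorted:
            self._keys.sort()
            self._sorted = True
        return self._keys

    # -- queries

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, ciphertext: bytes) -> Union[IndexHit, IndexMiss]:
        bits = digest_bits(ciphertext)
        if len(bits) != self.k:
            raise ValueError(f"ciphertext must be {self.k} bits")
        entry = self._entries.get(bits)
        if entry is not None:
            return IndexHit(entry)
        # first failing bit = longest stored prefix + 1
        depth = 0
        while depth < self.k and self.has_prefix(bits[: depth + 1]):
            depth += 1
        return IndexMiss(fail_depth=depth + 1)

    def has_prefix(self, prefix: str) -> bool:
        keys = self._key_list()
        i = bisect_left(keys, prefix)
        return i < len(keys) and keys[i].startswith(prefix)

    def children_at(self, prefix: str) -> Tuple[str, ...]:
        """Which next bits ('0'/'1') continue ``prefix`` in the logical
        depth-k tree."""
        return tuple(b for b in ("0", "1") if self.has_prefix(prefix + b))

    def entry_at(self, bits: str) -> Optional[IndexEntry]:
        return self._entries.get(bits)

    # -- serialization

    def to_json(self) -> str:
        return json.dumps({
            "format": "privgst-hi",
            "version": 1,
            "k": self.k,
            "entries": [
                [base64.b64encode(bits_to_bytes(bits)).decode(),
                 e.node_id, e.depth,
                 [base64.b64encode(t).decode() for t in e.ref_tokens]]
                for bits, e in sorted(self._entries.items())
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "HashIndex":
        doc = json.loads(text)
        if doc.get("format") != "privgst-hi" or doc.get("version") != 1:
            raise ValueError("not a version-1 privgst hash index")
        out = cls(doc["k"])
        for key_b64, node_id, depth, tokens in doc["entries"]:
            bits = digest_bits(base64.b64decode(key_b64))
            out._entries[bits] = IndexEntry(
                node_id, depth, tuple(base64.b64decode(t) for t in tokens)
            )
            out._keys.append(bits)
        out._sorted = False
        return out


def build_hash_index(egst: EncryptedGST) -> HashIndex:
    """Server-side step: index every node ciphertext of the encrypted tree.

    The entry for a node carries the opaque suffix references of every
    terminal leaf in its subtree — exactly the results a query matching
    that node's path should return.
    """
    k = egst.k
    # accumulate subtree reference tokens bottom-up (postorder)
    subtree: Dict[int, tuple] = {}
    order: List[int] = []
    stack = [egst.root.node_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(egst.nodes[nid].children)
    for nid in reversed(order):
        node = egst.nodes[nid]
        refs = list(node.ref_tokens)
        for cid in node.children:
            refs.extend(subtree[cid])
        subtree[nid] = tuple(refs)
    hi = HashIndex(k)
    for node in egst.nodes:
        if node.ciphertext is None:
            continue
        if len(node.ciphertext) * 8 != k:
            raise ValueError("ciphertext length inconsistent with k")
        hi.insert(node.ciphertext,
                  IndexEntry(node.node_id, node.depth, subtree[node.node_id]))
    return hi


def lookup(hi: HashIndex, ciphertext: bytes) -> Union[IndexHit, IndexMiss]:
    """Module-level alias for :meth:`HashIndex.lookup`."""
    return hi.lookup(ciphertext)
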