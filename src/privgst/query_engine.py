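"""The four string queries over the encrypted index, plus their plaintext oracle.

Queries (all against an n x m record matrix, positions 1-based):

* EM  — exact match: records equal to q over the full length m.
* ESM — exact substring match: records containing q contiguously; every
  occurrence is reported as a span (j1, j2) in record coordinates.
* SMM — set-maximal match: per record, the longest substring(s) of q that
  occur in it, subject to a minimum-length floor; records whose best shared
  substring is shorter than the floor are omitted.  The default floor is
  ceil((|q|+1)/2).
* TSMM — thresholded SMM: the floor is the caller's threshold t.

The secure path never sees plaintext: the researcher folds query substrings
through the salted top-down hash, encrypts the digests, and the server
walks its bit index; returned suffix references are opaque tokens the
researcher decrypts locally.  ``plaintext_oracle`` is an independent direct
scan of the records implementing the same query semantics — the
equivalence of the two paths is the package's central correctness property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .data_io import HaplotypeDataset, QueryString
from .rmt_hash import Salt, rmt_hash_string
from .secure_index import (
    EncryptedGST,
    EncryptionContext,
    HashIndex,
    IndexHit,
    decode_ref_token,
)

__all__ = [
    "QUERY_KINDS",
    "MatchSpan",
    "QueryResult",
    "QueryToken",
    "EncryptedQuery",
    "ServerBundle",
    "default_smm_floor",
    "make_query_tokens",
    "execute_query",
    "plaintext_oracle",
]

QUERY_KINDS = ("em", "esm", "smm", "tsmm")


@dataclass(frozen=True, order=True)
class MatchSpan:
    """A matched span in record coordinates: record ``seq_id`` matches the
    relevant query substring on columns [j1, j2], both 1-based."""

    seq_id: int
    j1: int
    j2: int

    @property
    def length(self) -> int:
        return self.j2 - self.j1 + 1


@dataclass
class QueryResult:
    kind: str
    status: str                      # "hit" | "miss"
    matches: List[MatchSpan] = field(default_factory=list)

    def records(self) -> List[int]:
        return sorted({m.seq_id for m in self.matches})

    def __eq__(self, other):
        if not isinstance(other, QueryResult):
            return NotImplemented
        return (self.kind == other.kind and self.status == other.status
                and sorted(self.matches) == sorted(other.matches))


@dataclass(frozen=True)
class QueryToken:
    ciphertext: bytes
    length: int
    offset: int          # 1-based offset of the substring within q


@dataclass(frozen=True)
class EncryptedQuery:
    """Researcher-side query material: ciphertexts of salted path digests,
    no plaintext symbols.  SMM/TSMM carry one token per distinct substring
    of q down to the length floor, ordered by decreasing length."""

    kind: str
    query_length: int
    tokens: Tuple[QueryToken, ...]
    floor: int


@dataclass
class ServerBundle:
    """What the cloud server holds: the encrypted tree and its bit index."""

    egst: EncryptedGST
    hi: HashIndex


def build_server_bundle(gst, salt: Salt, ctx: EncryptionContext,
                        hash_fn: str = "md5") -> ServerBundle:
    """Owner-then-server pipeline: hash the tree top-down, encrypt every
    digest, and index the ciphertext bits (the index step is the server's;
    it sees only the encrypted tree)."""
    from .rmt_hash import hash_tree
    from .secure_index import build_hash_index, encrypt_tree

    rmtree = hash_tree(gst, salt, hash_fn)
    egst = encrypt_tree(rmtree, ctx)
    return ServerBundle(egst=egst, hi=build_hash_index(egst))


def default_smm_floor(qlen: int) -> int:
    """Smallest per-record match length SMM reports, ceil((|q|+1)/2)."""
    return math.ceil((qlen + 1) / 2)


def make_query_tokens(
    q: QueryString,
    kind: str,
    salt: Salt,
    ctx: EncryptionContext,
    hash_fn: str = "md5",
    t: Optional[int] = None,
    min_match: Optional[int] = None,
    m: Optional[int] = None,
) -> EncryptedQuery:
    """Build the encrypted query for ``kind``.

    EM/ESM use a single token — the encrypted salted digest of q itself.
    SMM enumerates every distinct substring of q of length >= the floor
    (default ceil((|q|+1)/2), overridable via ``min_match``); TSMM uses
    floor t, 1 <= t <= |q|.
    """
    kind = kind.lower()
    if kind not in QUERY_KINDS:
        raise ValueError(f"unknown query kind {kind!r}")
    qs = q.symbols
    if m is not None and len(qs) > m:
        raise ValueError(f"query length {len(qs)} exceeds m={m}")
    if kind in ("em", "esm"):
        floor = len(qs)
        subs = [(qs, 1)]
    else:
        if kind == "tsmm":
            if t is None or not (1 <= t <= len(qs)):
                raise ValueError("tsmm requires a threshold 1 <= t <= |q|")
            floor = t
        else:
            floor = min_match if min_match is not None else default_smm_floor(len(qs))
            if not (1 <= floor <= len(qs)):
                raise ValueError("minimum match length must be in 1..|q|")
        subs = []
        seen = set()
        for length in range(len(qs), floor - 1, -1):
            for off in range(0, len(qs) - length + 1):
                sub = qs[off : off + length]
                if sub not in seen:
                    seen.add(sub)
                    subs.append((sub, off + 1))
    tokens = tuple(
        QueryToken(
            ciphertext=ctx.encrypt(rmt_hash_string(sub, salt, hash_fn)),
            length=len(sub),
            offset=off,
        )
        for sub, off in subs
    )
    return EncryptedQuery(kind=kind, query_length=len(qs), tokens=tokens,
                          floor=floor)


def _spans_from_hit(hit: IndexHit, length: int,
                    ctx: EncryptionContext) -> List[MatchSpan]:
    spans = []
    for token in hit.entry.ref_tokens:
        ref = decode_ref_token(token, ctx)
        spans.append(MatchSpan(ref.seq_id, ref.start, ref.start + length - 1))
    return spans


def execute_query(
    server: ServerBundle,
    eq: EncryptedQuery,
    ctx: EncryptionContext,
    m: Optional[int] = None,
    lookup_fn=None,
) -> QueryResult:
    """Run ``eq`` against the server's index.

    ``lookup_fn(ciphertext)`` defaults to the plain index walk; the
    oblivious protocol substitutes its own.  The server side only ever
    touches the index and opaque tokens; span decryption happens here on
    the researcher's behalf.  A key/salt mismatch between index and query
    is indistinguishable from a universal miss by design.
    """
    if lookup_fn is None:
        lookup_fn = server.hi.lookup

    if eq.kind in ("em", "esm"):
        res = lookup_fn(eq.tokens[0].ciphertext)
        if not isinstance(res, IndexHit):
            return QueryResult(eq.kind, "miss")
        spans = _spans_from_hit(res, eq.query_length, ctx)
        if eq.kind == "em":
            # full-length equality: the matched path must span all m columns
            if m is not None and res.entry.depth != m:
                return QueryResult(eq.kind, "miss")
            spans = [s for s in spans if s.j1 == 1]
            if not spans:
                return QueryResult(eq.kind, "miss")
        return QueryResult(eq.kind, "hit", sorted(spans))

    # SMM / TSMM: iterate token lengths descending; each record is settled
    # at the first (longest) length at which any of its suffixes match.
    settled: Dict[int, int] = {}
    matches: List[MatchSpan] = []
    current_len: Optional[int] = None
    pending: List[MatchSpan] = []

    def flush():
        for span in pending:
            if settled.get(span.seq_id, span.length) == span.length:
                settled[span.seq_id] = span.length
                matches.append(span)

    for token in eq.tokens:
        if token.length != current_len:
            flush()
            pending.clear()
            current_len = token.length
        res = lookup_fn(token.ciphertext)
        if isinstance(res, IndexHit):
            for span in _spans_from_hit(res, token.length, ctx):
                if span.seq_id not in settled:
                    pending.append(span)
    flush()
    if not matches:
        return QueryResult(eq.kind, "miss")
    return QueryResult(eq.kind, "hit", sorted(set(matches)))


# ---------------------------------------------------------------------------
# Plaintext oracle: a direct transcription of the query semantics
# ---------------------------------------------------------------------------

def _occurrences(record: str, sub: str) -> List[int]:
    out = []
    start = record.find(sub)
    while start != -1:
        out.append(start + 1)
        start = record.find(sub, start + 1)
    return out


def plaintext_oracle(
    dataset: HaplotypeDataset,
    q: QueryString,
    kind: str,
    t: Optional[int] = None,
    min_match: Optional[int] = None,
) -> QueryResult:
    """Ground truth by naive O(n * m * |q|) scanning of the records."""
    kind = kind.lower()
    if kind not in QUERY_KINDS:
        raise ValueError(f"unknown query kind {kind!r}")
    q.validate_against(dataset)
    qs = q.symbols
    matches: List[MatchSpan] = []

    if kind == "em":
        for sid, rec in dataset:
            if rec == qs:
                matches.append(MatchSpan(sid, 1, dataset.m))
    elif kind == "esm":
        for sid, rec in dataset:
            for j1 in _occurrences(rec, qs):
                matches.append(MatchSpan(sid, j1, j1 + len(qs) - 1))
    else:
        if kind == "tsmm":
            if t is None or not (1 <= t <= len(qs)):
                raise ValueError("tsmm requires a threshold 1 <= t <= |q|")
            floor = t
        else:
            floor = min_match if min_match is not None else default_smm_floor(len(qs))
        for sid, rec in dataset:
            for length in range(len(qs), floor - 1, -1):
                subs = {qs[o : o + length] for o in range(len(qs) - length + 1)}
                found = []
                for sub in subs:
                    for j1 in _occurrences(rec, sub):
                        found.append(MatchSpan(sid, j1, j1 + length - 1))
                if found:
                    matches.extend(set(found))
                    break
    if not matches:
        return QueryResult(kind, "miss")
    return QueryResult(kind, "hit", sorted(set(matches)))
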