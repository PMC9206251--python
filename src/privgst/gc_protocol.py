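"""Two-party oblivious bit matching against the hash index.

The researcher holds the k ciphertext bits of a query token; the server
holds the bit index.  Per round (one per index level, at most k rounds) the
server selects a candidate child bit — at random when both children exist —
and the two parties evaluate a single XNOR gate on their private bits.
Only the server learns the equality bit: on agreement it advances into the
selected child, on disagreement it takes the sibling if present and
otherwise reports a mismatch.  A walk that survives all k levels lands on
an index leaf and the server returns that leaf's opaque suffix references.
Functionally the protocol computes exactly the plain index lookup; what it
adds is that the researcher's bits never cross the wire in the clear.

Two interchangeable gate backends:

* ``simulated`` (default) — a trusted in-process broker computes the XNOR
  and emits fixed-size random stand-in blobs for the wire messages.
  Functionally faithful, zero cryptography; this is what the equivalence
  suites run.
* ``garbled`` — a real single-gate garbling: random 16-byte wire labels, a
  shuffled four-row table encrypted under SHA-256 of the label pair with a
  15-byte redundancy check (exactly one row decrypts), and a trivial
  oblivious-transfer abstraction delivering the researcher's input label.

Neither backend claims security against a malicious party; the round
structure, the gate, and the output-to-server-only rule follow the
two-party design, while the OT is deliberately minimal.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

from .secure_index import HashIndex, IndexEntry, IndexHit, IndexMiss
from .rmt_hash import digest_bits

__all__ = [
    "BACKENDS",
    "Round",
    "ProtocolTranscript",
    "GarbledXnorGate",
    "garbled_xnor",
    "run_oblivious_lookup",
]

BACKENDS = ("simulated", "garbled")

_LABEL = 16  # wire-label bytes


@dataclass(frozen=True)
class Round:
    depth: int
    blobs: Tuple[bytes, ...]   # opaque wire messages exchanged this round
    outcome: str               # "advance" | "mismatch" | "leaf-hit" (server-visible)


@dataclass
class ProtocolTranscript:
    backend: str
    rounds: List[Round] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rounds)


class GarbledXnorGate:
    """One garbled XNOR gate.

    The garbler (server) draws a random label per wire value; each table
    row is ``H(label_a || label_b) XOR (15 zero bytes || output bit)``, so
    an evaluator holding one label pair can decrypt exactly one row — the
    zero padding is the validity check.
    """

    def __init__(self, rng: random.Random):
        self.labels_a = (rng.randbytes(_LABEL), rng.randbytes(_LABEL))
        self.labels_b = (rng.randbytes(_LABEL), rng.randbytes(_LABEL))
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                out = 1 if a == b else 0
                pad = hashlib.sha256(
                    self.labels_a[a] + self.labels_b[b]
                ).digest()[:_LABEL]
                plain = bytes(15) + bytes([out])
                rows.append(bytes(x ^ y for x, y in zip(pad, plain)))
        rng.shuffle(rows)
        self.table = tuple(rows)

    def decryptable_rows(self, label_a: bytes, label_b: bytes) -> List[int]:
        pad = hashlib.sha256(label_a + label_b).digest()[:_LABEL]
        hits = []
        for i, row in enumerate(self.table):
            plain = bytes(x ^ y for x, y in zip(pad, row))
            if plain[:15] == bytes(15) and plain[15] in (0, 1):
                hits.append(i)
        return hits

    def evaluate(self, label_a: bytes, label_b: bytes) -> int:
        rows = self.decryptable_rows(label_a, label_b)
        if len(rows) != 1:
            raise ValueError("malformed garbled table or labels")
        pad = hashlib.sha256(label_a + label_b).digest()[:_LABEL]
        return bytes(x ^ y for x, y in zip(pad, self.table[rows[0]]))[15]


def _ot_fetch(labels: Tuple[bytes, bytes], choice: int) -> bytes:
    """Oblivious-transfer abstraction: the chooser obtains exactly the
    label for its bit.  In-process stand-in for a real 1-of-2 OT."""
    return labels[choice]


def garbled_xnor(
    server_bit: int,
    client_bit: int,
    backend: str = "simulated",
    rng: Optional[random.Random] = None,
) -> Tuple[int, Tuple[bytes, ...]]:
    """Equality of two private bits, output to the server role only.

    Returns ``(equality_bit, wire_blobs)``; the blobs are the opaque
    messages that crossed the wire (labels and table rows for the garbled
    backend, fixed-size random stand-ins for the simulated broker).
    """
    if server_bit not in (0, 1) or client_bit not in (0, 1):
        raise ValueError("inputs must be bits")
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    rng = rng or random.Random()
    if backend == "simulated":
        # trusted broker: computes the gate, never logs inputs
        blobs = (rng.randbytes(_LABEL), rng.randbytes(_LABEL))
        return (1 if server_bit == client_bit else 0), blobs
    gate = GarbledXnorGate(rng)
    label_server = gate.labels_a[server_bit]
    label_client = _ot_fetch(gate.labels_b, client_bit)
    out = gate.evaluate(label_server, label_client)
    return out, gate.table + (label_client,)


def run_oblivious_lookup(
    token_ciphertext: bytes,
    hi: HashIndex,
    backend: str = "simulated",
    seed: Optional[int] = None,
    whole_query: bool = False,
) -> Tuple[Union[IndexHit, IndexMiss], ProtocolTranscript]:
    """Walk the index obliviously; functionally identical to
    ``hi.lookup(token_ciphertext)``.

    The server's random child selection is seedable so transcripts are
    reproducible in tests.  The transcript ends at the first mismatch or,
    on a hit, after exactly k rounds.  ``whole_query=True`` selects the
    experimental non-iterative variant (the entire token enters a single
    conceptual circuit; one round, no per-bit disclosure) — functionally
    equivalent but outside the protocol-flow guarantees of the iterative
    path.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    rng = random.Random(seed)
    bits = digest_bits(token_ciphertext)
    if len(bits) != hi.k:
        raise ValueError(f"token must be {hi.k} bits")
    transcript = ProtocolTranscript(backend=backend)
    if whole_query:
        res = hi.lookup(token_ciphertext)
        transcript.rounds.append(Round(
            1, (rng.randbytes(_LABEL),),
            "leaf-hit" if isinstance(res, IndexHit) else "mismatch",
        ))
        return res, transcript
    prefix = ""
    for depth in range(1, hi.k + 1):
        children = hi.children_at(prefix)
        if not children:
            transcript.rounds.append(Round(depth, (), "mismatch"))
            return IndexMiss(fail_depth=depth), transcript
        candidate = children[0] if len(children) == 1 else rng.choice(children)
        client_bit = int(bits[depth - 1])
        eq, blobs = garbled_xnor(int(candidate), client_bit,
                                 backend=backend, rng=rng)
        if eq:
            prefix += candidate
        else:
            sibling = "1" if candidate == "0" else "0"
            if sibling not in children:
                transcript.rounds.append(Round(depth, blobs, "mismatch"))
                return IndexMiss(fail_depth=depth), transcript
            # binary wires: a mismatch with one child pins the bit to the
            # sibling, no extra round needed
            prefix += sibling
        outcome = "leaf-hit" if depth == hi.k else "advance"
        transcript.rounds.append(Round(depth, blobs, outcome))
    entry = hi.entry_at(prefix)
    if entry is None:  # cannot happen: every surviving prefix is a stored key
        return IndexMiss(fail_depth=hi.k), transcript
    return IndexHit(entry), transcript
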