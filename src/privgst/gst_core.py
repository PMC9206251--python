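"""Generalized suffix trees: naive trie builder, Ukkonen builder, equality.

Two builders produce the same logical object:

* :func:`build_trie` inserts every suffix symbol-by-symbol into an
  uncompressed trie.  It is quadratic but transparently correct and serves
  as the oracle for everything else.
* :func:`build_ukkonen` runs Ukkonen's linear-time online construction over
  each sequence (with a per-sequence sentinel), producing a compressed
  edge-labelled tree that expands to the identical trie.

The uncompressed trie is the canonical logical representation: downstream
hashing assigns one digest per single-symbol node, so the compressed form
exposes :meth:`CompressedGST.to_trie`.  Suffix multisets — the set of
``(sequence id, start, suffix string)`` triples — are the semantic equality
surface for trees; :func:`canonical_form` gives a decidable structural one.

Leaf terminators are typed ``Terminal(seq_id, start)`` objects, not in-band
characters, so they can never collide with alphabet symbols.  Positions are
1-based in full-sequence coordinates, also for column-restricted builds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Tuple

from .data_io import HaplotypeDataset

__all__ = [
    "Terminal",
    "GSTNode",
    "GST",
    "CompressedGST",
    "GSTError",
    "GSTFormatError",
    "build_trie",
    "build_ukkonen",
    "enumerate_suffixes",
    "canonical_form",
    "canonicalize",
    "serialize_gst",
    "deserialize_gst",
]


class GSTError(ValueError):
    """Structural violation in a suffix tree operation."""


class GSTFormatError(GSTError):
    """Unreadable or version-mismatched serialized tree."""


class Terminal(NamedTuple):
    """Suffix terminator: which sequence, and the 1-based start column."""

    seq_id: int
    start: int


class GSTNode:
    __slots__ = ("symbol", "children", "leaf_refs", "node_id")

    def __init__(self, symbol: Optional[str] = None, node_id: int = -1):
        self.symbol = symbol          # edge symbol from parent; None at root
        self.children = {}            # next symbol -> GSTNode
        self.leaf_refs = set()        # Terminals ending exactly here
        self.node_id = node_id


class GST:
    """Uncompressed generalized suffix trie."""

    representation = "trie"

    def __init__(self, root: GSTNode, m: int, alphabet: frozenset,
                 sequence_count: int = 0):
        self.root = root
        self.m = m
        self.alphabet = frozenset(alphabet)
        self.sequence_count = sequence_count

    def node_count(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            stack.extend(node.children.values())
        return count

    def leaf_ref_count(self) -> int:
        total = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            total += len(node.leaf_refs)
            stack.extend(node.children.values())
        return total

    def __eq__(self, other) -> bool:
        if not isinstance(other, (GST, CompressedGST)):
            return NotImplemented
        return canonical_form(self) == canonical_form(other)

    __hash__ = None


def _empty_trie(m: int, alphabet) -> GST:
    return GST(GSTNode(), m, frozenset(alphabet))


def _insert_suffix(root: GSTNode, suffix: str, ref: Terminal) -> None:
    node = root
    for sym in suffix:
        child = node.children.get(sym)
        if child is None:
            child = GSTNode(sym)
            node.children[sym] = child
        node = child
    node.leaf_refs.add(ref)


def _resolve_span(dataset: HaplotypeDataset, rows, span):
    rows = tuple(rows) if rows is not None else dataset.ids
    if not rows:
        raise GSTError("row set must be non-empty")
    bad = set(rows) - set(dataset.ids)
    if bad:
        raise GSTError(f"rows {sorted(bad)} not in dataset")
    c1, c2 = span if span is not None else (1, dataset.m)
    if not (1 <= c1 <= c2 <= dataset.m):
        raise GSTError(f"column span [{c1}, {c2}] outside 1..{dataset.m}")
    return rows, c1, c2


def build_trie(dataset: HaplotypeDataset, rows=None, span=None) -> GST:
    """Insert every suffix of every selected record (restricted to the
    column span) into a trie.  Suffix starts are recorded in full-sequence
    coordinates, so column-block builds can later be stitched together."""
    rows, c1, c2 = _resolve_span(dataset, rows, span)
    gst = _empty_trie(dataset.m, dataset.alphabet)
    for sid in rows:
        seq = dataset.record(sid)[c1 - 1 : c2]
        for j, _ in enumerate(seq):
            _insert_suffix(gst.root, seq[j:], Terminal(sid, c1 + j))
    gst.sequence_count = len(rows)
    return gst


def enumerate_suffixes(gst) -> set:
    """All ``(seq_id, start, suffix)`` triples indexed by the tree — the
    canonical semantic view used for tree equality."""
    if isinstance(gst, CompressedGST):
        gst = gst.to_trie()
    out = set()
    stack = [(gst.root, "")]
    while stack:
        node, path = stack.pop()
        for ref in node.leaf_refs:
            out.add((ref.seq_id, ref.start, path))
        for sym, child in node.children.items():
            stack.append((child, path + sym))
    return out


def canonicalize(gst) -> GST:
    """Copy with children sorted by symbol and node ids renumbered in
    preorder.  Idempotent; makes structural equality decidable."""
    if isinstance(gst, CompressedGST):
        gst = gst.to_trie()
    counter = [0]

    def copy(node: GSTNode, symbol) -> GSTNode:
        new = GSTNode(symbol, counter[0])
        counter[0] += 1
        new.leaf_refs = set(node.leaf_refs)
        for sym in sorted(node.children):
            new.children[sym] = copy(node.children[sym], sym)
        return new

    out = GST(copy(gst.root, None), gst.m, gst.alphabet, gst.sequence_count)
    return out


def canonical_form(gst) -> tuple:
    """Nested-tuple fingerprint of the canonicalized tree."""
    if isinstance(gst, CompressedGST):
        gst = gst.to_trie()

    def form(node: GSTNode) -> tuple:
        return (
            tuple(sorted(node.leaf_refs)),
            tuple((sym, form(node.children[sym]))
                  for sym in sorted(node.children)),
        )

    return form(gst.root)


# ---------------------------------------------------------------------------
# Ukkonen construction (compressed form)
# ---------------------------------------------------------------------------

class _Sentinel:
    """Unique end-of-sequence marker; compares unequal to every symbol."""

    __slots__ = ("idx",)

    def __init__(self, idx: int):
        self.idx = idx

    def __repr__(self):
        return f"$<{self.idx}>"


class _UNode:
    __slots__ = ("children", "link", "ref")

    def __init__(self):
        self.children = {}   # first symbol -> _UEdge
        self.link = None
        self.ref = None      # (text index, suffix start) on leaves


class _UEdge:
    __slots__ = ("tid", "start", "end", "node")

    def __init__(self, tid: int, start: int, end: Optional[int], node: _UNode):
        self.tid = tid
        self.start = start
        self.end = end       # None while the owning text is being processed
        self.node = node


class CompressedGST:
    """Edge-labelled (Ukkonen) generalized suffix tree.

    ``texts`` holds the indexed substrings (without sentinels); leaf refs
    map back to ``Terminal`` coordinates via ``origins`` = per-text
    (sequence id, first column).
    """

    representation = "compressed"

    def __init__(self, root: _UNode, texts, origins, m: int, alphabet):
        self.root = root
        self.texts = texts
        self.origins = origins
        self.m = m
        self.alphabet = frozenset(alphabet)

    def expand_iter(self):
        """Yield ``(path_string, ref_or_None)`` per logical trie node in
        depth-first order; refs surface at the node ending each suffix."""
        trie = self.to_trie()
        stack = [(trie.root, "")]
        while stack:
            node, path = stack.pop()
            if node.leaf_refs:
                for ref in node.leaf_refs:
                    yield path, ref
            else:
                yield path, None
            for sym, child in node.children.items():
                stack.append((child, path + sym))

    def to_trie(self) -> GST:
        out = _empty_trie(self.m, self.alphabet)
        stack = [(self.root, "")]
        paths = []
        while stack:
            node, path = stack.pop()
            if node.ref is not None:
                tid, j = node.ref
                sid, c1 = self.origins[tid]
                if j < len(self.texts[tid]):  # skip the bare-sentinel suffix
                    paths.append((path, Terminal(sid, c1 + j)))
                continue
            for edge in node.children.values():
                label = self.texts[edge.tid]
                end = edge.end if edge.end is not None else len(label) + 1
                chunk = label[edge.start : min(end, len(label))]
                stack.append((edge.node, path + "".join(chunk)))
        for path, ref in paths:
            _insert_suffix(out.root, path, ref)
        out.sequence_count = len(self.texts)
        return out

    def __eq__(self, other):
        if not isinstance(other, (GST, CompressedGST)):
            return NotImplemented
        return canonical_form(self) == canonical_form(other)

    __hash__ = None


def _ukkonen_insert(root: _UNode, texts, tid: int) -> None:
    """Run Ukkonen's algorithm for texts[tid] (+ sentinel) over a shared
    tree; the active point starts at the root for each new text."""
    text = list(texts[tid]) + [_Sentinel(tid)]
    active_node, active_edge, active_len = root, 0, 0
    remainder = 0

    def edge_symbols(edge: _UEdge):
        base = texts[edge.tid]
        return base, len(base) + 1  # +1 for sentinel slot

    def symbol_at(edge: _UEdge, offset: int):
        base, _ = edge_symbols(edge)
        pos = edge.start + offset
        if pos < len(base):
            return base[pos]
        return _Sentinel(edge.tid)  # sentinel occupies the last slot

    def edge_length(edge: _UEdge) -> int:
        if edge.end is not None:
            return edge.end - edge.start
        if edge.tid == tid:
            return pos_holder[0] + 1 - edge.start
        return len(texts[edge.tid]) + 1 - edge.start

    def key(sym):
        return sym if isinstance(sym, str) else ("$", sym.idx)

    pos_holder = [0]
    for pos, sym in enumerate(text):
        pos_holder[0] = pos
        remainder += 1
        last_internal = None
        while remainder:
            if active_len == 0:
                active_edge = pos
            first = text[active_edge]
            edge = active_node.children.get(key(first))
            if edge is None:
                leaf = _UNode()
                leaf.ref = (tid, pos - remainder + 1)
                active_node.children[key(first)] = _UEdge(
                    tid, active_edge, None, leaf
                )
                if last_internal is not None:
                    last_internal.link = active_node
                    last_internal = None
            else:
                elen = edge_length(edge)
                if active_len >= elen:
                    active_node = edge.node
                    active_edge += elen
                    active_len -= elen
                    continue
                nxt = symbol_at(edge, active_len)
                same = (
                    nxt == sym
                    if isinstance(nxt, str) and isinstance(sym, str)
                    else (not isinstance(nxt, str)
                          and not isinstance(sym, str)
                          and nxt.idx == sym.idx)
                )
                if same:
                    active_len += 1
                    if last_internal is not None:
                        last_internal.link = active_node
                        last_internal = None
                    break
                # split the edge at active_len
                split = _UNode()
                split_edge = _UEdge(
                    edge.tid, edge.start, edge.start + active_len, split
                )
                active_node.children[key(first)] = split_edge
                edge.start += active_len
                base, _ = edge_symbols(edge)
                tail_first = (
                    base[edge.start]
                    if edge.start < len(base)
                    else _Sentinel(edge.tid)
                )
                split.children[key(tail_first)] = edge
                leaf = _UNode()
                leaf.ref = (tid, pos - remainder + 1)
                split.children[key(sym)] = _UEdge(tid, pos, None, leaf)
                if last_internal is not None:
                    last_internal.link = split
                last_internal = split
            remainder -= 1
            if active_node is root and active_len > 0:
                active_len -= 1
                active_edge = pos - remainder + 1
            elif active_node is not root:
                active_node = active_node.link or root
    # freeze this text's open leaf edges
    stack = [root]
    while stack:
        node = stack.pop()
        for edge in node.children.values():
            if edge.end is None and edge.tid == tid:
                edge.end = len(texts[tid]) + 1
            stack.append(edge.node)


def build_ukkonen(dataset: HaplotypeDataset, rows=None, span=None) -> CompressedGST:
    """Linear-time construction; expands to the same trie as
    :func:`build_trie` (property-tested equivalence)."""
    rows, c1, c2 = _resolve_span(dataset, rows, span)
    texts = [dataset.record(sid)[c1 - 1 : c2] for sid in rows]
    origins = [(sid, c1) for sid in rows]
    root = _UNode()
    for tid in range(len(texts)):
        _ukkonen_insert(root, texts, tid)
    return CompressedGST(root, texts, origins, dataset.m, dataset.alphabet)


# ---------------------------------------------------------------------------
# Serialization (versioned JSON; self-describing)
# ---------------------------------------------------------------------------

_FORMAT = "privgst-gst"
_VERSION = 1


def serialize_gst(gst, path) -> Path:
    """Write the canonical trie view as versioned JSON.  Round-trips
    bit-exactly at the canonical-form level."""
    canon = canonicalize(gst)
    nodes = []

    def walk(node: GSTNode, parent: int):
        nodes.append(
            [
                node.node_id,
                parent,
                node.symbol,
                sorted([r.seq_id, r.start] for r in node.leaf_refs),
            ]
        )
        for child in node.children.values():
            walk(child, node.node_id)

    walk(canon.root, -1)
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "m": canon.m,
        "alphabet": sorted(canon.alphabet),
        "sequence_count": canon.sequence_count,
        "nodes": nodes,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def deserialize_gst(path) -> GST:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise GSTFormatError(f"unreadable tree file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise GSTFormatError(f"{path} is not a {_FORMAT} file")
    if doc.get("version") != _VERSION:
        raise GSTFormatError(
            f"unsupported version {doc.get('version')!r} (expected {_VERSION})"
        )
    try:
        by_id = {}
        root = None
        for node_id, parent, symbol, refs in doc["nodes"]:
            node = GSTNode(symbol, node_id)
            node.leaf_refs = {Terminal(s, p) for s, p in refs}
            by_id[node_id] = node
            if parent == -1:
                root = node
            else:
                by_id[parent].children[symbol] = node
        if root is None:
            raise KeyError("root")
        gst = GST(root, doc["m"], frozenset(doc["alphabet"]),
                  doc.get("sequence_count", 0))
    except (KeyError, TypeError, ValueError) as exc:
        raise GSTFormatError(f"truncated or corrupt tree file {path}") from exc
    return gst
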