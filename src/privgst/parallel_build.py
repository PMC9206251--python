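"""Partitioned, concurrent GST construction with duplicate-free merging.

The record matrix is tiled into contiguous blocks (horizontal = row groups,
vertical = column groups, bidirectional = both, p >= 4), one worker per
block.  Workers build their block trees independently and exchange them as
serialized files through a spool directory — the share-nothing contract of
a distributed-memory cluster, emulated on one machine.

A block that does not reach the last column only holds truncated suffixes;
each is extended by its sequence's tail — a *path graph*, the linear chain
of the remaining columns — before merging, with shared prefixes merged so
no level ever holds duplicate sibling symbols.  With more than two column
blocks the extension chains right-to-left: block j's tail is block j+1's
columns followed by block j+1's own tail.

The final merge may fan out over the root's first-symbol branches (subtrees
under distinct leading symbols share no edges, so they merge independently;
within one branch merging stays sequential).  The end-to-end contract:
``build_parallel`` equals the serial trie build, canonically, for every
scheme and worker count.
"""

from __future__ import annotations

import tempfile
from concurrent.futures import ProcessPoolExecutor, ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .data_io import HaplotypeDataset
from .gst_core import (
    GST,
    GSTError,
    GSTNode,
    Terminal,
    build_trie,
    canonicalize,
    deserialize_gst,
    serialize_gst,
)

__all__ = [
    "SCHEMES",
    "PartitionPlan",
    "PathGraph",
    "ParallelBuildError",
    "plan_partition",
    "extend_with_path_graphs",
    "merge_gst",
    "build_parallel",
]

SCHEMES = ("horizontal", "vertical", "bidirectional")


class ParallelBuildError(GSTError):
    def __init__(self, message, block_id=None):
        super().__init__(message)
        self.block_id = block_id


@dataclass(frozen=True)
class PartitionPlan:
    """Tiling of the n x m matrix plus a binary-reduction merge schedule.

    ``blocks`` is a list of ``(worker_id, (r1, r2), (c1, c2))`` with
    inclusive 1-based bounds; blocks tile the matrix exactly.  The merge
    schedule pairs workers by proximity rank (default: adjacent ids), one
    list of pairs per reduction round.
    """

    scheme: str
    p: int
    n: int
    m: int
    blocks: tuple
    merge_schedule: tuple

    def column_groups(self) -> List[List[tuple]]:
        """Blocks grouped by row range, each group ordered by column."""
        groups: Dict[tuple, list] = {}
        for blk in self.blocks:
            groups.setdefault(blk[1], []).append(blk)
        return [sorted(g, key=lambda b: b[2]) for _, g in sorted(groups.items())]


@dataclass(frozen=True)
class PathGraph:
    """Linear chain of tail symbols for one sequence: columns
    [start_col, start_col + len(symbols) - 1].  Every non-terminal node of
    the chain has exactly one child by construction."""

    label: str
    seq_id: int
    symbols: str
    start_col: int


def _split_even(total: int, parts: int) -> List[tuple]:
    """Contiguous 1-based ranges whose sizes differ by at most one."""
    base, extra = divmod(total, parts)
    out = []
    lo = 1
    for i in range(parts):
        size = base + (1 if i < extra else 0)
        out.append((lo, lo + size - 1))
        lo += size
    return out


def _reduction_schedule(worker_ids: Sequence[int]) -> tuple:
    """Adjacent-pair binary reduction; the surviving partner is the lower
    id ("closest nodes" proximity rank = id distance)."""
    rounds = []
    alive = list(worker_ids)
    while len(alive) > 1:
        pairs = []
        nxt = []
        for i in range(0, len(alive) - 1, 2):
            pairs.append((alive[i], alive[i + 1]))
            nxt.append(alive[i])
        if len(alive) % 2:
            nxt.append(alive[-1])
        rounds.append(tuple(pairs))
        alive = nxt
    return tuple(rounds)


def _factor_grid(p: int) -> Tuple[int, int]:
    best = None
    for rows in range(2, int(p ** 0.5) + 1):
        if p % rows == 0 and p // rows >= 2:
            best = (rows, p // rows)
    if best is None:
        raise GSTError(
            f"bidirectional partitioning needs p expressible as a product of "
            f"two factors >= 2; p={p} is not"
        )
    return best


def plan_partition(n: int, m: int, p: int, scheme: str) -> PartitionPlan:
    if scheme not in SCHEMES:
        raise GSTError(f"unknown scheme {scheme!r}")
    if p < 1:
        raise GSTError("worker count must be >= 1")
    if scheme == "bidirectional" and p < 4:
        raise GSTError("bidirectional partitioning requires p >= 4")
    p = min(p, n if scheme == "horizontal" else m if scheme == "vertical" else p)
    blocks = []
    if p == 1 or scheme == "horizontal":
        for wid, rows in enumerate(_split_even(n, min(p, n))):
            blocks.append((wid, rows, (1, m)))
    elif scheme == "vertical":
        for wid, cols in enumerate(_split_even(m, min(p, m))):
            blocks.append((wid, (1, n), cols))
    else:
        pr, pc = _factor_grid(p)
        pr, pc = min(pr, n), min(pc, m)
        wid = 0
        for rows in _split_even(n, pr):
            for cols in _split_even(m, pc):
                blocks.append((wid, rows, cols))
                wid += 1
    schedule = _reduction_schedule([b[0] for b in blocks]) if len(blocks) > 1 else ()
    return PartitionPlan(scheme, len(blocks), n, m, tuple(blocks), schedule)


# ---------------------------------------------------------------------------
# Path-graph extension for column-truncated blocks
# ---------------------------------------------------------------------------

def extend_with_path_graphs(gst_block: GST, tails: Dict[int, PathGraph],
                            block_end_col: int) -> GST:
    """Append each sequence's tail chain to every suffix of a truncated
    block so all suffixes end at column m.

    Operates purely on the block tree and the supplied path graphs.  Tail
    symbols are inserted "without duplication": shared prefixes merge into
    existing branches.  A zero-length tail set (block already ends at m) is
    the identity.
    """
    if not tails:
        return gst_block
    # collect (ref, partial suffix) pairs from the block tree
    pairs = []
    stack = [(gst_block.root, "")]
    while stack:
        node, path = stack.pop()
        for ref in node.leaf_refs:
            pairs.append((ref, path))
        for sym, child in node.children.items():
            stack.append((child, path + sym))
    out = GST(GSTNode(), gst_block.m, gst_block.alphabet,
              gst_block.sequence_count)
    for ref, path in pairs:
        tail = tails.get(ref.seq_id)
        if tail is None:
            raise GSTError(
                f"no path graph supplied for sequence {ref.seq_id} "
                f"(pending continuation past column {block_end_col})"
            )
        if tail.start_col != block_end_col + 1:
            raise GSTError(
                f"path graph %{tail.label} starts at column {tail.start_col}, "
                f"expected {block_end_col + 1}"
            )
        node = out.root
        for sym in path + tail.symbols:
            child = node.children.get(sym)
            if child is None:
                child = GSTNode(sym)
                node.children[sym] = child
            node = child
        node.leaf_refs.add(ref)
    return out


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _merge_nodes(dst: GSTNode, src: GSTNode) -> None:
    dst.leaf_refs |= src.leaf_refs
    for sym, child in src.children.items():
        mine = dst.children.get(sym)
        if mine is None:
            mine = GSTNode(sym)
            dst.children[sym] = mine
        _merge_nodes(mine, child)


def merge_gst(a: GST, b: GST) -> GST:
    """Union of two trees' suffix sets; inputs are left unmodified and no
    node level ends up with duplicate sibling symbols (one child per
    symbol, by construction of the children map)."""
    if a.alphabet != b.alphabet and a.root.children and b.root.children:
        raise GSTError(
            f"alphabet mismatch: {sorted(a.alphabet)} vs {sorted(b.alphabet)}"
        )
    out = GST(GSTNode(), max(a.m, b.m), a.alphabet or b.alphabet,
              a.sequence_count + b.sequence_count)
    _merge_nodes(out.root, a.root)
    _merge_nodes(out.root, b.root)
    return canonicalize(out)


def _merge_group(nodes: List[GSTNode]) -> GSTNode:
    dst = GSTNode(nodes[0].symbol)
    for node in nodes:
        _merge_nodes(dst, node)
    return dst


def _merge_many_branch_parallel(trees: List[GST], branch_depth: int,
                                pool) -> GST:
    """Merge a list of trees, fanning independent branches out over the
    pool.  Branch groups are keyed by the first ``branch_depth`` symbols of
    each root path; distinct keys share no edges so their merges are
    independent, while merging within one key stays sequential.  Nodes
    shallower than the branch depth (short suffixes) are unioned directly
    into the output spine."""
    depth = max(1, branch_depth)
    alphabet = next((t.alphabet for t in trees if t.alphabet), frozenset())
    out = GST(GSTNode(), max(t.m for t in trees), alphabet,
              sum(t.sequence_count for t in trees))

    groups: Dict[str, List[GSTNode]] = {}
    shallow: Dict[str, set] = {}
    for tree in trees:
        stack = [(tree.root, "")]
        while stack:
            node, prefix = stack.pop()
            if len(prefix) == depth:
                groups.setdefault(prefix, []).append(node)
                continue
            if node.leaf_refs:
                shallow.setdefault(prefix, set()).update(node.leaf_refs)
            for sym, child in node.children.items():
                stack.append((child, prefix + sym))

    if pool is None:
        merged = {prefix: _merge_group(nodes)
                  for prefix, nodes in groups.items()}
    else:
        futures = {prefix: pool.submit(_merge_group, nodes)
                   for prefix, nodes in groups.items()}
        merged = {prefix: fut.result() for prefix, fut in futures.items()}

    def walk_create(prefix: str) -> GSTNode:
        cursor = out.root
        for sym in prefix:
            nxt = cursor.children.get(sym)
            if nxt is None:
                nxt = GSTNode(sym)
                cursor.children[sym] = nxt
            cursor = nxt
        return cursor

    for prefix, node in sorted(merged.items()):
        parent = walk_create(prefix[:-1])
        existing = parent.children.get(prefix[-1])
        if existing is None:
            parent.children[prefix[-1]] = node
        else:
            _merge_nodes(existing, node)
    for prefix, refs in shallow.items():
        walk_create(prefix).leaf_refs |= refs
    return canonicalize(out)


# ---------------------------------------------------------------------------
# End-to-end parallel build
# ---------------------------------------------------------------------------

def _build_block(dataset: HaplotypeDataset, block, spool: Path) -> Path:
    wid, (r1, r2), (c1, c2) = block
    rows = [sid for sid in dataset.ids if r1 <= sid <= r2]
    tree = build_trie(dataset, rows=rows, span=(c1, c2))
    path = spool / f"block_{wid}.gst.json"
    serialize_gst(tree, path)
    return path


def _make_pool(executor: str, max_workers: Optional[int]):
    if executor == "serial":
        return None
    if executor == "thread":
        return ThreadPoolExecutor(max_workers=max_workers)
    if executor == "process":
        return ProcessPoolExecutor(max_workers=max_workers)
    raise GSTError(f"unknown executor {executor!r}")


def build_parallel(
    dataset: HaplotypeDataset,
    plan: PartitionPlan,
    executor: str = "thread",
    max_workers: Optional[int] = None,
    spool_dir=None,
    branch_depth: int = 1,
) -> GST:
    """Build per-block trees concurrently, extend truncated blocks with
    path graphs, and merge into one tree equal to the serial build.

    Workers share no state: every block tree crosses the worker boundary as
    a serialized file in the spool directory.  ``executor`` selects the
    concurrency backend ("thread" default, "process" for real OS-process
    isolation, "serial" for debugging).
    """
    if (plan.n, plan.m) != (dataset.n, dataset.m):
        raise GSTError("plan shape does not match dataset shape")
    own_spool = spool_dir is None
    spool = Path(tempfile.mkdtemp(prefix="privgst-spool-")) if own_spool \
        else Path(spool_dir)
    spool.mkdir(parents=True, exist_ok=True)
    pool = _make_pool(executor, max_workers)
    try:
        if pool is None:
            paths = {blk[0]: _build_block(dataset, blk, spool)
                     for blk in plan.blocks}
        else:
            futures = {blk[0]: pool.submit(_build_block, dataset, blk, spool)
                       for blk in plan.blocks}
            paths = {}
            for wid, fut in futures.items():
                try:
                    paths[wid] = fut.result()
                except Exception as exc:
                    raise ParallelBuildError(
                        f"worker for block {wid} failed: {exc}", block_id=wid
                    ) from exc
        trees = {wid: deserialize_gst(p) for wid, p in paths.items()}

        # blocks tile the matrix exactly, so one (seq, start) ref per cell
        expected_refs = dataset.n * dataset.m

        # vertical/bidirectional: extend truncated blocks, chaining tails
        # right-to-left within each row group
        extended: List[GST] = []
        for group in plan.column_groups():
            tail_by_seq: Dict[int, str] = {}
            for blk in reversed(group):
                wid, (r1, r2), (c1, c2) = blk
                tree = trees[wid]
                if c2 < dataset.m:
                    tails = {
                        sid: PathGraph(
                            label=str(wid),
                            seq_id=sid,
                            symbols=tail_by_seq[sid],
                            start_col=c2 + 1,
                        )
                        for sid in dataset.ids if r1 <= sid <= r2
                    }
                    tree = extend_with_path_graphs(tree, tails, c2)
                for sid in dataset.ids:
                    if r1 <= sid <= r2:
                        seq = dataset.record(sid)
                        tail_by_seq[sid] = seq[c1 - 1 : c2] + tail_by_seq.get(sid, "") \
                            if c2 < dataset.m else seq[c1 - 1 : c2]
                extended.append(tree)

        merged = _merge_many_branch_parallel(extended, branch_depth, pool)
        got_refs = merged.leaf_ref_count()
        if got_refs != sum(t.leaf_ref_count() for t in extended) or \
                got_refs != expected_refs:
            raise ParallelBuildError(
                f"leaf-reference conservation violated: {got_refs} refs after "
                f"merge, expected {expected_refs}"
            )
        return merged
    finally:
        if pool is not None:
            pool.shutdown()
        if own_spool:
            for f in spool.glob("*"):
                f.unlink()
            spool.rmdir()
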