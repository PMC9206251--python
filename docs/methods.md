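# Methods

## Data model

Records are strings of equal length m over a single alphabet, either
bi-allelic haplotypes {0,1} or nucleotides {A,C,G,T}; mixed alphabets are
rejected rather than coerced. Records are addressed by 1-based row index
and positions by 1-based column index at every public interface (matching
the usual "first row / position 3" reading of worked examples); internal
code is 0-based with conversion at the boundary.

## Suffix trees

The *uncompressed trie* — one symbol per edge — is the canonical logical
representation, because downstream hashing assigns one digest per
single-symbol node. Two builders exist: a transparently-correct naive trie
inserter (the oracle), and a generalized Ukkonen construction (compressed
edges, per-sequence sentinels, active-point reset between sequences) that
expands node-for-node to the same trie; their equivalence is
property-tested on random datasets. Suffix terminators are typed
`(sequence id, start)` objects rather than in-band characters, so they can
never collide with alphabet symbols.

A sequence of length m contributes exactly m non-empty suffixes. The
occasionally-quoted "m+1" count includes the empty suffix (the bare
terminator); enumeration here reports the m non-empty ones and treats the
terminator as metadata.

Column-restricted builds (needed by the vertical schemes) index the
suffixes of the restricted substring but record start positions in
full-sequence coordinates, which is what makes later stitching coherent.

Serialization is versioned JSON over the canonical trie view (children
sorted by symbol, preorder ids); round-trips preserve the canonical form
exactly. Compressed trees serialize through their trie expansion.

## Partitioning and parallel construction

`plan_partition` tiles the matrix into contiguous blocks whose sizes
differ by at most one row/column: row groups (horizontal), column groups
(vertical), or a pr × pc grid (bidirectional, which requires p ≥ 4 with
both factors ≥ 2). The merge schedule is an adjacent-pair binary
reduction; "proximity" between workers is modelled as id distance, since
real network latency is out of scope on one machine.

Workers build block trees concurrently and share nothing: every tree
crosses the worker boundary as a serialized file in a spool directory.
The default executor is thread-based; a process-pool executor provides
real OS-process isolation at higher startup cost, and both honour the same
file-exchange contract. (Thread default rather than process: a 1-CPU
machine pays pool startup per build, which matters when equivalence suites
run hundreds of builds.)

A block ending before column m holds truncated suffixes; each is extended
by its sequence's *path graph* — the linear chain of remaining columns —
with shared prefixes merging into existing branches. With more than two
column blocks the extension chains right-to-left: block j's tail is block
j+1's columns followed by block j+1's tail. The final merge partitions
every tree by the first `branch_depth` symbols of the root path (default
1); distinct prefixes share no edges and merge independently (possibly in
parallel), while merging within a prefix is sequential. Leaf-reference
conservation (n·m suffix references, before and after) is asserted on
every parallel build.

## Reverse-Merkle hashing

Digests flow top-down: the root digest *is* the k-bit SALT, and each child
digest is `H(parent_digest ‖ H(symbol))`. Consequently a node digest
depends only on (SALT, root path), the digest of a suffix or query string
is a single left fold over its symbols, and a prefix's digest seeds the
fold of the remainder — the property the iterative queries rely on.

Byte-level encodings are pinned for bit-exact reproducibility (the
schematic `h(AB)` notation never fixes them): symbols hash as their
one-byte ASCII form; concatenation is byte concatenation of the two k-bit
digests; the terminator of suffix (i, j) hashes as the byte string
`$i:j`, which folds the positional payload into each leaf digest. The
SALT length equals the digest length k/8. MD5 (k = 128) is the default
hash; SHA-256 (k = 256) is selectable and every structural invariant is
k-agnostic. Neither choice is a collision-resistance claim — the hash is a
compression/blinding device here, and MD5 is retained as the conventional
128-bit example.

## Encryption and the Hash Index

Every non-root digest is encrypted with AES-128-CBC under a fixed key/IV.
Determinism is a *requirement* (the researcher must reproduce server-side
ciphertexts), and with single-block plaintexts a fixed IV makes CBC
behave like ECB: equal digests yield equal ciphertexts. This
equality-pattern leak is accepted by the design and is the price of
searchability; the mitigations (per-depth keys, asymmetric or homomorphic
schemes) are out of scope. Digests are whole AES blocks, so ciphertexts
never expand. No AES provider is available in the target environment, so
the package carries a minimal table-driven AES-128 of its own, pinned to
the FIPS-197 known-answer vectors in the test suite.

The root is *not* encrypted or shipped: its digest is the SALT itself,
which must never reach the server in any form. The encrypted tree
preserves topology (plus one explicit leaf node per suffix terminator) but
contains no symbols; suffix references travel as AES-encrypted opaque
tokens, so a breached server leaks positions at worst, never content.

The server indexes every node ciphertext in a binary tree of fixed
logical depth k over the ciphertext bits (big-endian bit order).
Physically the index is a sorted table of bit strings with prefix queries
— a compressed radix realization chosen to avoid 128-level pointer chains —
but the per-level child structure of the logical tree is exposed for the
oblivious protocol. A lookup walks k bits (O(k); the sometimes-quoted
O(log k) bound is not achievable by a bit-walk and is documented as such);
a miss reports the depth of the first failing bit and never touches the
encrypted tree. Identical path strings (possible across repeated suffixes)
share a digest; their references merge into one entry. Serialized index
keys are base64 ciphertext bytes, not bit strings, so server artifacts
contain no 0/1 character runs that could be mistaken for (or collide with)
plaintext haplotype content.

## Queries

Query tokens are encrypted path digests of the query symbols only — the
same fold the owner applied to tree paths, so a researcher needs exactly
(q, SALT, key, IV). EM and ESM use one token; EM additionally requires the
matched node depth to equal m and the reference start to be 1. SMM/TSMM
enumerate the distinct substrings of q by decreasing length down to the
floor, and each record is settled at the first (longest) length at which
any of its suffixes match; all tied spans are reported, ordered by start.

Two semantic decisions, both resolved in favour of the worked examples:
set-maximal matching is *per record* (each surviving record reports its
own maximal matches, not only the global maximum), and "reducing the query"
enumerates all substrings, not prefixes only (the printed match positions
require non-prefix substrings). The SMM floor ⌈(|q|+1)/2⌉ is the smallest
rule consistent with the example outputs; it is exposed as `--min-match`.
Match spans (j₁, j₂) are record coordinates recovered from the suffix-start
references, since set-maximal matches between a short query and a record
are not position-aligned.

`plaintext_oracle` implements the same semantics by direct string scanning
of the records and is the ground truth in all equivalence suites.

## Oblivious protocol

Per index level the server picks a candidate child (uniformly when both
exist, seedable for reproducible transcripts) and the parties evaluate one
XNOR gate on their private bits; only the server learns the equality bit.
On disagreement the sibling — if present — is necessarily the researcher's
bit (binary wires), so each level costs exactly one round; a walk ends at
the first dead end or, on a hit, after exactly k rounds. The `garbled`
backend garbles the single gate properly (random 16-byte wire labels,
shuffled 4-row table under SHA-256 of the label pair, 15-byte redundancy
check, trivial OT abstraction); the default `simulated` backend computes
the gate in a trusted in-process broker and emits random fixed-size wire
blobs. Both are *functionally* faithful; neither claims security against
malicious parties, and the OT is deliberately minimal. The non-iterative
whole-query variant is exposed as an experimental flag only.

## Synthetic data

The generator emulates the random benchmark matrices used to exercise the
pipeline: uniform i.i.d. symbols (the distribution is not otherwise
specified; uniform is the natural null for bi-allelic markers), optional
planted substrings at stated (record, position) for queries that must hit,
fully deterministic per seed. It does not emulate linkage disequilibrium,
allele-frequency spectra, or relatedness between rows — so a green
equivalence suite establishes algorithmic correctness on arbitrary
strings, not statistical realism of haplotypes.

## Scale of the shipped suites

Equivalence suites run at desk scale: parallel ≡ serial on 30 random
datasets with n, m ≤ 32 across all schemes and p ∈ {1, 2, 4, 8}; secure ≡
plaintext on 500 random (dataset, query, kind) triples over 16×16
matrices, 50 of them additionally through the oblivious path. Wall-clock
speedup measurements on clusters are deployment-bound and out of scope.

## Known limitations

* Deterministic encryption leaks ciphertext equality patterns (by design).
* The index stores, per node, the suffix references of its whole subtree;
  memory is O(total suffix depth), fine at desk scale, wasteful at genome
  scale.
* Pure-Python AES runs ~35 µs/block — adequate here, not a performance
  claim.
* The three-entity separation is a directory convention on one machine,
  not an OS-level privilege boundary.
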