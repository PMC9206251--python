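# privgst

Parallel generalized suffix tree (GST) construction and privacy-preserving
string queries on haplotype matrices.

## The problem

A data owner holds an n × m matrix **D** of genomic records — bi-allelic
haplotypes (`0`/`1`, one SNP per column) or nucleotide strings — and wants
researchers to run string searches against it through an untrusted cloud
server, without the server ever learning a single symbol of the data or of
the queries. Four queries are supported for a query string *q*
(1 ≤ |q| ≤ m):

* **EM** (exact match): records xᵢ with q = xᵢ over the full length m;
* **ESM** (exact substring match): records containing q contiguously, with
  every occurrence span (j₁, j₂) reported;
* **SMM** (set-maximal match): per record, the longest substring(s) of q
  occurring in it, down to a minimum-length floor ⌈(|q|+1)/2⌉;
* **TSMM** (thresholded SMM): the floor is an explicit threshold t.

## How it works

1. **Parallel GST.** The matrix is tiled into contiguous blocks
   (horizontal rows, vertical columns, or both); one worker per block
   builds a suffix tree (naive trie oracle, or Ukkonen's linear
   construction) and workers exchange serialized trees through a spool
   directory. Column-truncated blocks are completed by appending each
   sequence's tail *path graph* before a duplicate-free merge; the merge
   fans out over the root's first-symbol branches. For every scheme and
   worker count the result is canonically equal to the serial build.
2. **Reverse-Merkle hashing.** Digests flow *top-down*: the root holds a
   secret SALT and each child digest is `H(parent ‖ H(symbol))`
   (MD5 by default, k = 128 bits; SHA-256 selectable). A node's digest
   therefore encodes its whole root path, so the digest of any suffix or
   query substring is one fold of its symbols — and without the SALT the
   small alphabet cannot be dictionary-attacked.
3. **Deterministic encryption + Hash Index.** Every digest is encrypted
   with AES-128-CBC under a fixed key/IV shared only with the researcher
   (determinism is what makes the ciphertexts searchable). The server
   builds a binary index of logical depth k over the ciphertext *bits*;
   a query token either walks all k bits to a leaf (hit, returning opaque
   encrypted suffix references) or dies at the first absent bit (miss,
   no tree traversal needed).
4. **Oblivious matching (optional).** A two-party protocol hides the
   researcher's token bits from the server: one XNOR gate per index level,
   garbled with random wire labels, output visible to the server only.
   Functionally identical to the plain lookup, at most k rounds.

## Worked example

The package ships a 5×6 demonstration matrix
(rows `100010 111010 110001 010110 010101`):

```
$ privgst selftest
EM   q=100010 -> records [1] [ok]
ESM  q=111    -> records [2] [ok]
SMM  q=1101   -> records [2, 3, 4, 5] [ok]
TSMM q=1011   -> records [2, 4, 5] [ok]
selftest passed
```

Read: query `100010` equals row 1 exactly; `111` occurs only inside row 2;
for `1101` the set-maximal matches are `1101`, `110`, `101`, `101` in rows
2–5 (row 1 shares nothing of length ≥ 3); with threshold 3, `1011` matches
rows 2, 4, 5 — row 2 via `101` starting at position 3, row 4 via the whole
query starting at position 2.

The same flow as separate role commands:

```
privgst generate --n 50 --m 40 --seed 1 --out owner/data.txt
privgst build --data owner/data.txt --scheme bidirectional --workers 4 --out owner/tree.json
privgst outsource --tree owner/tree.json --server-dir server/ --keyfile researcher/key.json
privgst query --server-dir server/ --keyfile researcher/key.json \
              --kind tsmm --query 1011 --threshold 3 --m 40 --oblivious
```

Each query result line is JSON: `{"record": r, "j1": a, "j2": b, "length": L}`;
exit status is 0 on a hit, 1 on a miss. The server directory never contains
the salt, the key, or any plaintext symbol.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline (parallel build → hash → encrypt → index → the
four secure queries) on the demonstration matrix and writes the measured
query outcomes — returned record indices, result-set sizes and match start
positions — as JSON. The seed only varies the generated key material; the
query results are key-independent by construction.
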