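"""Dataset model, file I/O and synthetic-data generation.

The unit of data throughout the package is a rectangular matrix of ``n``
sequences times ``m`` symbols over a small alphabet: bi-allelic haplotypes
({0,1}, one SNP per column) or nucleotides ({A,C,G,T}).  Records are
addressed by 1-based row index, positions within a record by 1-based column
index; all public interfaces use these coordinates, internal code uses
0-based offsets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BINARY",
    "DNA",
    "DatasetError",
    "RaggedRowError",
    "AlphabetError",
    "HaplotypeDataset",
    "QueryString",
    "load_dataset",
    "write_dataset",
    "generate_synthetic",
]

BINARY = frozenset("01")
DNA = frozenset("ACGT")

_SUPPORTED_ALPHABETS = (BINARY, DNA)


class DatasetError(ValueError):
    """Invalid dataset contents or shape."""


class RaggedRowError(DatasetError):
    """A row's length differs from the first row's length."""


class AlphabetError(DatasetError):
    """A symbol outside the supported alphabets, or a mixed alphabet."""


def _infer_alphabet(symbols: Iterable[str]) -> frozenset:
    seen = set(symbols)
    for alpha in _SUPPORTED_ALPHABETS:
        if seen <= alpha:
            return alpha
    raise AlphabetError(
        f"symbols {sorted(seen)} fit neither the binary {{0,1}} nor the "
        f"nucleotide {{A,C,G,T}} alphabet"
    )


@dataclass(frozen=True)
class HaplotypeDataset:
    """An n x m record matrix with 1-based row identifiers.

    Invariants (enforced on construction): at least one record, all records
    of equal length ``m``, every symbol drawn from one supported alphabet,
    ids unique.
    """

    records: tuple
    ids: tuple = ()
    alphabet: frozenset = field(default=frozenset())

    def __post_init__(self):
        records = tuple(self.records)
        if not records:
            raise DatasetError("a dataset must contain at least one record")
        m = len(records[0])
        if m == 0:
            raise DatasetError("records must be non-empty")
        for i, rec in enumerate(records, start=1):
            if len(rec) != m:
                raise RaggedRowError(
                    f"row {i} has length {len(rec)}, expected {m}"
                )
        alphabet = self.alphabet or _infer_alphabet("".join(records))
        extra = set("".join(records)) - alphabet
        if extra:
            raise AlphabetError(f"symbols {sorted(extra)} outside alphabet")
        ids = tuple(self.ids) if self.ids else tuple(range(1, len(records) + 1))
        if len(set(ids)) != len(ids) or len(ids) != len(records):
            raise DatasetError("record ids must be unique, one per record")
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "alphabet", frozenset(alphabet))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def m(self) -> int:
        return len(self.records[0])

    def record(self, seq_id: int) -> str:
        """Record by 1-based identifier."""
        return self.records[self.ids.index(seq_id)]

    def __iter__(self):
        return iter(zip(self.ids, self.records))


@dataclass(frozen=True)
class QueryString:
    """A query q over the dataset alphabet, 1 <= |q| <= m."""

    symbols: str

    def __post_init__(self):
        if not self.symbols:
            raise DatasetError("query must be non-empty")
        _infer_alphabet(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def validate_against(self, dataset: HaplotypeDataset) -> None:
        if len(self.symbols) > dataset.m:
            raise DatasetError(
                f"query length {len(self.symbols)} exceeds sequence length "
                f"{dataset.m}"
            )
        extra = set(self.symbols) - dataset.alphabet
        if extra:
            raise AlphabetError(
                f"query symbols {sorted(extra)} outside dataset alphabet"
            )


# ---------------------------------------------------------------------------
# File formats: plain-text matrix (one record per line) and FASTA.
# ---------------------------------------------------------------------------

def _parse_matrix(text: str) -> list:
    rows = []
    delim = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None and len(line) > 1 and not line[1].isalnum():
            delim = line[1]
        rows.append(line.replace(delim, "") if delim else line)
    return rows


def _guess_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return "fasta"
    return "matrix"


def load_dataset(path, format: Optional[str] = None) -> HaplotypeDataset:
    """Read a dataset from a matrix or FASTA file.

    Matrix format: one record per line, optional single-character delimiter
    between symbols, ``#`` comment lines skipped.  Row order is preserved
    and ids are assigned 1..n.
    """
    path = Path(path)
    fmt = _guess_format(path, format)
    if fmt == "matrix":
        rows = _parse_matrix(path.read_text())
    elif fmt == "fasta":
        from Bio import SeqIO

        rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not rows:
        raise DatasetError(f"no records found in {path}")
    return HaplotypeDataset(records=tuple(rows))


def write_dataset(dataset: HaplotypeDataset, path, format: Optional[str] = None):
    """Write a dataset; ``load_dataset(write_dataset(d))`` round-trips."""
    path = Path(path)
    fmt = _guess_format(path, format)
    if fmt == "matrix":
        path.write_text("\n".join(dataset.records) + "\n")
    elif fmt == "fasta":
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(rec), id=str(sid), description="")
            for sid, rec in dataset
        ]
        with open(path, "w") as fh:
            seqio_write(recs, fh, "fasta")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

def generate_synthetic(
    n: int,
    m: int,
    alphabet: Iterable[str] = BINARY,
    seed: int = 0,
    planted: Optional[Sequence] = None,
) -> HaplotypeDataset:
    """Generate an n x m matrix of uniform i.i.d. symbols.

    ``planted`` is an optional list of ``(substring, record_index, position)``
    triples (1-based) written verbatim over the random background, emulating
    queries known to occur in the data.  Deterministic for a given seed.
    """
    if n < 1 or m < 1:
        raise DatasetError("n and m must be >= 1")
    alpha = sorted(frozenset(alphabet))
    if not (frozenset(alpha) in _SUPPORTED_ALPHABETS):
        raise AlphabetError(f"unsupported alphabet {alpha}")
    rng = np.random.default_rng(seed)
    grid = rng.integers(0, len(alpha), size=(n, m))
    rows = [[alpha[v] for v in grid[i]] for i in range(n)]
    for sub, rec_idx, pos in planted or ():
        if not (1 <= rec_idx <= n):
            raise DatasetError(f"planted record index {rec_idx} outside 1..{n}")
        if pos < 1 or pos + len(sub) - 1 > m:
            raise DatasetError(
                f"planted span [{pos}, {pos + len(sub) - 1}] exceeds m={m}"
            )
        if set(sub) - set(alpha):
            raise AlphabetError(f"planted substring {sub!r} outside alphabet")
        rows[rec_idx - 1][pos - 1 : pos - 1 + len(sub)] = list(sub)
    return HaplotypeDataset(records=tuple("".join(r) for r in rows))
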