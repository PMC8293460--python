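"""Readers, writers and core data containers.

All tables are feature-major (rows = features, columns = samples). Delimited
inputs may be comma- or tab-separated; the delimiter is sniffed and a header
row of sample names is mandatory. Sequences are held 5'→3' over the RNA
alphabet {A, C, G, U}; DNA-alphabet FASTA is accepted and T is mapped to U
during ingestion (``dna_to_rna``, the default) unless strict RNA mode is
requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A file could not be parsed in the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


RNA_ALPHABET = frozenset("ACGU")
_ACCEPTED_RESIDUES = frozenset("ACGUTacgut")


@dataclass(frozen=True)
class MatureSequenceSet:
    """An ordered set of named mature RNA sequences (5'→3').

    Invariants: ids are unique and non-empty, sequences are non-empty and
    strictly over {A, C, G, U}.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dup}")
        for sid, seq in self.entries:
            if not sid:
                raise ValidationError("empty sequence id")
            if not seq:
                raise ValidationError(f"empty sequence for id {sid!r}")
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"record {sid!r}: residues outside RNA alphabet: {sorted(bad)}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MatureSequenceSet":
        return cls(tuple((str(i), str(s)) for i, s in pairs))

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)


def _normalize_sequence(sid: str, raw: str, alphabet_policy: str) -> str:
    bad = set(raw) - _ACCEPTED_RESIDUES
    if bad:
        raise ValidationError(
            f"record {sid!r}: unexpected residues {sorted(bad)} "
            "(accepted: A, C, G, U, T in either case)"
        )
    seq = raw.upper()
    if alphabet_policy == "dna_to_rna":
        seq = seq.replace("T", "U")
    elif alphabet_policy == "rna_strict":
        if "T" in seq:
            raise ValidationError(f"record {sid!r}: T found under rna_strict policy")
    else:
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    return seq


def read_fasta(path: str | Path, alphabet_policy: str = "dna_to_rna") -> MatureSequenceSet:
    """Read a FASTA file of mature miRNA sequences.

    Ids are the full header token up to the first whitespace. An empty file
    yields an empty set with a warning rather than an error.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty FASTA, returning empty sequence set", stacklevel=2)
        return MatureSequenceSet(())
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}")
            break
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append((rec.id, _normalize_sequence(rec.id, str(rec.seq), alphabet_policy)))
    return MatureSequenceSet(tuple(entries))


def write_fasta(seqs: MatureSequenceSet, path: str | Path) -> None:
    """Write sequences as FASTA; round-trips byte-identically with read_fasta."""
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


@dataclass
class CountTable:
    """A non-negative feature × sample matrix with per-sample labels.

    ``values`` is a DataFrame indexed by feature id with sample columns;
    ``meta`` is a DataFrame indexed by sample name carrying labels such as
    group, dose or condition.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = sorted(v.index[v.index.duplicated()].unique())
            raise ValidationError(f"duplicate feature ids: {dup}")
        if v.columns.has_duplicates:
            dup = sorted(v.columns[v.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample names: {dup}")
        arr = v.to_numpy(dtype=float)
        if pd.isna(arr).any():
            raise ValidationError("count table contains missing values")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("count table values must be finite and >= 0")
        if not self.meta.empty:
            missing = [s for s in v.columns if s not in self.meta.index]
            if missing:
                raise ValidationError(f"samples missing from labels: {missing}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    def label(self, key: str) -> pd.Series:
        """Per-sample label series for ``key``, ordered as the sample columns."""
        if key not in self.meta.columns:
            raise ValidationError(f"label {key!r} not present (have: {list(self.meta.columns)})")
        return self.meta.loc[list(self.values.columns), key]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: could not parse delimited table: {exc}") from exc


def read_count_table(path: str | Path, label_path: str | Path | None = None) -> CountTable:
    """Read a feature × sample count matrix and attach per-sample labels.

    The matrix header row gives sample names; the first column gives feature
    ids. The label file maps each sample (first column) to label columns.
    Sample order of the header is preserved exactly.
    """
    values = _read_delimited(path)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.DataFrame()
    if label_path is not None:
        meta = _read_delimited(label_path)
        meta.index = meta.index.astype(str)
    return CountTable(values=values, meta=meta)


def write_count_table(table: CountTable, path: str | Path, label_path: str | Path | None = None) -> None:
    table.values.to_csv(path, sep="\t")
    if label_path is not None:
        table.meta.to_csv(label_path, sep="\t")


@dataclass(frozen=True)
class GeneSet:
    """A named, order-preserving set of unique gene symbols (uppercased)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        seen: dict[str, None] = {}
        for s in symbols:
            s = str(s).strip().upper()
            if s:
                seen.setdefault(s)
        return cls(name, tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in set(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line, deduplicated, order preserved."""
    path = Path(path)
    symbols = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not symbols:
        raise ValidationError(f"{path}: gene set file is empty")
    return GeneSet.from_symbols(name or path.stem, symbols)


@dataclass(frozen=True)
class EdgeList:
    """Undirected edge list with self-loops dropped and duplicates collapsed.

    Edges are stored with endpoints sorted so (A, B) and (B, A) collapse.
    """

    edges: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], warn_self_loops: bool = True) -> "EdgeList":
        seen: dict[tuple[str, str], None] = {}
        n_loops = 0
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                n_loops += 1
                continue
            seen.setdefault((a, b) if a <= b else (b, a))
        if n_loops and warn_self_loops:
            warnings.warn(f"dropped {n_loops} self-loop edge(s)", stacklevel=2)
        return cls(tuple(seen))

    @property
    def nodes(self) -> list[str]:
        out: dict[str, None] = {}
        for a, b in self.edges:
            out.setdefault(a)
            out.setdefault(b)
        return list(out)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)


def read_edge_list(path: str | Path, min_score: float | None = None) -> EdgeList:
    """Read a two-column TSV edge list (STRING-export compatible).

    A third numeric column, when present, is treated as an interaction score
    and filtered with ``min_score``; otherwise it is ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: edge list needs at least two columns")
    # Tolerate a header row of column names (STRING-style exports).
    header_names = {"protein1", "protein2", "node1", "node2", "node_a", "node_b", "source", "target", "gene1", "gene2"}
    first = {str(x).strip().lower() for x in df.iloc[0, :2]}
    if first <= header_names:
        df = df.iloc[1:]
    if df.shape[1] >= 3:
        scores = pd.to_numeric(df.iloc[:, 2], errors="coerce")
        if scores.isna().iloc[0] and scores.notna().iloc[1:].all():
            df = df.iloc[1:]
            scores = scores.iloc[1:]
        if min_score is not None:
            df = df[scores >= min_score]
    return EdgeList.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))
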