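"""Sliding-window k-mer extraction and TLR7/8 motif counting.

Endosomal TLR7 and TLR8 are activated by G/U-rich single-stranded RNA; the
three 4-mers with the strongest reported propensity to activate them are
UUGU, GUUU and UGUU. Counting is window-based: every window position of a
sequence is tested independently, so overlapping occurrences all count
(e.g. ``UUGUUU`` contributes one occurrence of each of the three default
motifs). Each window matches at most one motif because the motifs are
distinct k-mers of equal length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RNA_ALPHABET, MatureSequenceSet, ValidationError

#: The top three G/U-rich TLR7/8-activating 4-mers, in reporting order.
DEFAULT_MOTIFS: tuple[str, ...] = ("UUGU", "GUUU", "UGUU")


@dataclass(frozen=True)
class MotifSet:
    """An ordered set of unique, equal-length RNA motifs."""

    motifs: tuple[str, ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValidationError("motif set is empty")
        norm = tuple(m.upper().replace("T", "U") for m in self.motifs)
        object.__setattr__(self, "motifs", norm)
        if len(set(norm)) != len(norm):
            raise ValidationError("motifs must be unique")
        if len({len(m) for m in norm}) != 1:
            raise ValidationError("motifs must share a single length k")
        for m in norm:
            bad = set(m) - RNA_ALPHABET
            if bad:
                raise ValidationError(f"motif {m!r}: non-RNA residues {sorted(bad)}")

    @property
    def k(self) -> int:
        return len(self.motifs[0])

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


def _check_rna(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValidationError(f"non-RNA residues in sequence: {sorted(bad)}")
    return seq


def extract_kmers(sequence: str, k: int) -> list[str]:
    """All k-mer windows of ``sequence`` in 5'→3' order.

    Returns ``len(sequence) - k + 1`` windows, or an empty list when the
    sequence is shorter than k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = _check_rna(sequence)
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def count_motifs(sequence: str, motif_set: MotifSet | Iterable[str] = DEFAULT_MOTIFS) -> dict[str, int]:
    """Per-motif window counts for one sequence, plus their ``total``.

    Every window position is tested independently, so overlapping motif
    occurrences are all counted.
    """
    if not isinstance(motif_set, MotifSet):
        motif_set = MotifSet(tuple(motif_set))
    counts = dict.fromkeys(motif_set.motifs, 0)
    for window in extract_kmers(sequence, motif_set.k):
        if window in counts:
            counts[window] += 1
    counts["total"] = sum(counts[m] for m in motif_set.motifs)
    return counts


@dataclass(frozen=True)
class MotifCountTable:
    """Per-sequence motif occurrence counts with set-level sums.

    ``per_sequence`` has one row per sequence id with one column per motif,
    a ``total_motifs`` column and an ``n_kmers`` column (number of windows,
    ``max(len - k + 1, 0)``).
    """

    per_sequence: pd.DataFrame
    motifs: tuple[str, ...]
    k: int

    @property
    def total_motifs(self) -> int:
        return int(self.per_sequence["total_motifs"].sum())

    @property
    def n_kmers(self) -> int:
        return int(self.per_sequence["n_kmers"].sum())

    @property
    def n_sequences_with_motif(self) -> int:
        return int((self.per_sequence["total_motifs"] > 0).sum())

    @property
    def motif_totals(self) -> pd.Series:
        return self.per_sequence[list(self.motifs)].sum()

    def to_frame(self) -> pd.DataFrame:
        return self.per_sequence.copy()


class MotifScanner(BaseEstimator, TransformerMixin):
    """Scan mature miRNA sequences for a set of equal-length motifs.

    Parameters
    ----------
    motifs : sequence of str
        RNA motifs of a common length k; defaults to the three G/U-rich
        TLR7/8-activating 4-mers UUGU, GUUU, UGUU.

    The transformer is stateless; ``fit`` only validates the motif set.
    """

    def __init__(self, motifs: Iterable[str] = DEFAULT_MOTIFS):
        self.motifs = tuple(motifs)

    def fit(self, X=None, y=None) -> "MotifScanner":
        self.motif_set_ = MotifSet(self.motifs)
        return self

    def transform(self, X: MatureSequenceSet | Iterable[tuple[str, str]]) -> MotifCountTable:
        """Count motif occurrences per sequence.

        X is a MatureSequenceSet (or iterable of (id, sequence) pairs).
        """
        if not hasattr(self, "motif_set_"):
            self.fit()
        ms = self.motif_set_
        entries = list(X)
        if not entries:
            raise ValidationError("cannot scan an empty sequence set")
        rows = []
        index = []
        for sid, seq in entries:
            try:
                counts = count_motifs(seq, ms)
            except ValidationError as exc:
                raise ValidationError(f"sequence {sid!r}: {exc}") from exc
            row = {m: counts[m] for m in ms.motifs}
            row["total_motifs"] = counts["total"]
            row["n_kmers"] = max(len(seq) - ms.k + 1, 0)
            rows.append(row)
            index.append(sid)
        frame = pd.DataFrame(rows, index=pd.Index(index, name="id"))
        return MotifCountTable(per_sequence=frame, motifs=ms.motifs, k=ms.k)


def scan_set(
    seqs: MatureSequenceSet, motif_set: MotifSet | Iterable[str] = DEFAULT_MOTIFS
) -> MotifCountTable:
    """Scan a sequence set; thin wrapper over :class:`MotifScanner`."""
    motifs = motif_set.motifs if isinstance(motif_set, MotifSet) else tuple(motif_set)
    return MotifScanner(motifs=motifs).fit().transform(seqs)
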