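"""Hypergeometric enrichment of motif-bearing windows in a foreground set.

The unit of enrichment is the k-mer window, not the miRNA: the contingency
compares windows-with-motif against windows-without, treating the foreground
windows as draws without replacement from the background window population.
Windows within a sequence overlap and are therefore not strictly
independent; the test treats them as exchangeable, which is the standard
approximation for sliding-window k-mer enrichment. A per-sequence
formulation (sequences-with-motif as the unit) is available via
``unit="sequence"``.

The upper tail includes the observed count's point mass: p = P(X >= observed).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator

from .io import MatureSequenceSet, ValidationError
from .motifs import DEFAULT_MOTIFS, MotifCountTable, MotifScanner


def hypergeometric_upper_tail(population: int, successes: int, draws: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeometric(population, successes, draws).

    Computed via scipy's survival function, which works on log-gamma terms
    and is numerically stable for large populations.
    """
    if not 0 <= successes <= population:
        raise ValueError(f"need 0 <= successes <= population, got {successes}, {population}")
    if not 0 <= draws <= population:
        raise ValueError(f"need 0 <= draws <= population, got {draws}, {population}")
    if not 0 <= observed <= min(successes, draws):
        raise ValueError(
            f"need 0 <= observed <= min(successes, draws), got {observed} vs "
            f"min({successes}, {draws})"
        )
    return float(hypergeom.sf(observed - 1, population, successes, draws))


@dataclass(frozen=True)
class EnrichmentResult:
    """Contingency and p-value for foreground-vs-background motif frequency.

    ``per_motif_freqs`` carries foreground and background per-window (or
    per-sequence) frequency of each motif, i.e. the data behind a motif
    frequency bar comparison.
    """

    fg_hits: int
    fg_windows: int
    bg_hits: int
    bg_windows: int
    p_value: float
    per_motif_freqs: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0 <= self.fg_hits <= self.fg_windows:
            raise ValidationError("need 0 <= fg_hits <= fg_windows")
        if not 0 <= self.bg_hits <= self.bg_windows:
            raise ValidationError("need 0 <= bg_hits <= bg_windows")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value outside [0, 1]")


def enrichment_test(
    fg: MotifCountTable,
    bg: MotifCountTable,
    unit: str = "window",
    subtract_foreground: bool = False,
    foreground_in_background: bool = True,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of motifs in ``fg`` versus ``bg``.

    The background is the population (windows, with motif hits as successes)
    and the foreground the draws. By default foreground windows are *not*
    removed from the background — the comparison is against the entire
    background set; ``subtract_foreground=True`` removes them first.
    """
    if fg.motifs != bg.motifs or fg.k != bg.k:
        raise ValidationError("foreground and background were scanned with different motif sets")
    if unit == "window":
        fg_hits, fg_n = fg.total_motifs, fg.n_kmers
        bg_hits, bg_n = bg.total_motifs, bg.n_kmers
        fg_denom = fg.n_kmers
        bg_denom = bg.n_kmers
        fg_freqs = fg.motif_totals / max(fg_denom, 1)
        bg_freqs = bg.motif_totals / max(bg_denom, 1)
    elif unit == "sequence":
        fg_hits, fg_n = fg.n_sequences_with_motif, len(fg.per_sequence)
        bg_hits, bg_n = bg.n_sequences_with_motif, len(bg.per_sequence)
        fg_freqs = (fg.per_sequence[list(fg.motifs)] > 0).mean()
        bg_freqs = (bg.per_sequence[list(bg.motifs)] > 0).mean()
    else:
        raise ValueError(f"unit must be 'window' or 'sequence', got {unit!r}")

    if foreground_in_background and fg_n > bg_n:
        raise ValidationError(
            "foreground has more windows than background but is flagged as a "
            "subset of it; pass foreground_in_background=False if intentional"
        )
    if subtract_foreground:
        bg_hits, bg_n = bg_hits - fg_hits, bg_n - fg_n
        if bg_hits < 0 or bg_n < 0:
            raise ValidationError("cannot subtract foreground: it is not contained in background")

    p = hypergeometric_upper_tail(bg_n, bg_hits, fg_n, fg_hits)
    freqs = pd.DataFrame({"foreground": fg_freqs, "background": bg_freqs})
    freqs.index.name = "motif"
    return EnrichmentResult(
        fg_hits=int(fg_hits),
        fg_windows=int(fg_n),
        bg_hits=int(bg_hits),
        bg_windows=int(bg_n),
        p_value=p,
        per_motif_freqs=freqs,
    )


class MotifEnrichment(BaseEstimator):
    """Motif-frequency enrichment test between two sequence sets.

    Scans both sets with the same motif set, assembles the window-level
    contingency (background windows as population, background motif hits as
    successes, foreground windows as draws) and reports the upper-tail
    hypergeometric probability of the observed foreground hit count.

    Attributes (after ``fit``)
    --------------------------
    result_ : EnrichmentResult
    p_value_ : float
    """

    def __init__(
        self,
        motifs=DEFAULT_MOTIFS,
        unit: str = "window",
        subtract_foreground: bool = False,
        foreground_in_background: bool = True,
    ):
        self.motifs = tuple(motifs)
        self.unit = unit
        self.subtract_foreground = subtract_foreground
        self.foreground_in_background = foreground_in_background

    def fit(self, foreground: MatureSequenceSet, background: MatureSequenceSet) -> "MotifEnrichment":
        scanner = MotifScanner(motifs=self.motifs).fit()
        self.foreground_counts_ = scanner.transform(foreground)
        self.background_counts_ = scanner.transform(background)
        self.result_ = enrichment_test(
            self.foreground_counts_,
            self.background_counts_,
            unit=self.unit,
            subtract_foreground=self.subtract_foreground,
            foreground_in_background=self.foreground_in_background,
        )
        self.p_value_ = self.result_.p_value
        return self
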