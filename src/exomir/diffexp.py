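"""Exosomal miRNA differential-abundance pipeline.

The procedure mirrors the small RNA-seq workflow for extracellular-vesicle
cargo: counts are normalized per sample by total read count and then by a
designated stable reference miRNA (miR-26a-5p is the established endogenous
control for exosomal miRNA), log2-transformed with a pseudocount, filtered
to drop low-abundance miRNAs (a miRNA is retained only if it exceeds the
per-sample 25th-percentile abundance in *every* sample of at least one
group), and tested per miRNA with a one-sided t-test for an increase in the
epileptogenic group. Candidates require p <= alpha (default 0.05) and a
linear fold change >= fc_min (default 1.5), computed as 2**(difference of
group means on the log2 scale).

A state machine (raw → normalized → log2) guards against double
normalization or filtering raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CountTable, ValidationError

EPILEPTOGENIC = "epileptogenic"
NON_EPILEPTOGENIC = "non_epileptogenic"


def _check_unique_finite(values: pd.DataFrame) -> None:
    if values.index.has_duplicates or values.columns.has_duplicates:
        raise ValidationError("duplicate feature or sample names")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValidationError("matrix values must be finite")


@dataclass
class MiRNACountMatrix:
    """miRNA × sample matrix with group labels and a reference miRNA.

    ``state`` tracks the normalization stage: ``raw`` → ``normalized``
    (total-count then reference-miRNA scaling) → ``log2``.
    """

    values: pd.DataFrame
    groups: pd.Series
    reference_mirna: str = "hsa-miR-26a-5p"
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state == "raw":
            CountTable(self.values)  # uniqueness, non-negativity, finiteness
        else:  # log2 values may be negative
            _check_unique_finite(self.values)
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if self.state == "raw":
            if self.reference_mirna not in self.values.index:
                raise ValidationError(f"reference miRNA {self.reference_mirna!r} absent from matrix")
            ref = self.values.loc[self.reference_mirna]
            if (ref <= 0).any():
                bad = list(ref.index[ref <= 0])
                raise ValidationError(
                    f"reference miRNA {self.reference_mirna!r} non-positive in samples {bad}"
                )

    def group_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, g in self.groups.items():
            out.setdefault(str(g), []).append(sample)
        return out


def normalize(m: MiRNACountMatrix) -> MiRNACountMatrix:
    """Two-step normalization: per-sample total count, then reference miRNA.

    Step 1 divides each sample's counts by that sample's total count; step 2
    divides each sample's values by its (total-normalized) reference-miRNA
    value. The reference row is exactly 1.0 in every sample afterwards, and
    the result is invariant to any per-sample library-size rescaling.
    """
    if m.state != "raw":
        raise ValidationError(f"normalize expects a raw matrix, got state {m.state!r}")
    totals = m.values.sum(axis=0)
    zero = list(totals.index[totals <= 0])
    if zero:
        raise ValidationError(f"zero total count in samples {zero}")
    per_total = m.values.div(totals, axis=1)
    ref = per_total.loc[m.reference_mirna]
    zero_ref = list(ref.index[ref <= 0])
    if zero_ref:
        raise ValidationError(f"reference miRNA zero after total normalization in samples {zero_ref}")
    values = per_total.div(ref, axis=1)
    return MiRNACountMatrix(values=values, groups=m.groups, reference_mirna=m.reference_mirna, state="normalized")


def log_and_filter(
    m: MiRNACountMatrix,
    pseudocount: float | str = "auto",
    percentile: float = 25.0,
    threshold_scale: str = "log",
) -> tuple[MiRNACountMatrix, list[str]]:
    """log2-transform and flag low-abundance miRNAs.

    The pseudocount admits zeros; the default ``"auto"`` uses half the
    smallest positive value of the normalized matrix, so it is negligible
    against expressed features on the reference-ratio scale (a large fixed
    pseudocount on that scale would shrink every fold change toward 1).

    Each sample's threshold is the given percentile of that sample's values
    across all miRNAs. A miRNA is retained iff there is at least one group
    in which it strictly exceeds the threshold in every sample of that
    group. Thresholds are computed on the log2 scale by default
    (``threshold_scale="raw"`` uses the pre-log values; retention is
    identical when the transform is monotone, which log2(x + c) is).
    """
    if m.state != "normalized":
        raise ValidationError(f"log_and_filter expects a normalized matrix, got state {m.state!r}")
    for g, samples in m.group_samples().items():
        if len(samples) < 1:
            raise ValidationError(f"group {g!r} has no samples")
    if pseudocount == "auto":
        arr = m.values.to_numpy(dtype=float)
        positive = arr[arr > 0]
        if positive.size == 0:
            raise ValidationError("matrix has no positive values")
        pseudocount = float(positive.min()) / 2.0
    logged = np.log2(m.values + pseudocount)
    basis = logged if threshold_scale == "log" else m.values
    if threshold_scale not in ("log", "raw"):
        raise ValueError(f"threshold_scale must be 'log' or 'raw', got {threshold_scale!r}")
    thresholds = basis.quantile(percentile / 100.0, axis=0)
    above = basis.gt(thresholds, axis=1)
    retained_mask = pd.Series(False, index=m.values.index)
    for samples in m.group_samples().values():
        retained_mask |= above[samples].all(axis=1)
    out = MiRNACountMatrix(values=logged, groups=m.groups, reference_mirna=m.reference_mirna, state="log2")
    return out, list(m.values.index[retained_mask])


def _one_sided_welch(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise one-sided p for mean(a) > mean(b); handles zero-variance rows."""
    import warnings

    with warnings.catch_warnings():
        # near-constant rows (e.g. the reference miRNA) trigger a scipy
        # precision warning; such rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, alternative="greater")
    p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (diff > 0)] = 0.0
    p[degenerate & (diff < 0)] = 1.0
    p[degenerate & (diff == 0)] = 1.0
    return p


def differential_test(
    m: MiRNACountMatrix,
    retained: Iterable[str] | None = None,
    test_group: str = EPILEPTOGENIC,
    control_group: str = NON_EPILEPTOGENIC,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-miRNA one-sided test for increased abundance in ``test_group``.

    Expects a log2 matrix. Returns a DataFrame with columns ``mean_test``,
    ``mean_control`` (log2 group means), ``fold_change`` (linear,
    ``2**(mean_test - mean_control)``), ``p_value`` (one-sided, test >
    control), ``degenerate``, ``passed_filter`` and ``selected``
    (= passed_filter & p <= alpha & fold_change >= fc_min), sorted by fold
    change descending.
    """
    if m.state != "log2":
        raise ValidationError(f"differential_test expects a log2 matrix, got state {m.state!r}")
    by_group = m.group_samples()
    for g in (test_group, control_group):
        if g not in by_group:
            raise ValidationError(f"group {g!r} not present (have {sorted(by_group)})")
        if len(by_group[g]) < 2:
            raise ValidationError(f"group {g!r} needs >= 2 samples for testing")
    a = m.values[by_group[test_group]].to_numpy(dtype=float)
    b = m.values[by_group[control_group]].to_numpy(dtype=float)
    p = _one_sided_welch(a, b, equal_var=equal_var)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    fc = 2.0 ** (mean_a - mean_b)
    passed = (
        m.values.index.isin(set(retained))
        if retained is not None
        else np.ones(len(m.values), dtype=bool)
    )
    out = pd.DataFrame(
        {
            "mean_test": mean_a,
            "mean_control": mean_b,
            "fold_change": fc,
            "p_value": p,
            "degenerate": degenerate,
            "passed_filter": passed,
        },
        index=m.values.index.rename("mirna"),
    )
    out["selected"] = out["passed_filter"] & (out["p_value"] <= alpha) & (out["fold_change"] >= fc_min)
    return out.sort_values("fold_change", ascending=False)


class DifferentialAbundance(BaseEstimator):
    """Full differential-abundance pipeline for exosomal miRNA counts.

    normalize (total count, then reference miRNA) → log2(+pseudocount) →
    25th-percentile abundance filter → one-sided t-test with fold-change and
    significance selection.

    Parameters
    ----------
    reference_mirna : stable endogenous control used for the second
        normalization step (default the miR-26a-5p id).
    alpha, fc_min : selection thresholds (p <= alpha, linear FC >= fc_min).
    pseudocount : added before log2 to admit zeros; "auto" (default) uses
        half the smallest positive normalized value.
    percentile : per-sample abundance percentile for the retention filter.
    threshold_scale : 'log' or 'raw' basis for the percentile thresholds.
    equal_var : pooled-variance t-test instead of Welch.

    Attributes (after ``fit``)
    --------------------------
    results_ : per-miRNA DataFrame sorted by fold change descending.
    retained_ids_ : miRNAs passing the abundance filter.
    selected_ : DataFrame of selected candidates.
    """

    def __init__(
        self,
        reference_mirna: str = "hsa-miR-26a-5p",
        test_group: str = EPILEPTOGENIC,
        control_group: str = NON_EPILEPTOGENIC,
        alpha: float = 0.05,
        fc_min: float = 1.5,
        pseudocount: float | str = "auto",
        percentile: float = 25.0,
        threshold_scale: str = "log",
        equal_var: bool = False,
    ):
        self.reference_mirna = reference_mirna
        self.test_group = test_group
        self.control_group = control_group
        self.alpha = alpha
        self.fc_min = fc_min
        self.pseudocount = pseudocount
        self.percentile = percentile
        self.threshold_scale = threshold_scale
        self.equal_var = equal_var

    def fit(self, X: MiRNACountMatrix | pd.DataFrame, y: pd.Series | Sequence[str] | None = None):
        """Run the pipeline on raw counts.

        X may be a MiRNACountMatrix, or a miRNA × sample DataFrame with the
        per-sample group labels passed as ``y``.
        """
        if isinstance(X, MiRNACountMatrix):
            m = X
        else:
            if y is None:
                raise ValidationError("group labels required when X is a plain matrix")
            groups = pd.Series(y, index=list(X.columns)) if not isinstance(y, pd.Series) else y
            m = MiRNACountMatrix(values=pd.DataFrame(X), groups=groups, reference_mirna=self.reference_mirna)
        normalized = normalize(m)
        logged, retained = log_and_filter(
            normalized,
            pseudocount=self.pseudocount,
            percentile=self.percentile,
            threshold_scale=self.threshold_scale,
        )
        self.normalized_ = normalized
        self.log_matrix_ = logged
        self.retained_ids_ = retained
        self.results_ = differential_test(
            logged,
            retained=retained,
            test_group=self.test_group,
            control_group=self.control_group,
            alpha=self.alpha,
            fc_min=self.fc_min,
            equal_var=self.equal_var,
        )
        self.selected_ = self.results_[self.results_["selected"]]
        return self
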