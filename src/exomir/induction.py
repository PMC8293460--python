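"""Expression-panel analysis of exosome-treated cells and tissue.

Covers four stages of the induction analysis:

* panel normalization — per-sample scaling so the geometric mean of
  housekeeping genes (or of all genes when none are given) is equal across
  samples, followed by log2 with a pseudocount. This is a transparent
  stand-in for proprietary panel-normalization software and reproduces its
  qualitative behaviour (removal of per-sample scale), not its internals.
* differential expression of a treatment condition against untreated
  controls (two-sided Welch t-test per gene on log2 values) with the
  significant genes partitioned into increased and repressed;
* dose-response summaries: per-gene condition means in dose order with a
  strict-monotone-increase flag (no formal trend test);
* pathway scores: mean per-gene z-score over pathway members, and the
  gene-set fold-change CDF shift test — per-gene log2 fold changes of two
  groups against a common reference condition, compared with a two-sample
  Kolmogorov–Smirnov test. A rightward shift of one group's fold-change CDF
  indicates collective induction of the gene set in that group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountTable, GeneSet, ValidationError


@dataclass
class ExpressionExperiment:
    """Gene × sample expression matrix with a condition label per sample.

    ``conditions`` maps each sample to its condition (e.g. control /
    dose_20 / dose_40, or normal_control / non_epileptogenic /
    epileptogenic). ``housekeeping`` optionally lists stable genes used for
    normalization. ``state`` is ``raw`` or ``log2`` (normalized).
    """

    values: pd.DataFrame
    conditions: pd.Series
    housekeeping: tuple[str, ...] | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state == "raw":
            CountTable(self.values)  # uniqueness, non-negativity, finiteness
        else:
            if self.values.index.has_duplicates or self.values.columns.has_duplicates:
                raise ValidationError("duplicate gene or sample names")
            if not np.isfinite(self.values.to_numpy(dtype=float)).all():
                raise ValidationError("matrix values must be finite")
        self.conditions = pd.Series(self.conditions)
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValidationError(f"samples without a condition label: {missing}")
        self.conditions = self.conditions.loc[list(self.values.columns)]
        if self.housekeeping is not None:
            self.housekeeping = tuple(self.housekeeping)
            absent = [g for g in self.housekeeping if g not in self.values.index]
            if absent:
                raise ValidationError(f"housekeeping genes absent from panel: {absent}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


def normalize_panel(e: ExpressionExperiment, pseudocount: float = 0.5) -> ExpressionExperiment:
    """Equalize per-sample geometric means of housekeeping genes, then log2.

    The scale factor for each sample is (target / sample geometric mean)
    where the target is the geometric mean of the per-sample geometric
    means; housekeeping genes default to all genes. Values are then
    log2(x + pseudocount).
    """
    if e.state != "raw":
        raise ValidationError(f"normalize_panel expects raw counts, got state {e.state!r}")
    genes = list(e.housekeeping) if e.housekeeping else list(e.values.index)
    basis = e.values.loc[genes] + pseudocount
    log_gm = np.log(basis).mean(axis=0)  # per-sample log geometric mean
    factors = np.exp(log_gm.mean() - log_gm)
    scaled = e.values.mul(factors, axis=1)
    logged = np.log2(scaled + pseudocount)
    out = ExpressionExperiment(values=logged, conditions=e.conditions, housekeeping=e.housekeeping, state="log2")
    out.scale_factors_ = factors  # type: ignore[attr-defined]
    return out


def _resolve_genes(genes: GeneSet, panel_index) -> tuple[dict[str, str], list[str]]:
    """Map gene-set symbols onto panel row ids, case-insensitively.

    Returns (symbol -> panel row id for resolvable genes, missing symbols),
    preserving gene-set order.
    """
    lookup: dict[str, str] = {}
    for rid in panel_index:
        lookup.setdefault(str(rid).upper(), rid)
    present: dict[str, str] = {}
    missing: list[str] = []
    for g in genes:  # GeneSet symbols are already uppercased
        if g in lookup:
            present[g] = lookup[g]
        else:
            missing.append(g)
    return present, missing


def de_vs_control(
    e: ExpressionExperiment,
    condition: str,
    control: str = "control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided per-gene Welch t-test of ``condition`` against ``control``.

    Returns per-gene ``fold_change`` (linear, 2**(mean log2 difference)),
    ``p_value``, and a ``direction`` column partitioning significant genes
    (p <= alpha) into 'increased' / 'repressed' ('ns' otherwise).
    """
    if e.state != "log2":
        raise ValidationError("de_vs_control expects a normalized (log2) experiment")
    cond_samples = e.samples_of(condition)
    ctrl_samples = e.samples_of(control)
    for name, samples in ((condition, cond_samples), (control, ctrl_samples)):
        if len(samples) < 2:
            raise ValidationError(
                f"condition {name!r} has {len(samples)} replicate(s); at least 2 are "
                "required for testing (report descriptive fold changes instead)"
            )
    a = e.values[cond_samples].to_numpy(dtype=float)
    b = e.values[ctrl_samples].to_numpy(dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant rows
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    out = pd.DataFrame(
        {
            "log2_fc": diff,
            "fold_change": 2.0**diff,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=e.values.index.rename("gene"),
    )
    sig = out["p_value"] <= alpha
    out["direction"] = np.where(sig & (diff > 0), "increased", np.where(sig & (diff < 0), "repressed", "ns"))
    return out.sort_values("fold_change", ascending=False)


def dose_response(
    e: ExpressionExperiment,
    genes: GeneSet,
    dose_order: Sequence[str] = ("control", "dose_20", "dose_40"),
) -> pd.DataFrame:
    """Per-gene condition means in dose order plus a strict-monotone flag.

    No formal trend p-value is computed. Genes absent from the panel are
    listed with ``missing=True`` rather than raising.
    """
    if e.state != "log2":
        raise ValidationError("dose_response expects a normalized (log2) experiment")
    for d in dose_order:
        if not e.samples_of(d):
            raise ValidationError(f"dose level {d!r} has no samples")
    rows = []
    present, _ = _resolve_genes(genes, e.values.index)
    for gene in genes:
        if gene not in present:
            rows.append({"gene": gene, "missing": True, "monotone_increase": False})
            continue
        rid = present[gene]
        means = {d: float(e.values.loc[rid, e.samples_of(d)].mean()) for d in dose_order}
        mono = all(means[dose_order[i]] < means[dose_order[i + 1]] for i in range(len(dose_order) - 1))
        rows.append({"gene": gene, "missing": False, "monotone_increase": mono, **{f"mean_{d}": means[d] for d in dose_order}})
    return pd.DataFrame(rows).set_index("gene")


def pathway_score(e: ExpressionExperiment, pathways: Iterable[GeneSet]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Mean per-gene z-score over pathway members, per sample.

    Each gene is standardized across samples; a pathway's score in a sample
    is the mean z-score of its member genes present on the panel. Returns
    (scores DataFrame pathway × sample, missing-member report). A pathway
    with no matching genes gets NaN scores and is reported.
    """
    if e.state != "log2":
        raise ValidationError("pathway_score expects a normalized (log2) experiment")
    vals = e.values
    sd = vals.std(axis=1, ddof=1)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    scores = {}
    missing: dict[str, list[str]] = {}
    for ps in pathways:
        present, absent = _resolve_genes(ps, vals.index)
        missing[ps.name] = absent
        rows = list(present.values())
        scores[ps.name] = z.loc[rows].mean(axis=0) if rows else pd.Series(np.nan, index=vals.columns)
    frame = pd.DataFrame(scores).T
    frame.index.name = "pathway"
    return frame, missing


@dataclass(frozen=True)
class GeneSetShiftResult:
    """Per-gene fold changes of two groups vs a reference, with a KS test.

    ``fold_changes`` has one row per resolvable gene with log2 fold-change
    columns for each group; ``ks_statistic``/``ks_p`` compare the two
    fold-change distributions (two-sample, two-sided).
    """

    fold_changes: pd.DataFrame
    ks_statistic: float
    ks_p: float
    missing_genes: tuple[str, ...]

    def cdf_table(self) -> pd.DataFrame:
        """Empirical CDF of both fold-change columns on a merged grid, for plotting."""
        cols = [c for c in self.fold_changes.columns]
        grid = np.sort(self.fold_changes.to_numpy().ravel())
        out = {"log2_fc": grid}
        n = len(self.fold_changes)
        for c in cols:
            x = np.sort(self.fold_changes[c].to_numpy())
            out[f"cdf_{c}"] = np.searchsorted(x, grid, side="right") / n
        return pd.DataFrame(out)


def geneset_shift_test(
    tissue: ExpressionExperiment,
    genes: GeneSet,
    group_a: str = "epileptogenic",
    group_b: str = "non_epileptogenic",
    reference: str = "normal_control",
    ks_method: str = "asymp",
) -> GeneSetShiftResult:
    """Gene-set fold-change CDF shift between two groups vs a reference.

    Per gene, the log2 fold change of each group is the difference of the
    group's mean log2 expression and the reference condition's mean. The
    two per-gene fold-change vectors (over the same gene set) are compared
    with a two-sample, two-sided Kolmogorov–Smirnov test (asymptotic by
    default; ``ks_method="exact"`` for small sets).
    """
    if tissue.state != "log2":
        raise ValidationError("geneset_shift_test expects a normalized (log2) experiment")
    for cond in (group_a, group_b, reference):
        if not tissue.samples_of(cond):
            raise ValidationError(f"condition {cond!r} has no samples")
    resolved, absent = _resolve_genes(genes, tissue.values.index)
    present = list(resolved.values())
    missing = tuple(absent)
    if len(present) < 10:
        import warnings

        warnings.warn(
            f"only {len(present)} of {len(genes)} gene-set genes resolvable on the panel",
            stacklevel=2,
        )
    if not present:
        raise ValidationError("no gene-set genes present on the panel")
    ref_mean = tissue.values.loc[present, tissue.samples_of(reference)].mean(axis=1)
    fc = pd.DataFrame(index=pd.Index(present, name="gene"))
    for grp in (group_a, group_b):
        grp_mean = tissue.values.loc[present, tissue.samples_of(grp)].mean(axis=1)
        fc[grp] = grp_mean - ref_mean
    ks = stats.ks_2samp(fc[group_a], fc[group_b], alternative="two-sided", method=ks_method)
    return GeneSetShiftResult(
        fold_changes=fc,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        missing_genes=missing,
    )


class PanelNormalizer(BaseEstimator, TransformerMixin):
    """Housekeeping geometric-mean normalization + log2, as a transformer."""

    def __init__(self, pseudocount: float = 0.5):
        self.pseudocount = pseudocount

    def fit(self, X: ExpressionExperiment, y=None) -> "PanelNormalizer":
        normalized = normalize_panel(X, pseudocount=self.pseudocount)
        self.scale_factors_ = normalized.scale_factors_  # type: ignore[attr-defined]
        return self

    def transform(self, X: ExpressionExperiment) -> ExpressionExperiment:
        return normalize_panel(X, pseudocount=self.pseudocount)


class PanelDifferentialExpression(BaseEstimator):
    """Condition-vs-control DE on a normalized panel.

    Attributes after ``fit``: ``results_`` (per-gene table), ``increased_``
    and ``repressed_`` (significant gene lists), ``n_de_``. Experiments
    with only 2 replicates per condition are permitted but flagged
    low-power in ``warnings_``.
    """

    def __init__(self, condition: str = "dose_40", control: str = "control", alpha: float = 0.05):
        self.condition = condition
        self.control = control
        self.alpha = alpha

    def fit(self, X: ExpressionExperiment, y=None) -> "PanelDifferentialExpression":
        self.results_ = de_vs_control(X, self.condition, control=self.control, alpha=self.alpha)
        self.increased_ = list(self.results_.index[self.results_["direction"] == "increased"])
        self.repressed_ = list(self.results_.index[self.results_["direction"] == "repressed"])
        self.n_de_ = len(self.increased_) + len(self.repressed_)
        self.warnings_ = []
        n_min = min(len(X.samples_of(self.condition)), len(X.samples_of(self.control)))
        if n_min <= 2:
            self.warnings_.append(f"low power: only {n_min} replicates per condition")
        return self


class PathwayScorer(BaseEstimator, TransformerMixin):
    """Per-sample mean-z-score pathway scoring over named gene sets."""

    def __init__(self, pathways: Sequence[GeneSet] = ()):
        self.pathways = tuple(pathways)

    def fit(self, X: ExpressionExperiment, y=None) -> "PathwayScorer":
        self.scores_, self.missing_ = pathway_score(X, self.pathways)
        return self

    def transform(self, X: ExpressionExperiment) -> pd.DataFrame:
        return pathway_score(X, self.pathways)[0]


class GeneSetShift(BaseEstimator):
    """Fold-change CDF shift test of a gene set between two tissue groups.

    Attributes after ``fit``: ``result_`` (GeneSetShiftResult),
    ``ks_statistic_``, ``ks_p_``.
    """

    def __init__(
        self,
        genes: GeneSet | None = None,
        group_a: str = "epileptogenic",
        group_b: str = "non_epileptogenic",
        reference: str = "normal_control",
        ks_method: str = "asymp",
    ):
        self.genes = genes
        self.group_a = group_a
        self.group_b = group_b
        self.reference = reference
        self.ks_method = ks_method

    def fit(self, X: ExpressionExperiment, y=None) -> "GeneSetShift":
        if self.genes is None:
            raise ValidationError("GeneSetShift requires a gene set")
        self.result_ = geneset_shift_test(
            X,
            self.genes,
            group_a=self.group_a,
            group_b=self.group_b,
            reference=self.reference,
            ks_method=self.ks_method,
        )
        self.ks_statistic_ = self.result_.ks_statistic
        self.ks_p_ = self.result_.ks_p
        return self
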