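"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its :class:`SimulationConfig` (seed
included): calling it twice with the same config yields identical objects,
and the files the CLI writes from them are byte-identical. Every generator
also returns a manifest dict recording the planted truth (which features
carry which fold change, where motifs were planted, which nodes are hubs),
so downstream recovery tests are self-contained.

Defaults emulate the study conditions the pipeline targets: a background of
2,656 mature miRNA sequences with ~1.45% of 4-mer windows carrying a
TLR7/8 motif and a 37-sequence foreground at ~2.5%; a two-group (3 + 3)
exosomal miRNA count design with planted fold changes spanning 1.5–17.4
and a stable miR-26a-5p-like reference; a 770-gene expression panel with
two exosome doses and 84 up- / 21 down-planted genes; and a 64-node
interaction graph with two planted hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EdgeList, MatureSequenceSet, ValidationError
from .diffexp import EPILEPTOGENIC, NON_EPILEPTOGENIC, MiRNACountMatrix
from .induction import ExpressionExperiment
from .motifs import DEFAULT_MOTIFS, count_motifs

_BASES = np.array(list("ACGU"))


def _default_planted_fc() -> tuple[tuple[str, float], ...]:
    # 37 increased miRNAs with fold changes log-spaced over the 1.5-17.41 range
    fcs = np.geomspace(1.5, 17.41, 37)
    return tuple((f"mir-planted-{i + 1:02d}", round(float(fc), 3)) for i, fc in enumerate(fcs[::-1]))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic generators; ``seed`` is mandatory."""

    seed: int

    # sequence simulation
    n_background_seqs: int = 2656
    n_foreground_seqs: int = 37
    seq_length_range: tuple[int, int] = (19, 24)
    motif_density: float = 0.0145         # background windows carrying a motif
    foreground_density: float = 0.0255    # foreground windows carrying a motif
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    exact_density: bool = True            # motif-free base via rejection sampling

    # miRNA count simulation (two-group exosomal design)
    n_mirnas: int = 400
    group_sizes: tuple[int, int] = (3, 3)
    planted_fc: tuple[tuple[str, float], ...] = field(default_factory=_default_planted_fc)
    within_group_sd_log2: float = 0.3
    reference_feature: str = "hsa-miR-26a-5p"
    reference_sd_log2: float = 0.05
    n_low_abundance: int = 100
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    low_abundance_log2_mean: float = 0.0
    low_abundance_log2_sd: float = 0.3
    library_size_fold: float = 2.0        # per-sample depth varies over this range

    # expression-panel simulation
    panel_genes: int = 770
    n_planted_up: int = 84
    n_planted_down: int = 21
    up_effect_log2: float = 1.0
    down_effect_log2: float = -1.0
    panel_sd_log2: float = 0.25
    dose_levels: tuple[str, ...] = ("control", "dose_20", "dose_40")
    dose_fractions: tuple[float, ...] = (0.0, 0.5, 1.0)
    n_replicates: int = 2
    n_dose_responsive: int = 9

    # tissue-panel simulation (gene-set shift design)
    tissue_group_sizes: tuple[int, int, int] = (3, 5, 5)  # reference, non-epi, epi
    geneset_size: int = 84
    tissue_shift_log2: float = 0.6
    tissue_fc_spread_log2: float = 0.5
    tissue_sd_log2: float = 0.25

    # graph simulation
    hub_spec: tuple[tuple[str, int], ...] = (("SQSTM1", 12), ("CDKN1A", 11))
    n_graph_nodes: int = 64
    background_mean_degree: float = 2.0

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("planted_fc", "hub_spec"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        for key in (
            "seq_length_range", "group_sizes", "motifs", "dose_levels",
            "dose_fractions", "tissue_group_sizes",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _motif_free_sequence(rng: np.random.Generator, length: int, motifs: Sequence[str]) -> str:
    while True:
        seq = _random_sequence(rng, length)
        if all(count_motifs(seq, motifs)[m] == 0 for m in motifs):
            return seq


def _plant_motifs(rng: np.random.Generator, length: int, n_plant: int, motifs: Sequence[str], exact: bool) -> str:
    """A sequence of given length carrying exactly (or at least) n_plant motif windows."""
    k = len(motifs[0])
    for _ in range(1000):
        seq = _motif_free_sequence(rng, length, motifs) if exact else _random_sequence(rng, length)
        starts: list[int] = []
        if n_plant > 0:
            candidates = list(range(length - k + 1))
            rng.shuffle(candidates)
            for pos in candidates:
                if all(abs(pos - s) >= k for s in starts):
                    starts.append(pos)
                    if len(starts) == n_plant:
                        break
        if len(starts) < n_plant:
            continue
        chars = list(seq)
        for pos in sorted(starts):
            motif = motifs[rng.integers(len(motifs))]
            chars[pos : pos + k] = motif
        out = "".join(chars)
        if not exact:
            return out
        realized = sum(count_motifs(out, motifs)[m] for m in motifs)
        if realized == n_plant:  # reject junction-created extras
            return out
    raise ValidationError(f"could not plant {n_plant} motifs in a length-{length} sequence")


def gen_sequences(cfg: SimulationConfig, role: str = "background") -> tuple[MatureSequenceSet, dict]:
    """Random mature-miRNA-like sequences with a controlled motif density.

    ``role`` selects the background (default) or foreground parameters.
    Sequences are uniform over {A,C,G,U}; motif instances are planted at
    non-overlapping random windows so the expected fraction of windows
    carrying a motif equals the configured density. With
    ``exact_density=True`` the base sequences are rejection-sampled to be
    motif-free first, so the realized hit count equals the planted count
    exactly (density 0 then yields exactly zero motifs).
    """
    if role == "background":
        n, density, prefix, stream = cfg.n_background_seqs, cfg.motif_density, "bg", 0
    elif role == "foreground":
        n, density, prefix, stream = cfg.n_foreground_seqs, cfg.foreground_density, "fg", 1
    else:
        raise ValueError(f"role must be 'background' or 'foreground', got {role!r}")
    if not 0.0 <= density <= 1.0:
        raise ValidationError(f"motif density must be in [0, 1], got {density}")
    lo, hi = cfg.seq_length_range
    k = len(cfg.motifs[0])
    max_density = (lo // k) / max(lo - k + 1, 1)
    if density > max_density:
        raise ValidationError(
            f"density {density} infeasible for minimum length {lo} "
            f"(at most {max_density:.3f} of windows can carry non-overlapping motifs)"
        )
    rng = np.random.default_rng((cfg.seed, stream))
    entries = []
    planted_total = 0
    windows_total = 0
    planted_per_seq = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        n_windows = length - k + 1
        n_plant = int(rng.binomial(n_windows, density))
        n_plant = min(n_plant, length // k)
        seq = _plant_motifs(rng, length, n_plant, cfg.motifs, cfg.exact_density)
        sid = f"{prefix}-mir-{i + 1:04d}"
        entries.append((sid, seq))
        planted_per_seq[sid] = n_plant
        planted_total += n_plant
        windows_total += n_windows
    manifest = {
        "role": role,
        "seed": cfg.seed,
        "n_sequences": n,
        "target_density": density,
        "planted_motifs": planted_total,
        "total_windows": windows_total,
        "realized_density": planted_total / windows_total if windows_total else 0.0,
        "planted_per_sequence": planted_per_seq,
        "motifs": list(cfg.motifs),
        "exact_density": cfg.exact_density,
    }
    return MatureSequenceSet(tuple(entries)), manifest


def gen_mirna_counts(cfg: SimulationConfig) -> tuple[MiRNACountMatrix, dict]:
    """Two-group exosomal miRNA count matrix with planted fold changes.

    Per-feature baseline abundances are log-normal; features listed in
    ``planted_fc`` are multiplied by their fold change in the epileptogenic
    group; the reference feature is near-constant (log2 noise sd
    ``reference_sd_log2``); ``n_low_abundance`` features sit far below the
    rest (for abundance-filter testing); per-sample library sizes vary over
    a ``library_size_fold`` range. Values are rounded to integer counts.
    """
    planted = dict(cfg.planted_fc)
    if cfg.reference_feature in planted:
        raise ValidationError("the reference feature cannot carry a planted fold change")
    n_named = 1 + len(planted) + cfg.n_low_abundance
    if n_named > cfg.n_mirnas:
        raise ValidationError(
            f"n_mirnas={cfg.n_mirnas} too small for {len(planted)} planted + "
            f"{cfg.n_low_abundance} low-abundance features + reference"
        )
    rng = np.random.default_rng((cfg.seed, 2))
    low_ids = [f"mir-low-{i + 1:03d}" for i in range(cfg.n_low_abundance)]
    null_ids = [f"mir-null-{i + 1:03d}" for i in range(cfg.n_mirnas - n_named)]
    features = [cfg.reference_feature] + list(planted) + low_ids + null_ids

    n_epi, n_non = cfg.group_sizes
    samples = [f"epi_{i + 1}" for i in range(n_epi)] + [f"non_{i + 1}" for i in range(n_non)]
    groups = pd.Series(
        [EPILEPTOGENIC] * n_epi + [NON_EPILEPTOGENIC] * n_non, index=samples
    )

    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(features))
    base[0] = cfg.baseline_log2_mean + 2.0  # abundant, stable reference
    lo_start = 1 + len(planted)
    base[lo_start : lo_start + cfg.n_low_abundance] = rng.normal(
        cfg.low_abundance_log2_mean, cfg.low_abundance_log2_sd, size=cfg.n_low_abundance
    )

    effect = np.zeros((len(features), len(samples)))
    for i, f in enumerate(features):
        if f in planted:
            effect[i, :n_epi] = np.log2(planted[f])

    sd = np.full(len(features), cfg.within_group_sd_log2)
    sd[0] = cfg.reference_sd_log2
    noise = rng.normal(0.0, 1.0, size=effect.shape) * sd[:, None]

    half = np.log2(cfg.library_size_fold) / 2.0
    lib = 2.0 ** rng.uniform(-half, half, size=len(samples))
    linear = 2.0 ** (base[:, None] + effect + noise) * lib[None, :]
    counts = np.rint(linear).astype(int)
    counts[0] = np.maximum(counts[0], 1)  # reference must stay positive

    values = pd.DataFrame(counts, index=pd.Index(features, name="mirna"), columns=samples)
    matrix = MiRNACountMatrix(values=values, groups=groups, reference_mirna=cfg.reference_feature)
    manifest = {
        "seed": cfg.seed,
        "planted_fold_changes": {f: fc for f, fc in planted.items()},
        "low_abundance_features": low_ids,
        "reference_feature": cfg.reference_feature,
        "group_sizes": list(cfg.group_sizes),
        "within_group_sd_log2": cfg.within_group_sd_log2,
        "library_factors": {s: float(f) for s, f in zip(samples, lib)},
    }
    return matrix, manifest


def gen_panel(cfg: SimulationConfig, design: str = "cells") -> tuple[ExpressionExperiment, dict]:
    """Expression-panel counts for the dose-response or tissue design.

    ``design="cells"``: conditions are the configured dose levels with
    ``n_replicates`` wells each; the first ``n_planted_up`` genes gain
    ``up_effect_log2`` (scaled by the per-dose fraction, so they are
    dose-monotone in expectation; the first ``n_dose_responsive`` of them
    are recorded as the dose-responsive set), and the next
    ``n_planted_down`` genes lose expression at dose.

    ``design="tissue"``: conditions are normal_control / non_epileptogenic /
    epileptogenic with the configured group sizes; the first
    ``geneset_size`` genes carry a per-gene induction drawn with spread
    ``tissue_fc_spread_log2`` in both tuber groups plus an extra
    ``tissue_shift_log2`` in the epileptogenic group.
    """
    rng = np.random.default_rng((cfg.seed, 3 if design == "cells" else 4))
    n_genes = cfg.panel_genes

    if design == "cells":
        n_special = cfg.n_planted_up + cfg.n_planted_down
        if n_special > n_genes:
            raise ValidationError("panel too small for the planted up/down genes")
        up_ids = [f"GENE_UP_{i + 1:03d}" for i in range(cfg.n_planted_up)]
        down_ids = [f"GENE_DOWN_{i + 1:03d}" for i in range(cfg.n_planted_down)]
        null_ids = [f"GENE_{i + 1:04d}" for i in range(n_genes - n_special)]
        genes = up_ids + down_ids + null_ids
        conditions, samples = [], []
        for level in cfg.dose_levels:
            for r in range(cfg.n_replicates):
                samples.append(f"{level}_r{r + 1}")
                conditions.append(level)
        frac = {lvl: f for lvl, f in zip(cfg.dose_levels, cfg.dose_fractions)}
        effect = np.zeros((n_genes, len(samples)))
        for j, s in enumerate(samples):
            f = frac[conditions[j]]
            effect[: cfg.n_planted_up, j] = cfg.up_effect_log2 * f
            effect[cfg.n_planted_up : n_special, j] = cfg.down_effect_log2 * f
        manifest_extra = {
            "planted_up": up_ids,
            "planted_down": down_ids,
            "dose_responsive": up_ids[: cfg.n_dose_responsive],
            "up_effect_log2": cfg.up_effect_log2,
            "down_effect_log2": cfg.down_effect_log2,
        }
        sd = cfg.panel_sd_log2
    elif design == "tissue":
        if cfg.geneset_size > n_genes:
            raise ValidationError("panel too small for the planted gene set")
        set_ids = [f"GENE_SET_{i + 1:03d}" for i in range(cfg.geneset_size)]
        null_ids = [f"GENE_{i + 1:04d}" for i in range(n_genes - cfg.geneset_size)]
        genes = set_ids + null_ids
        n_ref, n_non, n_epi = cfg.tissue_group_sizes
        samples = (
            [f"normal_{i + 1}" for i in range(n_ref)]
            + [f"nonepi_{i + 1}" for i in range(n_non)]
            + [f"epi_{i + 1}" for i in range(n_epi)]
        )
        conditions = (
            ["normal_control"] * n_ref + ["non_epileptogenic"] * n_non + ["epileptogenic"] * n_epi
        )
        gene_induction = rng.normal(0.0, cfg.tissue_fc_spread_log2, size=cfg.geneset_size)
        effect = np.zeros((n_genes, len(samples)))
        for j, c in enumerate(conditions):
            if c == "non_epileptogenic":
                effect[: cfg.geneset_size, j] = gene_induction
            elif c == "epileptogenic":
                effect[: cfg.geneset_size, j] = gene_induction + cfg.tissue_shift_log2
        manifest_extra = {
            "gene_set": set_ids,
            "tissue_shift_log2": cfg.tissue_shift_log2,
            "per_gene_induction_log2": [float(x) for x in gene_induction],
        }
        sd = cfg.tissue_sd_log2
    else:
        raise ValueError(f"design must be 'cells' or 'tissue', got {design!r}")

    base = rng.normal(9.0, 1.5, size=n_genes)
    noise = rng.normal(0.0, sd, size=effect.shape)
    half = np.log2(cfg.library_size_fold) / 2.0
    lib = 2.0 ** rng.uniform(-half, half, size=len(samples))
    counts = np.rint(2.0 ** (base[:, None] + effect + noise) * lib[None, :]).astype(int)
    counts = np.maximum(counts, 0)
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    experiment = ExpressionExperiment(values=values, conditions=pd.Series(conditions, index=samples))
    manifest = {
        "seed": cfg.seed,
        "design": design,
        "noise_sd_log2": sd,
        "library_factors": {s: float(f) for s, f in zip(samples, lib)},
        **manifest_extra,
    }
    return experiment, manifest


def gen_graph(cfg: SimulationConfig) -> tuple[EdgeList, dict]:
    """Interaction edge list with planted hubs over a sparse random remainder.

    Non-hub nodes form an Erdős–Rényi graph with the configured mean
    degree; each hub is then attached to its planted number of distinct
    non-hub nodes. Hub degrees therefore dominate the degree distribution
    by construction.
    """
    hubs = dict(cfg.hub_spec)
    n_other = cfg.n_graph_nodes - len(hubs)
    if n_other <= 0:
        raise ValidationError("n_graph_nodes must exceed the number of planted hubs")
    too_big = [h for h, d in hubs.items() if d > n_other]
    if too_big:
        raise ValidationError(f"hub degree(s) unrealizable with {n_other} non-hub nodes: {too_big}")
    rng = np.random.default_rng((cfg.seed, 5))
    others = [f"GENE_{i + 1:03d}" for i in range(n_other)]
    p = min(cfg.background_mean_degree / max(n_other - 1, 1), 1.0)
    edges: list[tuple[str, str]] = []
    for i in range(n_other):
        for j in range(i + 1, n_other):
            if rng.random() < p:
                edges.append((others[i], others[j]))
    for hub, degree in hubs.items():
        targets = rng.choice(n_other, size=degree, replace=False)
        for t in targets:
            edges.append((hub, others[int(t)]))
    edge_list = EdgeList.from_pairs(edges)
    manifest = {
        "seed": cfg.seed,
        "hub_spec": {h: int(d) for h, d in hubs.items()},
        "n_nodes": cfg.n_graph_nodes,
        "background_mean_degree": cfg.background_mean_degree,
        "n_edges": len(edge_list),
    }
    return edge_list, manifest
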