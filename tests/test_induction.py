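"""Expression-panel normalization, DE, dose response, pathway and CDF shift."""

import numpy as np
import pandas as pd
import pytest

from exomir import (
    ExpressionExperiment,
    GeneSet,
    GeneSetShift,
    PanelDifferentialExpression,
    SimulationConfig,
    de_vs_control,
    dose_response,
    gen_panel,
    geneset_shift_test,
    normalize_panel,
    pathway_score,
)
from exomir.io import ValidationError

from conftest import make_log2_experiment


def _experiment(values: dict, genes, conditions):
    v = pd.DataFrame(values, index=genes)
    return ExpressionExperiment(values=v, conditions=pd.Series(conditions, index=v.columns))


class TestNormalizePanel:
    def test_identical_samples_get_equal_factors(self):
        e = _experiment({"a": [10, 20], "b": [10, 20]}, ["g1", "g2"], ["control", "dose_40"])
        out = normalize_panel(e)
        f = out.scale_factors_
        assert f["a"] == pytest.approx(f["b"])

    def test_tripled_sample_matches_original_after_normalization(self):
        e = _experiment(
            {"a": [12, 40, 7], "b": [36, 120, 21]}, ["g1", "g2", "g3"], ["control", "control"]
        )
        out = normalize_panel(e, pseudocount=0.0)
        assert np.allclose(out.values["a"], out.values["b"])

    def test_known_scale_factors_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(5, 1, 300)
        true = np.array([0.5, 0.9, 1.3, 2.0])
        vals = {f"s{i}": base * f for i, f in enumerate(true)}
        e = _experiment(vals, [f"g{i}" for i in range(300)], ["control"] * 4)
        recovered = normalize_panel(e, pseudocount=0.0).scale_factors_.to_numpy()
        ratio = recovered * true
        assert np.allclose(ratio, ratio[0], rtol=1e-2)  # equal up to a common constant

    def test_housekeeping_subset_used(self):
        e = ExpressionExperiment(
            values=pd.DataFrame({"a": [10, 100], "b": [10, 900]}, index=["hk", "g"]),
            conditions=pd.Series({"a": "control", "b": "dose_40"}),
            housekeeping=("hk",),
        )
        out = normalize_panel(e, pseudocount=0.0)
        assert out.values.loc["hk", "a"] == pytest.approx(out.values.loc["hk", "b"])

    def test_absent_housekeeping_gene_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            ExpressionExperiment(
                values=pd.DataFrame({"a": [1]}, index=["g"]),
                conditions=pd.Series({"a": "control"}),
                housekeeping=("missing",),
            )


class TestDeVsControl:
    def test_single_replicate_rejected(self):
        e = _experiment({"a": [1, 2], "b": [1, 2], "c": [1, 2]}, ["g1", "g2"], ["control", "control", "dose_40"])
        norm = normalize_panel(e)
        with pytest.raises(ValidationError, match="replicate"):
            de_vs_control(norm, "dose_40")

    def test_same_distribution_yields_near_nominal_fp(self):
        rng = np.random.default_rng(1)
        n_genes, fp, total = 200, 0, 0
        for rep in range(20):
            cols = {f"s{i}": 9 + rng.normal(0, 0.25, n_genes) for i in range(6)}
            e = make_log2_experiment(
                cols, {f"s{i}": ("control" if i < 3 else "dose_40") for i in range(6)}
            )
            res = de_vs_control(e, "dose_40")
            fp += (res["direction"] != "ns").sum()
            total += n_genes
        assert fp / total < 0.10

    def test_planted_signs_partition_correctly(self):
        cfg = SimulationConfig(seed=31, n_replicates=3)
        panel, manifest = gen_panel(cfg)
        est = PanelDifferentialExpression().fit(normalize_panel(panel))
        up, down = set(est.increased_), set(est.repressed_)
        assert not up & set(manifest["planted_down"])
        assert not down & set(manifest["planted_up"])
        assert len(up & set(manifest["planted_up"])) > len(up - set(manifest["planted_up"]))

    def test_low_replicate_design_flagged(self):
        cfg = SimulationConfig(seed=32)
        panel, _ = gen_panel(cfg)  # default two replicate wells
        est = PanelDifferentialExpression().fit(normalize_panel(panel))
        assert any("low power" in w for w in est.warnings_)


class TestDoseResponse:
    def _norm_panel(self, seed=41, **kw):
        panel, manifest = gen_panel(SimulationConfig(seed=seed, **kw))
        return normalize_panel(panel), manifest

    def test_monotone_flag_true_for_increasing_means(self):
        e = make_log2_experiment(
            {"c1": [10.0], "c2": [10.2], "d1": [12.0], "d2": [12.1], "h1": [15.0], "h2": [15.2]},
            {"c1": "control", "c2": "control", "d1": "dose_20", "d2": "dose_20", "h1": "dose_40", "h2": "dose_40"},
            genes=["GENEX"],
        )
        res = dose_response(e, GeneSet.from_symbols("s", ["genex"]))
        assert res.loc["GENEX", "monotone_increase"]

    def test_non_monotone_flag_false(self):
        e = make_log2_experiment(
            {"c1": [10.0], "c2": [10.0], "d1": [14.0], "d2": [14.0], "h1": [12.0], "h2": [12.0]},
            {"c1": "control", "c2": "control", "d1": "dose_20", "d2": "dose_20", "h1": "dose_40", "h2": "dose_40"},
            genes=["GENEX"],
        )
        assert not dose_response(e, GeneSet.from_symbols("s", ["GENEX"]))["monotone_increase"].any()

    def test_planted_dose_responsive_genes_all_flagged_at_low_noise(self):
        norm, manifest = self._norm_panel(panel_sd_log2=0.05)
        genes = GeneSet.from_symbols("dose", manifest["dose_responsive"])
        res = dose_response(norm, genes)
        assert res["monotone_increase"].all()

    def test_unknown_genes_reported_missing_not_fatal(self):
        norm, _ = self._norm_panel()
        res = dose_response(norm, GeneSet.from_symbols("s", ["NOT_ON_PANEL"]))
        assert res.loc["NOT_ON_PANEL", "missing"]


class TestPathwayScore:
    def _experiment(self, seed=51):
        panel, manifest = gen_panel(SimulationConfig(seed=seed))
        return normalize_panel(panel), manifest

    def test_planted_up_pathway_scores_higher_at_dose(self):
        norm, manifest = self._experiment()
        ps = GeneSet.from_symbols("up", manifest["planted_up"])
        scores, _ = pathway_score(norm, [ps])
        dose = [s for s in norm.values.columns if s.startswith("dose_40")]
        ctrl = [s for s in norm.values.columns if s.startswith("control")]
        assert scores.loc["up", dose].mean() > scores.loc["up", ctrl].mean()

    def test_null_pathway_scores_near_zero(self):
        for rep in range(20):
            norm, manifest = self._experiment(seed=600 + rep)
            nulls = [g for g in norm.values.index if g.startswith("GENE_0")][:100]
            scores, _ = pathway_score(norm, [GeneSet.from_symbols("null", nulls)])
            assert scores.abs().to_numpy().max() < 0.5

    def test_single_gene_pathway_equals_gene_zscore(self):
        norm, _ = self._experiment()
        gene = norm.values.index[0]
        scores, _ = pathway_score(norm, [GeneSet.from_symbols("one", [gene])])
        v = norm.values.loc[gene]
        z = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(scores.loc["one"], z)

    def test_union_is_size_weighted_mean_of_disjoint_parts(self):
        norm, manifest = self._experiment()
        a = manifest["planted_up"][:10]
        b = manifest["planted_down"][:5]
        sa, _ = pathway_score(norm, [GeneSet.from_symbols("a", a)])
        sb, _ = pathway_score(norm, [GeneSet.from_symbols("b", b)])
        su, _ = pathway_score(norm, [GeneSet.from_symbols("u", a + b)])
        expected = (10 * sa.loc["a"] + 5 * sb.loc["b"]) / 15
        assert np.allclose(su.loc["u"], expected)

    def test_empty_pathway_reported_undefined(self):
        norm, _ = self._experiment()
        scores, missing = pathway_score(norm, [GeneSet.from_symbols("none", ["NOPE1", "NOPE2"])])
        assert scores.loc["none"].isna().all()
        assert missing["none"] == ["NOPE1", "NOPE2"]


class TestGeneSetShift:
    def _tissue(self, seed, **kw):
        panel, manifest = gen_panel(SimulationConfig(seed=seed, **kw), design="tissue")
        return normalize_panel(panel), GeneSet.from_symbols("set", manifest["gene_set"])

    def test_identical_groups_give_zero_statistic(self):
        cols = {f"n{i}": np.full(30, 9.0) for i in range(3)}
        rng = np.random.default_rng(0)
        tuber = 9 + rng.normal(0, 0.3, 30)
        cols |= {f"a{i}": tuber for i in range(5)}
        cols |= {f"b{i}": tuber for i in range(5)}
        cond = {f"n{i}": "normal_control" for i in range(3)}
        cond |= {f"a{i}": "epileptogenic" for i in range(5)}
        cond |= {f"b{i}": "non_epileptogenic" for i in range(5)}
        e = make_log2_experiment(cols, cond, genes=[f"G{i}" for i in range(30)])
        r = geneset_shift_test(e, GeneSet.from_symbols("s", [f"G{i}" for i in range(30)]))
        assert r.ks_statistic == 0.0
        assert r.ks_p == 1.0

    def test_planted_shift_detected(self):
        norm, gs = self._tissue(61)
        r = geneset_shift_test(norm, gs)
        assert r.ks_p < 0.01
        # the epileptogenic fold-change distribution sits to the right
        assert r.fold_changes["epileptogenic"].mean() > r.fold_changes["non_epileptogenic"].mean()

    def test_symmetric_in_group_order(self):
        norm, gs = self._tissue(62)
        r1 = geneset_shift_test(norm, gs)
        r2 = geneset_shift_test(norm, gs, group_a="non_epileptogenic", group_b="epileptogenic")
        assert r1.ks_p == pytest.approx(r2.ks_p)
        assert r1.ks_statistic == pytest.approx(r2.ks_statistic)

    def test_missing_genes_listed_and_excluded(self):
        norm, gs = self._tissue(63)
        bigger = GeneSet.from_symbols("s", list(gs) + ["ABSENT_GENE"])
        r = geneset_shift_test(norm, bigger)
        assert r.missing_genes == ("ABSENT_GENE",)
        assert len(r.fold_changes) == len(gs)

    def test_few_resolvable_genes_warn(self):
        norm, gs = self._tissue(64)
        small = GeneSet.from_symbols("s", list(gs)[:3])
        with pytest.warns(UserWarning, match="resolvable"):
            geneset_shift_test(norm, small)

    def test_cdf_table_monotone_reaching_one(self):
        norm, gs = self._tissue(65)
        cdf = geneset_shift_test(norm, gs).cdf_table()
        for col in cdf.columns[1:]:
            assert (cdf[col].diff().dropna() >= 0).all()
            assert cdf[col].iloc[-1] == pytest.approx(1.0)

    def test_estimator_wrapper_exposes_fitted_stats(self):
        norm, gs = self._tissue(66)
        est = GeneSetShift(genes=gs).fit(norm)
        assert 0 <= est.ks_statistic_ <= 1
        assert est.ks_p_ == est.result_.ks_p
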