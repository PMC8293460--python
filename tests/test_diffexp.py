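"""Normalization, abundance filtering and one-sided differential testing."""

import numpy as np
import pandas as pd
import pytest

from exomir import (
    DifferentialAbundance,
    MiRNACountMatrix,
    SimulationConfig,
    differential_test,
    gen_mirna_counts,
    log_and_filter,
    normalize,
)
from exomir.io import ValidationError

EPI, NON = "epileptogenic", "non_epileptogenic"


def _matrix(values: dict, index, groups, reference="ref"):
    v = pd.DataFrame(values, index=index)
    g = pd.Series(groups, index=v.columns)
    return MiRNACountMatrix(values=v, groups=g, reference_mirna=reference)


class TestNormalize:
    def test_two_step_hand_arithmetic(self):
        # totals (10, 4); row 1: (8/10)/(2/10) = 4, (2/4)/(2/4) = 1
        m = _matrix({"s1": [8, 2], "s2": [2, 2]}, ["mir-a", "ref"], [EPI, NON])
        out = normalize(m)
        assert out.values.loc["mir-a"].tolist() == [4.0, 1.0]

    def test_reference_row_becomes_one(self, toy_mirna_matrix):
        out = normalize(toy_mirna_matrix)
        assert (out.values.loc["hsa-miR-26a-5p"] == 1.0).all()
        assert out.state == "normalized"

    def test_library_size_invariance(self, toy_mirna_matrix):
        scaled = toy_mirna_matrix.values.copy()
        scaled["epi_1"] *= 10
        m2 = MiRNACountMatrix(values=scaled, groups=toy_mirna_matrix.groups)
        pd.testing.assert_frame_equal(normalize(toy_mirna_matrix).values, normalize(m2).values)

    def test_double_normalization_rejected(self, toy_mirna_matrix):
        out = normalize(toy_mirna_matrix)
        with pytest.raises(ValidationError, match="raw"):
            normalize(out)

    def test_zero_reference_names_sample(self):
        with pytest.raises(ValidationError, match="s2"):
            _matrix({"s1": [8, 2], "s2": [2, 0]}, ["mir-a", "ref"], [EPI, NON])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            _matrix({"s1": [8, 2]}, ["mir-a", "mir-b"], [EPI], reference="nope")


class TestLogAndFilter:
    def _normalized(self, values, index, groups):
        return normalize(_matrix(values, index, groups))

    def test_retained_if_above_threshold_in_one_group(self):
        # mir-hi is top in every sample; mir-lo is bottom everywhere
        vals = {
            "e1": [400, 100, 40, 4, 1],
            "e2": [420, 100, 41, 4, 1],
            "n1": [400, 100, 39, 4, 1],
            "n2": [410, 100, 40, 4, 1],
        }
        idx = ["mir-hi", "ref", "mir-mid", "mir-edge", "mir-lo"]
        m = self._normalized(vals, idx, [EPI, EPI, NON, NON])
        _, retained = log_and_filter(m)
        assert "mir-hi" in retained and "mir-mid" in retained
        assert "mir-lo" not in retained

    def test_strictly_greater_boundary(self):
        # with 5 features the 25th percentile lands exactly on the second-
        # lowest value; a feature sitting exactly at it must be excluded
        vals = {
            "e1": [1, 2, 4, 8, 16], "e2": [1, 2, 4, 8, 16],
            "n1": [1, 2, 4, 8, 16], "n2": [1, 2, 4, 8, 16],
        }
        idx = ["mir-lo", "mir-q", "mir-mid", "mir-hi", "ref"]
        m = self._normalized(vals, idx, [EPI, EPI, NON, NON])
        logged, retained = log_and_filter(m)
        thresholds = logged.values.quantile(0.25, axis=0)
        assert (logged.values.loc["mir-q"] == thresholds).all()
        assert "mir-q" not in retained
        assert logged.state == "log2"

    def test_planted_low_abundance_rows_all_excluded(self):
        cfg = SimulationConfig(seed=11)
        matrix, manifest = gen_mirna_counts(cfg)
        _, retained = log_and_filter(normalize(matrix))
        assert set(manifest["low_abundance_features"]).isdisjoint(retained)

    def test_raw_scale_thresholds_supported(self, toy_mirna_matrix):
        m = normalize(toy_mirna_matrix)
        _, r_log = log_and_filter(m, threshold_scale="log")
        _, r_raw = log_and_filter(m, threshold_scale="raw")
        assert set(r_log) == set(r_raw)  # log2(x + c) is monotone


class TestDifferentialTest:
    def test_identical_groups_null(self):
        vals = {"e1": [64, 10], "e2": [32, 10], "n1": [64, 10], "n2": [32, 10]}
        m = _matrix(vals, ["mir-a", "ref"], [EPI, EPI, NON, NON])
        logged, retained = log_and_filter(normalize(m))
        res = differential_test(logged, retained)
        assert res.loc["mir-a", "fold_change"] == pytest.approx(1.0)
        assert res.loc["mir-a", "p_value"] >= 0.5
        assert not res["selected"].any()

    def test_zero_variance_equal_means_flagged_degenerate(self):
        vals = {"e1": [64, 10], "e2": [64, 10], "n1": [64, 10], "n2": [64, 10]}
        m = _matrix(vals, ["mir-a", "ref"], [EPI, EPI, NON, NON])
        logged, _ = log_and_filter(normalize(m))
        res = differential_test(logged)
        assert res.loc["mir-a", "degenerate"]
        assert res.loc["mir-a", "p_value"] == 1.0

    def test_selection_invariant_to_library_rescaling(self):
        cfg = SimulationConfig(seed=21, n_mirnas=120, n_low_abundance=20)
        matrix, _ = gen_mirna_counts(cfg)
        scaled = MiRNACountMatrix(
            values=matrix.values * [3, 1, 1, 7, 1, 1],
            groups=matrix.groups,
            reference_mirna=matrix.reference_mirna,
        )
        r1 = DifferentialAbundance().fit(matrix).results_
        r2 = DifferentialAbundance().fit(scaled).results_
        assert (r1["selected"] == r2["selected"]).all()
        assert np.allclose(r1["fold_change"], r2["fold_change"])

    def test_missing_group_rejected(self):
        vals = {"e1": [64, 10], "e2": [32, 10]}
        m = _matrix(vals, ["mir-a", "ref"], [EPI, EPI])
        logged, _ = log_and_filter(normalize(m))
        with pytest.raises(ValidationError, match="non_epileptogenic"):
            differential_test(logged)

    def test_output_sorted_by_fold_change(self):
        cfg = SimulationConfig(seed=3, n_mirnas=80, n_low_abundance=10)
        matrix, _ = gen_mirna_counts(cfg)
        res = DifferentialAbundance().fit(matrix).results_
        assert (res["fold_change"].diff().dropna() <= 1e-12).all()


class TestRecovery:
    """Planted-effect recovery at the two-group exosomal design (3 + 3, sd 0.3)."""

    def test_four_fold_mirna_recovered_within_sampling_error(self):
        fcs = []
        for rep in range(60):
            cfg = SimulationConfig(
                seed=6000 + rep, n_mirnas=150, n_low_abundance=20,
                planted_fc=(("mir-four", 4.0),),
            )
            matrix, _ = gen_mirna_counts(cfg)
            fcs.append(DifferentialAbundance().fit(matrix).results_.loc["mir-four", "fold_change"])
        fcs = np.asarray(fcs)
        # the log2 estimate has sampling sd ~0.3*sqrt(2/3), so [3, 5.3] is a
        # ~90% interval for a planted 4-fold effect, not a hard envelope
        assert ((fcs > 3.0) & (fcs < 5.3)).mean() >= 0.8
        assert np.median(fcs) == pytest.approx(4.0, rel=0.10)

    def test_null_false_selection_at_most_nominal(self):
        n_false = n_null = 0
        for rep in range(40):
            cfg = SimulationConfig(seed=7000 + rep, n_mirnas=150, n_low_abundance=20, planted_fc=())
            matrix, _ = gen_mirna_counts(cfg)
            res = DifferentialAbundance().fit(matrix).results_
            n_false += int(res["selected"].sum())
            n_null += len(res)
        assert n_false / n_null <= 0.05
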