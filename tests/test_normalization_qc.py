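import numpy as np
import pandas as pd
import pytest
from scipy import stats

from restoromics.core_io import AbundanceMatrix, SampleMeta, SampleSheet
from restoromics.errors import StateError, ValidationError
from restoromics.normalization_qc import (
    apply_grubbs,
    bridge_scale,
    filter_min_peptides,
    filter_pooled_missing,
    grubbs_critical,
    grubbs_test,
    normalize_within_plex,
    rollup_proteins,
)
from restoromics.synthetic_data import SimulationConfig, simulate_study

from .oracles import grubbs_crit_reference


def two_channel_sheet():
    return SampleSheet(
        [
            SampleMeta("WT_1", "WT", 1, "plex1", "ch01"),
            SampleMeta("WT_2", "WT", 2, "plex1", "ch02"),
            SampleMeta("POOL_1", "POOL", 1, "plex1", "ch03"),
        ]
    )


class TestNormalizeWithinPlex:
    def test_forced_factors(self):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            {"WT_1": [40.0, 60.0], "WT_2": [120.0, 80.0], "POOL_1": [50.0, 100.0]},
            index=["p1", "p2"],
        )
        out = normalize_within_plex(AbundanceMatrix(data), sheet)
        totals = out.data.sum(axis=0)
        assert np.allclose(totals, totals.iloc[0])
        assert out.state == "within_plex_normalized"
        # channel totals were [100, 200, 150] -> mean 150 -> factors 1.5, .75, 1
        assert np.allclose(out.data["WT_1"], [60.0, 90.0])

    def test_already_equal_is_identity(self):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            {"WT_1": [40.0, 60.0], "WT_2": [70.0, 30.0], "POOL_1": [10.0, 90.0]},
            index=["p1", "p2"],
        )
        out = normalize_within_plex(AbundanceMatrix(data), sheet)
        pd.testing.assert_frame_equal(out.data, data)

    def test_missing_cells_excluded_from_totals_brute_force(self, rng):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            rng.lognormal(3, 1, (30, 3)),
            index=[f"p{i}" for i in range(30)],
            columns=sheet.sample_ids,
        )
        mask = rng.random(data.shape) < 0.2
        data = data.mask(mask)
        out = normalize_within_plex(AbundanceMatrix(data), sheet)
        # brute-force shared-row totals
        shared = [
            r for r in data.index if not data.loc[r].isna().any()
        ]
        totals = {c: sum(data.loc[r, c] for r in shared) for c in data.columns}
        mean_total = np.mean(list(totals.values()))
        for c in data.columns:
            factor = mean_total / totals[c]
            expected = data[c] * factor
            pd.testing.assert_series_equal(out.data[c], expected)

    def test_zero_total_channel_errors(self):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            {"WT_1": [0.0, 0.0], "WT_2": [1.0, 2.0], "POOL_1": [1.0, 1.0]},
            index=["p1", "p2"],
        )
        with pytest.raises(ValidationError, match="WT_1"):
            normalize_within_plex(AbundanceMatrix(data), sheet)

    def test_wrong_state_rejected(self):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            {"WT_1": [1.0], "WT_2": [1.0], "POOL_1": [1.0]}, index=["p1"]
        )
        m = AbundanceMatrix(data, state="bridge_scaled")
        with pytest.raises(StateError):
            normalize_within_plex(m, sheet)

    def test_within_channel_ratios_invariant(self, noisy_study):
        matrix, sheet, _ = noisy_study
        out = normalize_within_plex(matrix, sheet)
        col = "WT_1"
        before = matrix.data[col]
        after = out.data[col]
        ratio_before = before.iloc[0] / before.iloc[1]
        ratio_after = after.iloc[0] / after.iloc[1]
        assert ratio_after == pytest.approx(ratio_before)


def bridge_sheet():
    return SampleSheet(
        [
            SampleMeta("WT_1", "WT", 1, "plex1", "ch01"),
            SampleMeta("POOL_1", "POOL", 1, "plex1", "ch02"),
            SampleMeta("WT_2", "WT", 2, "plex2", "ch01"),
            SampleMeta("POOL_2", "POOL", 2, "plex2", "ch02"),
        ]
    )


class TestBridgeScale:
    def matrix(self, pool1, pool2):
        data = pd.DataFrame(
            {
                "WT_1": [10.0],
                "POOL_1": [pool1],
                "WT_2": [20.0],
                "POOL_2": [pool2],
            },
            index=["p1"],
        )
        return AbundanceMatrix(data, state="within_plex_normalized")

    def test_geometric_mean_closed_form(self):
        out = bridge_scale(self.matrix(50.0, 100.0), bridge_sheet())
        # geomean(50,100)=70.711; plex1 x sqrt2, plex2 x 1/sqrt2
        assert out.data.at["p1", "POOL_1"] == pytest.approx(np.sqrt(5000))
        assert out.data.at["p1", "POOL_2"] == pytest.approx(np.sqrt(5000))
        assert out.data.at["p1", "WT_1"] == pytest.approx(10 * np.sqrt(2))
        assert out.data.at["p1", "WT_2"] == pytest.approx(20 / np.sqrt(2))
        assert out.state == "bridge_scaled"

    def test_equal_pools_identity(self):
        m = self.matrix(70.0, 70.0)
        out = bridge_scale(m, bridge_sheet())
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_idempotent(self):
        m = self.matrix(50.0, 100.0)
        once = bridge_scale(m, bridge_sheet())
        again = bridge_scale(once.with_data(once.data, state="within_plex_normalized"), bridge_sheet())
        pd.testing.assert_frame_equal(once.data, again.data)

    def test_missing_pool_errors(self):
        m = self.matrix(np.nan, 100.0)
        with pytest.raises(ValidationError, match="filter_pooled_missing"):
            bridge_scale(m, bridge_sheet())

    def test_requires_normalized_state(self):
        m = self.matrix(50.0, 100.0)
        m.state = "raw"
        with pytest.raises(StateError):
            bridge_scale(m, bridge_sheet())

    def test_recovers_planted_plex_shift_exactly(self):
        base = SimulationConfig(
            n_proteins=40, frac_up=0, frac_down=0, noise_cv=0,
            coisolation_rho=0, seed=13, plex_shift_log2=0.0,
        )
        shifted = SimulationConfig(
            n_proteins=40, frac_up=0, frac_down=0, noise_cv=0,
            coisolation_rho=0, seed=13, plex_shift_log2=1.5,
        )
        m0, sheet, _ = simulate_study(base)
        m1, _, _ = simulate_study(shifted)
        r0 = bridge_scale(normalize_within_plex(m0, sheet), sheet)
        r1 = bridge_scale(normalize_within_plex(m1, sheet), sheet)
        assert np.allclose(r0.data.to_numpy(), r1.data.to_numpy(), rtol=1e-12)


class TestFilterPooledMissing:
    def frame(self):
        return pd.DataFrame(
            {
                "WT_1": [1.0, 2.0, 3.0],
                "POOL_1": [5.0, np.nan, 0.0],
                "WT_2": [1.0, 2.0, 3.0],
                "POOL_2": [6.0, 7.0, 8.0],
            },
            index=["keep", "missing_pool", "zero_pool"],
        )

    def test_missing_in_one_plex_excluded(self):
        m = AbundanceMatrix(self.frame())
        out, excluded = filter_pooled_missing(m, bridge_sheet())
        assert excluded == ["missing_pool", "zero_pool"]
        assert list(out.data.index) == ["keep"]

    def test_all_missing_boundary(self):
        df = self.frame()
        df["POOL_1"] = np.nan
        out, excluded = filter_pooled_missing(AbundanceMatrix(df), bridge_sheet())
        assert len(out.data) == 0
        assert excluded == ["keep", "missing_pool", "zero_pool"]


class TestGrubbs:
    def test_planted_outlier_example(self):
        res = grubbs_test([1, 1, 1, 1, 10], alpha=0.05)
        assert res.G == pytest.approx(1.7889, abs=1e-4)
        assert res.G_crit == pytest.approx(1.715, abs=1e-3)
        assert res.outlier_index == 4

    def test_no_outlier_example(self):
        res = grubbs_test([1, 2, 3, 4, 5], alpha=0.05)
        assert res.G == pytest.approx(1.2649, abs=1e-4)
        assert res.outlier_index is None

    def test_zero_variance(self):
        res = grubbs_test([3, 3, 3])
        assert res.G == 0.0
        assert res.outlier_index is None

    def test_n_too_small(self):
        with pytest.raises(ValidationError):
            grubbs_test([1, 2])

    @pytest.mark.parametrize("n", range(3, 31))
    def test_critical_values_match_t_quantile_oracle(self, n):
        for alpha in (0.01, 0.05, 0.1):
            assert grubbs_critical(n, alpha) == pytest.approx(
                grubbs_crit_reference(n, alpha), abs=1e-9
            )

    def test_flag_iff_G_exceeds_crit(self, rng):
        for _ in range(200):
            x = rng.normal(0, 1, rng.integers(3, 10))
            if x.std(ddof=1) == 0:
                continue
            res = grubbs_test(x, alpha=0.1)
            assert (res.outlier_index is not None) == (res.G > res.G_crit)


class TestApplyGrubbs:
    def test_planted_outlier_removed(self):
        cfg = SimulationConfig(
            n_proteins=60, frac_up=0, frac_down=0, noise_cv=0.05,
            outlier_rate=0.01, outlier_factor=10.0, seed=17,
        )
        matrix, sheet, truth = simulate_study(cfg)
        m = normalize_within_plex(matrix, sheet)
        m, _ = filter_pooled_missing(m, sheet)
        m = bridge_scale(m, sheet)
        cleaned, ledger = apply_grubbs(m, sheet, alpha=0.05)
        planted = {(r, c) for r, c in truth.outlier_cells}
        flagged = set(zip(ledger["protein"], ledger["sample"]))
        assert planted <= flagged
        for row, col in planted:
            assert np.isnan(cleaned.data.at[row, col])

    def test_null_flag_rate_bounded(self):
        cfg = SimulationConfig(
            n_proteins=400, frac_up=0, frac_down=0, noise_cv=0.2, seed=23,
        )
        matrix, sheet, _ = simulate_study(cfg)
        m = bridge_scale(
            *(filter_pooled_missing(normalize_within_plex(matrix, sheet), sheet)[0],),
            sheet,
        )
        _, ledger = apply_grubbs(m, sheet, alpha=0.05)
        n_sets = 400 * 5
        rate = len(ledger) / n_sets
        se = np.sqrt(0.05 * 0.95 / n_sets)
        assert rate <= 0.05 + 3 * se

    def test_small_groups_skipped(self):
        sheet = SampleSheet(
            [
                SampleMeta("WT_1", "WT", 1, "plex1", "ch01"),
                SampleMeta("WT_2", "WT", 2, "plex1", "ch02"),
                SampleMeta("POOL_1", "POOL", 1, "plex1", "ch03"),
            ]
        )
        data = pd.DataFrame(
            {"WT_1": [1.0], "WT_2": [100.0], "POOL_1": [1.0]}, index=["p1"]
        )
        m = AbundanceMatrix(data, state="bridge_scaled")
        cleaned, ledger = apply_grubbs(m, sheet)
        assert len(ledger) == 0
        pd.testing.assert_frame_equal(cleaned.data, data)


class TestFilterMinPeptides:
    def matrix(self):
        data = pd.DataFrame(
            {"WT_1": [1.0, 2.0, 3.0], "WT_2": [1.0, 2.0, 3.0], "POOL_1": [1.0, 2.0, 3.0]},
            index=["one_pep", "two_pep", "five_pep"],
        )
        return AbundanceMatrix(data)

    def test_below_threshold_excluded(self):
        counts = {"one_pep": 1, "two_pep": 2, "five_pep": 5}
        out, excluded = filter_min_peptides(self.matrix(), counts, 2)
        assert excluded == ["one_pep"]
        assert list(out.data.index) == ["two_pep", "five_pep"]

    def test_boundary_retained(self):
        counts = {"one_pep": 2, "two_pep": 2, "five_pep": 2}
        _, excluded = filter_min_peptides(self.matrix(), counts, 2)
        assert excluded == []

    def test_min_zero_identity(self):
        counts = {"one_pep": 0, "two_pep": 0, "five_pep": 0}
        out, excluded = filter_min_peptides(self.matrix(), counts, 0)
        assert excluded == []
        assert len(out.data) == 3

    def test_negative_count_rejected(self):
        counts = {"one_pep": -1, "two_pep": 2, "five_pep": 5}
        with pytest.raises(ValidationError):
            filter_min_peptides(self.matrix(), counts, 2)


class TestRollup:
    def test_razor_assignment(self):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            {
                "WT_1": [1.0, 2.0, 4.0, 8.0],
                "WT_2": [1.0, 2.0, 4.0, 8.0],
                "POOL_1": [1.0, 2.0, 4.0, 8.0],
            },
            index=["uniqA1", "uniqA2", "uniqB1", "shared"],
        )
        mapping = {
            "uniqA1": {"protA"},
            "uniqA2": {"protA"},
            "uniqB1": {"protB"},
            "shared": {"protA", "protB"},
        }
        m = AbundanceMatrix(data, level="peptide")
        prot, counts = rollup_proteins(m, mapping)
        # protA has 2 unique peptides vs protB's 1 -> razor goes to protA
        assert prot.data.at["protA", "WT_1"] == 1 + 2 + 8
        assert prot.data.at["protB", "WT_1"] == 4
        assert counts["protA"] == 3
        assert counts["protB"] == 1

    def test_tie_breaks_lexicographically(self):
        sheet = two_channel_sheet()
        data = pd.DataFrame(
            {"WT_1": [1.0, 2.0, 4.0], "WT_2": [1.0, 2.0, 4.0], "POOL_1": [1.0, 2.0, 4.0]},
            index=["uniqA", "uniqB", "shared"],
        )
        mapping = {"uniqA": {"pA"}, "uniqB": {"pB"}, "shared": {"pA", "pB"}}
        prot, _ = rollup_proteins(AbundanceMatrix(data, level="peptide"), mapping)
        assert prot.data.at["pA", "WT_1"] == 1 + 4
        assert prot.data.at["pB", "WT_1"] == 2
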