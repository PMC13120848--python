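"""FSHD composite scoring, Livak relative expression, and normalization."""

import numpy as np
import pandas as pd
import pytest
from dux4kit.scoring import (
    CtTable,
    NanoStringRun,
    fshd_composite,
    geometric_mean_composite,
    nanostring_normalize,
    relative_expression_ddct,
)
from conftest import make_ct_table


class TestFshdComposite:
    def test_identical_treated_and_mock_give_100(self):
        table = make_ct_table([30, 31, 32, 33], [30, 31, 32, 33], [20, 21], [20, 21])
        res = fshd_composite(table, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        assert res.per_sample["composite_percent"].tolist() == [100.0, 100.0]

    def test_two_cycle_knockdown_gives_25_percent(self):
        table = make_ct_table([32, 33, 34, 35], [30, 31, 32, 33], [20, 21], [20, 21])
        res = fshd_composite(table, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        treated = res.per_sample.loc["treated_0"]
        assert treated["delta_delta_ct"] == pytest.approx(2.0)
        assert treated["composite_percent"] == pytest.approx(25.0)

    def test_hand_evaluated_four_gene_example(self):
        # treated dCt = 31.5 - 20.5 = 11; mock dCt = 29.5 - 20.5 = 9 -> 25%
        table = make_ct_table([30, 31, 32, 33], [28, 29, 30, 31], [20, 21], [20, 21])
        res = fshd_composite(table, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        per = res.per_sample
        assert per.loc["treated_0", "delta_ct"] == pytest.approx(11.0)
        assert per.loc["mock_0", "delta_ct"] == pytest.approx(9.0)
        assert per.loc["treated_0", "composite_percent"] == pytest.approx(25.0)

    def test_multiplicative_in_added_target_cycles(self, rng):
        """Adding c cycles to treated target Cts scales the composite by 2^-c."""
        base = make_ct_table([30, 31, 32, 33], [28, 29, 30, 31], [20, 21], [20, 21])
        c = 1.7
        shifted_ct = base.ct.copy()
        treated_rows = base.condition == "treated"
        shifted_ct.loc[treated_rows, ["T1", "T2", "T3", "T4"]] += c
        shifted = CtTable(ct=shifted_ct, condition=base.condition, group=base.group)
        r0 = fshd_composite(base, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        r1 = fshd_composite(shifted, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        assert r1.per_sample.loc["treated_0", "composite_percent"] == pytest.approx(
            r0.per_sample.loc["treated_0", "composite_percent"] * 2.0**-c
        )

    def test_invariant_to_global_ct_shift(self):
        base = make_ct_table([30, 31, 32, 33], [28, 29, 30, 31], [20, 21], [20, 21])
        shifted = CtTable(ct=base.ct + 3.25, condition=base.condition, group=base.group)
        r0 = fshd_composite(base, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        r1 = fshd_composite(shifted, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        pd.testing.assert_series_equal(
            r0.per_sample["composite_percent"], r1.per_sample["composite_percent"]
        )

    def test_missing_gene_column_is_schema_error(self):
        table = make_ct_table([30, 31, 32, 33], [30, 31, 32, 33], [20, 21], [20, 21])
        with pytest.raises(KeyError, match="T9"):
            fshd_composite(table, ["T1", "T2", "T3", "T9"], ["H1", "H2"])

    def test_undetermined_ct_excluded_with_warning(self):
        table = make_ct_table([30, 31, 32, 33], [30, 31, 32, 33], [20, 21], [20, 21], n_reps=2)
        table.ct.loc["treated_1", "T1"] = np.nan
        with pytest.warns(UserWarning, match="undetermined"):
            res = fshd_composite(table, ["T1", "T2", "T3", "T4"], ["H1", "H2"])
        assert "treated_1" not in res.per_sample.index

    def test_undetermined_ct_strict_mode_raises(self):
        table = make_ct_table([30, 31, 32, 33], [30, 31, 32, 33], [20, 21], [20, 21])
        table.ct.loc["treated_0", "T1"] = np.nan
        with pytest.raises(ValueError, match="undetermined"):
            fshd_composite(table, ["T1", "T2", "T3", "T4"], ["H1", "H2"], strict=True)


class TestRelativeExpressionDdct:
    def test_control_sample_at_group_mean_scores_one(self):
        table = make_ct_table([30, 31, 32, 33], [30, 31, 32, 33], [20, 21], [20, 21])
        rel = relative_expression_ddct(table, "T1", "H1", control_group="mock")
        assert rel.loc["mock_0"] == pytest.approx(1.0)

    def test_one_cycle_drop_doubles_expression(self):
        table = make_ct_table([29, 31, 32, 33], [30, 31, 32, 33], [20, 21], [20, 21])
        rel = relative_expression_ddct(table, "T1", "H1", control_group="mock")
        assert rel.loc["treated_0"] == pytest.approx(2.0)

    def test_matches_spreadsheet_recomputation(self, rng):
        n = 12
        ct = pd.DataFrame(
            {"G": rng.normal(28, 2, n), "R": rng.normal(20, 0.5, n)},
            index=[f"s{i}" for i in range(n)],
        )
        group = pd.Series(["ctrl"] * 6 + ["dose"] * 6, index=ct.index)
        table = CtTable(ct=ct, condition=group.rename("condition"), group=group)
        rel = relative_expression_ddct(table, "G", "R", control_group="ctrl")
        # independent cell-by-cell recomputation of the Livak formula
        dct = ct["G"] - ct["R"]
        ref = dct[group == "ctrl"].mean()
        for s in ct.index:
            assert rel.loc[s] == pytest.approx(2.0 ** -(dct[s] - ref), abs=1e-9)


class TestGeometricMeanComposite:
    def _panel(self, values, groups):
        panel = pd.DataFrame(values, columns=["A", "B"])
        panel.index = [f"s{i}" for i in range(len(values))]
        return panel, pd.Series(groups, index=panel.index)

    def test_two_gene_geometric_mean(self):
        panel, group = self._panel([[1, 4], [1, 4]], ["veh", "dose"])
        comp = geometric_mean_composite(panel, group, ["A", "B"], "veh")
        assert comp.loc["s1"] == pytest.approx(100.0)  # gm 2 vs reference gm 2

    def test_reference_group_averages_100(self, rng):
        values = rng.lognormal(1, 0.4, size=(9, 2))
        panel, group = self._panel(values, ["veh"] * 4 + ["dose"] * 5)
        comp = geometric_mean_composite(panel, group, ["A", "B"], "veh")
        assert comp[group == "veh"].mean() == pytest.approx(100.0)

    def test_matches_log_space_oracle(self, rng):
        values = rng.lognormal(2, 0.5, size=(12, 2))
        panel, group = self._panel(values, ["veh"] * 4 + ["lo"] * 4 + ["hi"] * 4)
        comp = geometric_mean_composite(panel, group, ["A", "B"], "veh")
        gm = np.exp(np.log(values).mean(axis=1))
        expected = 100.0 * gm / gm[:4].mean()
        np.testing.assert_allclose(comp.to_numpy(), expected, atol=1e-9)

    def test_zero_value_without_floor_rejected(self):
        panel, group = self._panel([[0, 4], [1, 4]], ["veh", "dose"])
        with pytest.raises(ValueError, match="floor"):
            geometric_mean_composite(panel, group, ["A", "B"], "veh", floor=0.0)
        comp = geometric_mean_composite(panel, group, ["A", "B"], "veh", floor=0.5)
        assert np.isfinite(comp).all()


def make_run(counts: pd.DataFrame, calibrator=None) -> NanoStringRun:
    classes = {}
    for p in counts.columns:
        if p.startswith("POS"):
            classes[p] = "positive"
        elif p.startswith("HK"):
            classes[p] = "housekeeping"
        elif p.startswith("DUX4"):
            classes[p] = "dux4"
        else:
            classes[p] = "endogenous"
    return NanoStringRun(counts=counts, probe_class=classes, calibrator=calibrator)


class TestNanostringNormalize:
    def test_positive_control_factors_match_hand_computation(self):
        # per-sample positive-control geomeans 100 (A) and 200 (B);
        # platform geomean sqrt(100*200) -> A scaled x1.414..., B x0.707...
        from dux4kit.scoring import _content_factors

        counts = pd.DataFrame(
            {"POS1": [100.0, 200.0], "POS2": [100.0, 200.0]}, index=["A", "B"]
        )
        factors = _content_factors(counts, ["POS1", "POS2"])
        assert factors.loc["A"] == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert factors.loc["B"] == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-9)

    def test_flat_run_is_unchanged(self):
        counts = pd.DataFrame(
            {"POS1": [100.0, 100.0], "POS2": [80.0, 80.0], "HK1": [50.0, 50.0],
             "E1": [7.0, 7.0]},
            index=["A", "B"],
        )
        res = nanostring_normalize(make_run(counts))
        pd.testing.assert_frame_equal(res.normalized, counts)

    def test_dux4_signal_is_mean_of_three_probes(self):
        counts = pd.DataFrame(
            {"POS1": [100.0], "POS2": [100.0], "HK1": [50.0],
             "DUX4_1": [3.0], "DUX4_2": [4.0], "DUX4_3": [5.0]},
            index=["A"],
        )
        res = nanostring_normalize(make_run(counts))
        assert res.dux4_signal.loc["A"] == pytest.approx(4.0)

    def test_idempotent(self, rng):
        counts = pd.DataFrame(
            rng.lognormal(4, 0.5, size=(4, 5)),
            index=list("ABCD"),
            columns=["POS1", "POS2", "HK1", "E1", "E2"],
        )
        cal = pd.Series([True, True, False, False], index=list("ABCD"))
        once = nanostring_normalize(make_run(counts, cal)).normalized
        twice = nanostring_normalize(make_run(once, cal)).normalized
        pd.testing.assert_frame_equal(twice, once)

    def test_requires_two_positive_controls(self):
        counts = pd.DataFrame({"POS1": [1.0], "HK1": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="positive"):
            make_run(counts)

    def test_zero_positive_geomean_rejected(self):
        counts = pd.DataFrame(
            {"POS1": [0.0, 10.0], "POS2": [5.0, 10.0], "HK1": [5.0, 5.0]},
            index=["A", "B"],
        )
        with pytest.raises(ValueError, match="geometric mean"):
            nanostring_normalize(make_run(counts))
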