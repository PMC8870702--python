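"""Replicate aggregation and delta-Ct normalization against dual controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import adrenomir as am
from adrenomir.containers import CtTable


def ct_table_from_summary(summary: dict, group="ACA"):
    """Build a single-replicate CtTable from {sample: {assay: ct}}."""
    rows = []
    for sample, assays in summary.items():
        for assay, ct in assays.items():
            rows.append((sample, group, assay, 1, ct))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "assay",
                                     "replicate", "ct"])
    return CtTable(data=df)


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "reps, expected",
        [
            ((30.0, 30.2, 30.4), 30.2),          # plain mean
            ((31.0, np.nan, np.nan), 31.0),      # single surviving replicate
            ((np.nan, np.nan, np.nan), np.nan),  # all wells undetermined
        ],
    )
    def test_mean_over_surviving_replicates(self, reps, expected):
        rows = [("S1", "ACA", "hsa-miR-195", i + 1, v) for i, v in enumerate(reps)]
        rows += [("S1", "ACA", c, 1, 25.0) for c in ("RNU48", "cel-miR-39")]
        table = CtTable(pd.DataFrame(
            rows, columns=["sample_id", "group", "assay", "replicate", "ct"]))
        out = am.aggregate_replicates(table, "mean")
        got = out.loc["S1", "hsa-miR-195"]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_median_policy(self):
        rows = [("S1", "ACA", "hsa-miR-195", i + 1, v)
                for i, v in enumerate((30.0, 30.1, 39.0))]
        rows += [("S1", "ACA", c, 1, 25.0) for c in ("RNU48", "cel-miR-39")]
        table = CtTable(pd.DataFrame(
            rows, columns=["sample_id", "group", "assay", "replicate", "ct"]))
        assert am.aggregate_replicates(table, "median").loc["S1", "hsa-miR-195"] \
            == pytest.approx(30.1)


class TestNormalizeDeltaCt:
    def test_equal_controls_reduce_to_plain_delta_ct(self):
        table = ct_table_from_summary(
            {"S1": {"hsa-miR-195": 28.0, "RNU48": 25.0, "cel-miR-39": 25.0}})
        em = am.normalize_delta_ct(am.aggregate_replicates(table))
        assert em.values.loc["S1", "hsa-miR-195"] == pytest.approx(-3.0)

    def test_target_equal_to_reference_gives_zero(self):
        table = ct_table_from_summary(
            {"S1": {"hsa-miR-195": 25.0, "RNU48": 25.0, "cel-miR-39": 25.0}})
        em = am.normalize_delta_ct(am.aggregate_replicates(table))
        assert em.values.loc["S1", "hsa-miR-195"] == pytest.approx(0.0)

    def test_geometric_mean_reference_hand_value(self):
        # control_ref = sqrt(24 * 26) = 24.979992..., value = -(30 - ref)
        table = ct_table_from_summary(
            {"S1": {"hsa-miR-195": 30.0, "RNU48": 24.0, "cel-miR-39": 26.0}})
        em = am.normalize_delta_ct(am.aggregate_replicates(table))
        assert em.values.loc["S1", "hsa-miR-195"] == pytest.approx(-5.0200, abs=5e-5)
        assert em.control_ref.loc["S1"] == pytest.approx(np.sqrt(24 * 26), abs=1e-12)

    def test_controls_never_appear_as_features(self, discovery_matrix):
        assert "RNU48" not in discovery_matrix.assay_ids
        assert "cel-miR-39" not in discovery_matrix.assay_ids

    def test_missing_control_names_the_sample(self):
        table = ct_table_from_summary({
            "S1": {"hsa-miR-195": 30.0, "RNU48": np.nan, "cel-miR-39": 26.0},
            "S2": {"hsa-miR-195": 30.0, "RNU48": 24.0, "cel-miR-39": 26.0},
        })
        with pytest.raises(ValueError, match="S1"):
            am.normalize_delta_ct(am.aggregate_replicates(table))

    def test_shift_invariance_with_equal_controls(self):
        # shifting target and both (equal) controls by the same constant
        # leaves the normalized value unchanged
        base = ct_table_from_summary(
            {"S1": {"hsa-miR-195": 28.0, "RNU48": 25.0, "cel-miR-39": 25.0}})
        shifted = ct_table_from_summary(
            {"S1": {"hsa-miR-195": 31.0, "RNU48": 28.0, "cel-miR-39": 28.0}})
        v0 = am.normalize_delta_ct(am.aggregate_replicates(base))
        v1 = am.normalize_delta_ct(am.aggregate_replicates(shifted))
        assert v0.values.loc["S1", "hsa-miR-195"] == pytest.approx(
            v1.values.loc["S1", "hsa-miR-195"], abs=1e-12)

    def test_value_strictly_decreasing_in_target_ct(self):
        values = []
        for ct in (26.0, 28.0, 30.0):
            table = ct_table_from_summary(
                {"S1": {"hsa-miR-195": ct, "RNU48": 24.0, "cel-miR-39": 26.0}})
            em = am.normalize_delta_ct(am.aggregate_replicates(table))
            values.append(em.values.loc["S1", "hsa-miR-195"])
        assert values[0] > values[1] > values[2]

    @given(
        cts=arrays(np.float64, (5, 5),
                   elements=st.floats(min_value=15.0, max_value=39.0)),
        controls=arrays(np.float64, (5, 2),
                        elements=st.floats(min_value=18.0, max_value=30.0)),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_oracle_equivalence_one_line_formula(self, cts, controls):
        """values == -(Ct - sqrt(c1*c2)) to 1e-12 on random 5x5 tables."""
        samples = [f"S{i}" for i in range(5)]
        targets = [f"m{j}" for j in range(5)]
        summary = pd.DataFrame(cts, index=samples, columns=targets)
        summary["RNU48"] = controls[:, 0]
        summary["cel-miR-39"] = controls[:, 1]
        em = am.normalize_delta_ct(summary,
                                   groups=pd.Series("ACA", index=samples))
        expected = -(cts - np.sqrt(controls[:, 0] * controls[:, 1])[:, None])
        np.testing.assert_allclose(em.values.to_numpy(), expected,
                                   atol=1e-12, rtol=0)

    def test_arithmetic_mean_reference_option(self):
        table = ct_table_from_summary(
            {"S1": {"hsa-miR-195": 30.0, "RNU48": 24.0, "cel-miR-39": 26.0}})
        em = am.normalize_delta_ct(am.aggregate_replicates(table),
                                   control_mean="arithmetic")
        assert em.values.loc["S1", "hsa-miR-195"] == pytest.approx(-5.0)


class TestMissingPolicy:
    def _matrix_with_gap(self):
        samples = ["S1", "S2"]
        values = pd.DataFrame(
            {"hsa-miR-7": [np.nan, -4.0], "hsa-miR-503": [1.0, 2.0]},
            index=samples)
        return am.ExpressionMatrix(
            values=values,
            groups=pd.Series("ACA", index=samples),
            control_ref=pd.Series([25.0, 25.0], index=samples),
        )

    def test_omit_feature_drops_the_marker(self):
        out = am.apply_missing_policy(self._matrix_with_gap(), "omit_feature")
        assert out.assay_ids == ["hsa-miR-503"]

    def test_fully_observed_matrix_unchanged_under_both_policies(self, discovery_matrix):
        for policy in ("omit_feature", "censor_fill"):
            out = am.apply_missing_policy(discovery_matrix, policy)
            pd.testing.assert_frame_equal(out.values, discovery_matrix.values)

    def test_censor_fill_uses_detection_floor(self):
        out = am.apply_missing_policy(self._matrix_with_gap(), "censor_fill",
                                      ct_max=40.0)
        # floor = -(40 - 25) = -15
        assert out.values.loc["S1", "hsa-miR-7"] == pytest.approx(-15.0)
        assert out.values.loc["S2", "hsa-miR-7"] == pytest.approx(-4.0)
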