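"""Crt matrix model, replicate QC, detection filter, and normalizations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import build_matrix
from xenomir.errors import ConfigError, InputError
from xenomir.qpcr import (
    CrtMatrix,
    filter_by_detection,
    load_crt_table,
    make_sample_name,
    normalize_geomean,
    normalize_quantile,
    normalize_single_ref,
    parse_sample_name,
    qc_replicates,
    select_invariant_features,
)


class TestSampleNames:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("P_1_0", ("plasma", 1, "T0")),
            ("P_4_3", ("plasma", 4, "T3")),
            ("C_1_0", ("pbmc", 1, "T0")),
            ("C_5_6", ("pbmc", 5, "T6")),
        ],
    )
    def test_parse_convention(self, name, expected):
        assert parse_sample_name(name) == expected

    @pytest.mark.parametrize("bad", ["X_1_0", "P_1", "P_a_0", "plasma_1_0"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(InputError):
            parse_sample_name(bad)

    def test_roundtrip(self):
        assert make_sample_name(*parse_sample_name("C_3_6")) == "C_3_6"


class TestCrtMatrix:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[20.0, 21.0]], index=["f"], columns=["P_1_0", "P_1_0"])
        with pytest.raises(InputError):
            CrtMatrix(df)

    def test_out_of_range_rejected(self):
        df = pd.DataFrame([[20.0, 46.0]], index=["f"], columns=["P_1_0", "P_1_3"])
        with pytest.raises(InputError):
            CrtMatrix(df)

    def test_csv_roundtrip(self, tmp_path, paired_matrix):
        m = paired_matrix
        m.values.iloc[0, 0] = np.nan
        m = CrtMatrix(m.values)
        path = tmp_path / "crt.csv"
        m.to_csv(path)
        back = load_crt_table(path)
        pd.testing.assert_frame_equal(back.values, m.values)
        pd.testing.assert_frame_equal(back.meta, m.meta)

    def test_missing_tokens_become_nan(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("feature,P_1_0,P_1_3\nf1,20.5,Undetermined\nf2,,21.0\nf3,22.0,23.0\n")
        m = load_crt_table(path)
        assert m.values.isna().sum().sum() == 2

    def test_garbage_cell_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("feature,P_1_0,P_1_3\nf1,20.5,oops\n")
        with pytest.raises(InputError):
            load_crt_table(path)


class TestReplicateQC:
    @pytest.mark.parametrize(
        "cq,sd,flagged",
        [
            ((20, 20, 20), 0.0, False),
            ((36, 37, 38), 1.0, True),
            ((21.0, 21.2, 21.4), 0.2, False),
        ],
    )
    def test_sample_sd_and_flag(self, cq, sd, flagged):
        qc = qc_replicates(cq)
        assert qc.sd_cq == pytest.approx(sd)
        assert qc.flagged is flagged

    def test_single_value_rejected(self):
        with pytest.raises(InputError):
            qc_replicates([20.0])


class TestDetectionFilter:
    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(28, 2, size=(30, 10))
        mask = rng.random(vals.shape) < 0.25
        vals[mask] = np.nan
        m = build_matrix(vals)
        for k in (1, 5, 9, 10):
            kept = filter_by_detection(m, k)
            expected = [
                f for i, f in enumerate(m.features)
                if np.sum(~np.isnan(vals[i])) >= k
            ]
            assert kept.features == expected
            assert kept.samples == m.samples

    def test_fully_observed_unchanged(self, paired_matrix):
        assert filter_by_detection(paired_matrix, 10).features == paired_matrix.features

    def test_monotone_in_threshold(self, paired_matrix):
        vals = paired_matrix.values.copy()
        vals.iloc[0, :3] = np.nan
        vals.iloc[1, :1] = np.nan
        m = CrtMatrix(vals)
        prev = set(m.features)
        for k in range(1, 11):
            cur = set(filter_by_detection(m, k).features)
            assert cur <= prev
            prev = cur


class TestInvariantSelection:
    def test_smallest_sd_selected(self):
        # hand-set per-feature SDs via scaling a +/- pattern
        pattern = np.tile([-1.0, 1.0], 5)
        sds = [0.1, 0.4, 0.2, 0.3]
        vals = np.array([25.0 + s * pattern for s in sds])
        m = build_matrix(vals)
        assert select_invariant_features(m, 2) == ["miR-001", "miR-003"]

    def test_constant_feature_first(self, paired_matrix):
        vals = paired_matrix.values.copy()
        vals.iloc[2] = 25.0
        m = CrtMatrix(vals)
        assert select_invariant_features(m, 1) == [m.features[2]]

    def test_requires_enough_full_features(self, paired_matrix):
        vals = paired_matrix.values.copy()
        vals.iloc[:, 0] = np.nan
        with pytest.raises(InputError):
            select_invariant_features(CrtMatrix(vals), 1)


def _geomean(v):
    return float(np.exp(np.mean(np.log(v))))


class TestGeomeanNormalization:
    def test_hand_computed_2x2(self):
        m = build_matrix([[16.0, 25.0], [25.0, 16.0]], donors=1, timepoints=("T0", "T3"))
        normed = normalize_geomean(m, ["miR-001", "miR-002"])
        gms = np.array([_geomean([16, 25]), _geomean([25, 16])])
        corrections = gms - gms.mean()  # both 20 -> corrections 0
        assert np.allclose(corrections, 0)
        pd.testing.assert_frame_equal(normed.values, m.values)

    def test_hand_computed_correction(self):
        m = build_matrix([[20.0, 22.0], [30.0, 33.0]], donors=1)
        normed = normalize_geomean(m, ["miR-001"])
        gms = np.array([20.0, 22.0])
        c = gms - 21.0
        expected = m.values.to_numpy() - c
        assert np.allclose(normed.values.to_numpy(), expected)

    def test_singleton_equals_single_ref(self, paired_matrix):
        a = normalize_geomean(paired_matrix, ["miR-002"])
        b = normalize_single_ref(paired_matrix, "miR-002")
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_ref_geomean_equalized(self, paired_matrix):
        normed = normalize_geomean(paired_matrix, ["miR-001", "miR-002"])
        gms = np.exp(np.log(normed.values.loc[["miR-001", "miR-002"]]).mean(axis=0))
        # additive correction equalizes the ref geomean to second order
        assert gms.max() - gms.min() < 1e-2

    def test_idempotent(self, paired_matrix):
        once = normalize_geomean(paired_matrix, ["miR-001", "miR-002"])
        twice = normalize_geomean(once, ["miR-001", "miR-002"])
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-2)

    def test_missing_ref_rejected(self, paired_matrix):
        vals = paired_matrix.values.copy()
        vals.loc["miR-001", vals.columns[0]] = np.nan
        with pytest.raises(InputError):
            normalize_geomean(CrtMatrix(vals), ["miR-001"])


class TestSingleRefNormalization:
    def test_ref_becomes_constant_and_idempotent(self, paired_matrix):
        normed = normalize_single_ref(paired_matrix, "miR-001")
        ref = normed.values.loc["miR-001"]
        assert np.allclose(ref, ref.iloc[0])
        again = normalize_single_ref(normed, "miR-001")
        pd.testing.assert_frame_equal(
            normed.values, again.values, atol=1e-12, rtol=0
        )

    def test_shift_equivariance(self):
        base = np.array([[25.0] * 4, [27.0] * 4, [30.0] * 4])
        m0 = build_matrix(base, donors=2)
        shifted = base.copy()
        shifted[:, 1] += 1.0  # whole sample shifted one cycle later
        m1 = build_matrix(shifted, donors=2)
        n0 = normalize_single_ref(m0, "miR-001")
        n1 = normalize_single_ref(m1, "miR-001")
        # identical up to the global centering constant (+1/4 cycle here)
        delta = (n1.values - n0.values).to_numpy()
        assert np.allclose(delta, delta.flat[0])
        assert delta.flat[0] == pytest.approx(0.25)

    def test_three_sample_delta_crt_arithmetic(self):
        vals = np.array([[20.0, 21.0, 19.5], [28.0, 30.0, 27.0]])
        m = build_matrix(vals, donors=3, timepoints=("T0",))
        normed = normalize_single_ref(m, "miR-001")
        ref = vals[0]
        expected = vals - (ref - ref.mean())
        assert np.allclose(normed.values.to_numpy(), expected)


class TestQuantileNormalization:
    def test_identical_samples_unchanged(self):
        col = np.array([20.0, 24.0, 28.0])
        m = build_matrix(np.tile(col[:, None], 4), donors=2)
        q = normalize_quantile(m)
        assert np.allclose(q.values.to_numpy(), m.values.to_numpy())

    def test_monotone_transform_collapses(self):
        a = np.array([20.0, 24.0, 28.0, 31.0])
        b = 2.0 + 1.1 * a  # strictly monotone transform, ranks preserved
        m = build_matrix(np.column_stack([a, b]), donors=1)
        q = normalize_quantile(m)
        assert np.allclose(q.values.iloc[:, 0], q.values.iloc[:, 1])

    def test_hand_computed_3x3(self):
        vals = np.array([[2.0, 4.0, 3.0], [6.0, 8.0, 9.0], [10.0, 12.0, 15.0]])
        # order-statistic means: (2+4+3)/3=3, (6+8+9)/3=23/3, (10+12+15)/3=37/3
        m = build_matrix(vals + 18.0, donors=3, timepoints=("T0",))
        q = normalize_quantile(m)
        ref = np.array([3.0, 23.0 / 3.0, 37.0 / 3.0]) + 18.0
        for j in range(3):
            assert np.allclose(np.sort(q.values.iloc[:, j]), ref)

    def test_sorted_vectors_identical_without_missing(self):
        rng = np.random.default_rng(11)
        m = build_matrix(rng.normal(27, 3, size=(40, 10)))
        q = normalize_quantile(m)
        arr = np.sort(q.values.to_numpy(), axis=0)
        assert np.allclose(arr, arr[:, [0]])

    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(27, 3, size=(20, 10))
        vals[0, 0] = np.nan
        m = build_matrix(vals)
        q = normalize_quantile(m)
        assert math.isnan(q.values.iloc[0, 0])
        assert q.values.notna().sum().sum() == m.values.notna().sum().sum()

    def test_needs_two_samples(self):
        m = build_matrix(np.array([[20.0], [25.0], [30.0]]), donors=1, timepoints=("T0",))
        with pytest.raises(InputError):
            normalize_quantile(m)


@given(st.integers(0, 2**32 - 1))
def test_normalizations_preserve_within_sample_ranks(seed):
    """All three normalizations are rank-preserving within each sample."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(27, 3, size=(12, 6))
    m = build_matrix(vals, donors=3)
    for normed in (
        normalize_geomean(m, ["miR-001", "miR-002"]),
        normalize_single_ref(m, "miR-003"),
        normalize_quantile(m),
    ):
        for col in m.samples:
            orig = m.values[col].rank()
            new = normed.values[col].rank()
            pd.testing.assert_series_equal(orig, new)
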