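import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenoplast.rdpi import (
    MixedSignError,
    build_index_matrix,
    family_difference_test,
    family_permutation_test,
    indices_per_family,
    relative_distance_index,
)
from conftest import make_table


def brute_force_index(ww, ws):
    """Independent oracle: explicit double loop over cross-treatment pairs."""
    vals = list(ww) + list(ws)
    if any(v > 0 for v in vals) and any(v < 0 for v in vals):
        raise ValueError("mixed sign")
    if all(v <= 0 for v in vals) and any(v < 0 for v in vals):
        ww = [-v for v in ww]
        ws = [-v for v in ws]
    rs = []
    for a in ws:
        for b in ww:
            if a + b > 0:
                rs.append(abs(a - b) / (a + b))
    if not rs:
        raise ValueError("no pairs")
    return sum(rs) / len(rs)


class TestRelativeDistanceIndex:
    def test_identical_values_give_zero(self):
        value, pairs = relative_distance_index([2, 2], [2, 2])
        assert value == 0.0
        assert pairs.n_pairs == 4

    def test_single_pair(self):
        value, _ = relative_distance_index([1], [3])
        assert value == 0.5

    def test_brute_force_frozen_example(self):
        # (0.5 + 0.6 + 0.2 + 1/3) / 4, enumerated by hand
        value, pairs = relative_distance_index([1, 2], [3, 4])
        assert value == pytest.approx((0.5 + 0.6 + 0.2 + 1 / 3) / 4)
        assert value == pytest.approx(0.4083333333333334)
        assert pairs.n_pairs == 4

    def test_negative_scale_sign_normalization(self):
        # d13C-like values: hand computation on negated values gives 2/54
        value, _ = relative_distance_index([-28], [-26])
        assert value == pytest.approx(2 / 54)

    def test_maximal_divergence_is_one(self):
        value, _ = relative_distance_index([0, 0], [3, 5])
        assert value == 1.0

    def test_mixed_sign_error(self):
        with pytest.raises(MixedSignError):
            relative_distance_index([-1, 2], [3])

    def test_empty_treatment_error(self):
        with pytest.raises(ValueError):
            relative_distance_index([], [1.0])

    def test_all_pairs_dropped_error(self):
        with pytest.raises(ValueError, match="dropped"):
            relative_distance_index([0.0], [0.0])

    def test_zero_denominator_pairs_dropped_not_imputed(self):
        value, pairs = relative_distance_index([0.0, 1.0], [0.0, 1.0])
        assert pairs.n_dropped == 1
        assert pairs.n_pairs == 3
        # pairs (0,1), (1,0) -> 1; (1,1) -> 0
        assert value == pytest.approx(2 / 3)

    positive_lists = st.lists(
        st.floats(0.01, 1e3, allow_nan=False, allow_infinity=False), min_size=1, max_size=6
    )

    @given(ww=positive_lists, ws=positive_lists)
    @settings(max_examples=100)
    def test_matches_brute_force_oracle(self, ww, ws):
        value, _ = relative_distance_index(ww, ws)
        assert value == pytest.approx(brute_force_index(ww, ws), abs=1e-12)

    @given(ww=positive_lists, ws=positive_lists)
    @settings(max_examples=60)
    def test_bounded_zero_one(self, ww, ws):
        value, _ = relative_distance_index(ww, ws)
        assert 0.0 <= value <= 1.0

    @given(ww=positive_lists, ws=positive_lists, scale=st.floats(0.001, 1e3))
    @settings(max_examples=60)
    def test_scale_invariant(self, ww, ws, scale):
        base, _ = relative_distance_index(ww, ws)
        scaled, _ = relative_distance_index([scale * v for v in ww], [scale * v for v in ws])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    @given(ww=positive_lists, ws=positive_lists)
    @settings(max_examples=60)
    def test_swap_invariant(self, ww, ws):
        a, _ = relative_distance_index(ww, ws)
        b, _ = relative_distance_index(ws, ww)
        assert a == pytest.approx(b, abs=1e-12)

    @given(ww=positive_lists, shift=st.floats(0.0, 100.0))
    @settings(max_examples=60)
    def test_monotone_in_divergence(self, ww, shift):
        ws = [max(ww) + 1.0] * 3
        base, _ = relative_distance_index(ww, ws)
        shifted, _ = relative_distance_index(ww, [v + shift for v in ws])
        assert shifted >= base - 1e-12


class TestIndicesPerFamily:
    def test_null_table_all_zero(self, null_table):
        for kind in ("PP", "RE"):
            im = indices_per_family(null_table, kind)
            assert np.allclose(im.matrix.to_numpy(), 0.0)

    def test_shape_contract_16_families(self, full_table):
        im = build_index_matrix(full_table)
        assert im.matrix.shape[0] == 16
        pp_cols = [c for c in im.matrix.columns if c.startswith("PP-")]
        re_cols = [c for c in im.matrix.columns if c.startswith("RE-")]
        stress_traits = set(full_table.subset(phase="stress")["trait"])
        assert len(pp_cols) == len(stress_traits)
        assert sorted(re_cols) == sorted(
            f"RE-{t}" for t in ("A_area", "A_mass", "g_wv", "iWUE", "Phi_PSII")
        )

    def test_values_in_unit_interval(self, full_table):
        im = build_index_matrix(full_table)
        vals = im.matrix.to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0

    def test_phase_separation(self):
        rows = []
        for i, v in enumerate([10.0, 12.0]):
            rows.append((f"w{i}", "1", 1, "WW", "stress", "A_area", v))
            rows.append((f"w{i}", "1", 1, "WW", "recovery", "A_area", 8.0))
        for i, v in enumerate([2.0, 3.0]):
            rows.append((f"s{i}", "1", 1, "WS", "stress", "A_area", v))
            rows.append((f"s{i}", "1", 1, "WS", "recovery", "A_area", 8.0))
        table = make_table(rows)
        pp = indices_per_family(table, "PP").matrix.loc["1", "PP-A_area"]
        re = indices_per_family(table, "RE").matrix.loc["1", "RE-A_area"]
        assert pp > 0.0
        assert re == 0.0

    def test_missing_treatment_flags_cell(self, caplog):
        rows = [
            ("w0", "1", 1, "WW", "stress", "A_area", 10.0),
            ("w1", "1", 1, "WS", "stress", "A_area", 5.0),
            ("w2", "2", 1, "WW", "stress", "A_area", 9.0),
        ]
        with caplog.at_level("WARNING"):
            im = indices_per_family(make_table(rows), "PP")
        assert np.isnan(im.matrix.loc["2", "PP-A_area"])
        assert "missing a treatment" in caplog.text

    def test_bootstrap_se_attached(self, sim_table):
        im = indices_per_family(sim_table, "PP", n_boot_se=50, seed=1)
        assert all(r.se is not None and r.se >= 0 for r in im.results)


class TestFamilyDifferenceTest:
    def test_nperm_zero_is_error(self, sim_table):
        with pytest.raises(ValueError, match="n_perm"):
            family_difference_test(sim_table, "A_area", "PP", n_perm=0)

    def test_single_family_error(self):
        rows = [
            ("w0", "1", 1, "WW", "stress", "A_area", 10.0),
            ("w1", "1", 1, "WW", "stress", "A_area", 11.0),
            ("s0", "1", 1, "WS", "stress", "A_area", 5.0),
            ("s1", "1", 1, "WS", "stress", "A_area", 6.0),
        ]
        with pytest.raises(ValueError, match="two families"):
            family_difference_test(make_table(rows), "A_area", "PP", n_perm=99)

    def test_too_few_pairs_error(self):
        rows = [
            ("w0", "1", 1, "WW", "stress", "A_area", 10.0),
            ("s0", "1", 1, "WS", "stress", "A_area", 5.0),
            ("w1", "2", 1, "WW", "stress", "A_area", 9.0),
            ("s1", "2", 1, "WS", "stress", "A_area", 4.0),
            ("s2", "2", 1, "WS", "stress", "A_area", 4.5),
        ]
        with pytest.raises(ValueError, match="fewer than 2"):
            family_difference_test(make_table(rows), "A_area", "PP", n_perm=99)

    def test_detects_planted_family_difference(self):
        rng = np.random.default_rng(0)
        # family A: no treatment effect; family B: strong effect
        ww_a = 10 + 0.1 * rng.standard_normal(5)
        ws_a = 10 + 0.1 * rng.standard_normal(5)
        ww_b = 10 + 0.1 * rng.standard_normal(5)
        ws_b = 2 + 0.1 * rng.standard_normal(5)
        ww = np.concatenate([ww_a, ww_b])
        ws = np.concatenate([ws_a, ws_b])
        fam_ww = np.array(["A"] * 5 + ["B"] * 5)
        fam_ws = np.array(["A"] * 5 + ["B"] * 5)
        stat, p = family_permutation_test(ww, fam_ww, ws, fam_ws, n_perm=999, seed=1)
        assert p <= 0.01
        assert stat > 10

    def test_p_value_reproducible_under_seed(self, sim_table):
        a = family_difference_test(sim_table, "A_area", "PP", n_perm=199, seed=4)
        b = family_difference_test(sim_table, "A_area", "PP", n_perm=199, seed=4)
        assert a == b
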