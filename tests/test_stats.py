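"""Differential testing, BH adjustment, exclusivity calls and Venn partitioning."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from fetometab.stats import (
    bh_adjust,
    call_presence,
    differential_test,
    venn_partition,
)

from conftest import make_table


def two_group_table(gf_vals, spf_vals, organ="brain"):
    """n-feature table with explicit GF and SPF values for one organ."""
    gf = np.atleast_2d(np.asarray(gf_vals, float))
    spf = np.atleast_2d(np.asarray(spf_vals, float))
    vals = np.hstack([gf, spf])
    return make_table(vals, n_qc=0, organs=(organ,))


class TestBhAdjust:
    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_p_stay_equal(self):
        q = bh_adjust([0.2] * 5)
        np.testing.assert_allclose(q, 0.2)

    def test_hand_stepped_up_vector(self):
        q = bh_adjust([0.001, 0.01, 0.1, 0.9])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.13333333333, 0.9], rtol=1e-9)

    def test_four_equal_spacing_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_nan_excluded_from_family_size(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, expected, atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_oracle_equivalence_property(self, pvals):
        """Brute-force step-up definition: q_i = min_{p_j >= p_i} m * p_j / rank(j)."""
        p = np.array(pvals)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        for i in range(m):
            rank_i = int(np.where(order == i)[0][0]) + 1
            candidates = [
                m * p[order[j]] / (j + 1) for j in range(rank_i - 1, m)
            ]
            assert q[i] == pytest.approx(min(min(candidates), 1.0), abs=1e-12)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)


class TestDifferentialTest:
    def test_identical_groups_give_zero_effect(self):
        vals = np.tile([[5.0, 6.0, 7.0]], (3, 2))
        t = two_group_table(vals[:, :3], vals[:, 3:])
        res = differential_test(t, "brain", log_transform=False)
        np.testing.assert_allclose(res["cohens_d"], 0.0)
        assert (res["direction"] == "none").all()

    def test_hand_pooled_variance_example(self):
        # GF [1,2,3] vs SPF [4,5,6]: means 2 and 5, pooled sd 1, d = -3
        t = two_group_table([[1, 2, 3]], [[4, 5, 6]])
        res = differential_test(t, "brain", log_transform=False).iloc[0]
        assert res["mean_gf"] == pytest.approx(2.0)
        assert res["mean_spf"] == pytest.approx(5.0)
        assert res["cohens_d"] == pytest.approx(-3.0)
        # t = -3 / sqrt(1/3 + 1/3)
        assert res["t_stat"] == pytest.approx(-3 / np.sqrt(2 / 3))

    def test_zero_pooled_variance_reports_missing_p(self):
        t = two_group_table([[1.0, 1.0, 1.0], [1, 2, 3]], [[1.0, 1.0, 1.0], [4, 5, 6]])
        res = differential_test(t, "brain", log_transform=False)
        assert np.isnan(res.iloc[0]["p"])
        # excluded from BH family: remaining feature adjusted with m = 1
        assert res.iloc[1]["q"] == pytest.approx(res.iloc[1]["p"])

    def test_sign_convention_spf_higher_is_negative(self, rng):
        gf = rng.normal(10, 1, (1, 12))
        spf = gf + 5
        res = differential_test(two_group_table(gf, spf), "brain", log_transform=False)
        assert res.iloc[0]["cohens_d"] < -0.8
        assert res.iloc[0]["direction"] == "spf_higher"

    def test_label_flip_negates_d_and_swaps_directions(self, rng):
        gf = rng.lognormal(8, 0.5, (20, 12))
        spf = rng.lognormal(8.3, 0.5, (20, 12))
        t1 = two_group_table(gf, spf)
        t2 = two_group_table(spf, gf)  # groups swapped
        r1 = differential_test(t1, "brain")
        r2 = differential_test(t2, "brain")
        np.testing.assert_allclose(r1["cohens_d"], -r2["cohens_d"], rtol=1e-9)
        np.testing.assert_allclose(r1["q"], r2["q"], rtol=1e-9)
        swap = {"spf_higher": "gf_higher", "gf_higher": "spf_higher", "none": "none"}
        assert list(r1["direction"].map(swap)) == list(r2["direction"])


def presence_fixture(rng, snr_spf, snr_gf, q, d, floor=1000.0):
    """One feature, one organ, with group means set to snr * floor."""
    gf_mean = snr_gf * floor if snr_gf > 0 else np.nan
    spf_mean = snr_spf * floor
    gf = np.full((1, 6), gf_mean)
    spf = np.full((1, 6), spf_mean)
    t = two_group_table(gf, spf)
    diff = pd.DataFrame(
        {"organ": ["brain"], "q": [q], "cohens_d": [d]},
        index=pd.Index(["F1"], name="feature_id"),
    )
    return call_presence(t, diff, floor).iloc[0]


class TestCallPresence:
    def test_exclusivity_rule_applied_verbatim(self, rng):
        row = presence_fixture(rng, snr_spf=8, snr_gf=2, q=0.01, d=-1.2)
        assert row["call"] == "spf_only"

    def test_both_above_threshold_is_both_regardless_of_stats(self, rng):
        row = presence_fixture(rng, snr_spf=8, snr_gf=6, q=0.001, d=-3.0)
        assert row["call"] == "both"

    def test_undetected_in_gf_gives_zero_snr_and_spf_only(self, rng):
        row = presence_fixture(rng, snr_spf=20, snr_gf=0, q=0.001, d=-2.0)
        assert row["snr_gf"] == 0.0
        assert row["call"] == "spf_only"

    def test_gf_only_mirror(self, rng):
        row = presence_fixture(rng, snr_spf=2, snr_gf=9, q=0.01, d=1.5)
        assert row["call"] == "gf_only"

    def test_insignificant_one_sided_is_not_exclusive(self, rng):
        row = presence_fixture(rng, snr_spf=8, snr_gf=2, q=0.5, d=-1.2)
        assert row["call"] == "neither"

    def test_nonpositive_noise_floor_errors(self, rng):
        with pytest.raises(ValueError, match="noise_floor"):
            presence_fixture(rng, snr_spf=8, snr_gf=2, q=0.01, d=-1.2, floor=0.0)


def diff_frame(rows):
    """rows: list of (feature_id, organ, direction)."""
    df = pd.DataFrame(
        [
            {"organ": o, "direction": d, "q": 0.01, "cohens_d": -1 if d == "spf_higher" else 1}
            for _, o, d in rows
        ],
        index=pd.Index([f for f, _, _ in rows], name="feature_id"),
    )
    return df


class TestVennPartition:
    def test_all_three_organs_is_center_cell(self):
        diff = diff_frame(
            [("F1", o, "spf_higher") for o in ("brain", "intestine", "placenta")]
        )
        v = venn_partition(diff)
        assert v.spf_cells["brain+intestine+placenta"] == 1
        assert v.spf_any == 1 and v.gf_any == 0

    def test_feature_can_appear_in_both_diagrams(self):
        diff = diff_frame(
            [("F1", "placenta", "spf_higher"), ("F1", "brain", "gf_higher"),
             ("F1", "intestine", "none")]
        )
        v = venn_partition(diff)
        assert v.spf_cells["placenta"] == 1
        assert v.gf_cells["brain"] == 1

    def test_cells_sum_to_at_least_one_margin(self, rng):
        organs = ("brain", "intestine", "placenta")
        rows = []
        for i in range(300):
            for o in organs:
                d = rng.choice(["spf_higher", "gf_higher", "none"], p=[0.3, 0.2, 0.5])
                rows.append((f"F{i}", o, d))
        v = venn_partition(diff_frame(rows))
        assert sum(v.spf_cells.values()) == v.spf_any
        assert sum(v.gf_cells.values()) == v.gf_any

    def test_exact_subset_not_at_least(self):
        diff = diff_frame(
            [("F1", "brain", "spf_higher"), ("F1", "intestine", "spf_higher"),
             ("F1", "placenta", "none")]
        )
        v = venn_partition(diff)
        assert v.spf_cells["brain+intestine"] == 1
        assert v.spf_cells["brain+intestine+placenta"] == 0
        assert v.spf_cells["brain"] == 0
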