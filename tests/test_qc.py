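"""Quality-metric formulas and the cleanup decision rule."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fetometab.qc import QCThresholds, apply_cleanup, compute_quality_metrics
from fetometab.simulate import SyntheticConfig, generate_dataset

from conftest import make_table


def qc_table(qc_values, bio_values, n_bio=12):
    """One-feature table with given QC values and bio values."""
    vals = np.array([list(bio_values) + list(qc_values)], dtype=float)
    return make_table(vals, n_qc=len(qc_values))


class TestMetricFormulas:
    def test_hand_derived_rsd_values(self):
        # QC = [90,95,100,105,110]: median 100, MAD 5 -> RSD* = 1.4826*5/100;
        # mean 100, sd sqrt(62.5) -> classic RSD
        bio = [80, 90, 100, 110, 120, 130, 85, 95, 105, 115, 70, 125]
        t = qc_table([90, 95, 100, 105, 110], bio)
        m = compute_quality_metrics(t).iloc[0]
        assert m["rsd_star"] == pytest.approx(0.0741, abs=1e-4)
        assert m["rsd_classic"] == pytest.approx(0.0791, abs=1e-4)

    def test_zero_dispersion_qc(self):
        t = qc_table([100, 100, 100, 100], [80, 90, 100, 110, 120, 130] * 2)
        m = compute_quality_metrics(t).iloc[0]
        assert m["rsd_classic"] == 0.0
        assert m["rsd_star"] == 0.0

    def test_d_ratio_is_sd_ratio(self):
        rng = np.random.default_rng(0)
        bio = rng.normal(1000, 50, 12)
        qc = rng.normal(1000, 5, 6)
        t = qc_table(qc, bio)
        m = compute_quality_metrics(t).iloc[0]
        assert m["d_ratio"] == pytest.approx(
            np.std(qc, ddof=1) / np.std(bio, ddof=1), rel=1e-12
        )
        mad = lambda x: np.median(np.abs(x - np.median(x)))
        assert m["d_ratio_star"] == pytest.approx(mad(qc) / mad(bio), rel=1e-12)

    def test_detection_rates(self):
        vals = np.full((1, 16), 100.0)
        vals[0, 12:14] = np.nan      # 2 of 4 QCs missing
        vals[0, 0] = np.nan          # one GF bio missing
        t = make_table(vals, n_qc=4)
        m = compute_quality_metrics(t).iloc[0]
        assert m["qc_detection_rate"] == pytest.approx(0.5)
        assert m["best_group_detection_rate"] == pytest.approx(1.0)  # SPF complete
        assert m["overall_detection_rate"] == pytest.approx(13 / 16)

    def test_no_qc_injections_is_hard_error(self, rng):
        t = make_table(rng.uniform(1, 2, (2, 12)), n_qc=0)
        with pytest.raises(ValueError, match="QC"):
            compute_quality_metrics(t)

    def test_insufficient_qc_reported_missing_with_reason(self):
        vals = np.full((1, 14), 100.0)
        vals[0, 12] = np.nan  # 1 of 2 QCs detected
        t = make_table(vals, n_qc=2)
        out = apply_cleanup(compute_quality_metrics(t))
        assert np.isnan(out.iloc[0]["rsd_star"])
        assert not out.iloc[0]["kept"]
        assert "insufficient_qc" in out.iloc[0]["reason_codes"]


def metrics_row(**kw):
    base = dict(
        qc_detection_rate=1.0,
        best_group_detection_rate=1.0,
        overall_detection_rate=1.0,
        rsd_classic=0.05,
        rsd_star=0.05,
        d_ratio=0.05,
        d_ratio_star=0.05,
    )
    base.update(kw)
    return pd.DataFrame([base], index=pd.Index(["F1"], name="feature_id"))


class TestCleanupRule:
    def test_rescue_fails_when_rsd_star_above_ten_percent(self):
        # RSD* 0.25 fails the primary rule and, being >= 0.10, the rescue too
        out = apply_cleanup(
            metrics_row(rsd_star=0.25, d_ratio_star=0.12, rsd_classic=0.08, d_ratio=0.08)
        )
        assert not out.iloc[0]["kept"]

    def test_kept_via_rescue_clause(self):
        # D-ratio* 0.15 fails primary; classic RSD, RSD* and basic D-ratio
        # all below 10% rescue the feature
        out = apply_cleanup(
            metrics_row(rsd_star=0.09, rsd_classic=0.08, d_ratio=0.09, d_ratio_star=0.15)
        )
        assert out.iloc[0]["kept"]

    def test_qc_detection_sixty_five_percent_flagged(self):
        # "present in more than 70% of the QC samples" fails at 0.65
        out = apply_cleanup(metrics_row(qc_detection_rate=0.65))
        assert not out.iloc[0]["kept"]
        assert "low_qc_detection" in out.iloc[0]["reason_codes"]

    def test_boundary_is_strict_for_qc_detection(self):
        assert not apply_cleanup(metrics_row(qc_detection_rate=0.70)).iloc[0]["kept"]
        assert apply_cleanup(metrics_row(qc_detection_rate=0.71)).iloc[0]["kept"]

    def test_group_detection_at_least_sixty(self):
        assert apply_cleanup(metrics_row(best_group_detection_rate=0.60)).iloc[0]["kept"]
        assert not apply_cleanup(metrics_row(best_group_detection_rate=0.59)).iloc[0]["kept"]


def oracle_keep(row, th: QCThresholds) -> bool:
    """Straight-line restatement of the cleanup rule, kept independent of
    the implementation on purpose."""
    det = (
        row["qc_detection_rate"] > th.qc_detection
        and row["best_group_detection_rate"] >= th.group_detection
        and row["overall_detection_rate"] >= th.overall_detection
    )
    primary = (
        not np.isnan(row["rsd_star"])
        and not np.isnan(row["d_ratio_star"])
        and row["rsd_star"] < th.rsd_star_max
        and row["d_ratio_star"] < th.d_ratio_star_max
    )
    rescue = (
        not any(np.isnan(row[k]) for k in ("rsd_classic", "rsd_star", "d_ratio"))
        and row["rsd_classic"] < th.rescue_max
        and row["rsd_star"] < th.rescue_max
        and row["d_ratio"] < th.rescue_max
    )
    return det and (primary or rescue)


class TestRuleOracle:
    def test_agrees_with_brute_force_on_randomized_metrics(self, rng):
        n = 10_000
        th = QCThresholds()
        df = pd.DataFrame(
            {
                "qc_detection_rate": rng.uniform(0, 1, n),
                "best_group_detection_rate": rng.uniform(0, 1, n),
                "overall_detection_rate": rng.uniform(0, 1, n),
                # concentrate values around the thresholds to hit all branches
                "rsd_classic": rng.uniform(0, 0.3, n),
                "rsd_star": rng.uniform(0, 0.3, n),
                "d_ratio": rng.uniform(0, 0.3, n),
                "d_ratio_star": rng.uniform(0, 0.3, n),
            },
            index=pd.Index([f"F{i}" for i in range(n)], name="feature_id"),
        )
        out = apply_cleanup(df, th)
        expected = df.apply(lambda r: oracle_keep(r, th), axis=1)
        assert (out["kept"] == expected).all()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        rsd_c=st.floats(0, 0.3),
        rsd_s=st.floats(0, 0.3),
        dr=st.floats(0, 0.3),
        drs=st.floats(0, 0.3),
        qc_rate=st.floats(0, 1),
        g_rate=st.floats(0, 1),
        o_rate=st.floats(0, 1),
    )
    def test_rule_equivalence_property(self, rsd_c, rsd_s, dr, drs, qc_rate, g_rate, o_rate):
        th = QCThresholds()
        df = metrics_row(
            rsd_classic=rsd_c, rsd_star=rsd_s, d_ratio=dr, d_ratio_star=drs,
            qc_detection_rate=qc_rate, best_group_detection_rate=g_rate,
            overall_detection_rate=o_rate,
        )
        assert apply_cleanup(df, th).iloc[0]["kept"] == oracle_keep(df.iloc[0], th)

    def test_monotonicity_in_dispersion_metrics(self, rng):
        th = QCThresholds()
        for _ in range(200):
            row = metrics_row(
                rsd_classic=rng.uniform(0, 0.3),
                rsd_star=rng.uniform(0, 0.3),
                d_ratio=rng.uniform(0, 0.3),
                d_ratio_star=rng.uniform(0, 0.3),
            )
            kept_before = apply_cleanup(row, th).iloc[0]["kept"]
            for col in ("rsd_classic", "rsd_star", "d_ratio", "d_ratio_star"):
                lowered = row.copy()
                lowered[col] = row[col] * rng.uniform(0, 1)
                kept_after = apply_cleanup(lowered, th).iloc[0]["kept"]
                assert not (kept_before and not kept_after), (
                    f"decreasing {col} flipped kept -> flagged"
                )


class TestOnSyntheticData:
    def test_most_fully_detected_null_features_kept(self):
        cfg = SyntheticConfig(
            n_features_per_mode=400, modes=("RP+",), effect_proportions={},
            drift_amplitude=0.0, missingness_midpoint=1.0,
            qc_noise_cv=0.05, biological_cv=0.5, seed=21,
        )
        tables, _ = generate_dataset(cfg)
        out = apply_cleanup(compute_quality_metrics(tables["RP+"]))
        assert out["kept"].mean() >= 0.95
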