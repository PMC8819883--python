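"""Properties of the synthetic-data generator."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fetometab.model import GROUPS, ORGANS
from fetometab.simulate import (
    SyntheticConfig,
    SyntheticConfigError,
    generate_dataset,
    inject_drift,
)
from fetometab.qc import compute_quality_metrics

from conftest import make_table


SMALL = dict(n_features_per_mode=120, modes=("RP+",))


class TestDesignLayout:
    def test_study_design_counts(self):
        cfg = SyntheticConfig(**SMALL, seed=0)
        tables, _ = generate_dataset(cfg)
        inj = tables["RP+"].injections
        bio = inj[inj["sample_type"] == "biological"]
        # 2 groups x 6 dams x 2 fetuses x 3 organs
        assert len(bio) == 72
        for g in GROUPS:
            sub = bio[bio["group"] == g]
            assert sub["dam_id"].nunique() == 6
            fetuses = sub.groupby(["dam_id", "fetus_sex"]).size()
            sexes = sub.drop_duplicates(
                subset=["dam_id", "organ"]
            )
            # 12 fetuses per group: 7 male, 5 female
            per_fetus = sub.assign(
                fetus=sub.index.str.rsplit("_", n=1).str[0]
            ).drop_duplicates("fetus")
            assert len(per_fetus) == 12
            assert (per_fetus["fetus_sex"] == "M").sum() == 7
            assert (per_fetus["fetus_sex"] == "F").sum() == 5
        assert (inj["sample_type"] == "qc").sum() == cfg.n_qc
        assert inj["injection_order"].is_unique

    def test_qcs_interleaved_across_order(self):
        cfg = SyntheticConfig(**SMALL, seed=0)
        tables, _ = generate_dataset(cfg)
        inj = tables["RP+"].injections
        qc_orders = np.sort(
            inj.loc[inj["sample_type"] == "qc", "injection_order"].to_numpy()
        )
        gaps = np.diff(qc_orders)
        assert qc_orders[0] <= 2 and qc_orders[-1] >= inj["injection_order"].max() - 1
        assert gaps.max() <= 2 * (len(inj) / cfg.n_qc)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = SyntheticConfig(**SMALL, seed=42)
        t1, truth1 = generate_dataset(cfg)
        t2, truth2 = generate_dataset(SyntheticConfig(**SMALL, seed=42))
        pd.testing.assert_frame_equal(t1["RP+"].intensities, t2["RP+"].intensities)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_differs(self):
        t1, _ = generate_dataset(SyntheticConfig(**SMALL, seed=1))
        t2, _ = generate_dataset(SyntheticConfig(**SMALL, seed=2))
        assert not t1["RP+"].intensities.equals(t2["RP+"].intensities)


class TestNullGenerator:
    def test_null_p_values_uniform(self):
        # all-null, no drift, full detection: raw t-test p < 0.05 for ~5%
        cfg = SyntheticConfig(
            n_features_per_mode=600, modes=("RP+",), effect_proportions={},
            drift_amplitude=0.0, missingness_midpoint=1.0, seed=3,
        )
        tables, _ = generate_dataset(cfg)
        t = tables["RP+"].restrict_organ("brain")
        gf = np.log(t.intensities[t.injections.index[t.injections["group"] == "GF"]])
        spf = np.log(t.intensities[t.injections.index[t.injections["group"] == "SPF"]])
        _, p = sps.ttest_ind(gf, spf, axis=1)
        frac = float(np.mean(p < 0.05))
        # binomial tolerance at n = 600 (3.5 sigma)
        assert abs(frac - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / 600)

    def test_truth_consistency_recovers_planted_effects(self):
        cfg = SyntheticConfig(
            n_features_per_mode=200, modes=("RP+",),
            effect_proportions={"spf_up": 0.3},
            drift_amplitude=0.0, missingness_midpoint=1.0, seed=8,
        )
        tables, truth = generate_dataset(cfg)
        t = tables["RP+"]
        inj = t.injections
        planted = truth[truth["effect_class"] == "spf_up"]
        biases = []
        for fid, row in planted.iterrows():
            for organ in row["affected_organs"].split(","):
                gf_ids = inj.index[(inj["group"] == "GF") & (inj["organ"] == organ)]
                spf_ids = inj.index[(inj["group"] == "SPF") & (inj["organ"] == organ)]
                delta = (
                    np.log2(t.intensities.loc[fid, gf_ids]).mean()
                    - np.log2(t.intensities.loc[fid, spf_ids]).mean()
                )
                biases.append(delta + row["log2_effect"])  # GF - SPF = -effect
        assert abs(float(np.mean(biases))) < 0.15

    def test_qc_dispersion_smaller_than_biological(self):
        cfg = SyntheticConfig(**SMALL, effect_proportions={}, drift_amplitude=0.0,
                              missingness_midpoint=1.0, seed=5)
        tables, _ = generate_dataset(cfg)
        m = compute_quality_metrics(tables["RP+"])
        assert (m["d_ratio"].dropna() < 1).mean() > 0.99


class TestExclusiveFeatures:
    def test_exclusive_snr_holds_by_construction(self):
        cfg = SyntheticConfig(
            n_features_per_mode=200, modes=("RP+",),
            effect_proportions={"spf_exclusive": 0.10}, drift_amplitude=0.0, seed=6,
        )
        tables, truth = generate_dataset(cfg)
        t = tables["RP+"]
        inj = t.injections
        excl = truth[truth["effect_class"] == "spf_exclusive"]
        assert len(excl) == 20
        for fid, row in excl.iterrows():
            for organ in row["affected_organs"].split(","):
                for group, expect_present in (("SPF", True), ("GF", False)):
                    ids = inj.index[(inj["group"] == group) & (inj["organ"] == organ)]
                    vals = t.intensities.loc[fid, ids].dropna().to_numpy()
                    snr = vals.mean() / cfg.noise_floor if len(vals) else 0.0
                    if expect_present:
                        assert snr > 5, (fid, organ, snr)
                    else:
                        assert snr < 5, (fid, organ, snr)

    def test_infeasible_exclusive_effect_raises(self):
        with pytest.raises(SyntheticConfigError, match="infeasible"):
            SyntheticConfig(
                effect_proportions={"spf_exclusive": 0.1},
                log2_effects={"spf_exclusive": 1.0},
            )

    def test_proportions_must_sum_below_one(self):
        with pytest.raises(SyntheticConfigError, match="sum"):
            SyntheticConfig(effect_proportions={"spf_up": 0.7, "gf_up": 0.5})


class TestInjectDrift:
    def _flat_table(self, value=1000.0, n_inj=16, n_qc=4):
        return make_table(np.full((1, n_inj), value), n_qc=n_qc)

    def test_zero_amplitude_is_identity(self):
        t = self._flat_table()
        params = pd.DataFrame(
            {"c1": [1.0], "c2": [0.5], "amplitude": [0.0]},
            index=pd.Index(["F1"], name="feature_id"),
        )
        out = inject_drift(t, params)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_linear_drift_makes_qc_values_monotone(self):
        t = self._flat_table()
        params = pd.DataFrame(
            {"c1": [1.0], "c2": [0.0], "amplitude": [0.2]},
            index=pd.Index(["F1"], name="feature_id"),
        )
        out = inject_drift(t, params)
        qc_vals = out.intensities.loc["F1", out.qc_ids].to_numpy()
        order = out.injections.loc[out.qc_ids, "injection_order"].to_numpy()
        assert np.all(np.diff(qc_vals[np.argsort(order)]) > 0)

    def test_drift_raises_qc_rsd(self, rng):
        base = 1000.0 * np.exp(rng.normal(0, 0.02, 20))  # qc_noise_cv ~ 2%
        t = make_table(base.reshape(1, -1), n_qc=8)
        params = pd.DataFrame(
            {"c1": [1.0], "c2": [0.3], "amplitude": [0.2]},
            index=pd.Index(["F1"], name="feature_id"),
        )
        out = inject_drift(t, params)
        rsd = lambda x: np.std(x, ddof=1) / np.mean(x)
        before = rsd(t.intensities.loc["F1", t.qc_ids].to_numpy())
        after = rsd(out.intensities.loc["F1", out.qc_ids].to_numpy())
        assert after > before
        assert before == pytest.approx(0.02, abs=0.015)

    def test_missingness_untouched(self, rng):
        vals = rng.uniform(500, 1500, (1, 16))
        vals[0, 3] = np.nan
        t = make_table(vals, n_qc=4)
        params = pd.DataFrame(
            {"c1": [0.7], "c2": [0.2], "amplitude": [0.1]},
            index=pd.Index(["F1"], name="feature_id"),
        )
        out = inject_drift(t, params)
        assert np.isnan(out.intensities.iloc[0, 3])
        assert out.intensities.notna().sum().sum() == t.intensities.notna().sum().sum()
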