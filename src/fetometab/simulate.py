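"""Synthetic feature-table generator emulating the GF-vs-SPF fetal-organ design.

The generator reproduces the study layout — two maternal-microbiota groups
(germ-free and specific-pathogen-free), six dams per group with two sampled
fetuses each (12 fetuses per group, 7 male / 5 female), three organs per
fetus, four analytical modes, pooled-QC injections interleaved along the
injection order — and plants per-feature effects of five classes:

``null``
    no group difference;
``spf_up`` / ``gf_up``
    a log2-fold shift in the affected organs (SPF-higher features are
    modelled as a *decrease* in GF, matching the GF-minus-SPF sign
    convention used downstream);
``spf_exclusive`` / ``gf_exclusive``
    the feature is abundant in one group and pushed far below the detection
    noise floor in the other, so that the signal-to-noise exclusivity rule
    (SNR > 5 present / < 5 absent) holds by construction.

Biological intensities are log-normal around a per-feature baseline with
per-feature organ offsets (organs have distinct metabolomes, and the
between-organ spread is what dominates pooled biological dispersion) and a
shared dam intercept (fetuses are nested in dams); pooled-QC injections sit
at the per-feature mean of the biological samples on the log scale with a
small technical CV; a smooth multiplicative drift in injection order and a
logistic intensity-dependent detection model (lower intensity => more
missing) are applied to every injection.

Exclusive-class features additionally share a latent per-sample factor
(default correlation 0.8). Co-varying microbial metabolites are a real
phenomenon, and the correlation is what lets a random-forest imputer infer
low values for the absent group from the feature's detected companions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .model import FeatureTable, GROUPS, MODES, ORGANS

EFFECT_CLASSES = ("null", "spf_up", "gf_up", "spf_exclusive", "gf_exclusive")

#: Default effect-class proportions; scaled from the fractions such a study
#: reports (roughly 18% SPF-higher, 13% GF-higher, <1% exclusive).
DEFAULT_PROPORTIONS = {
    "spf_up": 0.18,
    "gf_up": 0.125,
    "spf_exclusive": 0.008,
    "gf_exclusive": 0.001,
}

DEFAULT_LOG2_EFFECTS = {
    "null": 0.0,
    "spf_up": 1.5,
    "gf_up": 1.5,
    "spf_exclusive": 6.0,
    "gf_exclusive": 6.0,
}


class SyntheticConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Intensities are in arbitrary detector counts; ``noise_floor`` is the
    per-mode instrument noise level used both as the midpoint of the logistic
    detection model and as the denominator of signal-to-noise ratios
    downstream.
    """

    n_features_per_mode: int = 1500
    modes: tuple[str, ...] = MODES
    n_dams_per_group: int = 6
    n_fetuses_per_dam: int = 2
    organs: tuple[str, ...] = ORGANS
    n_qc: int = 8
    drift_amplitude: float = 0.1
    missingness_midpoint: float = 2000.0
    missingness_steepness: float = 2.0
    effect_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    log2_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG2_EFFECTS)
    )
    qc_noise_cv: float = 0.05
    biological_cv: float = 0.5
    #: log-scale spread of per-feature organ baseline offsets: organs have
    #: distinct metabolomes, and the pooled biological dispersion that the
    #: D-ratio denominators see comes largely from between-organ differences.
    #: Each feature receives a random permutation of graded organ levels
    #: (+- organ_sd) plus jitter, so every feature has organ structure.
    organ_sd: float = 0.8
    dam_sd: float = 0.05
    exclusive_correlation: float = 0.8
    noise_floor: float = 2000.0
    baseline_log_min: float = float(np.log(2.0e4))
    baseline_log_max: float = float(np.log(2.0e6))
    #: safety factor by which the present group's mean must clear 5x the
    #: noise floor for exclusive features
    exclusive_snr_margin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.effect_proportions) - set(EFFECT_CLASSES)
        if unknown:
            raise SyntheticConfigError(f"unknown effect class(es): {sorted(unknown)}")
        total = sum(self.effect_proportions.values())
        if total > 1.0 + 1e-12 or any(v < 0 for v in self.effect_proportions.values()):
            raise SyntheticConfigError(
                f"effect-class proportions must be >= 0 and sum to <= 1 (got {total})"
            )
        if self.qc_noise_cv <= 0 or self.biological_cv <= 0:
            raise SyntheticConfigError("all CVs must be > 0")
        if not 0 <= self.exclusive_correlation < 1:
            raise SyntheticConfigError("exclusive_correlation must be in [0, 1)")
        if self.noise_floor <= 0:
            raise SyntheticConfigError("noise_floor must be > 0")
        self._check_exclusive_feasible()

    # log-sd corresponding to a lognormal CV
    @property
    def sigma_bio(self) -> float:
        return float(np.sqrt(np.log1p(self.biological_cv**2)))

    @property
    def sigma_qc(self) -> float:
        return float(np.sqrt(np.log1p(self.qc_noise_cv**2)))

    @property
    def n_fetuses_per_group(self) -> int:
        return self.n_dams_per_group * self.n_fetuses_per_dam

    def exclusive_absent_log_range(self) -> tuple[float, float]:
        """Log range of the absent group's underlying mean for exclusive features.

        Kept in a narrow band just below the detection floor (0.4-0.7x), so
        the absent group is occasionally detected at low intensity — as a
        genuinely-below-SNR-5 metabolite is in real data — while its
        detected-value SNR stays far from 5. The present group sits a planted
        log2 effect above this band.
        """
        return (
            float(np.log(0.4 * self.noise_floor)),
            float(np.log(0.7 * self.noise_floor)),
        )

    def updown_min_baseline(self, log2_eff: float) -> float:
        """Smallest log baseline for ordinary differential features.

        Keeps the depleted group's organ means above 5x the noise floor even
        under unfavourable organ offsets, so planted up/down features never
        masquerade as exclusive ones.
        """
        return float(
            np.log(5.0 * self.noise_floor * self.exclusive_snr_margin)
            + np.log(2.0) * log2_eff
            + 1.75 * self.organ_sd
        )

    def exclusive_min_baseline(self) -> float:
        """Smallest log baseline giving the present group SNR > 5 with margin."""
        return float(
            np.log(5.0 * self.noise_floor * self.exclusive_snr_margin)
            - 0.5 * self.sigma_bio**2
        )

    def _check_exclusive_feasible(self) -> None:
        wants_exclusive = any(
            self.effect_proportions.get(c, 0.0) > 0
            for c in ("spf_exclusive", "gf_exclusive")
        )
        if not wants_exclusive:
            return
        log2_eff = min(
            self.log2_effects.get(c, 0.0)
            for c in ("spf_exclusive", "gf_exclusive")
            if self.effect_proportions.get(c, 0.0) > 0
        )
        absent_lo, _ = self.exclusive_absent_log_range()
        baseline_min = absent_lo + np.log(2.0) * log2_eff
        if baseline_min < self.exclusive_min_baseline():
            raise SyntheticConfigError(
                "infeasible config: exclusive effect size too small to clear "
                "the SNR threshold in the present group (need log2 effect >= "
                f"{(self.exclusive_min_baseline() - absent_lo) / np.log(2.0):.2f})"
            )


# ---------------------------------------------------------------------- #


def _drift_curve(
    order: np.ndarray, c1: float, c2: float, amplitude: float, shape: str = "poly"
) -> np.ndarray:
    """Smooth multiplicative drift g(order) in [1 - a, 1 + a].

    ``poly``: a degree-2 Chebyshev-style polynomial of the order rescaled to
    [-1, 1]; ``sin``: one low-frequency sine wave (c1 = phase in turns,
    c2 = number of cycles over the run). Either way the curve is normalized
    so its maximum absolute excursion equals the amplitude.
    """
    if amplitude == 0.0:
        return np.ones_like(order, dtype=float)
    span = order.max() - order.min()
    t = (
        (order - order.min()) / span
        if span > 0
        else np.zeros_like(order, dtype=float)
    )
    if shape == "sin":
        h = np.sin(2.0 * np.pi * (c2 * t + c1))
    elif shape == "poly":
        u = 2.0 * t - 1.0
        h = c1 * u + c2 * (2.0 * u**2 - 1.0)
    else:
        raise ValueError(f"unknown drift shape {shape!r}")
    peak = np.max(np.abs(h))
    if peak == 0.0:
        return np.ones_like(order, dtype=float)
    return 1.0 + amplitude * h / peak


def inject_drift(
    table: FeatureTable, drift_params: pd.DataFrame
) -> FeatureTable:
    """Multiply intensities by a per-feature drift curve of injection order.

    ``drift_params`` is indexed by feature_id with columns ``c1``, ``c2``,
    ``amplitude`` and optionally ``shape`` (``poly``/``sin``); missing cells
    stay missing. A curve that is not strictly positive anywhere over the
    observed order range is an error.
    """
    out = table.copy()
    order = out.injections["injection_order"].to_numpy(float)
    for fid in out.intensities.index:
        if fid not in drift_params.index:
            continue
        p = drift_params.loc[fid]
        shape = str(p["shape"]) if "shape" in drift_params.columns else "poly"
        g = _drift_curve(
            order, float(p["c1"]), float(p["c2"]), float(p["amplitude"]), shape
        )
        if np.any(g <= 0):
            raise ValueError(f"drift curve non-positive for feature {fid}")
        out.intensities.loc[fid] = out.intensities.loc[fid].to_numpy(float) * g
    return out


def _assign_sexes(n_fetuses: int, rng: np.random.Generator) -> list[str]:
    # 7 male / 5 female out of 12; proportional rounding otherwise
    n_male = int(round(7.0 / 12.0 * n_fetuses))
    sexes = ["M"] * n_male + ["F"] * (n_fetuses - n_male)
    rng.shuffle(sexes)
    return sexes


def _injection_layout(
    config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Biological + QC injection metadata with QCs interleaved evenly."""
    rows = []
    for group in GROUPS:
        sexes = _assign_sexes(config.n_fetuses_per_group, rng)
        fetus_idx = 0
        for dam in range(1, config.n_dams_per_group + 1):
            dam_id = f"{group}_dam{dam}"
            for fetus in range(1, config.n_fetuses_per_dam + 1):
                sex = sexes[fetus_idx]
                fetus_idx += 1
                for organ in config.organs:
                    rows.append(
                        {
                            "injection_id": f"{group}_d{dam}_f{fetus}_{organ}",
                            "sample_type": "biological",
                            "group": group,
                            "organ": organ,
                            "dam_id": dam_id,
                            "fetus_sex": sex,
                        }
                    )
    bio = pd.DataFrame(rows)
    # analysis order is randomized, as the samples were randomized to batches
    bio = bio.iloc[rng.permutation(len(bio))].reset_index(drop=True)

    n_bio, n_qc = len(bio), config.n_qc
    n_total = n_bio + n_qc
    qc_positions = np.unique(
        np.round(np.linspace(0, n_total - 1, n_qc)).astype(int)
    )
    qc_rows = [
        {
            "injection_id": f"QC_{i + 1}",
            "sample_type": "qc",
            "group": "",
            "organ": "",
            "dam_id": "",
            "fetus_sex": "",
        }
        for i in range(len(qc_positions))
    ]
    all_rows: list[dict] = []
    qc_iter = iter(qc_rows)
    bio_iter = iter(bio.to_dict("records"))
    qc_set = set(qc_positions.tolist())
    for pos in range(n_total):
        all_rows.append(next(qc_iter) if pos in qc_set else next(bio_iter))
    layout = pd.DataFrame(all_rows)
    layout["injection_order"] = np.arange(1, n_total + 1)
    return layout.set_index("injection_id")


def _draw_truth(
    config: SyntheticConfig, mode: str, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_features_per_mode
    classes = np.array(["null"] * n, dtype=object)
    proportions = config.effect_proportions
    pool = rng.permutation(n)
    start = 0
    # canonical class order: assignment must not depend on dict key order
    for cls in EFFECT_CLASSES:
        k = int(round(proportions.get(cls, 0.0) * n))
        classes[pool[start : start + k]] = cls
        start += k

    baseline = rng.uniform(config.baseline_log_min, config.baseline_log_max, size=n)
    absent_lo, absent_hi = config.exclusive_absent_log_range()
    affected = np.empty(n, dtype=object)
    log2_effect = np.zeros(n)
    organs = list(config.organs)
    subsets = [
        tuple(o for j, o in enumerate(organs) if (i >> j) & 1)
        for i in range(1, 2 ** len(organs))
    ]
    for i in range(n):
        cls = classes[i]
        if cls == "null":
            affected[i] = ()
            continue
        affected[i] = subsets[rng.integers(len(subsets))]
        log2_effect[i] = config.log2_effects.get(cls, 0.0)
        if cls in ("spf_exclusive", "gf_exclusive"):
            # absent-group level lands just below the floor; the present
            # group sits the planted effect above it
            absent = rng.uniform(absent_lo, absent_hi)
            baseline[i] = absent + np.log(2.0) * log2_effect[i]
        else:
            # ordinary differential features stay well-detected in both groups
            lo = min(
                max(config.baseline_log_min, config.updown_min_baseline(log2_effect[i])),
                config.baseline_log_max - 0.5,
            )
            baseline[i] = rng.uniform(lo, config.baseline_log_max)

    # mz/rt drawn to mimic the peak-collection window
    mz = rng.uniform(50.0, 1500.0, size=n)
    rt = rng.uniform(0.5, 15.0, size=n)
    c1 = rng.normal(size=n)
    c2 = rng.normal(size=n)
    truth = pd.DataFrame(
        {
            "feature_id": [f"{mode}_F{i + 1:05d}" for i in range(n)],
            "mode": mode,
            "mz": mz,
            "rt": rt,
            "effect_class": classes,
            "affected_organs": [",".join(a) for a in affected],
            "log2_effect": log2_effect,
            "baseline_log_mean": baseline,
            "drift_c1": c1,
            "drift_c2": c2,
            "drift_amplitude": config.drift_amplitude,
        }
    ).set_index("feature_id")
    return truth


def _simulate_mode(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    layout: pd.DataFrame,
    rng: np.random.Generator,
) -> FeatureTable:
    n = len(truth)
    inj = layout
    n_inj = len(inj)
    bio_mask = (inj["sample_type"] == "biological").to_numpy()
    organ_arr = inj["organ"].to_numpy(object)
    group_arr = inj["group"].to_numpy(object)
    dam_arr = inj["dam_id"].to_numpy(object)
    order = inj["injection_order"].to_numpy(float)

    dams = sorted({d for d in dam_arr if d})
    dam_effects = {
        d: rng.normal(0.0, config.dam_sd, size=n) for d in dams
    }

    # per-feature organ baseline offsets (organs have distinct metabolomes):
    # a random permutation of graded levels spanning +- organ_sd, plus
    # jitter, so every feature has some organ structure; exclusive-class
    # features get none so their SNR guarantees stay exact
    n_org = len(config.organs)
    levels = config.organ_sd * np.linspace(-1.0, 1.0, n_org)
    perm_levels = rng.permuted(np.tile(levels, (n, 1)), axis=1)
    jitter = rng.normal(0.0, config.organ_sd / 3.0, size=(n, n_org))
    offset_mat = perm_levels + jitter
    exclusive = np.isin(
        truth["effect_class"].to_numpy(object), ["spf_exclusive", "gf_exclusive"]
    )
    offset_mat[exclusive, :] = 0.0
    organ_offsets = {o: offset_mat[:, k] for k, o in enumerate(config.organs)}

    ln2 = np.log(2.0)
    log_mu = np.tile(truth["baseline_log_mean"].to_numpy()[:, None], (1, n_inj))
    classes = truth["effect_class"].to_numpy(object)
    log2_eff = truth["log2_effect"].to_numpy(float)
    affected_sets = [
        set(a.split(",")) if a else set() for a in truth["affected_organs"]
    ]

    # group-by-organ shift: GF side moves, fixing the GF - SPF convention
    for j in range(n_inj):
        if not bio_mask[j]:
            continue
        log_mu[:, j] += dam_effects[dam_arr[j]] + organ_offsets[organ_arr[j]]
        if group_arr[j] != "GF":
            continue
        for i in range(n):
            if classes[i] == "null" or organ_arr[j] not in affected_sets[i]:
                continue
            if classes[i] in ("spf_up", "spf_exclusive"):
                log_mu[i, j] -= ln2 * log2_eff[i]
            else:  # gf_up, gf_exclusive
                log_mu[i, j] += ln2 * log2_eff[i]

    sigma = config.sigma_bio
    noise = rng.normal(0.0, sigma, size=(n, n_inj))
    # shared latent factor within each exclusive class
    rho = config.exclusive_correlation
    if rho > 0:
        for cls in ("spf_exclusive", "gf_exclusive"):
            members = np.where(classes == cls)[0]
            if len(members) == 0:
                continue
            z = rng.normal(0.0, 1.0, size=n_inj)
            noise[members, :] = sigma * (
                rho * z[None, :]
                + np.sqrt(1.0 - rho**2) * noise[members, :] / sigma
            )

    log_x = log_mu + noise

    # pooled QC: per-feature mean of the biological samples on the log scale
    qc_cols = np.where(~bio_mask)[0]
    if len(qc_cols):
        qc_base = log_x[:, bio_mask].mean(axis=1)
        qc_noise = rng.normal(0.0, config.sigma_qc, size=(n, len(qc_cols)))
        log_x[:, qc_cols] = qc_base[:, None] + qc_noise

    x = np.exp(log_x)

    # multiplicative injection-order drift
    amp = config.drift_amplitude
    if amp > 0:
        c1 = truth["drift_c1"].to_numpy()
        c2 = truth["drift_c2"].to_numpy()
        for i in range(n):
            x[i, :] *= _drift_curve(order, c1[i], c2[i], amp)

    # logistic intensity-dependent detection
    logit = config.missingness_steepness * (
        np.log(x) - np.log(config.missingness_midpoint)
    )
    p_detect = 1.0 / (1.0 + np.exp(-logit))
    detected = rng.random(size=x.shape) < p_detect
    x = np.where(detected, x, np.nan)

    intensities = pd.DataFrame(x, index=truth.index, columns=inj.index)
    features = truth[["mode", "mz", "rt"]].copy()
    return FeatureTable(intensities, features, inj.copy())


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[dict[str, FeatureTable], pd.DataFrame]:
    """Generate per-mode feature tables plus the planted ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps mode label to its
    :class:`~fetometab.model.FeatureTable` (identical injection sets across
    modes, disjoint feature ids) and ``truth`` is one row per feature with
    its effect class, affected organs, planted log2 effect, baseline and
    drift parameters. Output is a deterministic function of ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    layout = _injection_layout(config, rng)
    tables: dict[str, FeatureTable] = {}
    truths = []
    for mode in config.modes:
        truth = _draw_truth(config, mode, rng)
        tables[mode] = _simulate_mode(config, truth, layout, rng)
        truths.append(truth)
    truth_all = pd.concat(truths, axis=0)
    return tables, truth_all


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["modes"] = list(d["modes"])
    d["organs"] = list(d["organs"])
    d["effect_proportions"] = dict(d["effect_proportions"])
    d["log2_effects"] = dict(d["log2_effects"])
    return d
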