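"""Per-feature quality metrics and the cleanup decision rule.

Feature cleanup runs per analytical mode, before the modes are merged.
A feature is kept when all detection criteria pass and its dispersion
metrics pass, where the dispersion check is either the non-parametric pair
(RSD* < 20% and D-ratio* < 10%) or the rescue clause (classic RSD, RSD* and
basic D-ratio all below 10%). Flagged features are discarded from the
statistical analyses but retained for raw-signal presence/absence lookups.

Definitions, on detected (non-missing) values only:

* ``rsd_classic``  = sd(QC) / mean(QC)
* ``rsd_star``     = 1.4826 * MAD(QC) / median(QC)
* ``d_ratio``      = sd(QC) / sd(biological)
* ``d_ratio_star`` = MAD(QC) / MAD(biological)

MAD is the raw median absolute deviation; the 1.4826 Gaussian-consistency
constant enters RSD* but cancels in D-ratio* (a ratio of two MADs).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FeatureTable, GROUPS, sample_groups

MAD_SCALE = 1.4826


@dataclass
class QCThresholds:
    """Cleanup thresholds (defaults are the study's)."""

    qc_detection: float = 0.70          # strictly greater than
    group_detection: float = 0.60       # at least, in at least one group
    overall_detection: float = 0.50     # "low number of missing values"
    rsd_star_max: float = 0.20
    d_ratio_star_max: float = 0.10
    rescue_max: float = 0.10            # classic RSD, RSD* and basic D-ratio


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def compute_quality_metrics(table: FeatureTable) -> pd.DataFrame:
    """Per-feature QC statistics on detected values.

    Returns a DataFrame indexed by feature_id with columns
    ``qc_detection_rate``, ``best_group_detection_rate``,
    ``overall_detection_rate``, ``rsd_classic``, ``rsd_star``, ``d_ratio``,
    ``d_ratio_star``. Metrics that cannot be computed (fewer than two
    detected QC or biological values, or a zero denominator) are NaN.
    """
    qc_ids = table.qc_ids
    if len(qc_ids) == 0:
        raise ValueError("compute_quality_metrics: table has no QC injections")
    bio_ids = table.biological_ids
    groups = sample_groups(table.injections)

    qc = table.intensities[qc_ids].to_numpy(float)
    bio = table.intensities[bio_ids].to_numpy(float)

    qc_rate = np.mean(~np.isnan(qc), axis=1)
    overall = np.mean(
        ~np.isnan(table.intensities.to_numpy(float)), axis=1
    )
    group_rates = []
    for g in GROUPS:
        ids = groups[g]
        if len(ids):
            group_rates.append(
                np.mean(~np.isnan(table.intensities[ids].to_numpy(float)), axis=1)
            )
    best_group = (
        np.max(np.column_stack(group_rates), axis=1)
        if group_rates
        else np.zeros(table.n_features)
    )

    n = table.n_features
    rsd_classic = np.full(n, np.nan)
    rsd_star = np.full(n, np.nan)
    d_ratio = np.full(n, np.nan)
    d_ratio_star = np.full(n, np.nan)
    for i in range(n):
        q = qc[i][~np.isnan(qc[i])]
        b = bio[i][~np.isnan(bio[i])]
        if len(q) >= 2:
            m, s = float(np.mean(q)), float(np.std(q, ddof=1))
            med, mad = float(np.median(q)), _mad(q)
            if m != 0:
                rsd_classic[i] = s / m
            if med != 0:
                rsd_star[i] = MAD_SCALE * mad / med
            if len(b) >= 2:
                sb = float(np.std(b, ddof=1))
                madb = _mad(b)
                if sb > 0:
                    d_ratio[i] = s / sb
                if madb > 0:
                    d_ratio_star[i] = mad / madb
    return pd.DataFrame(
        {
            "qc_detection_rate": qc_rate,
            "best_group_detection_rate": best_group,
            "overall_detection_rate": overall,
            "rsd_classic": rsd_classic,
            "rsd_star": rsd_star,
            "d_ratio": d_ratio,
            "d_ratio_star": d_ratio_star,
        },
        index=table.intensities.index,
    )


def apply_cleanup(
    metrics: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the cleanup rule; returns metrics plus ``kept`` and ``reason_codes``.

    kept <=> detection criteria pass AND
             ((RSD* and D-ratio* below their thresholds) OR
              (classic RSD, RSD* and basic D-ratio all below the rescue cap)).

    A NaN dispersion metric fails its comparison (reason ``insufficient_qc``);
    detection-rate comparisons are ``>`` for the QC rate and ``>=`` for the
    group and overall rates.
    """
    th = thresholds or QCThresholds()
    out = metrics.copy()
    qc_rate = out["qc_detection_rate"].to_numpy(float)
    grp_rate = out["best_group_detection_rate"].to_numpy(float)
    all_rate = out["overall_detection_rate"].to_numpy(float)
    rsd_c = out["rsd_classic"].to_numpy(float)
    rsd_s = out["rsd_star"].to_numpy(float)
    dr = out["d_ratio"].to_numpy(float)
    drs = out["d_ratio_star"].to_numpy(float)

    det_qc = qc_rate > th.qc_detection
    det_group = grp_rate >= th.group_detection
    det_overall = all_rate >= th.overall_detection
    undefined = np.isnan(rsd_s) | np.isnan(drs)
    with np.errstate(invalid="ignore"):
        primary = (rsd_s < th.rsd_star_max) & (drs < th.d_ratio_star_max)
        rescue = (
            ~np.isnan(rsd_c)
            & ~np.isnan(dr)
            & (rsd_c < th.rescue_max)
            & (rsd_s < th.rescue_max)
            & (dr < th.rescue_max)
        )
        high_rsd_s = rsd_s >= th.rsd_star_max
        high_drs = drs >= th.d_ratio_star_max
    dispersion = ~undefined & (primary | rescue)
    kept = det_qc & det_group & det_overall & dispersion

    reasons = []
    for i in range(len(out)):
        if kept[i]:
            reasons.append("")
            continue
        codes = []
        if not det_qc[i]:
            codes.append("low_qc_detection")
        if not det_group[i]:
            codes.append("low_group_detection")
        if not det_overall[i]:
            codes.append("high_missingness")
        if undefined[i]:
            codes.append("insufficient_qc")
        elif not dispersion[i]:
            if high_rsd_s[i]:
                codes.append("high_rsd_star")
            if high_drs[i]:
                codes.append("high_d_ratio_star")
            codes.append("rescue_failed")
        reasons.append(";".join(codes))
    out["kept"] = kept
    out["reason_codes"] = reasons
    return out


def cleanup_table(
    table: FeatureTable, thresholds: QCThresholds | None = None
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame]:
    """Compute metrics, apply the rule, and split the table.

    Returns ``(kept_table, flagged_table, metrics)``; the flagged table is
    retained for presence/absence raw-signal lookups only.
    """
    metrics = apply_cleanup(compute_quality_metrics(table), thresholds)
    kept_ids = metrics.index[metrics["kept"]]
    flagged_ids = metrics.index[~metrics["kept"]]
    return (
        table.subset_features(kept_ids),
        table.subset_features(flagged_ids),
        metrics,
    )
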