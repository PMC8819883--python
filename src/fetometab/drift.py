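"""QC-anchored correction of injection-order intensity drift.

For each feature, a cubic smoothing spline (smoothing parameter chosen by
generalized cross-validation) is fitted to the log intensities of the pooled
QC injections against injection order. Every injection is then divided by
``exp(g(order) - g(order_ref))``, anchoring the corrected scale at the first
QC injection. When fewer than five detected QC values are available the fit
falls back to a least-squares line; with fewer than two the feature passes
through uncorrected.

The correction is gated: it is applied only when it strictly reduces the
feature's QC classic RSD. The gate makes the (unspecified) choice of drift
model safe — a fit that does not help leaves the data untouched.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .model import FeatureTable

#: minimum detected QC values for the GCV spline (scipy needs >= 5 points;
#: a GCV spline through fewer is degenerate anyway)
MIN_QC_FOR_SPLINE = 5
MIN_QC_FOR_LINEAR = 2


def _classic_rsd(values: np.ndarray) -> float:
    v = values[~np.isnan(values)]
    if len(v) < 2 or np.mean(v) == 0:
        return np.nan
    return float(np.std(v, ddof=1) / np.mean(v))


@dataclass
class _Fit:
    method: str
    g: np.ndarray  # fitted log-scale curve over all injections


def _fit_curve(
    qc_order: np.ndarray, qc_log: np.ndarray, all_order: np.ndarray
) -> _Fit:
    if len(qc_order) >= MIN_QC_FOR_SPLINE:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spl = make_smoothing_spline(qc_order, qc_log)  # GCV lambda
            return _Fit("spline", np.asarray(spl(all_order), dtype=float))
        except Exception:
            pass  # singular fits fall through to the line
    slope, intercept = np.polyfit(qc_order, qc_log, 1)
    return _Fit("linear", slope * all_order + intercept)


def correct_drift(
    table: FeatureTable, gate: bool = True
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove injection-order drift anchored on QC injections.

    Returns the corrected table and a per-feature report with columns
    ``method`` (``spline``/``linear``/``none``), ``qc_rsd_before``,
    ``qc_rsd_after`` and ``applied``. With ``gate=True`` (default) a fitted
    correction is applied only if it strictly reduces QC classic RSD.
    Missing cells stay missing; corrected values keep the feature's scale
    (multiplying a feature by a constant multiplies its corrected values by
    the same constant).
    """
    qc_ids = table.qc_ids
    if len(qc_ids) == 0:
        raise ValueError("correct_drift: table has no QC injections")
    out = table.copy()
    order_all = out.injections["injection_order"].to_numpy(float)
    qc_pos = out.injections.index.get_indexer(qc_ids)
    qc_order = order_all[qc_pos]
    anchor = np.argsort(qc_order)[0]  # first QC in injection order

    records = []
    mat = out.intensities.to_numpy(float)
    for i, fid in enumerate(out.intensities.index):
        row = mat[i]
        qc_vals = row[qc_pos]
        det = ~np.isnan(qc_vals)
        rsd_before = _classic_rsd(qc_vals)
        method, applied, rsd_after = "none", False, rsd_before
        if det.sum() >= MIN_QC_FOR_LINEAR and np.all(qc_vals[det] > 0):
            fit = _fit_curve(qc_order[det], np.log(qc_vals[det]), order_all)
            if np.all(np.isfinite(fit.g)):
                # clip runaway extrapolations; the RSD gate rejects bad fits
                log_factor = np.clip(
                    fit.g - fit.g[np.where(order_all == qc_order[anchor])[0][0]],
                    -50.0,
                    50.0,
                )
                factor = np.exp(log_factor)
                corrected = row / factor
                rsd_candidate = _classic_rsd(corrected[qc_pos])
                if (not gate) or (
                    np.isfinite(rsd_candidate)
                    and np.isfinite(rsd_before)
                    and rsd_candidate < rsd_before
                ):
                    mat[i] = corrected
                    method, applied, rsd_after = fit.method, True, rsd_candidate
        records.append(
            {
                "feature_id": fid,
                "method": method,
                "applied": applied,
                "qc_rsd_before": rsd_before,
                "qc_rsd_after": rsd_after,
            }
        )
    out.intensities = pd.DataFrame(
        mat, index=out.intensities.index, columns=out.intensities.columns
    )
    report = pd.DataFrame.from_records(records).set_index("feature_id")
    return out, report
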