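"""Per-organ differential abundance, exclusivity calls and Venn partitioning.

For each organ, every feature is tested with a two-sample Student's t-test
(pooled variance — the two-group "simple linear model") comparing GF against
SPF, p-values are Benjamini-Hochberg adjusted within the organ, and the
effect size is Cohen's d with the **GF minus SPF** sign convention: d < 0
means the feature is more abundant in SPF mice. A feature is significant
when q < 0.05 and |d| > 0.8.

Presence/absence ("exclusivity") calls apply the signal-to-noise rule on the
raw, pre-imputation intensities: a feature is SPF-only in an organ when its
SNR (mean detected intensity / noise floor) exceeds 5 in SPF, stays below 5
in GF, and the organ's test gives q < 0.05 with d < -0.8 (mirrored for
GF-only).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import FeatureTable, GROUPS, ORGANS, sample_groups

Q_THRESHOLD = 0.05
D_THRESHOLD = 0.8
SNR_THRESHOLD = 5.0


def bh_adjust(pvals: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, stable under ties.
    NaN entries are excluded from the family size m and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(adj, 1.0)
    q[valid] = qv
    return q


def differential_test(
    table: FeatureTable,
    organ: str,
    equal_var: bool = True,
    log_transform: bool = True,
) -> pd.DataFrame:
    """GF-vs-SPF test per feature within one organ.

    Expects the imputed, QC-free table. By default the test runs on log
    intensities (LC-MS intensities are log-normal; effect sizes are standard
    on that scale); ``log_transform=False`` tests the values as given.
    Returns a DataFrame with columns ``organ``, ``mean_gf``, ``mean_spf``
    (means of the tested values), ``t_stat``, ``p``, ``q``, ``cohens_d``,
    ``significant``, ``direction``. Features with zero pooled variance get
    ``p = NaN`` and are excluded from the BH family size.
    """
    sub = table.restrict_organ(organ)
    groups = sample_groups(sub.injections)
    gf_ids, spf_ids = groups["GF"], groups["SPF"]
    if len(gf_ids) < 2 or len(spf_ids) < 2:
        raise ValueError(f"organ {organ}: both groups need n >= 2")
    gf = sub.intensities[gf_ids].to_numpy(float)
    spf = sub.intensities[spf_ids].to_numpy(float)
    if np.isnan(gf).any() or np.isnan(spf).any():
        raise ValueError("differential_test expects a complete (imputed) table")
    if log_transform:
        if (gf <= 0).any() or (spf <= 0).any():
            raise ValueError("log_transform requires strictly positive intensities")
        gf, spf = np.log(gf), np.log(spf)

    n1, n2 = gf.shape[1], spf.shape[1]
    m1, m2 = gf.mean(axis=1), spf.mean(axis=1)
    v1, v2 = gf.var(axis=1, ddof=1), spf.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full(len(m1), n1 + n2 - 2, dtype=float)
        else:  # Welch, behind the flag
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m1 - m2) / se
        d = (m1 - m2) / np.sqrt(sp2)

    zero_var = sp2 == 0
    t[zero_var] = np.nan
    d[zero_var] = 0.0
    p = np.where(
        np.isnan(t), np.nan, 2.0 * sps.t.sf(np.abs(t), df)
    )
    q = bh_adjust(p)
    significant = (q < Q_THRESHOLD) & (np.abs(d) > D_THRESHOLD)
    significant = np.where(np.isnan(q), False, significant).astype(bool)
    direction = np.where(
        significant & (d < 0),
        "spf_higher",
        np.where(significant & (d > 0), "gf_higher", "none"),
    )
    return pd.DataFrame(
        {
            "organ": organ,
            "mean_gf": m1,
            "mean_spf": m2,
            "t_stat": t,
            "p": p,
            "q": q,
            "cohens_d": d,
            "significant": significant,
            "direction": direction,
        },
        index=sub.intensities.index.rename("feature_id"),
    )


def differential_all_organs(
    table: FeatureTable,
    organs: tuple[str, ...] = ORGANS,
    equal_var: bool = True,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Stack :func:`differential_test` over organs (BH per organ)."""
    return pd.concat(
        [
            differential_test(table, o, equal_var=equal_var, log_transform=log_transform)
            for o in organs
        ]
    )


# ---------------------------------------------------------------------- #
# presence / exclusivity calls


def estimate_noise_floor(table: FeatureTable) -> dict[str, float]:
    """Per-mode noise floor: the 1st percentile of detected intensities."""
    floors = {}
    for mode in table.modes():
        ids = table.features.index[table.features["mode"] == mode]
        vals = table.intensities.loc[ids].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"mode {mode}: no detected intensities")
        floors[mode] = float(np.percentile(vals, 1.0))
    return floors


def call_presence(
    raw_table: FeatureTable,
    diff: pd.DataFrame,
    noise_floor: float | dict[str, float],
) -> pd.DataFrame:
    """SNR-based exclusivity calls on raw (pre-imputation) intensities.

    ``noise_floor`` is a positive per-mode mapping (or one scalar for all
    modes). For each feature x organ in ``diff``: the group SNR is the mean
    of detected intensities in that group and organ divided by the noise
    floor (0 when undetected everywhere), and

    * ``spf_only``: SNR_SPF > 5, SNR_GF < 5, q < 0.05, d < -0.8
    * ``gf_only``:  SNR_GF > 5, SNR_SPF < 5, q < 0.05, d > 0.8
    * ``both`` / ``neither`` otherwise, by whether both SNRs clear 5.
    """
    if isinstance(noise_floor, (int, float)):
        floors = {m: float(noise_floor) for m in raw_table.modes()}
    else:
        floors = dict(noise_floor)
    if any(v <= 0 for v in floors.values()):
        raise ValueError("noise_floor must be > 0")

    inj = raw_table.injections
    records = []
    for (fid, organ), row in diff.set_index("organ", append=True).iterrows():
        mode = raw_table.features.loc[fid, "mode"]
        floor = floors[mode]
        snr = {}
        for g in GROUPS:
            ids = inj.index[
                (inj["sample_type"] == "biological")
                & (inj["group"] == g)
                & (inj["organ"] == organ)
            ]
            vals = raw_table.intensities.loc[fid, ids].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            snr[g] = float(np.mean(vals) / floor) if len(vals) else 0.0
        q, d = row["q"], row["cohens_d"]
        sig = not np.isnan(q) and q < Q_THRESHOLD
        if (
            snr["SPF"] > SNR_THRESHOLD
            and snr["GF"] < SNR_THRESHOLD
            and sig
            and d < -D_THRESHOLD
        ):
            call = "spf_only"
        elif (
            snr["GF"] > SNR_THRESHOLD
            and snr["SPF"] < SNR_THRESHOLD
            and sig
            and d > D_THRESHOLD
        ):
            call = "gf_only"
        elif snr["SPF"] > SNR_THRESHOLD and snr["GF"] > SNR_THRESHOLD:
            call = "both"
        else:
            call = "neither"
        records.append(
            {
                "feature_id": fid,
                "organ": organ,
                "snr_spf": snr["SPF"],
                "snr_gf": snr["GF"],
                "call": call,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------- #
# Venn partitioning


@dataclass
class VennSummary:
    """Organ-set membership per feature and the per-cell counts."""

    membership: pd.DataFrame      # feature_id -> spf_organs, gf_organs (frozensets as csv)
    spf_cells: dict[str, int]     # e.g. "brain+intestine" -> count
    gf_cells: dict[str, int]
    spf_any: int
    gf_any: int


def _cells(
    organ_sets: pd.Series, organs: tuple[str, ...]
) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    for i in range(1, 2 ** len(organs)):
        subset = frozenset(o for j, o in enumerate(organs) if (i >> j) & 1)
        label = "+".join(o for o in organs if o in subset)
        counts[label] = int((organ_sets == subset).sum())
    any_count = int((organ_sets.apply(len) > 0).sum())
    return counts, any_count


def venn_partition(
    diff: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    organs: tuple[str, ...] = ORGANS,
) -> VennSummary:
    """Partition features by the exact set of organs per direction.

    ``spf_organs`` is the set of organs where the feature is significantly
    SPF-higher (mirror for GF); cell counts are exact-subset counts, so the
    seven cells of each diagram sum to that direction's "at least one organ"
    margin. When presence calls are given, the same partition is computed
    for exclusive (``spf_only``/``gf_only``) features and exposed through
    the membership frame's ``spf_only_organs``/``gf_only_organs`` columns.
    """
    feats = diff.index.unique()
    spf_sets, gf_sets = {}, {}
    for fid in feats:
        rows = diff.loc[[fid]]
        spf_sets[fid] = frozenset(rows.loc[rows["direction"] == "spf_higher", "organ"])
        gf_sets[fid] = frozenset(rows.loc[rows["direction"] == "gf_higher", "organ"])
    spf_series = pd.Series(spf_sets)
    gf_series = pd.Series(gf_sets)
    membership = pd.DataFrame(
        {
            "spf_organs": spf_series.apply(lambda s: ",".join(sorted(s))),
            "gf_organs": gf_series.apply(lambda s: ",".join(sorted(s))),
        }
    )
    membership.index.name = "feature_id"
    spf_cells, spf_any = _cells(spf_series, organs)
    gf_cells, gf_any = _cells(gf_series, organs)

    if presence is not None:
        for direction, col in (("spf_only", "spf_only_organs"), ("gf_only", "gf_only_organs")):
            sets = (
                presence[presence["call"] == direction]
                .groupby("feature_id")["organ"]
                .apply(lambda s: ",".join(sorted(s)))
            )
            membership[col] = sets.reindex(membership.index).fillna("")
    return VennSummary(membership, spf_cells, gf_cells, spf_any, gf_any)
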