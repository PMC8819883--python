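"""Simplified mummichog-style m/z pathway enrichment.

Significant m/z peaks are mapped to candidate compounds under primary
adducts at a ppm tolerance, without requiring prior annotation. Per pathway,
over-representation of significant compounds is scored with a one-sided
Fisher exact test (hypergeometric tail), and an empirical null is built by
repeatedly drawing the same number of random m/z from the full feature list
and recomputing pathway hits. The compound universe defaults to every
compound reachable from the observed m/z list under the adduct rules (the
mummichog convention).

The MetaboAnalyst-style normalization used upstream of significance calls
(per-sample median normalization, cube-root transform, per-feature
autoscaling) is provided here as well.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import Adduct
from .model import FeatureTable, PathwaySet


def normalize_for_pathway(table: FeatureTable) -> FeatureTable:
    """Median-normalize per sample, cube-root transform, autoscale per feature.

    Each sample is divided by its median and multiplied by the grand median
    (so doubling every value of one sample is undone exactly), then values
    are cube-root transformed, then each feature is centred and scaled to
    unit variance. Requires strictly positive intensities (the cube root of
    negative values is disallowed by the normalization order).
    """
    out = table.copy()
    mat = out.intensities.to_numpy(float)
    if np.isnan(mat).any() or (mat <= 0).any():
        raise ValueError(
            "normalize_for_pathway requires complete, strictly positive intensities"
        )
    sample_medians = np.median(mat, axis=0, keepdims=True)
    grand = float(np.median(mat))
    mat = mat / sample_medians * grand
    mat = np.cbrt(mat)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    mat = (mat - mean) / sd
    out.intensities = pd.DataFrame(
        mat, index=out.intensities.index, columns=out.intensities.columns
    )
    return out


def mz_to_compounds(
    mz_table: pd.DataFrame,
    compound_universe: pd.DataFrame,
    adducts: tuple[Adduct, ...],
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Map each m/z to all compounds whose adduct mass lies within tolerance.

    ``mz_table`` has columns ``mz`` and boolean ``significant``;
    ``compound_universe`` has columns ``compound_id`` and
    ``monoisotopic_mass``. Returns one row per (mz, compound, adduct) match;
    isobaric candidates are all retained. A compound counts as significant
    if any significant m/z maps to it.
    """
    if not adducts:
        raise ValueError("mz_to_compounds: empty adduct set")
    masses = compound_universe["monoisotopic_mass"].to_numpy(float)
    ids = compound_universe["compound_id"].to_numpy(object)
    rows = []
    for _, r in mz_table.iterrows():
        mz = float(r["mz"])
        for adduct in adducts:
            expected = (masses + adduct.mass_shift) / abs(adduct.charge)
            ppm = np.abs(mz - expected) / expected * 1e6
            for k in np.where(ppm <= tol_ppm)[0]:
                rows.append(
                    {
                        "mz": mz,
                        "significant": bool(r["significant"]),
                        "compound_id": ids[k],
                        "adduct": adduct.name,
                        "ppm_error": float(ppm[k]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["mz", "significant", "compound_id", "adduct", "ppm_error"]
    )


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct enumeration.

    This is the one-sided Fisher exact p-value for enrichment of ``k`` hits
    among ``n`` draws when ``K`` of ``N`` universe members are in the set.
    """
    if k <= 0:
        return 1.0
    denom = math.comb(N, n)
    upper = min(K, n)
    total = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, upper + 1))
    return total / denom


@dataclass
class PathwayResult:
    pathway_id: str
    pathway_name: str
    n_members_in_universe: int
    n_significant_hits: int
    fisher_p: float
    perm_p: float
    enriched: bool


def enrich_pathways(
    candidates: pd.DataFrame,
    pathways: list[PathwaySet],
    mz_list: np.ndarray | None = None,
    compound_universe: pd.DataFrame | None = None,
    adducts: tuple[Adduct, ...] | None = None,
    tol_ppm: float = 10.0,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[PathwayResult]:
    """Score pathways on the candidate map from :func:`mz_to_compounds`.

    Fisher's exact test (one-sided, enrichment) compares significant against
    universe compounds per pathway. The permutation null redraws
    ``n_significant_mz`` m/z values from ``mz_list`` ``n_perm`` times and
    recomputes hits; ``perm_p`` is the add-one-smoothed fraction of
    permutations with at least the observed hit count. ``enriched`` means
    ``perm_p < alpha``. Pathways with no member in the universe are dropped
    with a warning.
    """
    universe = set(candidates["compound_id"])
    sig_compounds = set(candidates.loc[candidates["significant"], "compound_id"])
    sig_mz = candidates.loc[candidates["significant"], "mz"].unique()
    N, n = len(universe), len(sig_compounds)

    do_perm = (
        n_perm > 0 and mz_list is not None and compound_universe is not None
        and adducts is not None and len(sig_mz) > 0
    )
    perm_hits: dict[str, np.ndarray] = {}
    kept = []
    for pw in pathways:
        members = pw.member_compounds & universe
        if not members:
            import warnings

            warnings.warn(
                f"pathway {pw.pathway_id} has no members in the compound universe",
                stacklevel=2,
            )
            continue
        kept.append((pw, members))
        perm_hits[pw.pathway_id] = np.zeros(n_perm, dtype=int)

    if do_perm:
        rng = np.random.default_rng(seed)
        mz_pool = np.asarray(mz_list, dtype=float)
        for b in range(n_perm):
            draw = rng.choice(mz_pool, size=len(sig_mz), replace=False)
            perm_table = pd.DataFrame({"mz": draw, "significant": True})
            perm_cand = mz_to_compounds(
                perm_table, compound_universe, adducts, tol_ppm
            )
            perm_sig = set(perm_cand["compound_id"])
            for pw, members in kept:
                perm_hits[pw.pathway_id][b] = len(perm_sig & members)

    results = []
    for pw, members in kept:
        k = len(sig_compounds & members)
        fisher_p = hypergeom_tail(N, len(members), n, k)
        if do_perm:
            exceed = int(np.sum(perm_hits[pw.pathway_id] >= k)) if k > 0 else n_perm
            perm_p = (1 + exceed) / (n_perm + 1)
        else:
            perm_p = float("nan")
        results.append(
            PathwayResult(
                pathway_id=pw.pathway_id,
                pathway_name=pw.pathway_name,
                n_members_in_universe=len(members),
                n_significant_hits=k,
                fisher_p=fisher_p,
                perm_p=perm_p,
                enriched=bool(perm_p < alpha) if do_perm else bool(fisher_p < alpha),
            )
        )
    return results


def results_frame(results: list[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
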