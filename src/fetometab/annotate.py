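"""Compound annotation against a reference library with MSI confidence levels.

Each feature (m/z, retention time, optional MS2 spectrum) is compared with
library entries under a configured set of primary adducts. The assigned
identification level follows the Metabolomics Standards Initiative (CAWG)
scheme:

* **Level 1** — confirmed identification: in-house standard with matching
  retention time, accurate mass and MS2 spectrum.
* **Level 2** — putative annotation: matching m/z and MS2 against any
  source; or, when no MS2 is available, matching retention time and
  molecular formula against an in-house standard.
* **Level 3** — putative compound class, via a user-supplied class rule
  table (class-characteristic fragments or mass-defect windows). Without a
  rule table no level-3 calls are made.
* **Level 4** — unknown (everything else).

The first satisfied level wins (1 before 2 before 3); ties across entries
are broken by higher MS2 score, then smaller ppm error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ReferenceLibraryEntry

PROTON = 1.007276466


@dataclass(frozen=True)
class Adduct:
    name: str
    mass_shift: float
    charge: int = 1


#: Primary ions per ionization polarity.
POSITIVE_ADDUCTS = (
    Adduct("[M+H]+", PROTON),
    Adduct("[M+Na]+", 22.989218),
)
NEGATIVE_ADDUCTS = (
    Adduct("[M-H]-", -PROTON),
    Adduct("[M+Cl]-", 34.969402),
)


def adducts_for_mode(mode: str) -> tuple[Adduct, ...]:
    return POSITIVE_ADDUCTS if mode.endswith("+") else NEGATIVE_ADDUCTS


@dataclass
class MatchTolerances:
    mz_ppm: float = 10.0
    rt_window: float = 0.1      # minutes
    ms2_threshold: float = 0.7  # modified-cosine score
    fragment_tol: float = 0.02  # Da


@dataclass
class AnnotationRecord:
    feature_id: str
    msi_level: int
    compound_name: str | None = None
    matched_source: str = "none"
    ms2_score: float | None = None
    ppm_error: float | None = None
    adduct: str | None = None
    evidence: dict = field(default_factory=dict)


def ms2_cosine(
    spec_a: list[tuple[float, float]],
    spec_b: list[tuple[float, float]],
    fragment_tol_da: float = 0.02,
) -> float:
    """Greedy one-to-one matched cosine of square-root intensities.

    Candidate peak pairs within the fragment tolerance are matched greedily
    by decreasing intensity product; the score is the cosine between the
    square-root intensity vectors, with unmatched peaks contributing only to
    the norms. Identical spectra score 1, disjoint spectra 0.
    """
    if not spec_a or not spec_b:
        raise ValueError("ms2_cosine: empty spectrum")
    a = np.sqrt(np.asarray([i for _, i in spec_a], dtype=float))
    b = np.sqrt(np.asarray([i for _, i in spec_b], dtype=float))
    mza = np.asarray([m for m, _ in spec_a], dtype=float)
    mzb = np.asarray([m for m, _ in spec_b], dtype=float)

    pairs = [
        (float(a[i] * b[j]), i, j)
        for i in range(len(mza))
        for j in range(len(mzb))
        if abs(mza[i] - mzb[j]) <= fragment_tol_da
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for prod, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += prod
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    return dot / denom if denom > 0 else 0.0


def _ppm_error(observed_mz: float, entry_mass: float, adduct: Adduct) -> float:
    expected = (entry_mass + adduct.mass_shift) / abs(adduct.charge)
    return abs(observed_mz - expected) / expected * 1e6


def match_feature(
    feature_id: str,
    mz: float,
    rt: float,
    library: list[ReferenceLibraryEntry],
    ms2: list[tuple[float, float]] | None = None,
    adducts: tuple[Adduct, ...] = POSITIVE_ADDUCTS,
    tolerances: MatchTolerances | None = None,
    class_rules: pd.DataFrame | None = None,
) -> AnnotationRecord:
    """Annotate one feature; returns the best-evidence record.

    ``class_rules`` (optional) has columns ``compound_class``, ``mz_min``,
    ``mz_max`` and supports level-3 class calls; without it the outcome is
    level 1, 2 or 4.
    """
    tol = tolerances or MatchTolerances()
    candidates: list[AnnotationRecord] = []
    for entry in library:
        best_ppm, best_adduct = None, None
        for adduct in adducts:
            ppm = _ppm_error(mz, entry.monoisotopic_mass, adduct)
            if ppm <= tol.mz_ppm and (best_ppm is None or ppm < best_ppm):
                best_ppm, best_adduct = ppm, adduct
        mz_match = best_ppm is not None
        rt_match = entry.rt is not None and abs(rt - entry.rt) <= tol.rt_window
        score = None
        if ms2 and entry.ms2:
            score = ms2_cosine(ms2, entry.ms2, tol.fragment_tol)
        ms2_match = score is not None and score >= tol.ms2_threshold
        formula_match = entry.formula is not None and mz_match

        level = 4
        if (
            entry.source == "in_house"
            and rt_match
            and mz_match
            and ms2_match
        ):
            level = 1
        elif mz_match and ms2_match:
            level = 2
        elif (
            ms2 is None
            and entry.source == "in_house"
            and rt_match
            and formula_match
        ):
            level = 2
        if level == 4:
            continue
        candidates.append(
            AnnotationRecord(
                feature_id=feature_id,
                msi_level=level,
                compound_name=entry.compound_name,
                matched_source=entry.source,
                ms2_score=score,
                ppm_error=best_ppm,
                adduct=best_adduct.name if best_adduct else None,
                evidence={
                    "mz_match": mz_match,
                    "rt_match": rt_match,
                    "ms2_match": ms2_match,
                    "formula_match": formula_match,
                    "class_only": False,
                },
            )
        )
    if candidates:
        candidates.sort(
            key=lambda r: (
                r.msi_level,
                -(r.ms2_score if r.ms2_score is not None else -1.0),
                r.ppm_error if r.ppm_error is not None else math.inf,
            )
        )
        return candidates[0]

    if class_rules is not None and len(class_rules):
        hit = class_rules[
            (class_rules["mz_min"] <= mz) & (mz <= class_rules["mz_max"])
        ]
        if len(hit):
            return AnnotationRecord(
                feature_id=feature_id,
                msi_level=3,
                compound_name=None,
                matched_source="none",
                evidence={"class_only": True,
                          "compound_class": str(hit.iloc[0]["compound_class"])},
            )
    return AnnotationRecord(feature_id=feature_id, msi_level=4)


def annotate_table(
    features: pd.DataFrame,
    library: list[ReferenceLibraryEntry],
    spectra: dict[str, list[tuple[float, float]]] | None = None,
    tolerances: MatchTolerances | None = None,
    class_rules: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate every feature in a feature-metadata frame.

    ``features`` is indexed by feature_id with ``mode``, ``mz``, ``rt``;
    ``spectra`` optionally maps feature_id to an MS2 peak list. One compound
    can match several features (adducts, modes); the best-evidence feature
    per compound is flagged ``representative``.
    """
    spectra = spectra or {}
    records = []
    for fid, row in features.iterrows():
        rec = match_feature(
            feature_id=str(fid),
            mz=float(row["mz"]),
            rt=float(row["rt"]),
            library=library,
            ms2=spectra.get(fid),
            adducts=adducts_for_mode(str(row["mode"])),
            tolerances=tolerances,
            class_rules=class_rules,
        )
        records.append(
            {
                "feature_id": rec.feature_id,
                "msi_level": rec.msi_level,
                "compound_name": rec.compound_name,
                "matched_source": rec.matched_source,
                "ms2_score": rec.ms2_score,
                "ppm_error": rec.ppm_error,
                "adduct": rec.adduct,
            }
        )
    out = pd.DataFrame.from_records(records).set_index("feature_id")
    out["representative"] = False
    annotated = out.dropna(subset=["compound_name"])
    for _, grp in annotated.groupby("compound_name"):
        best = grp.sort_values(
            by=["msi_level", "ms2_score", "ppm_error"],
            ascending=[True, False, True],
            na_position="last",
        ).index[0]
        out.loc[best, "representative"] = True
    return out
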