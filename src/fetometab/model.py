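"""Shared data model for the pipeline.

The central exchange object is :class:`FeatureTable`: an intensity matrix
(features x injections, ``NaN`` = not detected) together with per-feature
metadata (analytical mode, m/z, retention time) and per-injection metadata
(injection order, sample type, experimental group, organ, dam, fetus sex).
Every stage of the pipeline consumes and produces this object.

Missing values are represented by a single sentinel (``NaN``) throughout;
zero-coded exports are converted at read time (see :mod:`fetometab.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The four analytical modes: reversed-phase and HILIC chromatography,
#: each with positive and negative electrospray ionization.
MODES = ("RP+", "RP-", "HILIC+", "HILIC-")

#: Organs sampled from each fetus.
ORGANS = ("brain", "intestine", "placenta")

#: Experimental groups: germ-free and specific-pathogen-free dams.
GROUPS = ("GF", "SPF")

#: Sample types: biological injections and pooled quality-control injections.
SAMPLE_TYPES = ("biological", "qc")

#: m/z window of the peak collection, in Da.
MZ_RANGE = (50.0, 1500.0)

FEATURE_COLUMNS = ("mode", "mz", "rt")
INJECTION_COLUMNS = (
    "injection_order",
    "sample_type",
    "group",
    "organ",
    "dam_id",
    "fetus_sex",
)


class FeatureTableError(ValueError):
    """Raised when a feature table violates its invariants."""


def make_feature_id(mode: str, mz: float, rt: float) -> str:
    """Build the canonical ``mode_mz@rt`` feature identifier."""
    return f"{mode}_{mz:.4f}@{rt:.2f}"


@dataclass
class FeatureTable:
    """Feature intensity matrix with feature and injection metadata.

    Parameters
    ----------
    intensities
        Float DataFrame, rows indexed by ``feature_id``, columns by
        ``injection_id``. ``NaN`` marks a non-detected cell; present values
        are non-negative.
    features
        DataFrame indexed by ``feature_id`` with columns ``mode``
        (one of :data:`MODES`), ``mz`` (Da) and ``rt`` (minutes).
    injections
        DataFrame indexed by ``injection_id`` with columns
        ``injection_order`` (positive int, unique), ``sample_type``
        (``biological``/``qc``), ``group`` (``GF``/``SPF``, empty for QC),
        ``organ`` (empty for QC), ``dam_id`` and ``fetus_sex``.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    injections: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    # invariants

    def validate(self) -> None:
        """Check all invariants; raise :class:`FeatureTableError` on violation."""
        ints, feats, injs = self.intensities, self.features, self.injections
        if ints.index.has_duplicates:
            dup = ints.index[ints.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature_id(s): {dup}")
        if ints.columns.has_duplicates:
            dup = ints.columns[ints.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate injection_id(s): {dup}")
        if not ints.index.equals(feats.index):
            raise FeatureTableError(
                "intensity rows and feature metadata must share the same index"
            )
        if not ints.columns.equals(injs.index):
            raise FeatureTableError(
                "intensity columns and injection metadata must share the same index"
            )
        missing_cols = set(FEATURE_COLUMNS) - set(feats.columns)
        if missing_cols:
            raise FeatureTableError(f"feature metadata lacks columns {sorted(missing_cols)}")
        missing_cols = set(INJECTION_COLUMNS) - set(injs.columns)
        if missing_cols:
            raise FeatureTableError(f"injection metadata lacks columns {sorted(missing_cols)}")

        bad_modes = set(feats["mode"].unique()) - set(MODES)
        if bad_modes:
            raise FeatureTableError(f"unknown mode label(s): {sorted(bad_modes)}")
        mz = feats["mz"].to_numpy(float)
        if np.any((mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])):
            raise FeatureTableError(
                f"m/z outside the peak-collection window {MZ_RANGE}"
            )
        vals = ints.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FeatureTableError("negative intensity values")

        bad_types = set(injs["sample_type"].unique()) - set(SAMPLE_TYPES)
        if bad_types:
            raise FeatureTableError(f"unknown sample_type label(s): {sorted(bad_types)}")
        order = injs["injection_order"]
        if order.isna().any() or (order <= 0).any():
            raise FeatureTableError("injection_order must be a positive integer")
        if order.duplicated().any():
            raise FeatureTableError("injection_order must be unique")
        bio = injs[injs["sample_type"] == "biological"]
        lacking = bio.index[
            bio["group"].isna()
            | ~bio["group"].isin(GROUPS)
            | bio["organ"].isna()
            | ~bio["organ"].isin(ORGANS)
        ]
        if len(lacking):
            raise FeatureTableError(
                f"biological injection(s) lacking valid group/organ: {list(lacking)}"
            )

    # ------------------------------------------------------------------ #
    # convenience accessors

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_injections(self) -> int:
        return self.intensities.shape[1]

    @property
    def qc_ids(self) -> pd.Index:
        return self.injections.index[self.injections["sample_type"] == "qc"]

    @property
    def biological_ids(self) -> pd.Index:
        return self.injections.index[self.injections["sample_type"] == "biological"]

    def modes(self) -> list[str]:
        """Modes present, in canonical order."""
        present = set(self.features["mode"])
        return [m for m in MODES if m in present]

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        idx = pd.Index(feature_ids)
        return FeatureTable(
            self.intensities.loc[idx].copy(),
            self.features.loc[idx].copy(),
            self.injections.copy(),
        )

    def subset_injections(self, injection_ids: Iterable[str]) -> "FeatureTable":
        idx = pd.Index(injection_ids)
        return FeatureTable(
            self.intensities[idx].copy(),
            self.features.copy(),
            self.injections.loc[idx].copy(),
        )

    def restrict_organ(self, organ: str) -> "FeatureTable":
        """Biological injections of one organ only (QCs dropped)."""
        if organ not in ORGANS:
            raise FeatureTableError(f"unknown organ {organ!r}")
        keep = self.injections.index[
            (self.injections["sample_type"] == "biological")
            & (self.injections["organ"] == organ)
        ]
        return self.subset_injections(keep)

    def drop_qc(self) -> "FeatureTable":
        return self.subset_injections(self.biological_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.features.copy(), self.injections.copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeatureTable({self.n_features} features x {self.n_injections} "
            f"injections, modes={self.modes()})"
        )


@dataclass
class ReferenceLibraryEntry:
    """One compound in the reference library.

    ``source`` separates in-house standards (run on the same instrument,
    with retention times) from public database entries (mass and MS2 only).
    ``ms2`` is a list of ``(mz, relative_intensity)`` pairs or ``None``.
    """

    compound_name: str
    monoisotopic_mass: float
    formula: str | None = None
    rt: float | None = None
    ms2: list[tuple[float, float]] | None = None
    source: str = "public"
    compound_class: str | None = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(
                f"{self.compound_name}: monoisotopic_mass must be > 0"
            )
        if self.ms2 is not None:
            if any(i < 0 for _, i in self.ms2):
                raise ValueError(f"{self.compound_name}: negative MS2 intensity")
        if self.source not in ("in_house", "public"):
            raise ValueError(f"{self.compound_name}: unknown source {self.source!r}")
        if self.source == "in_house" and self.rt is None:
            raise ValueError(
                f"{self.compound_name}: in-house entries must carry a retention time"
            )


@dataclass
class PathwaySet:
    """A named set of compounds, GMT-style."""

    pathway_id: str
    pathway_name: str
    member_compounds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.member_compounds:
            raise ValueError(f"pathway {self.pathway_id}: empty member set")


def sample_groups(injections: pd.DataFrame) -> dict[str, pd.Index]:
    """Map group label -> injection ids of biological samples in that group."""
    bio = injections[injections["sample_type"] == "biological"]
    return {g: bio.index[bio["group"] == g] for g in GROUPS}
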