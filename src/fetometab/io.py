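"""Readers and writers for the pipeline's external formats.

Feature matrices are delimited text with features in rows and injections in
columns, plus a sidecar injection-metadata table; spectral libraries are
NIST-style MSP as written by common alignment software; pathway sets are GMT.
All output is TSV, UTF-8, ``.`` decimal separator, so diffs are bit-stable.
"""
from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    FEATURE_COLUMNS,
    INJECTION_COLUMNS,
    FeatureTable,
    FeatureTableError,
    ReferenceLibraryEntry,
    PathwaySet,
    make_feature_id,
)

#: Fixed float formatting for all result tables (round-trips doubles exactly
#: for the precision we guarantee, 1e-9 relative).
FLOAT_FORMAT = "%.12g"


@dataclass
class Dialect:
    """How to interpret a delimited feature matrix."""

    sep: str = "\t"
    #: treat exact 0 cells as missing (MS-DIAL exports are 0-filled)
    zero_as_missing: bool = False
    na_values: tuple[str, ...] = ("", "NA", "NaN", "nan")


def read_feature_table(
    path: str | Path,
    metadata_path: str | Path,
    dialect: Dialect | None = None,
) -> FeatureTable:
    """Read a feature matrix and its injection metadata sidecar.

    The matrix file must have a ``feature_id`` column (created as
    ``mode_mz@rt`` when absent), ``mode``, ``mz`` and ``rt`` columns, and one
    column per injection. Missing cells may be empty, ``NA`` or -- with
    ``dialect.zero_as_missing`` -- zero-coded; all are converted to a single
    internal missing sentinel (NaN).
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(
        path, sep=dialect.sep, na_values=list(dialect.na_values),
        keep_default_na=False, dtype={"feature_id": str, "mode": str},
    )
    meta_cols = [c for c in ("feature_id",) + FEATURE_COLUMNS if c in raw.columns]
    for required in FEATURE_COLUMNS:
        if required not in raw.columns:
            raise FeatureTableError(f"{path}: missing feature column {required!r}")
    if "feature_id" not in raw.columns:
        raw.insert(
            0,
            "feature_id",
            [
                make_feature_id(m, z, t)
                for m, z, t in zip(raw["mode"], raw["mz"], raw["rt"])
            ],
        )
        meta_cols = ["feature_id"] + meta_cols
    if raw["feature_id"].duplicated().any():
        dup = raw.loc[raw["feature_id"].duplicated(), "feature_id"].tolist()
        raise FeatureTableError(f"{path}: duplicate feature_id(s): {dup}")

    features = raw[meta_cols].set_index("feature_id")
    features["mz"] = features["mz"].astype(float)
    features["rt"] = features["rt"].astype(float)
    intensities = raw.drop(columns=meta_cols).set_index(raw["feature_id"]).astype(float)
    intensities.index.name = "feature_id"
    if dialect.zero_as_missing:
        intensities = intensities.mask(intensities == 0.0)

    injections = pd.read_csv(
        metadata_path, sep=dialect.sep, na_values=list(dialect.na_values),
        keep_default_na=False, dtype=str,
    )
    if "injection_id" not in injections.columns:
        raise FeatureTableError(f"{metadata_path}: missing injection_id column")
    injections = injections.set_index("injection_id")
    for required in INJECTION_COLUMNS:
        if required not in injections.columns:
            raise FeatureTableError(
                f"{metadata_path}: missing metadata column {required!r}"
            )
    injections["injection_order"] = injections["injection_order"].astype(int)
    unknown = [c for c in intensities.columns if c not in injections.index]
    if unknown:
        raise FeatureTableError(
            f"{path}: injection column(s) {unknown} absent from metadata"
        )
    injections = injections.loc[intensities.columns]
    return FeatureTable(intensities, features, injections)


def write_feature_table(
    table: FeatureTable, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a feature table to a matrix TSV plus metadata sidecar TSV."""
    out = pd.concat([table.features, table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT)
    meta = table.injections.copy()
    meta.index.name = "injection_id"
    meta.to_csv(metadata_path, sep="\t", float_format=FLOAT_FORMAT)


def merge_modes(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Row-concatenate per-mode tables over a shared injection set.

    Feature ids clashing across modes are disambiguated by prefixing with
    their mode; intensity values are carried through untouched.
    """
    if not tables:
        raise FeatureTableError("merge_modes: no tables given")
    ref = tables[0]
    for t in tables[1:]:
        if set(t.intensities.columns) != set(ref.intensities.columns):
            raise FeatureTableError(
                "merge_modes: tables do not share an identical injection set"
            )
    aligned = [t.intensities[ref.intensities.columns] for t in tables]
    feats = [t.features.copy() for t in tables]

    all_ids = pd.concat([f.index.to_series() for f in feats])
    clashes = set(all_ids[all_ids.duplicated()])
    if clashes:
        for t, (mat, f) in zip(tables, zip(aligned, feats)):
            renamer = {
                fid: f"{mode}_{fid}"
                for fid, mode in f["mode"].items()
                if fid in clashes
            }
            mat.rename(index=renamer, inplace=True)
            f.rename(index=renamer, inplace=True)

    intensities = pd.concat(aligned, axis=0)
    features = pd.concat(feats, axis=0)
    if intensities.index.has_duplicates:
        dup = intensities.index[intensities.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"merge_modes: unresolved duplicate ids {dup}")
    return FeatureTable(intensities, features, ref.injections.copy())


# ---------------------------------------------------------------------- #
# MSP spectral libraries


class MSPError(ValueError):
    """Malformed MSP library file."""


def read_msp_library(path: str | Path) -> list[ReferenceLibraryEntry]:
    """Parse a NIST-dialect MSP library into reference entries.

    Recognized header fields (case-insensitive): ``NAME``, ``PRECURSORMZ``,
    ``FORMULA``, ``EXACTMASS``/``MONOISOTOPICMASS``, ``RETENTIONTIME``,
    ``SOURCE``, ``COMPOUNDCLASS``, ``Num Peaks``. Peak lines are
    ``mz intensity`` (whitespace or tab separated); a malformed peak line is
    an error citing its line number.
    """
    entries: list[ReferenceLibraryEntry] = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_expected = 0
    in_peaks = False

    def flush() -> None:
        nonlocal fields, peaks, n_expected, in_peaks
        if not fields:
            return
        name = fields.get("name")
        if name is None:
            raise MSPError(f"{path}: entry without NAME")
        mass = None
        for key in ("exactmass", "monoisotopicmass", "precursormz"):
            if key in fields:
                mass = float(fields[key])
                break
        if mass is None:
            raise MSPError(f"{path}: entry {name!r} has no mass field")
        rt = float(fields["retentiontime"]) if "retentiontime" in fields else None
        entries.append(
            ReferenceLibraryEntry(
                compound_name=name,
                monoisotopic_mass=mass,
                formula=fields.get("formula"),
                rt=rt,
                ms2=list(peaks) if peaks else None,
                source=fields.get("source", "public"),
                compound_class=fields.get("compoundclass"),
            )
        )
        fields, peaks, n_expected, in_peaks = {}, [], 0, False

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                flush()
                continue
            if in_peaks and len(peaks) < n_expected:
                parts = line.replace(";", " ").split()
                try:
                    mz, inten = float(parts[0]), float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise MSPError(
                        f"{path}:{lineno}: malformed peak line {line!r}"
                    ) from exc
                peaks.append((mz, inten))
                continue
            if ":" in line:
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "")
                value = value.strip()
                if key == "numpeaks":
                    n_expected = int(value)
                    in_peaks = True
                else:
                    fields[key] = value
            else:
                raise MSPError(f"{path}:{lineno}: unexpected line {line!r}")
    flush()
    return entries


def write_msp_library(
    entries: Iterable[ReferenceLibraryEntry], path: str | Path
) -> None:
    """Write reference entries back to MSP (used by the simulator and tests)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"NAME: {e.compound_name}\n")
            fh.write(f"EXACTMASS: {e.monoisotopic_mass:.6f}\n")
            if e.formula:
                fh.write(f"FORMULA: {e.formula}\n")
            if e.rt is not None:
                fh.write(f"RETENTIONTIME: {e.rt:.3f}\n")
            fh.write(f"SOURCE: {e.source}\n")
            if e.compound_class:
                fh.write(f"COMPOUNDCLASS: {e.compound_class}\n")
            if e.ms2:
                fh.write(f"Num Peaks: {len(e.ms2)}\n")
                for mz, inten in e.ms2:
                    fh.write(f"{mz:.4f}\t{inten:.6g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------- #
# GMT pathway sets


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read pathway sets from GMT (``pathway_id TAB name TAB member...``)."""
    out: list[PathwaySet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, name and >= 1 member"
                )
            out.append(
                PathwaySet(parts[0], parts[1], {m for m in parts[2:] if m})
            )
    return out


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pathways:
            members = "\t".join(sorted(p.member_compounds))
            fh.write(f"{p.pathway_id}\t{p.pathway_name}\t{members}\n")


# ---------------------------------------------------------------------- #
# result tables and the run manifest


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write result DataFrames as TSV plus a run manifest.

    Returns the manifest dict; re-reading any written table reproduces its
    numeric values to within 1e-9 relative (in practice exactly, via the
    12-significant-digit float format).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config": dict(config) if config is not None else None,
        "python": sys.version.split()[0],
        "tables": {},
    }
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["tables"][name] = {
            "path": path.name,
            "n_rows": int(df.shape[0]),
            "sha256": digest,
        }
    if config is not None:
        cfg_blob = json.dumps(manifest["config"], sort_keys=True).encode()
        manifest["config_sha256"] = hashlib.sha256(cfg_blob).hexdigest()
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
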