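"""End-to-end orchestration: cleanup per mode -> drift correction per mode ->
merge -> imputation -> per-organ statistics -> exclusivity calls -> Venn
partitioning -> clustering, with a run manifest for exact reproduction.

Drift correction runs per mode before merging, since the QC drift curves are
mode-specific; imputation runs on the merged, QC-free table. Thresholds
default to the study's values (QC detection > 70%, group detection >= 60%,
RSD* < 20%, D-ratio* < 10%, rescue < 10%, q < 0.05, |d| > 0.8, SNR 5,
10 ppm, k = 10).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .cluster import kmeans_rows, tsne_embed
from .drift import correct_drift
from .impute import impute_rf
from .model import FeatureTable, ORGANS
from .qc import QCThresholds, cleanup_table
from .simulate import SyntheticConfig, config_to_dict, generate_dataset
from .stats import (
    call_presence,
    differential_all_organs,
    estimate_noise_floor,
    venn_partition,
)

log = logging.getLogger("fetometab")


@dataclass
class RunConfig:
    """Pipeline configuration; serialized verbatim into the run manifest."""

    seed: int = 0
    out_dir: str = "fetometab_run"
    # input: either per-mode (matrix, metadata) file pairs, or a synthetic config
    input_files: list[tuple[str, str]] | None = None
    synthetic: dict | None = None
    zero_as_missing: bool = False
    # stage toggles
    run_qc: bool = True
    run_drift: bool = True
    run_impute: bool = True
    run_stats: bool = True
    run_cluster: bool = False
    #: correct drift before computing QC metrics (default): uncorrected
    #: drift inflates QC dispersion and would flag otherwise good features
    drift_before_qc: bool = True
    # thresholds (defaults are the study's)
    qc_thresholds: dict = field(
        default_factory=lambda: asdict(QCThresholds())
    )
    drift_gate: bool = True
    impute_log_scale: bool = True
    noise_floor: float | None = None   # None -> estimated per mode
    equal_var: bool = True
    tsne_perplexity: float = 10.0
    kmeans_k: int = 10

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["input_files"] is not None:
            d["input_files"] = [list(p) for p in d["input_files"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("input_files") is not None:
            d["input_files"] = [tuple(p) for p in d["input_files"]]
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _load_inputs(config: RunConfig) -> tuple[dict[str, FeatureTable], pd.DataFrame | None]:
    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        tables, truth = generate_dataset(syn)
        return tables, truth.reset_index()
    if not config.input_files:
        raise StageError("input: neither input_files nor a synthetic config given")
    dialect = fio.Dialect(zero_as_missing=config.zero_as_missing)
    tables = {}
    for matrix, meta in config.input_files:
        t = fio.read_feature_table(matrix, meta, dialect)
        for mode in t.modes():
            ids = t.features.index[t.features["mode"] == mode]
            tables[mode] = t.subset_features(ids)
    return tables, None


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages in order; returns the run directory.

    Every stage logs its input/output feature counts; a failure aborts the
    run with the failing stage named, keeping partial outputs on disk.
    Deterministic outputs are byte-identical across re-runs with the same
    config and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    stage = "input"
    try:
        tables, truth = _load_inputs(config)
        if truth is not None:
            results["truth"] = truth
        n_in = sum(t.n_features for t in tables.values())
        log.info("input: %d features over %d mode(s)", n_in, len(tables))

        stage = "drift"
        drift_frames = []
        if config.run_drift and config.drift_before_qc:
            for mode in list(tables):
                corrected, report = correct_drift(tables[mode], gate=config.drift_gate)
                tables[mode] = corrected
                r = report.reset_index()
                r.insert(1, "mode", mode)
                drift_frames.append(r)
                log.info(
                    "drift %s: correction applied to %d/%d features",
                    mode, int(report["applied"].sum()), len(report),
                )

        kept_tables: dict[str, FeatureTable] = {}
        raw_tables: dict[str, FeatureTable] = {}
        qc_frames = []
        stage = "qc"
        if config.run_qc:
            th = QCThresholds(**config.qc_thresholds)
            for mode, t in tables.items():
                kept, flagged, metrics = cleanup_table(t, th)
                n_kept, n_flagged = kept.n_features, flagged.n_features
                assert n_kept + n_flagged == t.n_features, "count conservation"
                log.info(
                    "qc %s: %d in = %d kept + %d flagged",
                    mode, t.n_features, n_kept, n_flagged,
                )
                m = metrics.reset_index(names="feature_id")
                m.insert(1, "mode", mode)
                qc_frames.append(m)
                kept_tables[mode] = kept
                raw_tables[mode] = t
            results["qc_metrics"] = pd.concat(qc_frames, ignore_index=True)
        else:
            log.warning("qc stage disabled; downstream statistics run on uncleaned data")
            kept_tables = {m: t.copy() for m, t in tables.items()}
            raw_tables = tables

        stage = "drift"
        if config.run_drift and not config.drift_before_qc:
            for mode in list(kept_tables):
                corrected, report = correct_drift(
                    kept_tables[mode], gate=config.drift_gate
                )
                kept_tables[mode] = corrected
                r = report.reset_index()
                r.insert(1, "mode", mode)
                drift_frames.append(r)
                log.info(
                    "drift %s: correction applied to %d/%d features",
                    mode, int(report["applied"].sum()), len(report),
                )
        if drift_frames:
            results["drift_report"] = pd.concat(drift_frames, ignore_index=True)

        stage = "merge"
        merged = fio.merge_modes(list(kept_tables.values()))
        raw_merged = fio.merge_modes(list(raw_tables.values()))
        log.info("merge: %d features after combining modes", merged.n_features)

        stage = "impute"
        if config.run_impute:
            imputed, oob = impute_rf(
                merged.drop_qc(), seed=config.seed, log_scale=config.impute_log_scale
            )
            log.info("impute: OOB error %.4g", oob)
        else:
            imputed, oob = merged.drop_qc(), float("nan")
        fio.write_feature_table(
            imputed, out_dir / "imputed_matrix.tsv", out_dir / "injection_metadata.tsv"
        )

        stage = "stats"
        if config.run_stats:
            organs = tuple(o for o in ORGANS if o in set(imputed.injections["organ"]))
            diff = differential_all_organs(imputed, organs, equal_var=config.equal_var)
            floors = (
                config.noise_floor
                if config.noise_floor is not None
                else estimate_noise_floor(raw_merged)
            )
            presence = call_presence(raw_merged, diff, floors)
            venn = venn_partition(diff, presence, organs)
            results["differential"] = diff.reset_index()
            results["presence_calls"] = presence
            results["venn_membership"] = venn.membership.reset_index()
            results["venn_counts"] = pd.DataFrame(
                [
                    {"direction": "spf_higher", "cell": cell, "count": cnt}
                    for cell, cnt in venn.spf_cells.items()
                ]
                + [
                    {"direction": "gf_higher", "cell": cell, "count": cnt}
                    for cell, cnt in venn.gf_cells.items()
                ]
                + [
                    {"direction": "spf_higher", "cell": "any", "count": venn.spf_any},
                    {"direction": "gf_higher", "cell": "any", "count": venn.gf_any},
                ]
            )
            log.info(
                "stats: %d SPF-higher / %d GF-higher in >= 1 organ",
                venn.spf_any, venn.gf_any,
            )

        stage = "cluster"
        if config.run_cluster:
            organs = tuple(o for o in ORGANS if o in set(imputed.injections["organ"]))

            def _perp(n_samples: int) -> float:
                # respect the n >= 3 * perplexity feasibility bound per scope
                return min(config.tsne_perplexity, max(2.0, (n_samples - 1) / 3.0))

            n_all = len(imputed.biological_ids)
            embeddings = [tsne_embed(imputed, "all", _perp(n_all), config.seed)]
            clusters = []
            for o in organs:
                n_o = int((imputed.injections["organ"] == o).sum())
                embeddings.append(
                    tsne_embed(imputed, o, _perp(n_o), config.seed)
                )
                clusters.append(
                    kmeans_rows(imputed, o, k=config.kmeans_k, seed=config.seed)
                    .reset_index()
                )
            results["embeddings"] = pd.concat(
                [e.reset_index() for e in embeddings], ignore_index=True
            )
            results["clusters"] = pd.concat(clusters, ignore_index=True)
    except Exception as exc:
        fio.write_results(results, out_dir, config=config.to_dict(), seed=config.seed)
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    fio.write_results(results, out_dir, config=config.to_dict(), seed=config.seed)
    return out_dir


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Re-run a pipeline exactly as recorded in a manifest."""
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    config.out_dir = str(out_dir)
    return run_pipeline(config)
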