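"""Pipeline orchestration: files in, consolidated condition report out.

Chains the stages -- input validation, headspace decoding, per-vial
kinetics, per-condition aggregation (mean and n-1 sd over replicate vials),
dose-response fits per exposure modality, and community indices when count
tables are provided -- under one seeded, logged configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import io as bio
from .gas_kinetics import cod_removal_efficiency, cumulative_methane, summarize_kinetics
from .inhibition import (
    DoseResponsePoint,
    bootstrap_ic50_ci,
    compare_modalities,
    fit_dose_response,
    ic50_interpolated,
)

logger = logging.getLogger("bmpkit")

CONDITION_METRICS = ("ammonium_g_per_L", "latency_days", "mpr", "yield_ml_per_g_cod",
                     "residual_scod_g_per_L", "cod_removal_pct")


@dataclass
class RunConfig:
    measurements: str | Path
    metadata: str | Path
    chemistry: str | Path | None = None
    counts: str | Path | None = None
    taxonomy: str | Path | None = None
    sample_meta: str | Path | None = None
    qpcr: str | Path | None = None
    pressure_unit: str = "Pa"
    latency_floor: float | None = None  # Nml; None = automatic
    window_sizes: tuple[int, ...] = (4, 5, 6)
    monotone_clamp: bool = False
    dose_response_model: str = "log_logistic_3p"
    n_boot: int = 0
    rarefaction_depth: int | None = None  # None = depth of the shallowest sample
    network_rank: str = "family"
    network_top_k: int = 50
    network_r_threshold: float = 0.8
    network_alpha: float = 0.05
    seed: int = 0
    out_dir: str | Path | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window_sizes" in data:
            data["window_sizes"] = tuple(data["window_sizes"])
        return cls(**data)


@dataclass
class PipelineReport:
    vial_table: pd.DataFrame
    condition_table: pd.DataFrame
    fits: dict
    comparison: dict | None
    community: dict
    validation: bio.ValidationReport
    config: RunConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vials": out / "vial_kinetics.csv",
            "conditions": out / "condition_summary.csv",
            "fits": out / "dose_response.json",
        }
        self.vial_table.to_csv(paths["vials"], index=False)
        self.condition_table.to_csv(paths["conditions"], index=False)
        payload = {
            "fits": {
                m: {k: v for k, v in dataclasses.asdict(f).items()}
                for m, f in self.fits.items()
            },
            "comparison": self.comparison,
            "seed": self.config.seed,
        }
        paths["fits"].write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
        return paths


def validate_config(config: RunConfig) -> bio.ValidationReport:
    paths = {
        "measurements": config.measurements,
        "metadata": config.metadata,
        "chemistry": config.chemistry,
        "counts": config.counts,
        "taxonomy": config.taxonomy,
        "sample_meta": config.sample_meta,
        "qpcr": config.qpcr,
    }
    return bio.validate_inputs(paths, {"pressure_unit": config.pressure_unit})


def _vial_kinetics_table(config: RunConfig) -> pd.DataFrame:
    measurements = bio.read_measurements(config.measurements, config.pressure_unit)
    vials = bio.read_vial_metadata(config.metadata)
    meta_frame = bio.read_metadata_frame(config.metadata).set_index("vial_id")
    chemistry = None
    if config.chemistry is not None:
        chemistry = bio.read_chemistry(config.chemistry).set_index("vial_id")
    else:
        logger.warning("no chemistry file: COD-removal columns will be absent")
    rows = []
    for vial_id, obs in bio.observations_by_vial(measurements).items():
        if vial_id not in vials:
            logger.warning("vial %s has measurements but no metadata; skipped", vial_id)
            continue
        vial = vials[vial_id]
        series = cumulative_methane(obs, vial, monotone_clamp=config.monotone_clamp)
        residual = None
        if chemistry is not None and vial_id in chemistry.index:
            residual = float(chemistry.loc[vial_id, "residual_scod_g_per_L"])
        summary = summarize_kinetics(
            series,
            vial,
            residual_scod_g_per_l=residual,
            baseline_floor=config.latency_floor,
            window_sizes=config.window_sizes,
        )
        rows.append(
            {
                "vial_id": vial_id,
                "condition": meta_frame.loc[vial_id].get("condition", ""),
                "modality": vial.modality,
                "ammonium_g_per_L": vial.ammonium_level,
                "replicate": vial.replicate,
                "latency_days": summary.latency_days,
                "latency_onset": summary.latency_onset,
                "mpr": summary.mpr,
                "mpr_window_start": summary.mpr_window[0],
                "mpr_window_size": summary.mpr_window[1],
                "yield_ml_per_g_cod": summary.yield_ml_per_g_cod,
                "max_cumulative_ml": summary.max_cumulative_ml,
                "residual_scod_g_per_L": residual,
                "cod_removal_pct": summary.cod_removal_pct,
            }
        )
    return pd.DataFrame(rows)


def aggregate_conditions(vial_table: pd.DataFrame) -> pd.DataFrame:
    """Condition-level mean and sample (n-1) sd over replicate vials."""
    groups = vial_table.groupby(["modality", "condition"], sort=False)
    rows = []
    for (modality, condition), g in groups:
        row = {"modality": modality, "condition": condition, "n_vials": len(g)}
        for metric in CONDITION_METRICS:
            values = g[metric].dropna() if metric in g else pd.Series(dtype=float)
            row[f"{metric}_mean"] = float(values.mean()) if len(values) else np.nan
            row[f"{metric}_sd"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["modality", "ammonium_g_per_L_mean"]).reset_index(drop=True)


def fit_modalities(vial_table: pd.DataFrame, config: RunConfig) -> tuple[dict, dict | None]:
    fits = {}
    for modality, g in vial_table.groupby("modality"):
        points = [
            DoseResponsePoint(
                ammonium=float(r.ammonium_g_per_L),
                mpr=float(r.mpr),
                modality=modality,
                replicate=int(r.replicate),
            )
            for r in g.itertuples()
            if r.ammonium_g_per_L > 0
        ]
        if len(points) < 4 or len({p.ammonium for p in points}) < 3:
            logger.warning("modality %s: too few points for a dose-response fit", modality)
            continue
        fit = fit_dose_response(points, model=config.dose_response_model, modality=modality)
        if config.n_boot > 0:
            fit.ci_ic50 = bootstrap_ic50_ci(points, config.n_boot, seed=config.seed)
        fit_dict = fits[modality] = fit
        logger.info(
            "modality %s: ic50=%.3f g N/L, mpr_max=%.2f, hill=%.2f (rss %.3g, n=%d)",
            modality, fit.ic50, fit.mpr_max, fit.hill, fit.rss, fit.n_points,
        )
        interp = ic50_interpolated(points)
        logger.info("modality %s: model-free interpolated ic50=%s", modality, interp)
    comparison = None
    if {"independent", "successive"} <= set(fits):
        comparison = compare_modalities(fits["independent"], fits["successive"])
    return fits, comparison


def community_indices(config: RunConfig) -> dict:
    table = bio.read_count_table(config.counts, config.taxonomy, config.sample_meta)
    depth = config.rarefaction_depth or int(table.counts.sum(axis=1).min())
    rarefied = comm.rarefy(table, depth, seed=config.seed)
    alpha = pd.DataFrame(
        [
            dict(zip(("richness", "shannon"), comm.alpha_diversity(rarefied.counts.loc[s])), sample=s)
            for s in rarefied.counts.index
        ]
    ).set_index("sample")
    divergence, trend = comm.dna_rna_divergence(rarefied)
    networks = {}
    for modality, meta in rarefied.sample_meta.groupby("modality"):
        mask = (rarefied.sample_meta["modality"] == modality) & (
            rarefied.sample_meta["fraction"] == "RNA"
        )
        if mask.sum() < 3:
            logger.warning("modality %s: <3 active-fraction samples, network skipped", modality)
            continue
        stratum = rarefied.select_samples(mask)
        networks[modality] = comm.cooccurrence_network(
            stratum,
            rank=config.network_rank,
            top_k=config.network_top_k,
            r_threshold=config.network_r_threshold,
            alpha=config.network_alpha,
        )
    out = {
        "rarefaction_depth": depth,
        "rarefaction_seed": config.seed,
        "alpha": alpha,
        "divergence": divergence,
        "divergence_trend": trend,
        "networks": networks,
    }
    if config.qpcr is not None:
        qpcr = bio.read_qpcr(config.qpcr)
        out["activity_ratios"] = {q.sample: comm.activity_ratio(q) for q in qpcr}
    return out


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every configured stage; raises on validation failure."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    validation = validate_config(config)
    for note in validation.notes:
        logger.info(note)
    if not validation.ok:
        raise ValueError(f"input validation failed: {validation.failures}")
    logger.info(
        "run config: seed=%d windows=%s latency_floor=%s clamp=%s",
        config.seed, config.window_sizes, config.latency_floor, config.monotone_clamp,
    )
    vial_table = _vial_kinetics_table(config)
    condition_table = aggregate_conditions(vial_table)
    fits, comparison = fit_modalities(vial_table, config)
    community = {}
    if config.counts is not None and config.taxonomy is not None and config.sample_meta is not None:
        community = community_indices(config)
    report = PipelineReport(
        vial_table=vial_table,
        condition_table=condition_table,
        fits=fits,
        comparison=comparison,
        community=community,
        validation=validation,
        config=config,
    )
    if config.out_dir is not None:
        paths = report.write(config.out_dir)
        for modality, net in community.get("networks", {}).items():
            bio.write_network(net.edges, net.graph, Path(config.out_dir) / f"network_{modality}")
        logger.info("report written to %s", sorted(str(p) for p in paths.values()))
    return report
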