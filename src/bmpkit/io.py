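"""File dialects: reading, validation and unit conversion.

All tables are plain delimited text.  Measurement and metadata files are
CSV; count tables, taxonomy, sample metadata and network edge lists are TSV.
Internal units are SI; declared dialects (mbar pressure, ml volumes) are
converted on read and flagged informationally in validation reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .community import CountTable, NetworkEdge, QpcrAbundance
from .gas_kinetics import HeadspaceObservation, VialSpec

MEASUREMENT_COLUMNS = ["vial_id", "time_days", "overpressure_Pa", "ch4_fraction"]
METADATA_COLUMNS = [
    "vial_id",
    "total_volume_ml",
    "headspace_volume_ml",
    "temperature_K",
    "atmospheric_pressure_Pa",
    "inoculum_vs_g",
    "fed_scod_g",
    "ammonium_g_per_L",
    "modality",
    "replicate",
]
CHEMISTRY_COLUMNS = [
    "vial_id",
    "residual_scod_g_per_L",
    "acetate_mg_per_L",
    "propionate_mg_per_L",
    "butyrate_mg_per_L",
]

PRESSURE_FACTORS = {"Pa": 1.0, "kPa": 1e3, "mbar": 100.0, "bar": 1e5}


def read_measurements(path: str | Path, pressure_unit: str = "Pa") -> pd.DataFrame:
    """Measurement CSV -> DataFrame with overpressure in Pa."""
    if pressure_unit not in PRESSURE_FACTORS:
        raise ValueError(f"unknown pressure unit {pressure_unit!r}")
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing measurement columns {sorted(missing)}")
    df = df.copy()
    df["overpressure_Pa"] = df["overpressure_Pa"] * PRESSURE_FACTORS[pressure_unit]
    return df


def read_vial_metadata(path: str | Path) -> dict[str, VialSpec]:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    vials = {}
    for _, row in df.iterrows():
        vials[str(row["vial_id"])] = VialSpec(
            vial_id=str(row["vial_id"]),
            total_volume=float(row["total_volume_ml"]) * 1e-6,
            headspace_volume=float(row["headspace_volume_ml"]) * 1e-6,
            temperature=float(row["temperature_K"]),
            atmospheric_pressure=float(row["atmospheric_pressure_Pa"]),
            inoculum_vs=float(row["inoculum_vs_g"]),
            fed_scod=float(row["fed_scod_g"]),
            ammonium_level=float(row["ammonium_g_per_L"]),
            modality=str(row["modality"]),
            replicate=int(row["replicate"]),
        )
    return vials


def read_metadata_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def read_chemistry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CHEMISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing chemistry columns {sorted(missing)}")
    return df


def observations_by_vial(measurements: pd.DataFrame) -> dict[str, list[HeadspaceObservation]]:
    out: dict[str, list[HeadspaceObservation]] = {}
    for vial_id, group in measurements.groupby("vial_id", sort=False):
        group = group.sort_values("time_days")
        out[str(vial_id)] = [
            HeadspaceObservation(
                time=float(r.time_days),
                overpressure=float(r.overpressure_Pa),
                ch4_fraction=float(r.ch4_fraction),
                vial_id=str(vial_id),
            )
            for r in group.itertuples()
        ]
    return out


def read_count_table(
    counts_path: str | Path, taxonomy_path: str | Path, sample_meta_path: str | Path
) -> CountTable:
    """Feature-rows count TSV + taxonomy TSV + sample-metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).T  # -> samples x features
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="feature_id")
    meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
    return CountTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


def write_count_table(table: CountTable, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "sample_meta": out / "sample_metadata.tsv",
    }
    table.counts.T.to_csv(paths["counts"], sep="\t")  # features as rows
    table.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="feature_id")
    table.sample_meta.to_csv(paths["sample_meta"], sep="\t")
    return paths


def read_qpcr(path: str | Path) -> list[QpcrAbundance]:
    """qPCR CSV (sample, target, fraction, copies_per_g) -> per-sample copies.

    DNA and cDNA rows for the same sample are paired; ``target`` strata
    (bacteria/archaea) are summed per fraction.
    """
    df = pd.read_csv(path)
    required = {"sample", "fraction", "copies_per_g"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: qPCR file needs columns {sorted(required)}")
    out = []
    for sample, group in df.groupby("sample"):
        genes = group.loc[group["fraction"] == "DNA", "copies_per_g"].sum()
        transcripts = group.loc[group["fraction"] == "cDNA", "copies_per_g"].sum()
        out.append(QpcrAbundance(sample=str(sample), gene_copies=genes, transcript_copies=transcripts))
    return out


def write_network(
    edges: list[NetworkEdge], graph: nx.Graph, out_prefix: str | Path
) -> dict[str, Path]:
    """Edge-list TSV plus GraphML for one co-occurrence network."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"edges": prefix.with_suffix(".edges.tsv"), "graphml": prefix.with_suffix(".graphml")}
    pd.DataFrame(
        [
            {"family_a": e.family_a, "family_b": e.family_b, "r": e.r, "p": e.p, "sign": e.sign}
            for e in edges
        ],
        columns=["family_a", "family_b", "r", "p", "sign"],
    ).to_csv(paths["edges"], sep="\t", index=False)
    nx.write_graphml(graph, paths["graphml"])
    return paths


@dataclass
class ValidationReport:
    failures: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def fail(self, file: str, message: str, **context) -> None:
        self.failures.append({"file": file, "message": message, **context})


def validate_inputs(paths: dict[str, str | Path], dialects: dict | None = None) -> ValidationReport:
    """Schema-check every provided input file without mutating anything.

    ``paths`` maps logical names (measurements, metadata, chemistry, counts,
    taxonomy, sample_meta, qpcr) to file paths; only the provided ones are
    checked.  Pressure declared in a non-Pa dialect is noted informationally.
    """
    dialects = dialects or {}
    report = ValidationReport()
    for name, path in paths.items():
        if path is None:
            continue
        if not Path(path).exists():
            report.fail(str(path), f"{name} file does not exist")
    if report.failures:
        return report

    if "measurements" in paths and paths["measurements"] is not None:
        fname = str(paths["measurements"])
        try:
            unit = dialects.get("pressure_unit", "Pa")
            df = read_measurements(paths["measurements"], pressure_unit=unit)
            if unit != "Pa":
                report.notes.append(f"{fname}: pressure converted from {unit} to Pa")
            for col in ("time_days", "overpressure_Pa", "ch4_fraction"):
                if not np.issubdtype(df[col].dtype, np.number):
                    report.fail(fname, f"column {col} is not numeric")
            if ((df["ch4_fraction"] < 0) | (df["ch4_fraction"] > 1)).any():
                bad = df.index[(df["ch4_fraction"] < 0) | (df["ch4_fraction"] > 1)]
                report.fail(fname, "ch4_fraction outside [0, 1]", rows=list(bad[:5]))
            for vial_id, group in df.groupby("vial_id"):
                times = group["time_days"].to_numpy()
                if np.any(np.diff(times) <= 0):
                    where = int(np.nonzero(np.diff(times) <= 0)[0][0])
                    report.fail(
                        fname,
                        f"non-monotone times for vial {vial_id}",
                        rows=list(group.index[where : where + 2]),
                    )
        except ValueError as err:
            report.fail(fname, str(err))

    if "metadata" in paths and paths["metadata"] is not None:
        fname = str(paths["metadata"])
        try:
            read_vial_metadata(paths["metadata"])
        except ValueError as err:
            report.fail(fname, str(err))

    if "chemistry" in paths and paths["chemistry"] is not None:
        fname = str(paths["chemistry"])
        try:
            chem = read_chemistry(paths["chemistry"])
            if (chem["residual_scod_g_per_L"] < 0).any():
                report.fail(fname, "negative residual sCOD")
        except ValueError as err:
            report.fail(fname, str(err))

    count_keys = ("counts", "taxonomy", "sample_meta")
    if all(paths.get(k) is not None for k in count_keys):
        try:
            read_count_table(paths["counts"], paths["taxonomy"], paths["sample_meta"])
        except (ValueError, KeyError) as err:
            report.fail(str(paths["counts"]), f"count-table bundle invalid: {err}")

    if "qpcr" in paths and paths["qpcr"] is not None:
        try:
            read_qpcr(paths["qpcr"])
        except ValueError as err:
            report.fail(str(paths["qpcr"]), str(err))
    return report
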