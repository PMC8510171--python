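"""Bundled reference data: the condition-level performance summary of the
two-modality ammonium-gradient BMP study the package analyses.

Each row is one experimental condition (mean and sd over triplicate vials):
ammonium level, latency phase, maximal methane production rate, methane
yield, residual soluble COD and COD removal efficiency.  These numbers serve
as worked-example inputs (e.g. for the model-free IC50 interpolation) and as
cross-checks for the arithmetic the pipeline reports.
"""

from __future__ import annotations

import pandas as pd

#: Fed soluble COD and volatile solids, g per liter of working volume.
FED_SCOD_G_PER_L = 17.5
VS_G_PER_L = 17.5

#: Vial geometry (ml) and incubation temperature (K).
VIAL_TOTAL_ML = 57.2
WORKING_VOLUME_ML = 28.6
INCUBATION_T_K = 310.15

#: Fitted IC50s reported for the study, g N-NH4+/L; the successive
#: (stepwise) exposure had the lower one.  Reference context, not a
#: reproduction target: the underlying replicate data are not bundled.
REPORTED_IC50 = {"independent": 3.30, "successive": 2.19}

_ROWS = [
    # modality, condition, N (sd), latency (sd), MPR (sd), yield (sd), residual (sd), removal (sd)
    ("independent", "1-1", 1.7, 0.1, 0.0, 0.0, 60.6, 3.2, 299.6, 20.7, 0.2, 0.1, 99.1, 0.5),
    ("independent", "1-2", 4.8, 0.1, 0.0, 0.0, 50.7, 1.8, 310.8, 21.1, 1.0, 0.3, 94.3, 1.5),
    ("independent", "1-3", 7.2, 0.3, 16.7, 1.8, 12.9, 0.8, 331.1, 23.2, 4.6, 0.7, 73.9, 4.0),
    ("independent", "1-4", 8.9, 0.2, 20.8, 3.1, 10.3, 1.3, 269.1, 24.5, 6.0, 0.2, 65.6, 1.1),
    ("independent", "1-5", 9.8, 0.4, 20.8, 2.6, 9.3, 1.3, 238.6, 33.2, 9.4, 0.6, 46.6, 3.4),
    ("independent", "1-6", 12.8, 0.6, 20.8, 4.2, 8.1, 0.7, 179.6, 6.5, 11.6, 0.8, 33.9, 4.4),
    ("independent", "1-7", 15.3, 0.9, 66.7, 4.6, 3.6, 0.9, 201.8, 17.5, 12.2, 1.6, 30.1, 9.1),
    ("successive", "2-1", 1.7, 0.1, 0.0, 0.0, 38.4, 2.6, 309.9, 32.4, 1.7, 0.1, 90.4, 0.0),
    ("successive", "2-2", 3.5, 0.3, 1.0, 0.5, 25.1, 3.6, 144.7, 26.4, 7.7, 1.1, 56.2, 6.2),
    ("successive", "2-3", 6.7, 1.4, 1.0, 0.5, 14.5, 2.5, 223.4, 31.8, 6.4, 2.5, 55.5, 9.8),
    ("successive", "2-4", 8.8, 2.1, 2.1, 1.0, 19.0, 4.9, 171.5, 77.6, 12.9, 3.8, 26.2, 21.5),
    ("successive", "2-5", 10.4, 0.8, 3.1, 1.0, 4.6, 1.1, 92.3, 28.1, 14.1, 3.3, 19.7, 18.6),
    ("successive", "2-6", 11.3, 2.0, 3.8, 1.5, 1.0, 0.3, 17.5, 2.6, 14.7, 3.8, 16.0, 21.5),
    ("successive", "2-7", 15.1, 0.3, 5.2, 1.5, 1.7, 0.3, 18.8, 8.1, 14.9, 2.0, 15.0, 11.3),
]

_COLUMNS = [
    "modality",
    "condition",
    "ammonium_g_per_l",
    "ammonium_sd",
    "latency_days",
    "latency_sd",
    "mpr",
    "mpr_sd",
    "yield_ml_per_g_cod",
    "yield_sd",
    "residual_cod_g_per_l",
    "residual_sd",
    "cod_removal_pct",
    "removal_sd",
]

#: Conditions whose printed residual COD and removal efficiency disagree
#: with each other (removal 55.5 % implies residual ~7.8 g/L, not the
#: printed 6.4 g/L) -- a typo in the published summary, kept verbatim here.
INCONSISTENT_REMOVAL_CONDITIONS = ("2-3",)


def reference_performance_table() -> pd.DataFrame:
    """The study's condition-level summary as a tidy DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def reference_levels(modality: str) -> list[float]:
    """Ammonium level means (g N/L) of one exposure design."""
    df = reference_performance_table()
    return df.loc[df["modality"] == modality, "ammonium_g_per_l"].tolist()
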