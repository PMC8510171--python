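#!/usr/bin/env python
"""Fit the ammonium dose-response of the MPR for each exposure design.

Takes the per-vial kinetics of step 02, fits the 3-parameter log-logistic
inhibition curve per modality with a bootstrap IC50 interval, reports the
model-free interpolated IC50 as a cross-check, and compares the designs.
Writes results/dose_response/fits.json.
"""

import json
from pathlib import Path

import pandas as pd

from bmpkit.inhibition import (
    DoseResponsePoint,
    bootstrap_ic50_ci,
    compare_modalities,
    fit_dose_response,
    ic50_interpolated,
)

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 17


def main() -> None:
    fits, payload = {}, {}
    for modality in ("independent", "successive"):
        vials = pd.read_csv(BASE / "kinetics" / modality / "vial_kinetics.csv")
        points = [
            DoseResponsePoint(r.ammonium_g_per_L, r.mpr, modality, int(r.replicate))
            for r in vials.itertuples()
        ]
        fit = fit_dose_response(points, modality=modality)
        fit.ci_ic50 = bootstrap_ic50_ci(points, n_boot=500, seed=SEED)
        interp = ic50_interpolated(points)
        fits[modality] = fit
        payload[modality] = {
            "ic50": fit.ic50, "ci_ic50": fit.ci_ic50, "mpr_max": fit.mpr_max,
            "hill": fit.hill, "rss": fit.rss, "n_points": fit.n_points,
            "ic50_interpolated": interp,
        }
        print(
            f"{modality}: IC50 = {fit.ic50:.2f} g N/L "
            f"(95% CI {fit.ci_ic50[0]:.2f}-{fit.ci_ic50[1]:.2f}), "
            f"mpr_max = {fit.mpr_max:.1f} ml/gVS/d, hill = {fit.hill:.2f}; "
            f"model-free crossing at {interp:.2f} g N/L"
        )
    comparison = compare_modalities(fits["independent"], fits["successive"])
    payload["comparison"] = comparison
    print(f"ordering: {comparison['ordering']} (difference {comparison['difference']:.2f} g N/L)")
    out = BASE / "dose_response"
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits.json").write_text(json.dumps(payload, indent=2, default=float))


if __name__ == "__main__":
    main()
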