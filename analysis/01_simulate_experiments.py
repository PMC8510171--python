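#!/usr/bin/env python
"""Generate both exposure designs of the synthetic ammonium-gradient study.

Simulates the two nitrogen-input strategies -- direct independent additions
at seven target concentrations (6 vials per level) and stepwise successive
transfers through the same gradient (24 vials, 3 sacrificed per level) --
with the default ground-truth kinetics and measurement noise, and writes the
raw input tables (headspace measurements, vial metadata, endpoint chemistry,
ground truth) under scratch/simulated/<modality>/ (regenerable raw data).
"""

from pathlib import Path

from bmpkit.datasets import reference_levels
from bmpkit.simulate import DesignSpec, KineticTruth, simulate_counts, simulate_design
from bmpkit.io import write_count_table

SEED = 20_260_925
OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulated"


def main() -> None:
    for modality, vials in (("independent", 6), ("successive", 24)):
        levels = tuple(reference_levels(modality))
        design = DesignSpec(modality, levels, vials_per_level=vials)
        bundle = simulate_design(design, KineticTruth(seed=SEED), seed=SEED)
        paths = bundle.write(OUT / modality)
        n_vials = bundle.metadata["vial_id"].nunique()
        n_obs = len(bundle.measurements)
        print(f"{modality}: {n_vials} vials, {n_obs} headspace observations "
              f"over {len(levels)} ammonium levels -> {paths['measurements'].parent}")
        table, _ = simulate_counts(levels, modality=modality, seed=SEED + 1)
        count_paths = write_count_table(table, OUT / modality / "amplicon")
        print(f"{modality}: count table {table.counts.shape[0]} samples x "
              f"{table.counts.shape[1]} ASVs -> {count_paths['counts'].parent}")


if __name__ == "__main__":
    main()
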