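# bmpkit

Anaerobic digestion of protein-rich wastewater releases ammonium, and high
N-NH4⁺ concentrations inhibit the methanogenic community — how strongly
depends on how the community was exposed. `bmpkit` is a Python toolkit for
analysing biomethane-potential (BMP) batch assays run along an ammonium
gradient under two exposure strategies: *independent* (direct, single
additions at each target concentration) and *successive* (stepwise transfers
through increasing concentrations). It is written for process engineers and
microbial ecologists who need to turn raw vial measurements into inhibition
metrics and community summaries.

The package covers the full chain:

- **Gas kinetics** — decode daily headspace measurements (manometer
  overpressure + GC CH4 fraction, with venting to atmospheric after each
  reading) into produced methane via the ideal-gas mole balance
  Δn_CH4 = [(P_atm + P_HS(t))·x(t) − P_atm·x(t−1)]·V_HS/(R·T), cumulate to
  volume at NTP (273 K, 101 325 Pa), and extract per-vial metrics: maximal
  production rate (best OLS slope over 4–6 successive points, per g VS),
  latency (20 %-rise onset above a detection floor), yield per g COD and
  COD removal efficiency.
- **Inhibition** — fit MPR(N) = mpr_max/(1 + (N/IC50)^h), the 3-parameter
  log-logistic inhibition curve, per exposure modality with multi-start
  least squares and a bootstrap IC50 interval, plus a model-free
  interpolated IC50 as a cross-check, and compare modalities.
- **Community** — rarefaction, observed richness and Shannon index,
  Bray-Curtis dissimilarity, DNA-vs-RNA (present-vs-active) divergence,
  transcript:gene activity ratios, taxonomic aggregation with
  unclassified-rank labels, row z-scores, and Pearson co-occurrence
  networks thresholded at |r| > 0.8, p < 0.05.
- **Simulation** — a synthetic experiment generator (modified-Gompertz
  kinetics, exact headspace encoding, niche-structured Dirichlet-multinomial
  count tables) producing every input the pipeline consumes, with ground
  truth for validation.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate a three-level independent-exposure design without noise, decode it
and summarise per condition:

```
$ bmpkit simulate --design independent --levels 1.7,4.8,7.2 \
    --vials-per-level 2 --noise-pressure 0 --noise-fraction 0 \
    --seed 4 --out sim
$ bmpkit kinetics --measurements sim/measurements.csv \
    --metadata sim/vial_metadata.csv --chemistry sim/chemistry.csv --out kin
condition  ammonium_g_per_L_mean  latency_days_mean   mpr_mean  cod_removal_pct_mean ...
      1-1                    1.7                0.0  46.975623             85.712700
      1-2                    4.8               13.0  16.734851             79.069965
      1-3                    7.2               20.0   7.453708             73.927203
```

The control vials convert ≈47 ml CH4 g⁻¹ VS d⁻¹ (the generator's true
inhibited rate at the 1.7 g N/L baseline is 50.4; daily sampling slightly
smooths the peak slope); at 7.2 g N/L the rate has fallen ≈6-fold and a
20-day lag has appeared, while COD removal declines more gently — the
classic signature of ammonium stress on methanogenesis.

The numbered scripts under `analysis/` run the same stages as a narrative:
`01_simulate_experiments.py` generates both exposure designs (raw tables
under `scratch/`, regenerable), `02_vial_kinetics.py` writes the
condition summaries, `03_dose_response.py` fits the inhibition curves
(printing, for the bundled defaults, IC50 ≈ 3.3 g N/L with a 95 % bootstrap
interval), and `04_community_structure.py` computes diversity, DNA/RNA
divergence trends and the active-fraction co-occurrence networks under
`results/`.

As a reference input, `bmpkit.datasets.reference_performance_table()` ships
the condition-level summary of the study the package reanalyses; the
model-free IC50 interpolated from its MPR means is 6.10 g N/L for the
independent design and 5.76 g N/L for the successive one — the stepwise
exposure is the more inhibited, matching the study's reported ordering.

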