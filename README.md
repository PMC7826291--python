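# clefmap

Footprint mapping of cooperative protein binding on short single-stranded DNA
lattices. The package combines an exact finite-lattice model of
nonoverlapping, cooperatively interacting ligands with the three
spectroscopic analysis stages used to map a binding cleft at single
nucleotide resolution:

- **`lattice_model`** — exact equilibrium statistics of `n`-nucleotide
  ligands on an `N`-nucleotide lattice (two-state recursion with a
  brute-force enumeration oracle, log-domain overflow fallback), mass-balance
  titration curves, and the finite-lattice cooperativity exponent
  `(m-1)/m` of the saturated cluster.
- **`observable_models`** — affine maps from per-position coverage to the
  observables: 2-AP fluorescence enhancement `F/F0 = 1 + (R-1)·θ`, a
  three-state (free / stably bound / transiently exchanging) Stern–Volmer
  accessibility model, and the dimer-probe exciton CD amplitude.
- **`synthetic_data`** — deterministic instrument-like datasets for all
  three assays (stock-addition dilution, replicate noise, background
  series), standing in for undeposited instrument data.
- **`titration_analysis`** — background/dilution corrections,
  normalization, first-six/last-six equivalence-point stoichiometry,
  `F_P/F_0` enhancement ratios, and least-squares inversion for
  `(K_a, ω, active fraction)` with identifiability warnings.
- **`quenching_analysis`** — Stern–Volmer regression (`F0/F` vs `[Q]`),
  half-quench concentrations, and the position × ratio `K_SV` surface.
- **`cd_analysis`** — replicate scan averaging, mdeg → Δε/2-AP conversion,
  325 nm exciton-peak extraction, and titration profiles (plateau and
  initial slope).
- **`cli_io`** — construct nomenclature (`21T9`, `28T22,23`, …), CSV
  schemas, configuration, and the end-to-end pipeline driver with a
  provenance manifest.

## Command line

```sh
# end-to-end: simulate all three assays, analyze, write report tables
clefmap run --seed 1 --outdir out/

# individual stages
clefmap simulate --seed 1 --outdir out/
clefmap titrate out/simulated_fluorescence.csv --outdir out/
clefmap quench out/simulated_quench.csv --outdir out/
clefmap cd out/simulated_cd.csv --outdir out/

# query the lattice model directly
clefmap model --length 21 --ka 1e7 --omega 1e3 --total-ligand 1.5e-6
```

`--config` accepts a YAML file overriding any `GeneratorConfig` field
(constructs, concentrations, noise, replicate counts, binding parameters,
seed, …). Outputs are tidy CSVs plus a `manifest.json` recording the config,
seed, and output checksums; runs are byte-identical under a fixed seed.

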