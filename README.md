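# warmclip

Reusable, tested implementations of the computational analyses used in a
paired-factorial grassland experiment crossing warming and clipping
(aboveground biomass removal):

- **`synthetic_data`** — generators for every input the pipeline consumes
  (block × treatment property tables, probe-level functional-gene-array
  fixtures, soil-carbon-model driver/observation series), all with known
  ground truth and explicit seeds.
- **`geochip_preprocess`** — probe-to-gene preprocessing for functional
  gene arrays: flag/SNR QC, three-level normalization (subgrid → technical
  replicates → across slides), gene/probe detection filters,
  relative-abundance rescaling, and ln(x+1) transform.
- **`factorial_effects`** — warming (W), clipping (C), observed combined
  (OE), and predicted additive (PE = W + C) percent effects per block;
  paired and exact sign-flip permutation paired t tests; classification of
  the interaction as additive / synergistic / antagonistic; per-category
  gene abundance effects.
- **`teco_inversion`** — a six-pool daily soil-carbon forward model with
  Q10-scaled heterotrophic respiration, and Bayesian inversion of seven
  parameters (Q10 ∈ [1.5, 5] plus six pool exit rates) by random-walk
  Metropolis–Hastings, with posterior mode / credible-interval summaries.
- **`mixing_model`** — two-source δ¹³C mixing model for the fraction of
  soil carbon derived from C4 plants.
- **`community_stats`** — Morisita–Horn dissimilarity, two-group
  permutational MANOVA (pseudo-F), Mantel tests, and alpha diversity
  (richness, evenness, Shannon, Simpson, inverse Simpson).

## CLI

Everything is reachable through the `warmclip` entry point:

```sh
# generate synthetic inputs (configs are TOML)
warmclip simulate properties --config props.toml --out data/
warmclip simulate geochip    --config chip.toml  --out data/
warmclip simulate teco       --config teco.toml  --out data/

# probe table -> normalized gene x sample matrix
warmclip preprocess --in data/probes.tsv --designed data/designed_counts.tsv \
    --out matrix.tsv

# factorial effects + interaction calls for every variable
warmclip effects --in data/properties.tsv --alpha 0.05 --marginal-alpha 0.10

# Metropolis-Hastings inversion of Q10 and the pool exit rates
warmclip invert-q10 --drivers data/ --obs data/ --seed 1 --out chain.tsv

# community statistics
warmclip stats adonis    --in abundances.tsv --groups UU,UW
warmclip stats mantel    --in1 d1.tsv --in2 d2.tsv
warmclip stats diversity --in abundances.tsv

# isotope mixing model
warmclip mix-c4 --in soils.tsv --c3 -27.0 --c4 -12.5
```

See `tests/test_cli.py` for minimal working TOML configs.

## Conventions worth knowing

- Percent effects use each block's own untreated control as denominator;
  means are arithmetic means over blocks, and PE = W + C holds exactly
  per block and in the means.
- The exact sign-flip permutation p-value counts the identity assignment
  (p ≥ 2/2ⁿ); it is conservative at small n.
- No multiple-testing correction is applied anywhere; raw p-values are
  reported against the 0.05 / 0.10 tiers.
- SNR defaults to (signal − background) / background_sd; switchable to
  signal / background via `--snr-mode ratio`.
- Model structure defaults in `teco_inversion` (allocation fractions,
  respired fraction, Tref = 10 °C) are implementation choices exposed as
  keyword arguments, not fitted quantities.
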