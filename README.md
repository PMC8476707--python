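# aavcdms

Models, simulation and quantitation for charge detection mass spectrometry
(CDMS) of recombinant AAV vectors: how much DNA is inside the particles, and
what the measured masses imply about it.

## What it does

- **Capsid mass model** (`aavcdms.capsid`): multinomial VP1/VP2/VP3
  stoichiometry over 60 subunits — expected mass, exact composition pmf,
  closed-form moments, Monte-Carlo sampling.
- **Genome masses** (`aavcdms.genome`): ionized, strand-averaged ssDNA
  masses from base count or sequence (FASTA supported), and expected vector
  masses for empty/partial/full/multi-genome particles.
- **Instrument model** (`aavcdms.instrument`): trapping-time-dependent
  charge RMSD, per-ion mass error, a charge-vs-mass law (surface-area
  scaling anchored at 150 e @ 3.7 MDa), and predicted peak shapes combining
  capsid heterogeneity with resolution.
- **Counterion mass balance** (`aavcdms.counterions`): the linear model
  relating measured full-minus-empty mass differences to genome sequence
  mass (slope → effective cation mass, intercept → internal basic sites),
  with OLS fitting and physical interpretation.
- **Single-ion simulator** (`aavcdms.simulate`): synthetic (m/z, charge)
  events from configurable mixtures of empty, partial, full, capacity-pinned
  (headful) and multimer species, including co-packaged DNA fragments,
  counterion inflation, flagged multi-ion/short-trap events, and a
  heat-incubation transform.
- **Spectrum quantitation** (`aavcdms.spectrum`): 20 kDa binning,
  1-D Gaussian-mixture fitting with per-component mean charge, window-based
  packaging-state fractions, and genome mass by empty/full difference.
- **Workflow** (`aavcdms.config`, `aavcdms.cli`): YAML scenario configs,
  bundled `fig1` (eight-construct survey) and `fig6` (counterion recovery)
  scenarios, and a deterministic runner (same config + seed ⇒ byte-identical
  outputs).

## CLI

```sh
# expected capsid / genome / vector masses
aavcdms expected-mass --bases 2219

# run a bundled scenario end to end (events, spectra, fractions, fits)
aavcdms run --scenario fig6 --seed 1 --out out/fig6

# simulate from a YAML config, overriding seed and bin width
aavcdms simulate --config scenario.yaml --seed 7 --bin-width 20000 --out out/sim

# analyze an event table
aavcdms analyze out/sim/events_CMV-GFP.tsv --empty-mass 3732045 \
    --goi-mass 783000 --out out/ana

# fit the counterion model to a points table
aavcdms fit-counterions points.tsv --cation NH4 --out fit.json
```

Event tables, spectra, fractions and component tables are all delimited
text; fit reports are JSON.

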