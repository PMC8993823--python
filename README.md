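# steppedemo

Simulation-based demographic inference for paired steppe lineages:
coalescent simulation of RAD-like SNP matrices under three explicit
glacial-cycle scenarios, SNP-image encoding, a calibrated convolutional
neural network for scenario classification and parameter prediction, an
ABC rejection step yielding scenario posterior probabilities and parameter
posteriors, divergence-time calibration (τ → years), and site-frequency
spectra with hypergeometric down-projection for missing data.

The biological setting is the late Quaternary history of Eurasian steppe
species that occur both in the continuous (*zonal*) steppe belt and in
isolated (*extrazonal*) steppe patches of temperate Europe. Cold stages
expanded steppe habitat enormously; the package compares three demographic
hypotheses for a pair of sister lineages (extrazonal EZ / zonal Z):

1. **Parallel expansion** — effective size *n* of both lineages increased
   during the last glacial period (LGP) and collapsed in the Holocene;
2. **Zonal expansion only** — the same for the zonal lineage, constant
   *n* in the extrazonal one;
3. **No expansion** — constant *n* in both.

All scenarios share a split at `t_split` (the mid-Pleistocene divergence
of the two lineages) and bidirectional migration in the pre-LGP and LGP
epochs. Inference follows the CNN–ABC recipe: simulate SNP matrices under
each scenario, encode them as three-level images (−1 reference / +1
alternative / 0 missing, with missingness injected at the empirical rate),
train a CNN to recognize the scenarios, calibrate its probabilities by
temperature scaling, and use the calibrated probability vectors — of the
observed data and of an independent simulation set — as ABC summary
statistics. Parameters are estimated analogously with a CNN regressor
(τ = 2µt converts relative divergence to years with gamma-distributed µ
and generation time; the model is in `docs/methods.md`).

## Layout

* `src/steppedemo/` — the library: `demography` (scenarios, priors, event
  schedules), `simulate` (msprime-backed SNP matrices, missingness,
  reference tables), `encoding` (SNP images), `nn` + `cnn_abc` (network,
  temperature scaling, ABC), `timescale`, `sfs`, `synthetic_data`
  (species-shaped fixtures and end-to-end experiments), `io_cli`
  (VCF/filters/CLI).
* `analysis/01…06_*.py` — numbered narrative drivers that run each stage
  at desk scale and write tables under `results/`.
* `scripts/acceptance.py` — recomputes the headline accuracies (below).
* The `steppedemo` console command exposes `simulate`, `train`,
  `calibrate`, `classify`, `estimate`, `timescale`, `sfs`, `fixtures`,
  `recover` subcommands over the same library.

## Worked example

`python analysis/03_classify_scenarios.py` simulates balanced reference
sets for the smallest species shape (10+10 diploid individuals, 250 SNP
columns, 42% missing genotypes), trains and calibrates the CNN, and
classifies one pseudo-observed dataset whose true scenario is known:

```
held-out accuracy 0.483 on 180 simulations (chance = 0.333);
temperature T = 0.48 (val NLL 0.992 -> 0.958)

scenario posterior probabilities for a pseudo-observed parallel-expansion dataset:
          scenario       pp
PARALLEL_EXPANSION 0.666667
        ZONAL_ONLY 0.111111
      NO_EXPANSION 0.222222
```

Held-out accuracy is the fraction of fresh simulations assigned to their
true scenario (0.48 at this deliberately small desk scale — far above the
0.33 chance level; accuracy grows with SNP columns and training
simulations, see `docs/methods.md`). The temperature below 1 sharpens
under-confident probabilities and lowers validation loss. The ABC step
then favors the true scenario (PP 0.67) for the pseudo-observed dataset.

`python analysis/04_parameter_posteriors.py` continues under the chosen
scenario and prints, e.g.:

```
                median  hpd_low  hpd_high    truth
t_split_years 9.63e+05 3.09e+05  1.51e+06 1.32e+06
t_exp_years   5.98e+04  4.2e+04  1.13e+05 5.77e+04
n_z_lgp       9.36e+05 4.48e+03  9.34e+06 9.11e+06
n_z_post      1.17e+04 2.22e+03  7.82e+04 1.08e+04
...
posterior-median fold changes (zonal lineage):
  LGP expansion   88.5x (truth 700.9x)
```

i.e. posterior medians with 95% highest-posterior-density intervals per
demographic parameter, next to the known truth, and the implied
glacial-expansion fold change. `python analysis/05_divergence_times.py`
calibrates synthetic τ posteriors to absolute ages (e.g. a grasshopper-like
τ sample yields 1.43 My, 95% HPD 0.96–1.91 My), and
`python analysis/06_site_frequency_spectra.py` writes down-projected
marginal and joint site-frequency spectra for a 42%-missing dataset.

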