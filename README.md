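# lineagebias

**Quantifying structural biases in ascendant genealogies with demographic
microsimulation.**

Family trees reconstructed backwards from living people — the ascendant
genealogies that crowd-sourced platforms compile by the millions — are
tempting sources for historical demography, but they are built on three
structural selections: only lineages that survived to the present are
visible; genealogists often record direct ancestors while skipping
collateral kin; and certain people (children who died young, women who
left no descendants) are disproportionately forgotten.  `lineagebias`
measures what those selections do to the demographic estimates a
researcher would compute from such data.

The approach is fully simulation-based. A SOCSIM-style discrete-event
microsimulation produces a *fully-recorded* synthetic population under
age-specific fertility and mortality schedules (read from HFD/HMD-style
tables or generated by a built-in Swedish-like synthesiser, 1751–2022).
A sample of surviving adults — the hypothetical genealogists — then
traces ascendant trees up to nine generations, and three experiments
rebuild the classic failure modes:

1. **Incomplete surviving lineages** — direct ancestors only, with and
   without cross-tree duplicates;
2. **Complete surviving lineages** — direct ancestors plus all their
   offspring, deduplicated;
3. **Selective omission** — complete lineages minus a random 25–100% of
   (a) children dead before age five or (b) childless women.

Period ASFR, ASMR, TFR and life expectancy at birth (e₀) are computed
from each subset and from the whole simulation with identical estimators
(mid-year exposure denominators; TFR = Σₐ ASFR(a); e₀ from a period life
table with q = m/(1+(1−a)m), open interval at 100).  Bias is the subset
minus full-population value, per year, averaged over calendar windows and
replicates.

## Worked example

```python
from lineagebias import (SimConfig, ExperimentConfig, constant_params,
                         synth_rates, run_replicates, run_experiment,
                         summarise_experiment)

# a pre-transition regime: 4.4 children per woman, e0 = 39 years
schedule = synth_rates(constant_params(1800, 1930, tfr=4.4, e0=39), seed=0)
config = SimConfig(n_initial=1000, start_year=1800, end_year=1930,
                   burn_in_years=60, tail_years=20, seed=100)
registries, manifest = run_replicates(config, schedule, replicates=2)

results = run_experiment(registries, ExperimentConfig(seed=1), "1",
                         years=range(1800, 1931))
summary = summarise_experiment(results)
print(summary[["dataset", "measure", "abs_mean_diff",
               "rel_mean_diff_pct", "n_years"]].round(2).to_string(index=False))
```

Output (about a minute on one CPU):

```
     dataset measure  abs_mean_diff  rel_mean_diff_pct  n_years
  direct_dup     tfr          -3.26             -74.97       48
  direct_dup      e0          23.22              61.29       63
direct_dedup     tfr          -2.33             -53.53       48
direct_dedup      e0          23.11              60.75       63
```

Read: genealogies holding only the genealogists' direct ancestors
underestimate the total fertility rate by 2.3 children per woman
(deduplicated; 3.3 with duplicates kept, because shared ancestors inflate
the female denominators) and overestimate female life expectancy at birth
by ~23 years — none of the members died in childhood, since all of them
survived to reproduce.  `n_years` counts the calendar years covered well
enough by the subset to enter the averages.

## Command line

A thin CLI wraps the same library:

```bash
lineagebias simulate   --config cfg.yaml --seed 1 --replicates 10 --out run/
lineagebias extract    --registry run/registry_1.csv --experiment 2 --out run/
lineagebias measure    --registry run/registry_1.csv --subset run/subset_complete.csv --out m.csv
lineagebias experiment --config cfg.yaml --experiment 3a --out run/
lineagebias pipeline   --config cfg.yaml --seed 1 --out run/
```

`pipeline` runs simulate → extract → measure → summarise for all four
experiments, records per-stage manifests (config, seeds, file hashes) and
skips stages that are already up to date.  An empty config file is valid:
every key defaults to the study design (100-year burn-in, 50-year tail,
10 replicates, 10% genealogist sample of adults 18+, nine generations).

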