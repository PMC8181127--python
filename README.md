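# tpemet

Tools for defining target populations of environments (TPEs) from climate and
soil covariates, analysing multi-environment wheat yield trials with mixed
models, quantifying direct and correlated response to selection, pedigree-based
reaction-norm prediction, and genetic-gain estimation — exercised end-to-end on
synthetic data emulating an international elite spring wheat trial network
(~41 Indian sites in 3 TPE groups over 13 annual cycles, 49 lines + a local
check per cycle in a replicated alpha-lattice, plus 5 managed selection
environments at a single breeding station).

## What is in the box

| Module | Purpose |
| --- | --- |
| `tpemet.io_config` | CSV readers/writers, validation, run configuration and manifests |
| `tpemet.synthetic_data` | Pedigrees, daily weather/soil covariates and phenotypes with known ground truth (ANOVA and reaction-norm generative modes) |
| `tpemet.tpe_definition` | 20-day windowing of daily weather, correlation-matrix PCA, Ward clustering of sites, site proportions, thin-plate-spline surfaces |
| `tpemet.lmm_engine` | REML variance components (profiled restricted likelihood, bound-constrained), BLUPs, genotype BLUEs, broad-sense heritability; Gibbs cross-check |
| `tpemet.selection_response` | Phenotypic/genetic correlations, correlated and direct response to selection |
| `tpemet.pedigree_kinship` | Pedigree ordering/validation and the additive relationship matrix (tabular method) |
| `tpemet.reaction_norm` | Hadamard covariance kernels (additive, environment, additive×environment, covariate, additive×covariate) fitted by Gibbs sampling; closed-form fixed-variance solution; variance proportions; predictive correlations |
| `tpemet.genetic_gain` | Relationship-matrix BLUPs of per-cycle genotype means regressed on year (kg/ha/year) |

## Command line

All stages are subcommands of `tpemet`; each writes CSV outputs plus a
`manifest_<stage>.json` with the seed, configuration digest and library
versions. Identical configuration and seed give byte-identical outputs.

```bash
# generate a small synthetic network (trials, pedigree, weather, soil, truth)
tpemet simulate --seed 1 --out data/ --cycles 3 --sites 4,3,4

# window daily weather, cluster sites into TPEs, report proportions
tpemet define-tpe --daily data/daily_weather.csv --soil data/soil.csv --k 3 --out tpe/

# REML variance components for one of the trial models (eq3/eq4/eq7/eq8)
tpemet fit-met --trials data/trials.csv --model eq4 --out met/
tpemet fit-met --trials data/trials.csv --model eq8 --group-kind SE --out se/

# additive relationship matrix from a pedigree CSV (id,parent1,parent2; 0 = unknown)
tpemet build-a --pedigree data/pedigree.csv --out a/

# reaction-norm prediction of held-out records (NaN y = held out)
tpemet predict --records records.csv --pedigree data/pedigree.csv \
    --model AE-AxE --seed 1 --out pred/

# correlated/direct response table from per-year correlations and heritabilities
tpemet response --per-year per_year.csv --out resp/

# yield-gain slopes from per-cycle BLUEs and the pedigree
tpemet gain --blues blues.csv --pedigree data/pedigree.csv --out gain/
```

## File formats

All files are UTF-8, comma-delimited, `.` decimal, header mandatory.

- **Phenotypes**: `cycle_year, site_id, group_label, group_kind (TPE|SE),
  replicate, sub_block, genotype_id, is_local_check, grain_yield` (t/ha;
  empty = missing, never imputed).
- **Pedigree**: `id, parent1, parent2` with `0` for unknown parents.
- **Covariates (long)**: `site_id, variable, window, value`; window `0` marks
  a static soil variable.
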