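# coagclass

Discovering compact, time-localized assays for coagulation phenotypes from
kinetic simulations of thrombin generation.

## The problem

Acute coronary syndromes (ACS) leave blood in a hyper-coagulable state
relative to stable coronary artery disease (CAD), but conventional
thrombin-generation read-outs — peak thrombin, area under the thrombin
curve, time to 2 nM — summarise a single species and discard most of the
system's dynamics. Mechanistic models of the tissue-factor (Tf)-initiated
extrinsic pathway track dozens of chemical species; the question is which
species, and *when*, carry the information that separates two clinical
groups.

`coagclass` answers this in silico:

1. sample virtual patients as plasma-factor compositions from per-group
   lognormal distributions (percent of physiological mean, converted
   linearly to molar initial conditions; 5 pM Tf trigger);
2. integrate the mass-action ODE system `dx/dt = Sᵀ f(x)`,
   `f_j(x) = k_j ∏ᵢ xᵢ^{s_ij}`, stiffly for 3600 s;
3. featurize each trajectory four ways — monotone piecewise-cubic-Hermite
   (PCHIP) coefficients on 139 uniform pieces (34 species × 139 × 4 =
   18 904 features), 18 consecutive 200-second moving averages per species
   (612 features), the 11 conventional thrombin/fXa summary parameters,
   and the 8 raw factor percentages;
4. classify the groups with random forests (501 trees, Gini criterion,
   ⌊√p⌋ features per split), scoring by out-of-bag accuracy, mean (SD)
   over 50 seeded runs;
5. select species by mean-decrease-in-Gini (MDGini) importance — fXa and
   thrombin always; the species with the highest mean of their top ~10%
   coefficient importances; the species dominating the last 600 s — then
   resolve each species' significance across the 18 time windows and
   evaluate small species-at-window combinations as candidate assays.

The intended users are systems-biology and clinical-modelling groups who
have a kinetic clotting model and summary statistics of a patient
population, and want to know which few measurements, at which times, would
best separate groups.

## Worked example

The package bundles a reduced 21-species clotting cascade and a synthetic
two-group cohort specification (group differences on prothrombin, factor
VIII, TFPI and antithrombin; see `docs/methods.md`). Run the full pipeline
on them:

```bash
coagclass fixture -o fx --n-per-group 50 --seed 7
coagclass run -c fx/config.toml
```

which prints (seed 7, 50 samples per group, 501 trees, 10 runs; about
3 minutes on one CPU):

```
report bundle written to fx/out
  All PCHIP Coefficients           72.10 (1.52)
  8 Initial Conditions             69.90 (1.85)
  Conventional fXa                 56.20 (1.55)
  Conventional Active Thrombin     60.20 (1.62)
  All 200s-MA                      73.70 (1.34)
```

Each number is the mean (SD) out-of-bag accuracy, in %, over the seeded
forest runs: the high-dimensional dynamic feature sets (PCHIP, moving
averages) classify somewhat better than the raw compositions, and clearly
better than the conventional single-species parameters — the dynamics
contain group information that the classical read-outs miss. `fx/out/`
additionally contains the species selection with criterion provenance
(`selection.csv`), per-window MDGini profiles
(`time_resolved_mdgini.csv`, plotted in `mdgini_vs_time.png`), per-species
all-18/best-3/best-1 accuracies, a ranked table of three-species
combination assays (`table_combinations.csv`), and a manifest recording
every seed.

Your own model goes in as a plain-text file (`[species]` /
`[reactions]` sections, `A + B -> C, k=1.0e7` lines; see
`src/coagclass/data/toy_model.txt`), and a real cohort as a CSV/XLSX table
with columns `group, fII, fV, fVII, fVIII, fIX, fX, TFPI, AT` in percent
units.

## Layout

```
src/coagclass/
  kinetics.py            mass-action networks, model-file parser, stiff ODE solver
  cohort.py              lognormal cohort sampling, percentage→molar mapping
  features.py            PCHIP / moving-average / conventional / initial features
  forest.py              random forests, OOB accuracy, MDGini importances
  selection.py           species selection, time resolution, combinations
  pipeline.py            end-to-end orchestration, caching, report bundle
  cli.py                 `coagclass` command-line interface
  synthetic_profiles.py  planted-signal trajectory fixtures
  data/toy_model.txt     bundled reduced clotting cascade
docs/methods.md          model, parameters, numerical choices, limitations
```
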