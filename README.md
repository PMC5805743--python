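# nhejsim

Mechanistic simulation of ion-induced DNA double strand breaks (DSBs) and
their repair by canonical non-homologous end joining (c-NHEJ), for
computational radiobiology: predicting how many breaks a proton or alpha
exposure leaves **misrepaired** (a proxy for chromosome aberration) or
**residual** (unrepaired) after 24 hours, directly from the beam quantities
a treatment planning system already scores — dose D (Gy) and track-averaged
LET, L (keV/µm).

The package is aimed at researchers in particle-therapy modelling and DNA
damage/repair simulation. It provides:

- **`damage_generation`** — DSB damage patterns in a 5 µm spherical
  nucleus, either from a calibrated parametric track emulator (straight
  chords, Neyman–Scott intra-track clustering) or by nanodosimetric
  clustering of an external energy-deposition list (5–37.5 eV linear damage
  ramp, 15 % sensitive fraction, 3.32 nm / opposite-strand DBSCAN rule, and
  the genomic 10 bp / 3 bp chromatin-fibre variant).
- **`nhej_repair`** — event-driven 24 h c-NHEJ simulation: sub-diffusive
  continuous-time random walk motion of break ends (ensemble MSD ∝ t^α,
  α < 1), stochastic protein recruitment
  (inhibition ⇄ naked → Ku70/80 → DNA-PKcs), 25 nm synapsis with a 95 s
  transient long-range complex, lesion cleaning and ligation; joins are
  classified correct/misrepaired and unligated breaks counted as residual.
- **`metrics`** — the **cluster density** (mean number of other DSBs within
  70 nm of each DSB — the damage-pattern statistic that predicts
  misrepair), separation PDFs, displacement percentiles, repeat summaries.
- **`correlations`** — the fitted correlation layer and its constants a–h
  per species:

      F_mis = a·CD + b,   F_res = c,   N_DSB = D(dL + e),
      CD(L) = fL² + gL + h,
      Misrepair yield = N_DSB · F_mis · (1−c),
      Residual yield  = N_DSB · c

  plus parameter fitting from simulation grids and the misrepair/residual
  crossover LET.
- **`sobp_application`** — maps both yields along a (depth, dose, LET)
  profile of a proton spread-out Bragg peak, where the biological effect
  falls off more slowly than physical dose.
- **`orchestration`** / **CLI** — reproducible experiment grids,
  deterministic seeding, fixtures, and a `nhejsim` command with
  `generate / calldsb / repair / metrics / predict / crossover / sobp /
  grid / fixtures / calibrate` subcommands.

## Worked example

Predict the 24 h outcome for a 2 Gy proton exposure at 10 keV/µm from the
correlation layer:

```bash
$ nhejsim predict --species proton --dose 2 --let 10
{
 "n_dsb": 71.18,
 "cluster_density": 0.12849,
 "f_mis": 0.033261134,
 "f_res": 0.0736,
 "misrepair_yield": 2.1932774927863683,
 "residual_yield": 5.238848000000001
}
```

Read: the exposure induces ≈ 71 DSBs per nucleus; each DSB sees on average
0.128 neighbours within 70 nm; 3.3 % of joined breaks are predicted to
misrepair, 7.36 % of all breaks to remain unrepaired — i.e. ≈ 2.2
misrepaired and ≈ 5.2 residual DSBs per nucleus at 24 h. The LET above
which misrepair outweighs residuals (dose cancels):

```bash
$ nhejsim crossover --species proton
22.55 keV/um
```

The same question answered by the full mechanistic chain instead of the
correlations — generate a damage pattern, score it, repair it:

```bash
$ nhejsim generate --species proton --dose 2 --let 10 --seed 7 --out pattern.csv
66 DSBs -> pattern.csv
$ nhejsim metrics --pattern pattern.csv --radius 70 --out metrics.json
cluster density (r=70 nm): 0.09091
$ nhejsim repair --pattern pattern.csv --hours 24 --seed 3 --out outcome.json
joined 59 (misrepair fraction 0.0000), residual 7 -> outcome.json
```

One nucleus is noisy (66 breaks induced, 7 residual ≈ 10.6 %); averaged
over repeats the simulation reproduces the correlation-layer numbers — the
residual fraction converges to ≈ 7.3 % and misrepair grows linearly with
cluster density. `nhejsim grid --out grid.json` runs the full
species × dose × LET study and writes per-cell means with standard errors.

For depth profiles (CSV with `depth_cm,dose_gy,let_kev_um` columns;
`nhejsim fixtures` writes a synthetic nine-peak example):

```bash
$ nhejsim sobp --profile sobp_synthetic.csv --species proton --out yields.csv
```

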