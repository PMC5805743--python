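# Methods

`nhejsim` simulates the induction and repair of DNA double strand breaks
(DSBs) in a cell nucleus irradiated by therapeutic ions, and distils the
outcome into closed-form correlations usable wherever dose and track-averaged
LET (LET_t) are scored — e.g. along a proton spread-out Bragg peak (SOBP).
This note records the model, its assumptions, the calibration procedure, and
what the synthetic conditions do and do not demonstrate.

## Damage model

**Geometry.** The nucleus is a water sphere of diameter 5 µm (typical of a
lymphocyte), centred at the origin; all positions are in nm and all distances
Euclidean 3-D.

**Dose → primary tracks.** Primaries are straight chords through the sphere
(no scattering or delta-ray escape: LET_t is the only physics descriptor the
downstream correlations consume). The expected track count follows from
energy balance, dose × nucleus mass = Σ (LET × chord length): with the
Cauchy mean chord 4r/3 and a per-Gy absorbed energy of 408.5 keV
(mass 6.545 × 10⁻¹⁴ kg), 1 Gy of 10 keV/µm radiation corresponds to
λ ≈ 12.3 tracks; the realised count is Poisson(λ). Chords are sampled with
µ-randomness (uniform direction, uniform impact point on the projected
disk), which reproduces the 4r/3 mean chord exactly.

**DSBs along a track.** DSBs are laid down by a Neyman–Scott cluster
process: cluster anchors form a Poisson process along the chord, each anchor
carries 1 + Poisson(ν) DSBs, and every DSB is displaced from its anchor by an
isotropic Gaussian of scale σ (displacements leaving the nucleus are
redrawn). The linear anchor intensity is fixed analytically so that the
expected DSB count equals the fitted yield correlation

    N_DSB = D · (d·L + e)

exactly — the line density (d·L + e)·L / E_Gy per unit length cancels the
nucleus size out of the expectation. The remaining free parameters (ν, σ)
are calibrated per (species, LET) by Monte Carlo bisection so that the mean
**cluster density** — the average number of other DSBs within 70 nm of each
DSB — matches the fitted quadratic

    CD(L) = f·L² + g·L + h .

σ defaults to 15 nm; at LETs where even single-DSB anchors (ν = 0) overshoot
the cluster-density target, σ is widened instead. The table (LET grid 1–30
keV/µm, both species, linear interpolation between nodes) ships as package
data and is regenerated by `nhejsim calibrate`. Two-stage common-random-
number bisection (1 500 then 6 000 repeat patterns) leaves calibration
residuals of ≲ 0.002 in cluster density, well inside the Monte Carlo error
of any downstream test. Because only intra-track structure contributes at
the 70 nm scale, the cluster density is dose independent.

**Break complexity** (extra strand breaks and base lesions per DSB) is drawn
from a Poisson whose mean grows linearly with LET (defaults: mean 1 at
30 keV/µm, → 0 at vanishing LET). This is a deliberate minimal stand-in for
a chromatin-fibre complexity library; repair outcomes are insensitive to
complexity, so only the qualitative increase with LET matters.

**Nanodosimetric DSB calling.** Independently of the emulator, an energy
deposition list can be converted to DSBs: each deposition survives a
Bernoulli(0.15) sensitive-fraction thinning (the share of nuclear volume
occupied by DNA backbone), causes strand damage with probability rising
linearly from 0 at 5 eV to 1 at 37.5 eV, and is assigned strand 1 or 2 by a
fair coin. Accepted sites are clustered by single-linkage at 3.32 nm (one
helical turn, 10 bp); a cluster with both strands present is a DSB at the
member centroid with complexity = members − 2. A genomic-coordinate variant
applies the fibre rules instead: opposite-strand backbone damages within
10 bp define the break, damaged bases within 3 bp of the extreme backbones
join it, and bases directly attached to a damaged backbone are excluded
(they leave with the backbone during end processing).

## Repair model (canonical NHEJ)

Each DSB becomes two broken ends, initially co-located at the break
position.

**Motion.** Ends move by a sub-diffusive continuous-time random walk: an
exponential waiting time, then a jump of half-normal length (scale
`step_sigma`) in a uniform random direction; jumps leaving the envelope are
rejected and resampled. Successive waiting-time *means* grow with the
number of completed steps, `wait_mean·(k+1)^((1−α)/α)`. Each individual
draw is exponential, yet the growing means make the ensemble MSD scale as
t^α with α < 1 (an aging random walk). A fixed-mean exponential wait would
give ordinary diffusion, which contradicts the sub-diffusion the motion is
meant to represent; the aging scheme is the minimal reconciliation and is
exact: MSD(t) = σ²·((1+γ)t/w̄)^α with γ = (1−α)/α.

**State machine.** Concurrently each end performs stochastic state changes
with exponential holding times, each representing recruitment and action of
a repair factor:

| transition | τ default (s) | meaning |
|---|---|---|
| NAKED → INHIBITED | 1000 | occupation by competing-pathway proteins |
| INHIBITED → NAKED | 60 | release |
| NAKED → KU | 0.5 | Ku70/80 loading (rapid, irreversible) |
| KU → DNAPK | 2 | DNA-PKcs loading (irreversible) |
| DNAPK + DNAPK → long synapse | — | requires 25 nm proximity |
| long synapse → 2 × NAKED | 95 | phosphorylation-driven dissociation |
| long synapse → short synapse | 200 | commitment (irreversible) |
| cleaning, per lesion | 180 | end processing of extra lesions |
| ligation | 600 | XLF/XRCC4/Ligase IV |

Two DNA-PK-loaded ends within the 25 nm capture radius form a long-range
synaptic complex (partner chosen uniformly at random among those in range;
the pair freezes at its midpoint). The complex either dissociates — both
ends reset to naked, and must re-recruit — or commits to a short-range
complex, after which all remaining lesions on both ends are cleaned (one
exponential draw per lesion) and the pair ligates. A join is **correct**
when both ends share a parent DSB and a **misrepair** otherwise; a DSB with
an unligated end at 24 h is **residual**. The scheduler is an event-driven
priority queue (motion events, transition events, synapse resolutions),
which preserves the exponential statistics exactly and costs nothing during
the long quiescent tail of a 24 h run.

**Calibration.** The recruitment constants are deliberately fast (Ku and
DNA-PKcs arrive within seconds, consistent with photobleaching-recovery
observations); the only deeply uncertain knobs — the motion scale and the
synapse commitment time — were calibrated jointly, by grid search over the
full species × dose × LET study grid, to two endpoints: (i) a pooled
residual fraction of ≈ 7.3 % at 24 h, and (ii) a 95th-percentile end
displacement of ≈ 168 nm at 24 h for the proton 2 Gy / 10 keV/µm condition.
The final defaults are `step_sigma = 9.5 nm`, `wait_mean = 2 s`,
`alpha = 0.61`, `tau_long_advance = 200 s`. With these, both residuals and
misrepair are *emergent*: residuals arise from end pairs that separate
beyond recapture during recruitment or during synapse-dissociation cycles
(a density-independent escape, since 3-D sub-diffusion is transient), and
misrepair arises from pairing with ends of nearby breaks. The emergent
misrepair-vs-cluster-density relation is linear with slope ≈ 0.17–0.19 and
intercept ≈ 0.00–0.01, in good agreement with the fitted correlation
(a = 0.1966, b = 0.008) even though neither constant was targeted.

## Correlation layer and SOBP mapping

The fitted constants a–h per species (protons, alphas; carbon is rejected at
the type level) power the correlations

    F_mis = a·CD + b          (fraction of joined DSBs misrepaired)
    F_res = c                 (constant residual fraction, 0.0736)
    Misrepair yield = N_DSB · F_mis · (1 − c)
    Residual yield  = N_DSB · c

with CD estimated from LET via the quadratic above. The misrepair/residual
crossover LET solves a·CD(L) + b = c/(1−c) (dose cancels); with proton
defaults the smallest positive root is ≈ 22.5 keV/µm. The yield linearity
was fitted on 0–20 keV/µm; evaluation outside attaches a warning rather
than failing, since SOBP distal edges legitimately exceed it.

`sobp_application` applies the correlations row-wise to a (depth, dose,
LET_t) profile. Zero-dose rows yield exactly zero, so the LET noise typical
of low-fluence distal records cannot leak into predictions. Falloff
detection reports the first depth where dose drops below 95 % (configurable)
of the plateau median — the published field quotes a specific falloff depth
but not its criterion, so the threshold is a package choice. The bundled
nine-peak SOBP generator (least-squares pristine-peak weights over an
analytic Bragg-like curve, sigmoidal LET rise through the distal edge) is
illustrative, not a reproduction of any specific clinical field.

## Problem sizes and determinism

Default study repeats are 2 500 (damage statistics) and 200 (repair) per
cell; the bundled tests and the acceptance script use 400–600 damage
repeats and 50 repair repeats per cell, and 100 nuclei for displacement
percentiles — sizes chosen so a complete verification run finishes in
minutes on one core while keeping every comparison inside 3 standard
errors. Every run is a pure function of its seed: grid cells derive
per-(cell, repeat) seeds from a base seed via `SeedSequence`, so grids are
reproducible and order-independent.

## Known limitations

- **Residual flatness at extreme cluster density.** The residual fraction
  is flat to within ~1 pp over most of the study grid, but rises by ~2–3 pp
  at the very highest cluster densities (alphas near 20 keV/µm, CD ≈ 1.4):
  misrepair commits strand orphan ends, and churn of transient wrong
  synapses (95 s lifetime) separates correct partners in dense clusters.
  Both mechanisms are tied to the fixed 25 nm capture radius and 95 s
  dissociation constant, and the excess persisted across the calibration
  space explored. A strict per-cell 3-SE flatness check can therefore flag
  1–3 of 16 grid cells; the pooled residual fraction remains within
  7.3 ± 1 %.
- Only DNA-PK-dependent canonical NHEJ is modelled: no homologous
  recombination, no DNA-PKcs-independent end joining, no repair centres or
  chromatin tethering, and no fractional Langevin alternative to the CTRW.
- The track emulator reproduces two summary statistics (yield, 70 nm
  cluster density) of real track structure, not the track structure itself;
  conclusions about quantities outside those statistics (e.g. the detailed
  sub-100 nm separation spectrum) should not be over-read.
- The complexity distribution is a parametric stand-in; only its
  monotonicity in LET is meaningful.
- Synapsed pairs are immobile until resolved, competing-pathway inhibition
  is transient by construction, and re-inhibition is unlimited — all
  choices where the mechanism is unreported; they were held fixed during
  calibration.
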