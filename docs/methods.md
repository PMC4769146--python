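# Methods

## Model structure and assumptions

The simulator is a static, diameter-class-structured model of fire effects
on 1.0-ha mono-specific patches: no growth, mortality or recruitment other
than the fire itself, no spatial fire spread, and no wind effects on flame
geometry. A patch is fifteen 2-cm DBH classes (1–3 to 29–31 cm) of live-stem
counts; everything else is derived. Crowns are cylinders: crown fuel is
distributed uniformly between the crown base H(1−CR) and the top height H,
and the scorched fraction of crown volume equals the scorched fraction of
crown length.

The chain per simulated fire is: class allometry → patch summary → vertical
fuel profile → available canopy bulk density → crowning decision → intensity
update → scorch height → per-class crown scorch and mortality → binomial
kills → percent basal-area loss.

## Allometry

Heights use H = 1.3 + a·QMD^b (black spruce a = 1.065, b = 0.886; jack pine
a = 1.306, b = 0.834). The 1.3 m term is the breast-height intercept of the
source height models; the multiplicative reading (1.3 + a)·QMD^b would put a
10-cm spruce at ~18 m, which no boreal spruce attains, so the additive form
is used.

The crown-ratio model takes "BA" as *stand* basal area in m² ha⁻¹ — the
convention of crown-ratio models, where competition reduces live crown —
computed from the patch itself before crown ratios. CR is clamped to
(0.01, 1]. Note a consequence: densifying a patch changes its crown ratios,
so patch summaries are only scaling-invariant at fixed crown geometry.

Bark thickness is BT = f·2.54·QMD (f = 0.032 spruce, 0.040 pine), in cm.
The 2.54 factor is kept exactly as in the source mortality model (it is a
units artifact of that model's imperial origin); the 0.3937 cm⁻¹ factor in
the mortality logistic partially inverts it.

## Canopy fuel profile and available CBD

Fuel mass per class (crown biomass × stems) is allocated uniformly over the
1-m layers its crown spans; layer k covers [k−1, k) m. Layer density is
allocated mass over layer volume (10 000 m² × 1 m), so the profile conserves
canopy fuel load to machine precision. The "available" CBD is the maximum
running mean of the profile over a window of 3.0 m (default; the source for
the running-mean approach does not print its window, so it is exposed as
`cbd_window`). The top of the deepest combustible stratum is the top of the
highest layer covered by any window position whose mean reaches the
0.11 kg m⁻³ threshold, capped at the last fuel-bearing layer; if crowning
holds but no window qualifies, the flame top falls back to CBH + CL.

Load-over-depth CBD (CFL/10⁴/CL) and available CBD are deliberately
different quantities: the former is a patch covariate, the latter the
crowning criterion input.

## Fire behaviour

The crowning criterion is used in its critical-height form
CBH_c = 100·I^(2/3)/h, h = 460 + 25.9·FMC, FMC = 100 %; the equivalent
critical-intensity form I₀ = (0.01·CBH·h)^1.5 is implemented as a
cross-check and both are tested to agree. Exponents are written as exact
2/3 rather than the conventional 0.667 rounding; the difference is below
0.1 % everywhere. Scorch height is SH = 0.1483·I^(2/3).

On crowning, I_f = 259.833·L^2.174 inverts Byram's L = 0.0775·I^0.46 with
flame length L equal to the combustible stratum top (a modelling decision;
`flame_length_scale` allows alternatives such as 1.5× a class height). The
intensity actually used is max(I_i, I_f): a crown fire cannot release less
energy than the surface fire that initiated it.

## Mortality and severity

The mortality logistic is increasing in crown scorch and decreasing in bark
thickness. It implies a non-zero death probability for thin-barked stems
even with zero scorch (M ≈ 0.87 at BT = 0, CS = 0); this baseline is part of
the published model and is kept, with a `no_scorch_no_mortality` switch to
force M = 0 when CS = 0 for sensitivity analyses. Kills are
Binomial(n_i, M_i) per class with a per-run seed derived from the master
seed, making every run reproducible and the closed-form expectation
E[S] = 100·Σ ba_i n_i M_i / BA available for verification. All fifteen
classes, saplings included, enter the basal-area severity statistic.
Severity classes put the boundary values 25 and 75 in the moderate class.

## Intensity sampling

Size-weighted resampling uses selection probability proportional to final
size among fires ≥ 0.1 ha. The within-fire distribution assumes ignition at
the rear focus of the final ellipse and self-similar growth under constant
conditions; local intensity is proportional to the front-normal spread
rate, so a point drawn uniformly over the burned area, projected radially
from the focus to the perimeter, has relative intensity
((P−F)·n̂)/(a+c) ∈ [(1−e)/(1+e), 1]. Sampling is by area Monte Carlo; a
deterministic dense-grid quadrature of the same projection serves as the
verification oracle (Kolmogorov distance ≲ 0.003 at n = 10⁵). The
length-to-breadth ratio defaults to 3.0 for both species (the
species-characteristic values used with the original archive are not
published; per-species overrides are config keys). Head and relative
vectors are paired index-wise; since both are i.i.d. draws this is
distributionally identical to drawing one product per run.

## Synthetic data

The real inputs (provincial inventory plots; the fire-protection agency's
1994–2010 archive) are proprietary, so generators emulate their structure:

- **Plots.** Two shape families over the 15 classes — truncated-geometric
  decay (reverse-J, "uneven") and discretised Gaussian with σ = 1.1 classes
  ("even"). Per plot, density and basal-area targets (defaults from the
  study system: spruce 4 000 stems ha⁻¹ / 22 m² ha⁻¹, pine 2 200 / 15) are
  log-normally jittered (12 % / 10 %), the family's shape parameter is
  solved by root-finding so the expected basal area matches, per-class
  counts get 15 % log-normal noise and are rounded to integers. Under these
  defaults mean SWDI falls in the uneven (1.8–2.4) and even (1.2–1.7)
  bands, and spruce patches land near the study system's covariate
  envelope (CBD ≈ 0.30 kg m⁻³, CBH ≈ 2.8 m).
- **Fires.** Log-normal head intensities (fuel-type scale: C-2 median
  800 kW m⁻¹, C-3 median 400 kW m⁻¹, reflecting the markedly hotter black
  spruce fires of the emulated archive; σ_log = 1.3) and log-normal sizes
  with a log-log slope of 0.5 on intensity, so big fires are hot fires.

What passing tests on these inputs shows is that the *mechanism* behaves as
specified — spruce strata burn at high severity more often than pine
strata, severity rises with intensity, structure labels map to SWDI bands.
The generators do not reproduce regional soil/drainage stratification,
inventory measurement error, or the empirical intensity distributions of
the real archive, so the numerical severity proportions of the original
study are not reproduction targets, only their direction.

## Experiment and problem sizes

The stratified design is 3 000 runs per region × species stratum by
default. Tests and the acceptance script use scaled-down designs
(250–750 runs per stratum, 20 plots and 200–250 fire records per stratum),
sizes chosen so Monte-Carlo checks resolve the directional contrasts
comfortably while the whole suite runs in seconds. Determinism is
end-to-end: stratum seeds derive from (master seed, species index, region
index), and each run's binomial seed is drawn from the stratum stream and
logged in the output table.

## Known limitations

- No within-patch spatial fuel heterogeneity (crown clumping), no wind, no
  duff/soil-organic-layer consumption, no stem or root injury pathways.
- Cylindrical crowns bias the vertical fuel placement relative to conic or
  parabolic profiles.
- The canopy base height is a count-weighted mean over classes; other
  definitions (e.g. lowest dense layer) would shift crowning thresholds.
- Severity saturates near 99 % rather than 100 % because very thick-barked
  large stems retain a small survival probability even when fully scorched.
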