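# Methods

## Scope and data model

The package analyses two measurement modalities on tissue-mimicking
phantoms (agarose gels with Intralipid as scatterer and diluted India ink
as absorber) carrying a fluorescent contrast agent, typically a dye
conjugated to gold nanorods (GNRs):

* **Diffuse reflectance (DR)** — reflected intensity Γ versus
  source–detector separation ρ on the phantom surface, used to recover
  the effective attenuation coefficient.
* **FLIM** — a scanned grid of per-pixel TCSPC photon-arrival histograms,
  used to map fluorescence lifetimes.

The lifetime-shortening mechanism itself (plasmonic near-field coupling
between dye and metal) is *not* modelled; the shortened fast lifetime and
its amplitude fraction are treated as ground-truth parameters of the
probe, taken from reference measurements (`phantomflim.reference`).

Units are fixed package-wide: lengths in mm, optical coefficients per mm,
times in ns, IRF widths in ps, volumes in µL.

## Diffuse reflectance

The forward model for a pencil beam on a semi-infinite turbid medium is
Γ(ρ) = c₁/ρ² · exp(−µ_eff ρ) with µ_eff = √(3 µ_a µ_s′), valid in the
diffusive regime (ρ beyond a transport mean free path, absorption not
dominant). The analysis linearises with y = ln(ρ²Γ) and fits y = c₂ − µ_eff ρ
by **unweighted ordinary least squares** — deliberately the plain
computation a DR rig reports, not a noise-optimal weighted fit.

Numerical choices:

* Samples with Γ ≤ 0 or Γ ≤ noise_floor are **dropped, not clipped**;
  clipping would bias the slope. Exclusions are counted and reported.
* Fewer than two valid samples raises `InsufficientDataError`; at the
  comparison level (`compare_slopes`) this becomes a `detected=False` row
  rather than an exception, because a concentration-ladder study must
  survive individual phantoms whose light is entirely absorbed.
* c₂ is never stored; it is ln(c₁) on demand.
* The default simulated ρ grid is 1.0–6.0 mm in 0.25 mm steps. Real rigs
  rarely publish their separations; this spans the diffusive regime for a
  fibre-illuminated surface scan and is configurable.

With µ_s′ known (e.g. from the Intralipid load), µ_a = µ_eff²/(3µ_s′).
Simultaneous two-coefficient inversion from a single profile is
under-determined and not offered.

## FLIM decay model

The decay law is I(t) = Σᵢ αᵢ exp(−t/τᵢ). Under pulsed excitation with
period T = 1000/rep_rate ns, photons from earlier pulses pile into the
observation window; per component the steady-state wrapped curve has the
geometric-series form exp(−t/τ)/(1 − exp(−T/τ)). Expected per-bin counts
integrate this exactly over each of the n_bins equal bins (closed form,
no quadrature), so periodisation conserves intensity: the bins of one
period sum to the infinite-horizon integral. At 50 MHz and τ = 3.92 ns
the wrap factor is 1.0061 — small but systematic, so the correction is
always applied in simulation and (by default) in fitting.

The amplitude-weighted mean lifetime is ⟨τ⟩ = Σ fᵢτᵢ with amplitude
fractions fᵢ = αᵢ/Σαⱼ. Amplitudes are normalised before applying the
formula so ⟨τ⟩ is well defined for unnormalised fits; consistently, a₁%
is the **amplitude** fraction of the free component (not the intensity
fraction α₁τ₁/Σαⱼτⱼ).

The instrument response is modelled, when enabled, as a Gaussian of
configurable FWHM applied as a circular convolution (the excitation is
periodic). The default is `irf_fwhm = 0`: excitation pulses of 10–100 ps
are one to two orders below the shortest lifetime of interest (~0.35 ns),
so the delta approximation is defensible and keeps the fit model simple.
`n_bins = 256` per period is a typical TCSPC ADC resolution.

## Per-pixel fitting

Two models, matching the free-dye / conjugate protocol:

* **mono** — free amplitude, lifetime, constant background;
* **biexp_fixed** — free total amplitude, free fraction f₁ ∈ [0,1], free
  fast lifetime τ₁, constant background; the slow lifetime τ₂ is held at
  the free-dye value measured once per matrix (3.92 ns in solution,
  3.74 ns in phantom).

Component 1 is **always the free lifetime**; components are never sorted
by value, so τ₁ may exceed τ₂ and the labels keep their meaning.
|τ₁ − τ₂| < 0.05 ns raises an identifiability flag (not a rejection).

**Objective.** The default objective is the exact Poisson maximum
likelihood, implemented as least squares on signed square-root deviance
residuals. The classical Neyman-weighted χ² fit (σ² = max(c,1)) is
available via `objective="wls"`, but it is *not* the default: at the
study's 10⁴ counts/pixel the tail bins hold only a few photons each and
Neyman weighting biases a 3.92 ns lifetime low by ≈0.18 ns (measured on
simulated replicates) — several times the per-pixel statistical scatter.
The Neyman **reduced χ²** is still computed and reported for every fit as
the conventional TCSPC quality metric; values above 1.5 are flagged.

Other choices:

* Deterministic initialisation — τ from the log-linear slope of the
  leading decade of the background-subtracted curve, f₁ = 0.7, background
  from the mean of the last 5% of bins — so image fits are reproducible
  without any seed.
* Lifetime bounds [0.05, 15] ns: the plausible 0.1–10 ns range padded so
  genuine values never sit on a bound.
* Pixels with fewer than 100 total photons are excluded (reported, not
  errored); below that a two-component fit is meaningless.
* A constant background is fitted even though the pure decay law omits
  it — real TCSPC has dark counts. The simulator's default background is
  zero so the pure-model path stays testable.
* Optimiser: `scipy.optimize.least_squares` (bounded trust region).

Image-level aggregation reports mean and sample STD of τ₁, a₁%, χ² and
⟨τ⟩ over converged pixels, plus a τ₁ histogram (default 0.05 ns bins).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **DR profiles** — forward model scaled to a photon budget at the
  nearest separation, per-sample Poisson draws, configurable dark-count
  floor. Baseline optics: µ_s′ = 1.0 /mm (Intralipid-like), ink-only
  µ_a = 0.005 /mm, plus a per-(mg/mL gold) absorption increment larger at
  650 nm than at 780 nm, mirroring the nanorods' absorption spectrum.
  These are literature-plausible placeholders, configurable per run — the
  reference study reports no coefficient values.
* **FLIM images** — every pixel shares the ground-truth decay; expected
  curves are scaled by a spatially smoothed log-normal concentration
  field (CV and correlation length, default 4 px, are the only knobs;
  mean fixed at 1 so total intensity is CV-invariant), then counts are
  drawn Poisson per bin. The field emulates the concentration
  inhomogeneity that gel solidification produces; smooth rather than
  blockwise because solidification gradients are continuous.
* **Recipes** — fixed fractions (10% Intralipid, 3% ink, water to
  volume, agarose 1 g/100 mL) plus a contrast volume from
  target/stock concentration; volumes conserve exactly, and a contrast
  demand above 87% of total is rejected as infeasible.

Seeds are explicit everywhere; no global random state is touched.

What the generator does **not** emulate: detector afterpulsing and dead
time, measured (non-Gaussian) IRFs, scattering-induced temporal
broadening of the excitation inside the phantom, dye photobleaching, and
any concentration dependence of the decay parameters. Passing recovery
tests therefore demonstrates the correctness of the estimators under
ideal counting statistics, not robustness to every instrumental artefact
of a real rig.

## Problem sizes

Recovery checks use 64×64 pixels at ~10⁴ counts/pixel (the study's
maximum scan size); unit and property tests use 4×4 to 20×20 grids and
reduced bin counts, which this package treats as its standard small-image
regression conditions. The χ² calibration check runs at 10⁵ counts/pixel
where the Neyman statistic is well calibrated (mean within [0.85, 1.15]
over 100 pixels).

## Known limitations

* The bi-exponential fit with τ₁ close to the fixed τ₂ (e.g. 2.72 vs
  3.92 ns) is weakly identifiable at 10⁴ counts: single-pixel estimates
  of (τ₁, a₁%) are strongly correlated and image means drift upward by a
  fraction of the per-pixel STD. This is a property of the model/counts
  regime, not the optimiser; tests bound it by the reference per-pixel
  STDs.
* DR slope recovery is validated property-wise (exact round trip,
  monotonicity, detection failure) because no numeric slope values exist
  to anchor against; absolute µ_a recovery inherits whatever error the
  assumed µ_s′ carries.
* The reported χ² follows the Neyman convention and is biased high when
  many bins hold <~10 counts; it is a comparative quality flag, not a
  formal goodness-of-fit test, at low counts.
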