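# phantomflim

Dual-modal analysis of tissue-mimicking phantoms carrying fluorescent
nano-probes: **diffuse reflectance (DR)** for optical-property recovery and
**fluorescence-lifetime imaging (FLIM)** for per-pixel decay analysis, plus a
synthetic-data generator that simulates both measurements with known ground
truth so every stage is verifiable by parameter recovery.

It is written for researchers characterising contrast agents — e.g.
fluorescein-conjugated gold nanorods (GNRs) — in agarose/Intralipid/India-ink
phantoms, where the plasmonic near field of the metal shortens the dye's
fluorescence lifetime and the gold load raises the phantom's absorption.

## The models

**Diffuse reflectance.** A pencil beam entering a semi-infinite turbid medium
produces a surface reflectance profile

```
Γ(ρ) = c₁/ρ² · exp(−µ_eff · ρ),      µ_eff = √(3 µ_a µ_s′)
```

with source–detector separation ρ (mm), absorption µ_a and reduced scattering
µ_s′ (per mm). `ln(ρ²Γ)` is linear in ρ with slope −µ_eff, so ordinary least
squares on the transformed profile recovers µ_eff; with one coefficient known
the other follows from µ_a = µ_eff²/(3 µ_s′). Samples below the detection
floor are dropped, not clipped; if fewer than two remain the phantom is
reported as *not detected* — exactly what happens to heavily gold-loaded
phantoms at the rod's absorption peak.

**FLIM.** Each pixel's TCSPC histogram follows I(t) = Σᵢ αᵢ·exp(−t/τᵢ) under
periodic pulsed excitation (20/50/80 MHz). Because τ is not ≪ the pulse
period, the expected counts use the wrapped (incomplete-decay) closed form
exp(−t/τ)/(1−exp(−T/τ)) integrated exactly over each bin. Pixels are fitted
either mono-exponentially (free dye) or bi-exponentially with the slow
lifetime **fixed** at the free-dye value, reporting the fast lifetime τ₁, the
amplitude percentage a₁% = 100·α₁/(α₁+α₂), the amplitude-weighted mean
lifetime ⟨τ⟩ = Σ fᵢτᵢ, and the Neyman reduced χ². Fits minimise the Poisson
deviance (exact MLE for counting noise) with deterministic initialisation, so
repeated runs are bit-identical.

## Worked example

```python
import numpy as np
from phantomflim import (AcquisitionSettings, DecayModel, FlimImageFitter,
                         PhantomSpec, simulate_flim_image)

settings = AcquisitionSettings(rep_rate=50.0, n_bins=256, counts_target=1e4)
truth = DecayModel(amplitudes=(0.8116, 0.1884), lifetimes=(1.15, 3.92))
spec = PhantomSpec(truth_decay=truth, grid=(16, 16), seed=4)
image = simulate_flim_image(spec, settings)

fitter = FlimImageFitter(mode="biexp_fixed", tau2_fixed=3.92).fit(image)
s = fitter.summary_
print(f"tau1 = {s.tau1_mean:.3f} +- {s.tau1_std:.3f} ns")
print(f"a1%  = {s.a1_pct_mean:.2f} +- {s.a1_pct_std:.2f}")
print(f"chi2 = {s.chi2_mean:.3f}")
```

prints

```
tau1 = 1.154 +- 0.035 ns
a1%  = 81.27 +- 0.66
chi2 = 1.103
```

i.e. a 16×16 image simulated from a GNR-conjugate decay (81.16% of the
amplitude in a 1.15 ns quenched component, the rest at the free-dye 3.92 ns)
is refitted with the slow component held at 3.92 ns: the image-mean fast
lifetime and amplitude fraction recover the ground truth within counting
statistics, and the reduced χ² near 1 confirms the model describes the noise.

The same flows are available from the shell:

```sh
phantomflim simulate  --out sim  --seed 1            # synthetic measurement suite
phantomflim analyze   --input sim --out report       # fit everything, write tables
phantomflim reproduce --out full --seed 1            # simulate + analyze + recovery report
```

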