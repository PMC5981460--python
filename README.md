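# ppgsim

Monte Carlo simulation of the origin of remote photoplethysmography (PPG)
signals in multilayered skin, 450–1000 nm.

Remote PPG cameras and contact probes read a tiny cardiac-synchronous
modulation of the light returned from skin.  Whether that modulation really
comes from arterial **blood-volume variations** (the volumetric model) — and
from *which depth* — has been contested, with direct consequences for the
validity of camera-based SpO₂.  `ppgsim` is built for researchers in
biomedical optics and camera-based vital-signs monitoring who want to probe
that question computationally: it simulates the PPG-amplitude spectrum of a
six-layer finger-pad skin model under diastole/systole perturbations,
compares the penetration depth of the incident light with the depth-origin
of the pulsatile signal, models the effect of skin compression and of a
ferrule-shielded fiber probe, and implements the full measurement-side
signal-processing chain on synthetic recordings with known ground truth.

## Model in brief

Skin is a stack of layers ℓ (epidermis, capillary loops, upper plexus,
reticular dermis, deep plexus, subcutis) with per-layer absorption built
from whole-blood HbO₂/Hb, water, fat and baseline-tissue coefficients.
Blood confined in vessels of diameter v_d is corrected for self-shielding
(pigment packaging):

    f[μa·v_d] = 1 / (1 + 1.007·(μa·v_d/2)^1.228)

Systole adds a pulse fraction p of arterial blood to a layer; the layer
signature at wavelength λ is the normalized drop in total diffuse
reflectance,

    PPG_REM(λ, ℓ) = (RdT_d − RdT_s) / RdT_d ,

computed by correlated Monte Carlo transport (diastolic and systolic runs
share photon paths).  The remote spectrum is the weighted mixture
Σ_ℓ w_ℓ·PPG_REM(λ, ℓ); band ratios GoR = green/red and IRoR = IR/red
summarize it.  Penetration depth (PD) and depth-origin (DO) are the
63.2 % (1 − 1/e) cumulative-area depths of the diastolic flux F(z) and of
the mixed differential flux |ΔF(z)|.  A transfer function
TF = PPG_REM/PPG_OFP links fiber-probe readings to remote ones.
See `docs/methods.md` for the complete account.

## Worked example

```python
import numpy as np
from ppgsim import (MCConfig, band_ratios, mix_signatures, reference_model,
                    self_shield, simulate_condition)
from ppgsim.depth_metrics import depth_origin, penetration_depth

print(f"self-shielding f(250 cm^-1, 40 um) = {self_shield(250.0, 40.0):.3f}")
print(f"self-shielding f(250 cm^-1, 20 um) = {self_shield(250.0, 20.0):.3f}")

model = reference_model()
lams = [530.0, 550.0, 577.0, 660.0, 700.0, 800.0, 840.0]
run = simulate_condition(model, lams, MCConfig(n_photons=20_000, seed=7))
spec = mix_signatures(run.signatures(), model.weights)
gor, iror = band_ratios(spec)
print(f"GoR = {gor:.2f}, IRoR = {iror:.2f}")

prof = run.flux_profiles(550.0)
print(f"PD(550) = {penetration_depth(prof):.3f} cm, "
      f"DO(550) = {depth_origin(prof, model.weights):.3f} cm")
```

Output (about half a minute on one core):

```
self-shielding f(250 cm^-1, 40 um) = 0.699
self-shielding f(250 cm^-1, 20 um) = 0.845
GoR = 5.39, IRoR = 2.60
PD(550) = 0.101 cm, DO(550) = 0.203 cm
```

Reading it: green light in vessels 40 µm wide effectively absorbs ~30 %
less than a homogeneous blood–tissue mixture would (~15 % less at 20 µm).
The mixed spectrum is several times stronger in green than in red
(GoR ≈ 5) with IR about 2–3× red (IRoR ≈ 2.6) — the characteristic
remote-PPG amplitude spectrum.  And at 550 nm the pulsatile signal
originates about twice as deep (2.0 mm, upper-plexus/reticular-dermis
level) as the bulk of the incident light penetrates (1.0 mm): green PPG
does reach pulsating arterioles, which is the volumetric-model claim the
simulation supports.  Simulating the compressed model
(`ppgsim.compressed_model()`) collapses GoR while leaving IRoR nearly
unchanged, mirroring what compression does to measured spectra.

A command-line interface mirrors these steps:

```bash
ppgsim spectra --model reference --lam 450:1000:25 --photons 1e5 --seed 42 --out spectra.csv
ppgsim depth   --model reference --lam 500,550,577 --out depth.csv
ppgsim tf      --model reference --lam 450:1000:50 --out tf.csv
```

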