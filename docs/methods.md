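# Methods

## Scope

`ppgsim` is a forward-simulation and signal-processing package for the
opto-physiological origin of remote photoplethysmography (PPG).  It answers,
on synthetic inputs, the question: *can cardiac blood-volume variations in
dermal and subdermal vessel layers quantitatively explain the remote
PPG-amplitude spectrum of finger-pad skin in 450–1000 nm, including its
response to skin compression?*  The package simulates light transport through
multilayered skin under diastolic and systolic states, extracts per-layer
pulse "signatures", mixes them into amplitude spectra, compares penetration
depth (PD) against the depth-origin (DO) of the pulsatile signal, converts
fiber-probe readings into remote-equivalent spectra, and implements the
measurement-side processing chain used to obtain such spectra from raw
reflectance recordings.

## Skin model

Finger-pad skin is modelled as a stack of homogeneous layers: epidermis
(EPI, bloodless), capillary loops (CL), upper plexus (UP), reticular dermis
(RD), deep plexus (DP) and subcutis (SC).  A compressed variant (firm
pressure on the pad) merges RD and DP, reduces dermal blood and water
fractions roughly four-fold, removes dermal venous blood (ra:rv = 1:0) and
pools partially venous blood at the subcutis (0.75:0.25).  Layer parameters
(thickness d, refractive index n, blood fraction Cb, water fraction Cw, fat
fraction Cf, mean vessel diameter vd) are tabulated in
`skin_models.reference_model()` / `compressed_model()` and shipped as
editable YAML configs (`data/reference.cfg`, `data/compressed.cfg`).
Melanin is excluded: the finger pad has very low melanocyte density.

### Absorption

Epidermal absorption combines water with a connective-tissue baseline
`γ·[0.244 + 85.3·exp(−(λ−154)/66.2)]` (γ = 0.5).  Dermal/subcutis non-blood
absorption mixes fat, water and a water-scaled baseline
`γ·(Cw/0.65)·[0.244 + 16.82·exp(−(λ−400)/80.5)]` with γ = 0.5 for dermis and
0.25 for subcutis.  Blood enters through whole-blood oxy/deoxy-hemoglobin
coefficients weighted by the arterial/venous split and oxygen saturations
(SpO2 = 0.97, SvO2 = 0.67).

Because blood is confined to discrete vessels rather than homogeneously
mixed, its effective absorption is reduced by the self-shielding (pigment
packaging) factor `f[x] = 1/(1 + 1.007·(x/2)^1.228)` with `x = μa,blood·vd`.
In green light at 250 cm⁻¹ whole-blood absorption this gives ≈ 0.70 for
40 µm vessels and ≈ 0.85 for 20 µm vessels; in red/IR, f ≈ 1.

*Consistency choice.* The printed diastolic and systolic absorption
formulas weight the non-blood term by different blood fractions (actual Cb
vs apparent, self-shielded Cb′), which breaks the requirement that the
systolic state reduce to the diastolic one at zero pulse and injects a
spurious absorption offset comparable to the true pulse signal in the IR.
This package weights the systolic non-blood term by the *actual* blood
volume plus the added increment, `1 − (Cb + p·fa)`, restoring continuity at
p = 0.

### Systole

A systolic event increments the apparent arterial fraction by a relative
pulse fraction p: `fa_s = fa_d·(1 + p)`.  p is not known from first
principles; the default p = 0.05 per pulsating layer yields AC/DC amplitudes
in the 10⁻³–10⁻² range typical of finger-pad recordings, and it can be set
per model.  The increment is interpreted relatively (proportional to the
layer's own arterial content) rather than as an absolute volume fraction:
an absolute reading would add ~4 % blood volume to layers holding 0.4–4 %
blood and produce amplitudes an order of magnitude above the observed
bound of 0.1.

Two volume-bookkeeping mechanisms are implemented.  *Layer expansion* (LE)
lets the layer thicken by the added volume (`d_s = d·(1 + Cb′_s·p)`) and
renormalizes concentrations by E = d/d_s.  *Water displacement* (WD) keeps
the geometry fixed and lets the added blood replace an equal volume of
water.  Their perturbations of the optical thickness μa·d differ only by the
plasma-water term of the added blood, under 10 % of the perturbation even at
the 975 nm water peak (asserted analytically across the grid in the tests).
The spectra and depth pipelines default to WD: with fixed geometry the
correlated-sampling estimator below becomes nearly exact, whereas LE's
~10⁻⁴ cm boundary shifts desynchronize photon pairs and raise the signature
noise by two orders of magnitude at desk photon budgets.  LE remains
selectable everywhere (`mechanism="LE"`).

### Scattering

Reduced scattering follows `μs′ = c0·λ^−b` with b = 0.1 below 580 nm and
0.05 above, pinned per layer class at 580 nm (EPI 15, dermal 20, subcutis
10 cm⁻¹), which also makes the two exponent bands continuous there; the
choice of 580 nm as the pinning point matters by < 2 % anywhere in band.
Anisotropy is g = 0.9 throughout; μs = μs′/(1−g).

### Chromophore tables

The bundled table (`data/chromophores.csv`) is a synthetic compilation:
hemoglobin molar-extinction anchor values from the standard literature
compilations converted to whole blood at 150 g Hb/L, water from Pope/Fry and
Hale/Querry anchors, lipid from van-Veen-style measurements, all
monotone-spline interpolated to a 5 nm grid.  The 150 g/L convention is a
documented package choice — the blood fractions Cb multiply whole-blood
coefficients directly.  Anchor fidelity is roughly 10–20 % at some
wavelengths, which shifts simulated spectra slightly but preserves every
feature the package asserts (green ≫ red amplitudes, the deoxy/oxy crossing
in red, the ~800 nm isosbestic point, water-dominated IR structure).

## Monte Carlo transport

The engine traces weighted photon packets through the layer stack in
cylindrical (r, z) geometry: collimated pencil beam at the origin, specular
entry reflection, Henyey–Greenstein scattering, Fresnel
reflection/refraction with total internal reflection at every
index-mismatched interface, and Russian roulette termination (threshold
10⁻⁴, survival 0.1).

Absorption uses *pathlength weighting* rather than collision-based capture:
collision sites are sampled from μs alone and the packet weight decays
continuously as `exp(−μa·ℓ)` along each hop, the lost weight being deposited
segment-by-segment into the depth grid.  The estimator is unbiased — the
engine reproduces the van de Hulst benchmark slab (albedo 0.9, g = 0.75,
optical thickness 2: Rd = 0.09739, Tt = 0.66096) and the Chandrasekhar
H-function result for a matched semi-infinite isotropic medium within
Monte Carlo error — and it makes a photon's trajectory independent of
absorption.  Two runs sharing a seed and differing only in μa therefore
follow identical paths, so the 10⁻³-relative systolic reflectance drop is
measured by correlated sampling with noise far below that of independent
runs (measured signature noise ~10⁻⁶ at 5·10⁴ photons).  Each photon owns a
counter-derived xorshift64* stream, and Russian roulette draws from a
separate per-photon substream, so pairwise correlation survives differing
draw counts.  Runs are bit-reproducible for a fixed seed.

Scoring grids: radial dr = 0.0005 cm × 3000 bins (spanning 1.5 cm, the
grid the probe transfer function is defined on), depth dz = 0.002 cm sized
to the stack, with overflow bins so that energy conservation
(Rsp + RdT + A + Tt = 1) holds to 10⁻³ — exactly in expectation, with only
roulette variance remaining.

### Problem sizes

The paper-scale computation (10⁸–4·10⁹ photons per run on a GPU) is scaled
down to desk budgets: 3·10⁴ photons per run for the shared condition
fixtures, 5·10⁵ for the benchmark comparisons, and a 10⁴/10⁵/10⁶ ladder for
the precision-scaling analysis.  Thanks to the correlated estimator these
budgets resolve even the weakest subcutis signatures (~10⁻⁵) with a few
percent noise.  Statistical precision is characterized by the
repeat-to-repeat coefficient of variation of the mixed spectrum, which
follows the expected 1/√N photon scaling (verified over the ladder); the
paper-scale CV of ~5 % at 10⁸ photons per run with *independent* diastolic
and systolic runs is not reproducible at desk scale and is represented by
that scaling law instead.

## Spectra, depth metrics and probe transfer

A layer's *signature* is `(RdT_d − RdT_s)/RdT_d` with only that layer
perturbed; the remote spectrum is the weight-mixed sum over signature slots,
with default weights w_ref = (0,0,1,2,3,1)/3 over (EPI, CL, UP, RD, DP, SC)
and w_comp = (0,0,0,2,18,1)/3 over six slots on the five compressed layers.
The six-onto-five mapping is a documented convention: slots 5 and 6 both
address the subcutis ("SC" and "SC & digital artery"), slot 6 being a
second, independently seeded SC perturbation pair.  Spectra are reported as
AC/DC and scaled to the value at (the grid point nearest) 660 nm; GoR and
IRoR are band *means* over 520–577, 660–700 and 800–840 nm — band
integrals would give identical ratios up to bandwidth constants.

PD is the depth containing 1 − 1/e ≈ 63.2 % of the area under the
diastolic depth-resolved flux F(z); DO applies the same crossing to the
weight-mixed differential flux ΔF(z) = |Σ_l w_l (F_d − F_l_s)|, the signed
per-layer differences being mixed *before* the absolute value.  Crossings
are interpolated linearly inside the crossing bin, so neither metric is
quantized to the 0.002 cm grid, and both are invariant to flux rescaling.
F(z) is the pathlength-estimated fluence (exact also where μa = 0); bins
containing an internal interface are replaced by the mean of their
neighbours (de-spiking).  Whether the original post-processing used fluence
or absorbed power density is not determinable; the PD/DO area ratios are
insensitive to the per-layer 1/μa factor within a layer but not across
layers, so this remains a caveat on absolute depth values (the PD < DO
ordering is robust to it).

The fiber-probe (OFP) observable clips the radial reflectance profile:
cumulative reflectance from bin n_r0 = 278 outward (1.39 mm on the dr grid;
the probe ferrule nominally shields 1.59 mm — the mismatch is inherited
as-is), rescaled by C = RdT/uDR(n_ε) with n_ε = 10 to avoid near-origin
numerical noise.  The transfer function TF(λ) is the ratio of weight-mixed
remote over probe amplitudes; TF < 1 where the ferrule geometry boosts the
apparent amplitude (mostly below 600 nm), and TF·PPG_OFP reconstructs
PPG_REM identically by construction.

## Measurement-side chain

* **DRS calibration**: (raw − dark)/(reference − dark) per wavelength.
* **AC/DC**: divide by a zero-phase 4th-order Butterworth low-pass at
  40 beats/min (0.667 Hz) and subtract 1; exactly gain-invariant.
* **Adaptive bandpass (ABPF)**: short-time transform, Hann window of 256
  samples, 50 % overlap-add, retaining ±1 bin around the pulse-rate
  fundamental and 6 harmonics; bin-centered in-band content passes with
  < 1 % RMS distortion, between-harmonic tones are attenuated > 20 dB.
* **Ensemble averaging**: cycles demarcated at systolic peaks, linearly
  resampled to 31 samples, combined with a 10 % trimmed mean; residual noise
  follows σ/√(0.8 N).
* **Features**: R is the ratio of fundamental-component standard deviations
  of two channels (the std-of-ratio alternative is unstable near zero
  crossings and was rejected); P their phase difference at the fundamental,
  in (−180°, 180°].  Pulse rate is estimated by Fourier argmax over 10–20 s
  windows.  Demarcation precision is one sample period, rounded up (63 ms
  at 16 Hz).
* **PPG imaging**: translation-only registration by FFT cross-correlation
  (frames below a correlation threshold are dropped), per-pixel trimmed
  means of peak and valley frames, normalized difference
  (diastolic − systolic)/diastolic, block-averaged downscale (default 4).

## Synthetic data

Generators produce every input with exact ground truth: pulse streams (7
harmonics with amplitudes (1, 0.45, 0.25, 0.12, 0.06, 0.03, 0.015), zero
phases by default — a fixed, physiologic-looking waveform whose systolic
peaks are returned analytically), multiplicative slow drift, additive
Gaussian sensor noise, two-channel pairs with prescribed fundamental ratio R
and phase P, multi-wavelength spectroscopy streams with dark/reference
frames whose amplitude profile is flat within the red and IR analysis bands
(so the generated IRoR is exact) and whose phase steps by 30° near 600 nm,
and textured video stacks with optional integer-pixel jitter.  What they do
*not* emulate: Poisson/shot noise, ballistocardiographic motion, specular
reflections, subject-to-subject variability — so closed-loop test passes
demonstrate correctness of the processing chain, not robustness to every
real-world nuisance.

## Known limitations

* One-dimensional layering only; no lateral heterogeneity or tree-like
  vascular geometry.
* Bundled chromophore tables are anchor-interpolated, not a verbatim
  published compilation; absolute spectra carry that uncertainty.
* The pulse fraction p and the mixing weights are calibration conventions,
  not measured quantities; inverse estimation of the weights from a
  measured spectrum is ill-posed and out of scope.
* LE-mechanism signatures are noise-limited at desk photon budgets in the
  red/IR; quantitative LE/WD cross-checks are restricted to green
  wavelengths plus the analytic full-grid comparison.
* Paper-budget precision figures require GPU-scale photon counts and are
  represented by the 1/√N scaling law, not reproduced numerically.
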