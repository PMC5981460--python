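"""Layer signatures, mixed remote PPG-amplitude spectra and band ratios.

A per-layer *signature* is the normalized pulse amplitude the skin would show
if only that layer pulsed: the relative drop of total diffuse reflectance
between diastole and systole, ``(RdT_d - RdT_s) / RdT_d``.  The remote PPG
spectrum is a weighted linear mixture of the signatures; band-amplitude
ratios (green-over-red, IR-over-red) summarize it.

Diastolic and systolic runs at one wavelength share the photon launch seed,
so the tiny reflectance difference is estimated by correlated sampling
rather than as the difference of two independent noisy totals.  This is a
deliberate variance-reduction choice; at desk photon budgets an uncorrelated
difference of two quantities that differ by ~1e-3 would be pure noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .mc_transport import MCConfig, MCResult, run_mc
from .skin_models import SkinModel, build_optical_stack

__all__ = [
    "SignatureSet",
    "PPGSpectrum",
    "SimulationRun",
    "simulate_condition",
    "layer_signature",
    "mix_signatures",
    "band_ratios",
    "simulation_precision",
    "DEFAULT_WAVELENGTHS",
    "BANDS",
]

#: default simulation grid, nm
DEFAULT_WAVELENGTHS = np.arange(450.0, 1001.0, 5.0)
#: analysis bands, nm: green, red, infrared
BANDS = {"green": (520.0, 577.0), "red": (660.0, 700.0), "ir": (800.0, 840.0)}
#: wavelength the scaled spectrum is normalized at, nm
SCALE_NM = 660.0
# seed spacing between wavelengths / the independent second-SC pair
_LAM_SEED_STRIDE = 7919
_VIRTUAL_SEED_OFFSET = 104729


@dataclass
class SignatureSet:
    """Per-slot, per-wavelength normalized PPG amplitudes with MC errors."""

    wavelengths: np.ndarray
    signatures: np.ndarray  # (n_lam, n_slots)
    stderr: np.ndarray
    condition: str
    slot_names: list[str]
    p: float
    n_photons: int
    seeds: list[int] = field(default_factory=list)

    def slot(self, name: str) -> np.ndarray:
        return self.signatures[:, self.slot_names.index(name)]


@dataclass
class PPGSpectrum:
    """Weight-mixed PPG-amplitude spectrum (AC/DC and scaled-to-660 forms)."""

    wavelengths: np.ndarray
    acdc: np.ndarray
    scaled: np.ndarray
    weights: np.ndarray
    scale_wavelength: float


@dataclass
class SimulationRun:
    """All transport results of one condition over a wavelength grid.

    ``diastole[lam]`` is the diastolic result; ``systole[lam][slot]`` the
    result with only that signature slot's layer perturbed.  The second-SC
    slot of the compressed model is backed by an independently seeded
    diastole/systole pair (``diastole_alt``).
    """

    model: SkinModel
    wavelengths: np.ndarray
    config: MCConfig
    p: float
    mechanism: str
    diastole: dict[float, MCResult]
    systole: dict[float, dict[int, MCResult]]
    diastole_alt: dict[float, MCResult]
    seeds: dict[float, int]

    @property
    def slot_names(self) -> list[str]:
        names = []
        seen: dict[str, int] = {}
        for idx in self.model.signature_layers:
            base = self.model.layers[idx].name
            seen[base] = seen.get(base, 0) + 1
            names.append(base if seen[base] == 1 else f"{base}*{seen[base]}")
        return names

    def signatures(self) -> SignatureSet:
        """Per-slot normalized pulse amplitudes across the grid."""
        n_lam = len(self.wavelengths)
        slots = self.model.signature_layers
        sig = np.zeros((n_lam, len(slots)))
        err = np.zeros_like(sig)
        for i, lam in enumerate(self.wavelengths):
            rd = self.diastole[lam]
            for s, layer_idx in enumerate(slots):
                if not self.model.layers[layer_idx].pulsatile:
                    continue
                rs = self.systole[lam].get(s)
                if rs is None:
                    continue
                base = self.diastole_alt.get(lam, rd) if self._is_alt_slot(s) else rd
                sig[i, s] = (base.RdT - rs.RdT) / base.RdT
                err[i, s] = (
                    np.hypot(base.RdT_stderr, rs.RdT_stderr) / base.RdT
                )
        return SignatureSet(
            wavelengths=self.wavelengths,
            signatures=sig,
            stderr=err,
            condition=self.model.condition,
            slot_names=self.slot_names,
            p=self.p,
            n_photons=self.config.n_photons,
            seeds=[self.seeds[lam] for lam in self.wavelengths],
        )

    def ofp_signatures(self, n_eps: int | None = None, n_r0: int | None = None) -> np.ndarray:
        """Per-slot pulse amplitudes as seen by the ferrule-shielded probe."""
        from . import probe_transfer as pt

        n_eps = pt.N_EPSILON if n_eps is None else n_eps
        n_r0 = pt.N_R0 if n_r0 is None else n_r0
        slots = self.model.signature_layers
        sig = np.zeros((len(self.wavelengths), len(slots)))
        for i, lam in enumerate(self.wavelengths):
            rd = self.diastole[lam]
            for s, layer_idx in enumerate(slots):
                if not self.model.layers[layer_idx].pulsatile:
                    continue
                rs = self.systole[lam].get(s)
                if rs is None:
                    continue
                base = self.diastole_alt.get(lam, rd) if self._is_alt_slot(s) else rd
                sig[i, s] = pt.ofp_ppg(base, rs, n_eps, n_r0)
        return sig

    def _is_alt_slot(self, slot: int) -> bool:
        layers = self.model.signature_layers
        return layers.count(layers[slot]) > 1 and slot == len(layers) - 1

    def flux_profiles(self, lam: float):
        """Assemble the diastolic/perturbed flux profiles at one wavelength."""
        from .depth_metrics import FluxProfile
        from .mc_transport import flux_profile

        stack_d = build_optical_stack(self.model, lam, "diastole")
        rd = self.diastole[lam]
        zd, Fd = flux_profile(rd, stack_d)
        F_s = {}
        for s, layer_idx in enumerate(self.model.signature_layers):
            if not self.model.layers[layer_idx].pulsatile or self._is_alt_slot(s):
                continue
            rs = self.systole[lam].get(s)
            if rs is None:
                continue
            _, Fs = flux_profile(rs, stack_d)
            F_s[s] = Fs
        return FluxProfile(z=zd, F_d=Fd, F_s_by_slot=F_s,
                           T_s=self.model.total_thickness)


def simulate_condition(
    model: SkinModel,
    wavelengths=None,
    config: MCConfig | None = None,
    p: float | None = None,
    mechanism: str = "WD",
    only_slots=None,
) -> SimulationRun:
    """Run the diastole + per-slot systole transport set over a grid.

    One diastolic run per wavelength is shared by all slot perturbations at
    that wavelength (same seed: correlated sampling).  A duplicated layer
    slot (the compressed model's second subcutis entry) gets its own
    independently seeded diastole/systole pair.  ``only_slots`` restricts the
    systolic runs to a subset of signature slots (the others stay at 0).
    """
    wavelengths = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(
        wavelengths, float
    )
    config = config or MCConfig()
    p = model.p if p is None else p

    diastole: dict[float, MCResult] = {}
    diastole_alt: dict[float, MCResult] = {}
    systole: dict[float, dict[int, MCResult]] = {}
    seeds: dict[float, int] = {}
    slots = model.signature_layers
    has_alt = len(slots) != len(set(slots))

    for i, lam in enumerate(wavelengths):
        seed = config.seed + i * _LAM_SEED_STRIDE
        seeds[lam] = seed
        cfg = MCConfig(**{**config.__dict__, "seed": seed})
        stack_d = build_optical_stack(model, lam, "diastole")
        diastole[lam] = run_mc(stack_d, cfg, n_ambient_top=model.n_ambient_top)
        per_slot: dict[int, MCResult] = {}
        for s, layer_idx in enumerate(slots):
            if not model.layers[layer_idx].pulsatile:
                continue
            if only_slots is not None and s not in only_slots:
                continue
            alt = has_alt and slots.count(layer_idx) > 1 and s == len(slots) - 1
            run_seed = seed + _VIRTUAL_SEED_OFFSET if alt else seed
            scfg = MCConfig(**{**config.__dict__, "seed": run_seed})
            stack_s = build_optical_stack(
                model, lam, "systole", p=p, perturb_layer=layer_idx,
                mechanism=mechanism,
            )
            per_slot[s] = run_mc(stack_s, scfg, n_ambient_top=model.n_ambient_top)
            if alt and lam not in diastole_alt:
                diastole_alt[lam] = run_mc(
                    stack_d, scfg, n_ambient_top=model.n_ambient_top
                )
        systole[lam] = per_slot

    return SimulationRun(
        model=model,
        wavelengths=wavelengths,
        config=config,
        p=p,
        mechanism=mechanism,
        diastole=diastole,
        systole=systole,
        diastole_alt=diastole_alt,
        seeds=seeds,
    )


def layer_signature(
    model: SkinModel,
    layer_index: int,
    lam: float,
    p: float | None = None,
    config: MCConfig | None = None,
    mechanism: str = "WD",
) -> float:
    """Normalized pulse amplitude of a single layer at one wavelength.

    Non-pulsatile layers return exactly 0 (with a warning), as no
    perturbation is possible there.
    """
    config = config or MCConfig()
    p = model.p if p is None else p
    layer = model.layers[layer_index]
    if not layer.pulsatile:
        warnings.warn(f"layer {layer.name!r} is not pulsatile; signature is 0")
        return 0.0
    stack_d = build_optical_stack(model, lam, "diastole")
    stack_s = build_optical_stack(
        model, lam, "systole", p=p, perturb_layer=layer_index, mechanism=mechanism
    )
    rd = run_mc(stack_d, config, n_ambient_top=model.n_ambient_top)
    rs = run_mc(stack_s, config, n_ambient_top=model.n_ambient_top)
    return (rd.RdT - rs.RdT) / rd.RdT


def mix_signatures(sigset: SignatureSet, weights=None) -> PPGSpectrum:
    """Linear mixture of layer signatures into one PPG-amplitude spectrum.

    ``scaled`` divides the mixture by its value at (the grid point nearest)
    660 nm, the red-minimum reference used for spectrum comparisons.
    """
    weights = np.asarray(weights, float) if weights is not None else None
    if weights is None:
        raise TypeError("weights are required; pass model.weights for the defaults")
    if len(weights) != sigset.signatures.shape[1]:
        raise ValueError("weights length must match the number of signature slots")
    if not np.any(weights):
        raise ValueError("at least one mixing weight must be non-zero")
    acdc = sigset.signatures @ weights
    iref = int(np.argmin(np.abs(sigset.wavelengths - SCALE_NM)))
    if acdc[iref] == 0:
        raise ZeroDivisionError(
            f"mixed amplitude is 0 at the {sigset.wavelengths[iref]} nm scaling point"
        )
    return PPGSpectrum(
        wavelengths=sigset.wavelengths,
        acdc=acdc,
        scaled=acdc / acdc[iref],
        weights=weights,
        scale_wavelength=float(sigset.wavelengths[iref]),
    )


class BandRatios(NamedTuple):
    GoR: float
    IRoR: float


def band_ratios(spectrum: PPGSpectrum) -> BandRatios:
    """Green-over-red and IR-over-red band-mean amplitude ratios."""
    means = {}
    for name, (lo, hi) in BANDS.items():
        mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
        if not np.any(mask):
            raise ValueError(
                f"wavelength grid has no points in the {name} band [{lo}, {hi}] nm"
            )
        means[name] = float(spectrum.acdc[mask].mean())
    return BandRatios(GoR=means["green"] / means["red"],
                      IRoR=means["ir"] / means["red"])


def simulation_precision(
    model: SkinModel,
    config: MCConfig,
    n_repeats: int,
    wavelengths=None,
    weights=None,
    lam_range: tuple[float, float] = (475.0, 1000.0),
    seed_stride: int = 15485863,
) -> float:
    """Mean coefficient of variation of the mixed spectrum across repeats.

    Repeats differ only in their seed (``seed_stride`` apart; a stride of 0
    makes all repeats identical and the CV exactly 0); the CV is computed per
    wavelength over ``n_repeats`` mixed AC/DC values and averaged over
    ``lam_range``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    weights = model.weights if weights is None else np.asarray(weights, float)
    wavelengths = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(
        wavelengths, float
    )
    only = [i for i, w in enumerate(weights) if w != 0]
    spectra = []
    for rep in range(n_repeats):
        cfg = MCConfig(**{**config.__dict__, "seed": config.seed + rep * seed_stride})
        run = simulate_condition(model, wavelengths, cfg, only_slots=only)
        spectra.append(mix_signatures(run.signatures(), weights).acdc)
    arr = np.array(spectra)  # (repeats, n_lam)
    mask = (wavelengths >= lam_range[0]) & (wavelengths <= lam_range[1])
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1)
    cv = np.where(mean != 0, std / np.abs(mean), 0.0)
    return float(cv[mask].mean())
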