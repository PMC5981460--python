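"""Per-layer optical coefficients for diastole and systole.

Converts a physiological layer description (blood/water/fat fractions, vessel
diameter, arteriovenous split, oxygen saturations) into absorption and
scattering coefficients at a given wavelength, for the diastolic baseline and
for a systolic state in which the arterial compartment is incremented by a
fractional pulse ``p``.

Two systole mechanisms are available:

* layer expansion (LE, the default): the added blood expands the layer
  thickness slightly and all concentrations are renormalized by the expansion
  factor ``E = d / d_s``;
* water displacement (WD): the added blood displaces an equal volume of
  water, the layer thickness is unchanged.

Blood confined to discrete vessels absorbs less than a homogeneous
equivalent; this self-shielding (pigment packaging) is corrected with an
empirical decaying function of the product of whole-blood absorption and
vessel diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .chromophores import (
    SpectralTable,
    absorption_at,
    dermal_baseline,
    epidermal_baseline,
    load_default_table,
)

__all__ = [
    "LayerPhysiology",
    "LayerOptics",
    "self_shield",
    "mu_a_epidermis",
    "mu_a_nonblood",
    "blood_fractions_diastole",
    "mu_a_diastole",
    "systolic_state",
    "systolic_state_wd",
    "scattering",
    "SCATTER_TARGETS",
    "SCATTER_NORM_NM",
    "ANISOTROPY",
]

#: reduced scattering targets (cm^-1) per layer class at the normalization wavelength
SCATTER_TARGETS = {"EPI": 15.0, "dermal": 20.0, "SC": 10.0}
#: wavelength (nm) at which mus' is pinned to its class target, in both exponent bands
SCATTER_NORM_NM = 580.0
#: Henyey-Greenstein anisotropy assumed for all tissue
ANISOTROPY = 0.9


@dataclass
class LayerPhysiology:
    """Physiological description of one skin layer.

    Thickness ``d`` in cm, vessel diameter ``vd`` in micrometers; all
    fractions dimensionless in [0, 1].  ``gamma`` scales the baseline
    (bloodless-tissue) absorption; ``scatter_class`` selects the reduced
    scattering target (EPI / dermal / SC).
    """

    name: str
    n: float
    d: float
    Cb: float
    Cw: float
    vd: float
    Cf: float = 0.0
    ra: float = 0.5
    rv: float = 0.5
    SpO2: float = 0.97
    SvO2: float = 0.67
    gamma: float = 0.5
    pulsatile: bool = False
    scatter_class: str = "dermal"
    is_epidermis: bool = False

    def __post_init__(self) -> None:
        for f in ("Cb", "Cw", "Cf", "ra", "rv", "SpO2", "SvO2"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {f}={v} outside [0, 1]")
        if self.d <= 0:
            raise ValueError(f"{self.name}: thickness must be > 0")
        if self.n < 1:
            raise ValueError(f"{self.name}: refractive index must be >= 1")
        if self.vd < 0:
            raise ValueError(f"{self.name}: vessel diameter must be >= 0")
        if self.Cb > 0 and abs(self.ra + self.rv - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: ra + rv must equal 1 for vascular layers")
        if self.scatter_class not in SCATTER_TARGETS:
            raise ValueError(f"{self.name}: unknown scatter class {self.scatter_class!r}")


@dataclass(frozen=True)
class LayerOptics:
    """Transport-ready optics of one layer: mua, mus (cm^-1), g, n, d (cm)."""

    mua: float
    mus: float
    g: float
    n: float
    d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mua) and self.mua >= 0):
            raise ValueError("mua must be finite and >= 0")
        if not (np.isfinite(self.mus) and self.mus > 0):
            raise ValueError("mus must be finite and > 0")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.d <= 0:
            raise ValueError("thickness must be > 0")


def self_shield(mua_blood: float, vd_um: float) -> float:
    """Self-shielding (pigment packaging) correction factor, dimensionless.

    ``1 / (1 + 1.007 * (mua * vd / 2)**1.228)`` with the vessel diameter
    converted to cm; equals 1 for a vanishing product (no shielding).
    """
    if mua_blood < 0 or vd_um < 0:
        raise ValueError("mua_blood and vd must be >= 0")
    x = mua_blood * (vd_um * 1e-4)  # vd um -> cm
    if x == 0.0:
        return 1.0
    return 1.0 / (1.0 + 1.007 * (x / 2.0) ** 1.228)


def _blood_mua(table: SpectralTable, lam: float, sat: float) -> float:
    """Whole-blood absorption at oxygen saturation ``sat``."""
    return (1.0 - sat) * absorption_at(table, "Hb", lam) + sat * absorption_at(
        table, "HbO2", lam
    )


def mu_a_epidermis(lam: float, Cw: float, table: SpectralTable | None = None) -> float:
    """Epidermal absorption: water plus connective-tissue baseline (gamma=0.5)."""
    if not 0.0 <= Cw <= 1.0:
        raise ValueError("Cw outside [0, 1]")
    table = table or load_default_table()
    return Cw * absorption_at(table, "water", lam) + (1.0 - Cw) * epidermal_baseline(
        lam, 0.5
    )


def mu_a_nonblood(
    lam: float, Cw: float, Cf: float, gamma: float, table: SpectralTable | None = None
) -> float:
    """Non-blood tissue absorption of a dermal/subcutis layer, cm^-1."""
    if not (0.0 <= Cw <= 1.0 and 0.0 <= Cf <= 1.0):
        raise ValueError("Cw, Cf outside [0, 1]")
    table = table or load_default_table()
    base = dermal_baseline(lam, gamma, Cw) if Cw > 0 else 0.0
    return (
        Cf * absorption_at(table, "fat", lam)
        + (1.0 - Cf) * Cw * absorption_at(table, "water", lam)
        + (1.0 - Cf) * (1.0 - Cw) * base
    )


class DiastolicBlood(NamedTuple):
    fa: float
    fv: float
    Cb_apparent: float


def blood_fractions_diastole(
    layer: LayerPhysiology, lam: float, table: SpectralTable | None = None
) -> DiastolicBlood:
    """Apparent (self-shielded) arterial/venous blood fractions at diastole."""
    table = table or load_default_table()
    if layer.Cb == 0.0:
        return DiastolicBlood(0.0, 0.0, 0.0)
    fa = layer.ra * layer.Cb * self_shield(_blood_mua(table, lam, layer.SpO2), layer.vd)
    fv = layer.rv * layer.Cb * self_shield(_blood_mua(table, lam, layer.SvO2), layer.vd)
    return DiastolicBlood(fa, fv, fa + fv)


def mu_a_diastole(
    layer: LayerPhysiology, lam: float, table: SpectralTable | None = None
) -> float:
    """Total diastolic absorption of a dermal/subcutis layer, cm^-1."""
    table = table or load_default_table()
    fa, fv, cb_app = blood_fractions_diastole(layer, lam, table)
    mua_nb = mu_a_nonblood(lam, layer.Cw, layer.Cf, layer.gamma, table)
    return (
        fa * _blood_mua(table, lam, layer.SpO2)
        + fv * _blood_mua(table, lam, layer.SvO2)
        + cb_app * absorption_at(table, "water", lam)
        + (1.0 - layer.Cb) * mua_nb
    )


class SystolicState(NamedTuple):
    fa_s: float
    Cb_s: float
    E: float
    d_s: float
    mua_s: float


def systolic_state(
    layer: LayerPhysiology,
    lam: float,
    p: float,
    table: SpectralTable | None = None,
) -> SystolicState:
    """Systolic layer state under the layer-expansion (LE) mechanism.

    The arterial compartment gains a fraction ``p`` of its diastolic apparent
    volume (``fa_s = fa_d * (1 + p)``); the layer expands to accommodate it
    (``d_s = d * (1 + Cb_s * p)``) and the absorption bracket is renormalized
    by ``E = d / d_s``.  Non-pulsatile layers are returned unperturbed.
    """
    if p < 0:
        raise ValueError("pulsatile increment p must be >= 0")
    table = table or load_default_table()
    if not layer.pulsatile:
        p = 0.0
    fa, fv, cb_app = blood_fractions_diastole(layer, lam, table)
    mua_art = _blood_mua(table, lam, layer.SpO2)
    mua_ven = _blood_mua(table, lam, layer.SvO2)
    mua_nb = mu_a_nonblood(lam, layer.Cw, layer.Cf, layer.gamma, table)
    fa_s = fa * (1.0 + p)
    cb_s = cb_app + p * fa
    d_s = layer.d * (1.0 + cb_s * p)
    E = layer.d / d_s
    # non-blood volume shrinks by the *added* blood only; using the apparent
    # systolic fraction here would break the mua_s == mua_d identity at p = 0
    # because self-shielding makes the apparent fraction smaller than Cb
    cb_actual_s = layer.Cb + p * fa
    mua_s = E * (
        fa_s * mua_art
        + fv * mua_ven
        + cb_s * absorption_at(table, "water", lam)
        + (1.0 - cb_actual_s) * mua_nb
    )
    return SystolicState(fa_s, cb_s, E, d_s, mua_s)


def systolic_state_wd(
    layer: LayerPhysiology,
    lam: float,
    p: float,
    table: SpectralTable | None = None,
) -> float:
    """Systolic absorption under the water-displacement (WD) mechanism.

    The incremental arterial blood replaces an equal volume fraction of
    water, so the plasma-water term stays at its diastolic value and the
    layer thickness is unchanged (E = 1).  Returns mua_s in cm^-1.
    """
    if p < 0:
        raise ValueError("pulsatile increment p must be >= 0")
    table = table or load_default_table()
    if not layer.pulsatile:
        p = 0.0
    fa, fv, cb_app = blood_fractions_diastole(layer, lam, table)
    mua_art = _blood_mua(table, lam, layer.SpO2)
    mua_ven = _blood_mua(table, lam, layer.SvO2)
    mua_nb = mu_a_nonblood(lam, layer.Cw, layer.Cf, layer.gamma, table)
    fa_s = fa * (1.0 + p)
    return (
        fa_s * mua_art
        + fv * mua_ven
        + cb_app * absorption_at(table, "water", lam)
        + (1.0 - (layer.Cb + p * fa)) * mua_nb
    )


def scattering(lam: float, layer_class: str) -> tuple[float, float]:
    """Scattering coefficient mus (cm^-1) and anisotropy g for a layer class.

    Reduced scattering follows ``mus' = c0 * lam**-b`` with exponent
    ``b = 0.1`` below 580 nm and ``0.05`` above; ``c0`` is calibrated per
    band so mus' equals the class target exactly at 580 nm, which also makes
    the two bands continuous there.
    """
    if not 450.0 <= lam <= 1000.0:
        raise ValueError("wavelength outside [450, 1000] nm")
    try:
        target = SCATTER_TARGETS[layer_class]
    except KeyError:
        raise ValueError(f"unknown layer class {layer_class!r}") from None
    b = 0.1 if lam < SCATTER_NORM_NM else 0.05
    mus_prime = target * (lam / SCATTER_NORM_NM) ** (-b)
    return mus_prime / (1.0 - ANISOTROPY), ANISOTROPY
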