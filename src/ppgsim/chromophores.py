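"""Bundled chromophore absorption spectra and baseline tissue absorption.

The package ships whole-blood oxy/deoxy-hemoglobin absorption (at the standard
150 g Hb/L whole-blood convention), water and lipid absorption on a 5 nm grid
covering 450-1000 nm.  Layer absorption models combine these with closed-form
baseline ("background tissue") absorption terms for the epidermis and for
dermal/subcutaneous tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SpectralTable",
    "load_default_table",
    "absorption_at",
    "epidermal_baseline",
    "dermal_baseline",
    "CHROMOPHORES",
]

#: chromophore names accepted by :func:`absorption_at`
CHROMOPHORES = ("HbO2", "Hb", "water", "fat")

_COLUMN = {
    "HbO2": "mua_hbo2_cm1",
    "Hb": "mua_hb_cm1",
    "water": "mua_water_cm1",
    "fat": "mua_fat_cm1",
}


@dataclass(frozen=True)
class SpectralTable:
    """Absorption spectra of the four bundled chromophores.

    All coefficients are in cm^-1; blood columns are whole-blood values at a
    stated reference hemoglobin concentration (bundled table: 150 g/L).
    """

    wavelengths_nm: np.ndarray
    mua_HbO2: np.ndarray
    mua_Hb: np.ndarray
    mua_water: np.ndarray
    mua_fat: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, float)
        if w.ndim != 1 or len(w) < 2:
            raise ValueError("wavelength grid must be a 1-D array of >=2 points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in CHROMOPHORES:
            col = np.asarray(getattr(self, f"mua_{name}" if name != "HbO2" else "mua_HbO2"), float)
            if col.shape != w.shape:
                raise ValueError(f"column for {name} does not match the grid shape")
            if not np.all(np.isfinite(col)) or np.any(col < 0):
                raise ValueError(f"absorption values for {name} must be finite and >= 0")

    @property
    def lam_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def lam_max(self) -> float:
        return float(self.wavelengths_nm[-1])

    def column(self, chromophore: str) -> np.ndarray:
        if chromophore not in _COLUMN:
            raise KeyError(
                f"unknown chromophore {chromophore!r}; expected one of {CHROMOPHORES}"
            )
        attr = {"HbO2": "mua_HbO2", "Hb": "mua_Hb", "water": "mua_water", "fat": "mua_fat"}
        return getattr(self, attr[chromophore])


_DEFAULT: SpectralTable | None = None


def load_default_table() -> SpectralTable:
    """Load (and cache) the bundled chromophore table."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.files("ppgsim.data").joinpath("chromophores.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        _DEFAULT = SpectralTable(
            wavelengths_nm=df["wavelength_nm"].to_numpy(float),
            mua_HbO2=df["mua_hbo2_cm1"].to_numpy(float),
            mua_Hb=df["mua_hb_cm1"].to_numpy(float),
            mua_water=df["mua_water_cm1"].to_numpy(float),
            mua_fat=df["mua_fat_cm1"].to_numpy(float),
            provenance={
                "blood": "whole blood, 150 g Hb/L, standard molar-extinction compilation",
                "water": "Pope/Fry + Hale/Querry anchors",
                "fat": "van Veen-style lipid anchors",
            },
        )
    return _DEFAULT


def absorption_at(table: SpectralTable, chromophore: str, lam) -> float | np.ndarray:
    """Linearly interpolated absorption coefficient (cm^-1) at wavelength(s) ``lam``.

    Exact at grid nodes; raises for wavelengths outside the tabulated range or
    for an unknown chromophore name.
    """
    col = table.column(chromophore)
    lam_arr = np.asarray(lam, float)
    if np.any(lam_arr < table.lam_min) or np.any(lam_arr > table.lam_max):
        raise ValueError(
            f"wavelength {lam} nm outside tabulated range "
            f"[{table.lam_min}, {table.lam_max}] nm"
        )
    out = np.interp(lam_arr, table.wavelengths_nm, col)
    return float(out) if np.isscalar(lam) or lam_arr.ndim == 0 else out


def epidermal_baseline(lam, gamma: float) -> float | np.ndarray:
    """Baseline (connective-tissue) absorption of the epidermis, cm^-1.

    ``gamma * [0.244 + 85.3 * exp(-(lam - 154) / 66.2)]`` with ``lam`` in nm;
    gamma rescales ex-vivo baseline measurements toward in-vivo hydration.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    lam = np.asarray(lam, float) if not np.isscalar(lam) else float(lam)
    return gamma * (0.244 + 85.3 * np.exp(-(lam - 154.0) / 66.2))


def dermal_baseline(lam, gamma: float, Cw: float, Cw0: float = 0.65) -> float | np.ndarray:
    """Baseline absorption of dermis/subcutis, cm^-1, scaled by water content.

    ``gamma * (Cw / Cw0) * [0.244 + 16.82 * exp(-(lam - 400) / 80.5)]``; the
    reference water fraction ``Cw0 = 0.65`` is the hydration at which the
    underlying ex-vivo baseline was measured.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if Cw <= 0:
        raise ValueError("water fraction Cw must be > 0")
    lam = np.asarray(lam, float) if not np.isscalar(lam) else float(lam)
    return gamma * (Cw / Cw0) * (0.244 + 16.82 * np.exp(-(lam - 400.0) / 80.5))
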