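"""Fiber-probe (OFP) observables and the probe-to-remote transfer function.

A contact fiber probe shielded by a ferrule rejects the shortest-path photons
returning near the source.  Its reading is modelled by clipping the radial
diffuse-reflectance profile: the cumulative reflectance from radial bin
``n_r0`` outward, renormalized by a near-origin correction factor so the
clipped and total reflectances share a scale.  The transfer function
TF = PPG_remote / PPG_probe converts probe-measured pulse-amplitude spectra
into remote-equivalent ones; TF < 1 where the probe geometry boosts the
apparent amplitude (mostly below 600 nm).

The default clipping index n_r0 = 278 on the 0.0005 cm grid corresponds to
1.39 mm, close to (but not exactly) the 1.59 mm ferrule shielding radius the
probe geometry suggests; the index is used as specified rather than
re-derived from the ferrule dimension.
"""

from __future__ import annotations

import numpy as np

from .mc_transport import MCResult

__all__ = ["cumulative_radial", "ofp_ppg", "transfer_function", "N_EPSILON", "N_R0"]

#: near-origin index used for the scale-correction factor
N_EPSILON = 10
#: radial clipping index of the ferrule-shielded probe
N_R0 = 278


def cumulative_radial(result: MCResult, i: int) -> float:
    """Cumulative diffuse reflectance from radial bin ``i`` outward.

    Bin weights (escaping fraction per annulus) are summed from ``i`` through
    the last bin; the out-of-grid overflow weight counts as the last bin, so
    ``cumulative_radial(res, 0)`` equals ``RdT`` exactly.
    """
    nr = len(result.Rd_r_weight)
    if not 0 <= i <= nr:
        raise IndexError(f"radial index {i} outside [0, {nr}]")
    return float(result.Rd_r_weight[i:].sum() + result.Rd_overflow)


def ofp_ppg(
    result_d: MCResult,
    result_s: MCResult,
    n_eps: int = N_EPSILON,
    n_r0: int = N_R0,
) -> float:
    """Pulse amplitude as seen by the ferrule-shielded fiber probe.

    Each state's clipped cumulative reflectance uDR(n_r0) is rescaled by
    C = RdT / uDR(n_eps); the amplitude is the normalized diastole-systole
    difference of the rescaled readings.  With ``n_r0 == n_eps`` the
    correction cancels exactly and the probe amplitude equals the remote one.
    """
    readings = []
    for res in (result_d, result_s):
        u_eps = cumulative_radial(res, n_eps)
        if u_eps == 0.0:
            raise ZeroDivisionError(
                "cumulative reflectance at the correction index is zero"
            )
        c = res.RdT / u_eps
        readings.append(c * cumulative_radial(res, n_r0))
    dr_d, dr_s = readings
    if dr_d == 0.0:
        raise ZeroDivisionError("diastolic probe reading is zero")
    return (dr_d - dr_s) / dr_d


def transfer_function(
    signatures_rem: np.ndarray,
    signatures_ofp: np.ndarray,
    weights,
) -> np.ndarray:
    """Pointwise TF(lambda) = mixed remote / mixed probe amplitude.

    Inputs are (n_lam, n_slots) signature arrays on the same grid with the
    same slot order.  Wavelengths where the mixed probe amplitude is zero
    yield NaN (flagged missing, excluded from band statistics) rather than an
    error.
    """
    rem = np.asarray(signatures_rem, float)
    ofp = np.asarray(signatures_ofp, float)
    if rem.shape != ofp.shape:
        raise ValueError("remote and probe signature arrays must share a shape")
    weights = np.asarray(weights, float)
    num = rem @ weights
    den = ofp @ weights
    with np.errstate(divide="ignore", invalid="ignore"):
        tf = np.where(den != 0.0, num / den, np.nan)
    return tf
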