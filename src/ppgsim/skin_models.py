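"""Reference and compressed finger-pad skin models.

The reference (resting) model stacks six layers: epidermis (EPI), capillary
loops (CL), upper plexus (UP), reticular dermis (RD), deep plexus (DP) and
subcutis (SC).  The compressed model mimics firm pressure on the pad: five
layers (RD and DP merge), strongly reduced dermal blood and water, venous
blood expelled from the dermis (ra:rv = 1:0) and partial pooling at the
subcutis (0.75:0.25).

Signature mixing weights: the per-layer PPG contributions are combined with
six weights per condition.  For the compressed five-layer stack the six
weights map onto six signature *slots* where slots 5 and 6 both address the
subcutis: slot 6 ("SC & digital artery") is a second, independently seeded
perturbation run of the SC layer.  ``SkinModel.signature_layers`` records the
slot -> layer mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .layer_optics import LayerOptics, LayerPhysiology, scattering
from .layer_optics import mu_a_diastole, mu_a_epidermis, systolic_state, systolic_state_wd

__all__ = [
    "SkinModel",
    "reference_model",
    "compressed_model",
    "build_optical_stack",
    "load_model",
    "save_model",
    "DEFAULT_PULSE_FRACTION",
]

#: default fractional systolic increase of apparent arterial blood per pulsating layer
DEFAULT_PULSE_FRACTION = 0.05


@dataclass
class SkinModel:
    """Ordered layer stack (surface -> depth) for one measurement condition."""

    condition: str
    layers: list[LayerPhysiology]
    weights: np.ndarray
    signature_layers: list[int]
    n_ambient_top: float = 1.0
    p: float = DEFAULT_PULSE_FRACTION

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.signature_layers):
            raise ValueError("weights and signature_layers must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("mixing weights must be >= 0")
        for idx in self.signature_layers:
            if not 0 <= idx < len(self.layers):
                raise ValueError(f"signature slot maps to invalid layer index {idx}")
        n_prev = 0.0
        for layer in self.layers:
            if layer.n < n_prev - 1e-12:
                raise ValueError("refractive index must be non-decreasing with depth")
            n_prev = layer.n

    @property
    def total_thickness(self) -> float:
        return float(sum(layer.d for layer in self.layers))

    @property
    def pulsatile_indices(self) -> list[int]:
        return [i for i, layer in enumerate(self.layers) if layer.pulsatile]


def reference_model() -> SkinModel:
    """Six-layer resting finger-pad skin model."""
    mk = _make_layer
    layers = [
        mk("EPI", 1.33, 0.080, 0.0, 0.20, 0.0),
        mk("CL", 1.37, 0.015, 0.004, 0.65, 10.0),
        mk("UP", 1.40, 0.008, 0.020, 0.65, 20.0),
        mk("RD", 1.40, 0.120, 0.004, 0.65, 20.0),
        mk("DP", 1.40, 0.050, 0.040, 0.65, 40.0),
        mk("SC", 1.44, 0.500, 0.030, 0.05, 50.0, Cf=0.40, gamma=0.25,
           scatter_class="SC"),
    ]
    weights = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 1.0]) / 3.0
    return SkinModel(
        condition="reference",
        layers=layers,
        weights=weights,
        signature_layers=[0, 1, 2, 3, 4, 5],
    )


def compressed_model() -> SkinModel:
    """Five-layer compressed finger-pad skin model (RD and DP merged)."""
    mk = _make_layer
    layers = [
        mk("EPI", 1.33, 0.080, 0.0, 0.05, 0.0),
        mk("CL", 1.37, 0.008, 0.0012, 0.15, 10.0, ra=1.0, rv=0.0),
        mk("UP", 1.40, 0.004, 0.0024, 0.15, 20.0, ra=1.0, rv=0.0),
        mk("RD&DP", 1.40, 0.100, 0.024, 0.15, 20.0, ra=1.0, rv=0.0),
        mk("SC", 1.44, 0.200, 0.036, 0.35, 40.0, Cf=0.40, gamma=0.25,
           ra=0.75, rv=0.25, scatter_class="SC"),
    ]
    # six signature slots over five layers: slots 5 and 6 both perturb the SC
    weights = np.array([0.0, 0.0, 0.0, 2.0, 18.0, 1.0]) / 3.0
    return SkinModel(
        condition="compressed",
        layers=layers,
        weights=weights,
        signature_layers=[0, 1, 2, 3, 4, 4],
    )


def _make_layer(
    name, n, d, Cb, Cw, vd, Cf=0.0, gamma=0.5, ra=0.5, rv=0.5, scatter_class=None
) -> LayerPhysiology:
    epi = name == "EPI"
    if scatter_class is None:
        scatter_class = "EPI" if epi else "dermal"
    return LayerPhysiology(
        name=name,
        n=n,
        d=d,
        Cb=Cb,
        Cw=Cw,
        vd=vd,
        Cf=Cf,
        ra=ra if Cb > 0 else 0.5,
        rv=rv if Cb > 0 else 0.5,
        SpO2=0.97,
        SvO2=0.67,
        gamma=gamma,
        pulsatile=Cb > 0,
        scatter_class=scatter_class,
        is_epidermis=epi,
    )


def build_optical_stack(
    model: SkinModel,
    lam: float,
    state: str = "diastole",
    p: float | None = None,
    perturb_layer: int | None = None,
    mechanism: str = "LE",
) -> list[LayerOptics]:
    """Derive the transport-ready optics of every layer at wavelength ``lam``.

    ``state='systole'`` perturbs pulsatile layers (all of them, or the single
    ``perturb_layer`` index for per-layer signature runs) with the pulse
    fraction ``p``; mechanism is layer expansion ('LE') or water displacement
    ('WD').
    """
    if state not in ("diastole", "systole"):
        raise ValueError("state must be 'diastole' or 'systole'")
    if mechanism not in ("LE", "WD"):
        raise ValueError("mechanism must be 'LE' or 'WD'")
    p = model.p if p is None else p
    stack: list[LayerOptics] = []
    for i, layer in enumerate(model.layers):
        try:
            mus, g = scattering(lam, layer.scatter_class)
            d = layer.d
            if layer.is_epidermis:
                mua = mu_a_epidermis(lam, layer.Cw)
            else:
                perturb = (
                    state == "systole"
                    and layer.pulsatile
                    and (perturb_layer is None or perturb_layer == i)
                )
                if perturb:
                    if mechanism == "LE":
                        st = systolic_state(layer, lam, p)
                        mua, d = st.mua_s, st.d_s
                    else:
                        mua = systolic_state_wd(layer, lam, p)
                else:
                    mua = mu_a_diastole(layer, lam)
            stack.append(LayerOptics(mua=mua, mus=mus, g=g, n=layer.n, d=d))
        except Exception as exc:
            raise type(exc)(f"layer {layer.name!r}: {exc}") from exc
    return stack


# ---------------------------------------------------------------------------
# config file round trip

_LAYER_KEYS = (
    "n", "d", "Cb", "Cw", "Cf", "vd", "ra", "rv", "SpO2", "SvO2",
    "gamma", "pulsatile", "scatter_class", "is_epidermis",
)


def save_model(model: SkinModel, path: str | Path) -> None:
    """Serialize a skin model to a human-editable YAML config."""
    doc = {
        "condition": model.condition,
        "n_ambient_top": model.n_ambient_top,
        "p": model.p,
        "weights": [float(w) for w in model.weights],
        "signature_layers": list(model.signature_layers),
        "layers": [
            {"name": layer.name, **{k: getattr(layer, k) for k in _LAYER_KEYS}}
            for layer in model.layers
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(source: str | Path) -> SkinModel:
    """Load a skin model from a YAML config, or by name.

    ``source`` may be ``'reference'``, ``'compressed'`` or a path to a config
    file written by :func:`save_model`.
    """
    if source == "reference":
        return reference_model()
    if source == "compressed":
        return compressed_model()
    doc = yaml.safe_load(Path(source).read_text())
    layers = [LayerPhysiology(name=spec["name"], **{k: spec[k] for k in _LAYER_KEYS})
              for spec in doc["layers"]]
    return SkinModel(
        condition=doc["condition"],
        layers=layers,
        weights=np.asarray(doc["weights"], float),
        signature_layers=list(doc["signature_layers"]),
        n_ambient_top=float(doc.get("n_ambient_top", 1.0)),
        p=float(doc.get("p", DEFAULT_PULSE_FRACTION)),
    )


def bundled_config_path(condition: str) -> Path:
    """Path of a bundled model config ('reference' or 'compressed')."""
    if condition not in ("reference", "compressed"):
        raise ValueError("condition must be 'reference' or 'compressed'")
    return Path(str(resources.files("ppgsim.data").joinpath(f"{condition}.cfg")))
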