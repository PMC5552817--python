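"""Pixel-wise quality prediction maps.

A fitted calibration model is applied to every fruit pixel of a calibrated
hypercube: a reduced image is first formed at the model's effective
wavelengths, then the model runs on each masked pixel's spectrum, producing a
spatial distribution map of firmness or SSC.  pH maps are excluded by
default — pH characterizes the whole fruit and a per-pixel pH is not
physically meaningful — but can be forced.

The two published SPA-MLR mapping equations for kiwifruit (firmness from 7
effective wavelengths, SSC from 14) ship as versioned coefficient fixtures,
stored exactly as printed (7 significant figures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np

from .chemometrics import RegressionModel, predict
from .envi import Hypercube, band_index
from .segmentation import Mask

__all__ = [
    "PredictionMap",
    "pixelwise_predict",
    "eq1_firmness",
    "eq2_ssc",
    "EQ1_FIRMNESS",
    "EQ2_SSC",
    "reference_model",
    "render_map",
]

# Published SPA-MLR mapping equations (reference fixtures, version 1).
# Each: (intercept, ((wavelength_nm, coefficient), ...)).
EQ1_FIRMNESS = (
    -743.0095,
    (
        (555.0, 5806.358),
        (1000.0, 3465.474),
        (638.0, -3800.496),
        (503.0, -8457.285),
        (452.0, 2374.435),
        (700.0, -425.6517),
        (822.0, -110.9676),
    ),
)

EQ2_SSC = (
    21.5258,
    (
        (987.0, -1299.308),
        (960.0, 1163.962),
        (487.0, -870.8445),
        (496.0, 767.1981),
        (737.0, -173.2891),
        (814.0, 209.0592),
        (450.0, 732.1533),
        (945.0, 340.0846),
        (912.0, -299.165),
        (643.0, -60.82231),
        (558.0, 55.44099),
        (522.0, -47.22904),
        (451.0, -502.9426),
        (692.0, 50.60174),
    ),
)


def _eval_equation(eq, reflectances, name: str) -> float:
    intercept, terms = eq
    x = np.asarray(reflectances, dtype=float).ravel()
    if len(x) != len(terms):
        raise ValueError(f"{name} expects {len(terms)} reflectance values, got {len(x)}")
    if np.any((x < -0.1) | (x > 1.5)):
        raise ValueError(f"{name}: reflectance outside plausible range [-0.1, 1.5]")
    return float(intercept + sum(c * xi for (_, c), xi in zip(terms, x)))


def eq1_firmness(reflectances) -> float:
    """Firmness (N cm^-2) from reflectance at 555, 1000, 638, 503, 452, 700,
    822 nm via the published SPA-MLR equation."""
    return _eval_equation(EQ1_FIRMNESS, reflectances, "eq1_firmness")


def eq2_ssc(reflectances) -> float:
    """SSC (deg Brix) from reflectance at the 14 published effective
    wavelengths (987, 960, 487, ... nm) via the published SPA-MLR equation."""
    return _eval_equation(EQ2_SSC, reflectances, "eq2_ssc")


def reference_model(which: str) -> RegressionModel:
    """The published mapping equation wrapped as an MLR :class:`RegressionModel`
    (``which`` in {'eq1', 'firmness', 'eq2', 'ssc'}), usable anywhere a fitted
    model is."""
    if which in ("eq1", "firmness"):
        eq, attr = EQ1_FIRMNESS, "firmness"
    elif which in ("eq2", "ssc"):
        eq, attr = EQ2_SSC, "ssc"
    else:
        raise ValueError("which must be 'eq1'/'firmness' or 'eq2'/'ssc'")
    intercept, terms = eq
    return RegressionModel(
        family="MLR",
        wavelengths=np.array([t[0] for t in terms]),
        attribute=attr,
        intercept=intercept,
        coefficients=np.array([t[1] for t in terms]),
    )


@dataclass
class PredictionMap:
    """2-D image of a predicted attribute over the fruit mask.

    ``values`` is NaN on background.  Values are *not* clipped: sensor noise
    can push per-pixel predictions outside the calibration range, and the map
    records that honestly — ``out_of_range_fraction`` reports how many fruit
    pixels fall outside ``display_range``; clipping happens only at render
    time.
    """

    values: np.ndarray
    mask: Mask
    attribute: str
    model_id: str
    display_range: tuple[float, float]
    out_of_range_fraction: float = 0.0
    metadata: dict = field(default_factory=dict)

    def fruit_values(self) -> np.ndarray:
        return self.values[self.mask.data == 1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "attribute": self.attribute,
                    "model_id": self.model_id,
                    "display_range": list(self.display_range),
                    "out_of_range_fraction": self.out_of_range_fraction,
                    **self.metadata,
                },
                indent=2,
            )
        )


def pixelwise_predict(
    cube: Hypercube,
    mask: Mask,
    model: RegressionModel,
    display_range: tuple[float, float] | None = None,
    allow_ph: bool = False,
) -> PredictionMap:
    """Apply ``model`` to every masked pixel of a reflectance cube.

    A reduced image is formed at the model's wavelengths (nearest-band rule
    with the half-spacing tolerance), then the model predicts each fruit
    pixel.  ``display_range`` defaults to the min/max of the predicted fruit
    pixels when not given (pass the calibration-set y range for
    cross-comparable maps).
    """
    if model.attribute == "ph" and not allow_ph:
        raise ValueError(
            "per-pixel pH maps are disabled by default (whole-fruit attribute); "
            "pass allow_ph=True to force"
        )
    if mask.data.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    # one full spacing of slack: named EWs can sit just past a trim boundary
    bands = [band_index(cube.wavelengths, nm, tol_factor=1.0) for nm in model.wavelengths]
    reduced = cube.data[:, :, bands]
    m = mask.data == 1
    if not m.any():
        raise ValueError("empty mask")
    values = np.full(mask.data.shape, np.nan)
    values[m] = predict(model, reduced[m])
    fruit = values[m]
    if display_range is None:
        display_range = (float(fruit.min()), float(fruit.max()))
    lo, hi = display_range
    oor = float(np.mean((fruit < lo) | (fruit > hi)))
    return PredictionMap(
        values=values,
        mask=mask,
        attribute=model.attribute,
        model_id=model.family,
        display_range=(lo, hi),
        out_of_range_fraction=oor,
    )


def render_map(pmap: PredictionMap, out_path: str | Path, colormap: str = "jet") -> Path:
    """Render a PNG with a color bar; out-of-range values saturate at the
    ends of ``display_range`` and background renders neutral gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not (pmap.mask.data == 1).any():
        raise ValueError("empty mask")
    lo, hi = pmap.display_range
    if hi <= lo:
        hi = lo + 1e-9
    shown = np.ma.masked_invalid(np.clip(pmap.values, lo, hi))
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap(colormap).copy()
    cmap.set_bad("0.85")
    im = ax.imshow(shown, cmap=cmap, vmin=lo, vmax=hi)
    ax.set_axis_off()
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label(pmap.attribute)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
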