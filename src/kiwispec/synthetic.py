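"""Synthetic kiwifruit hyperspectral scenes with known ground truth.

The generator emulates what a push-broom Vis/NIR (512 bands, 380-1023 nm) or
NIR (256 bands, 874-1734 nm) reflectance imaging system records when scanning
kiwifruits on a conveyor: a raw-count hypercube plus dark and white reference
frames, a per-fruit reference table of destructively measured quality
attributes (firmness in N cm^-2, soluble solids content in degrees Brix, pH),
and ground-truth fruit masks.

Kiwifruit reflectance has broadband absorption features near 673 nm
(chlorophyll), 835 nm (carbohydrate O-H overtones), 970, 1200 and 1460 nm
(water).  Each synthetic fruit spectrum is a smooth continuum minus Gaussian
dips at those centers, with dip depths tied *linearly* to the fruit's quality
attributes through configurable link coefficients.  That linear link is the
generator's identifiability handle: a calibration model that recovers the
attribute from the spectrum is demonstrably reading the dips, not an
artifact.  The link coefficients are free modelling parameters, not estimates
of kiwifruit biology.

Raw counts are synthesized by inverting the dark/white calibration,
raw = dark + I * (white - dark), so downstream calibration is exercised
nontrivially and round-trips exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .envi import Hypercube, write_envi

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "DEFAULT_RANGES",
    "DEFAULT_STATS",
    "generate_attributes",
    "attribute_to_spectrum",
    "generate_scene",
    "write_scene",
]

ATTRIBUTES = ("firmness", "ssc", "ph")

# Measured-dataset attribute ranges and calibration-set mean/SD for the
# 133-fruit kiwifruit study this pipeline targets.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "firmness": (44.086, 642.213),
    "ssc": (13.56, 18.69),
    "ph": (3.64, 4.04),
}
DEFAULT_STATS: dict[str, tuple[float, float]] = {
    "firmness": (228.559, 200.688),
    "ssc": (16.02, 1.20),
    "ph": (3.78, 0.09),
}

_VARIETIES = ("Xuxiang", "Hongyang", "Cuixiang")

_MODES = {
    "visnir": (512, 380.0, 1023.0),
    "nir": (256, 874.0, 1734.0),
}

# absorption centers (nm), Gaussian widths (nm), and the per-attribute linear
# link from attribute value to dip depth (reflectance units per attribute unit)
_DEFAULT_CENTERS = (673.0, 835.0, 970.0, 1200.0, 1460.0)
_DEFAULT_WIDTHS = (25.0, 20.0, 45.0, 60.0, 80.0)
_DEFAULT_LINKS: dict[str, tuple[float, ...]] = {
    "firmness": (3.0e-4, 0.0, 0.0, 0.0, 0.0),
    "ssc": (0.0, 4.0e-3, 8.0e-3, 0.0, 0.0),
    "ph": (0.0, 0.0, 0.0, 0.02, 0.045),
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic scan.

    ``link_coefficients[attr][k]`` is the dip depth at ``absorption_centers[k]``
    contributed per unit of ``attr``; depth is linear in the attribute with no
    offset.  ``gradient`` adds a left-to-right within-fruit linear ramp on the
    linked attribute, as a +/- fraction of the fruit's value at the rim, to
    give pixel-wise maps a ground-truth spatial pattern.
    """

    spectral_mode: str = "visnir"
    n_fruits: int = 4
    image_shape: tuple[int, int] = (100, 100)
    fruit_radius: int = 15
    absorption_centers: tuple[float, ...] = _DEFAULT_CENTERS
    absorption_widths: tuple[float, ...] = _DEFAULT_WIDTHS
    link_coefficients: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_LINKS.items()}
    )
    noise_sd: float = 0.0
    background_level: float = 0.05
    gradient: float = 0.0
    gradient_attribute: str = "firmness"
    dark_level: float = 96.0
    white_scale: float = 3000.0
    seed: int = 20170810

    def __post_init__(self) -> None:
        if self.spectral_mode not in _MODES:
            raise ValueError(f"spectral_mode must be one of {tuple(_MODES)}")
        if len(self.absorption_widths) != len(self.absorption_centers):
            raise ValueError("absorption_widths must match absorption_centers")
        for attr, link in self.link_coefficients.items():
            if attr not in ATTRIBUTES:
                raise ValueError(f"unknown attribute '{attr}' in link_coefficients")
            if len(link) != len(self.absorption_centers):
                raise ValueError("each link vector must match absorption_centers")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.background_level < 1:
            raise ValueError("background_level must be in (0, 1)")

    @property
    def wavelengths(self) -> np.ndarray:
        n, lo, hi = _MODES[self.spectral_mode]
        return np.linspace(lo, hi, n)

    def to_json(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        d["link_coefficients"] = {k: list(v) for k, v in self.link_coefficients.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneConfig":
        d = json.loads(Path(path).read_text())
        d["image_shape"] = tuple(d["image_shape"])
        d["absorption_centers"] = tuple(d["absorption_centers"])
        d["absorption_widths"] = tuple(d["absorption_widths"])
        d["link_coefficients"] = {k: tuple(v) for k, v in d["link_coefficients"].items()}
        return cls(**d)


@dataclass
class SceneTruth:
    """Ground truth for one generated scene: fruit label image (0 =
    background, 1..n = fruit id) and the per-pixel value of the gradient
    attribute (NaN on background)."""

    labels: np.ndarray
    pixel_attribute: np.ndarray
    attribute: str

    def mask(self, fruit_id: int) -> np.ndarray:
        return self.labels == fruit_id


# ---------------------------------------------------------------------------
# Attributes
# ---------------------------------------------------------------------------

def generate_attributes(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 20170810,
    distribution: str = "uniform",
    stats: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Draw a reference table of n fruits.

    ``distribution='uniform'`` samples uniformly within each attribute range;
    ``'truncnorm'`` samples from a normal with the given (mean, SD) per
    attribute, rejection-truncated at the range.  Varieties are assigned
    cyclically (labels only; they do not influence the spectra).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    stats = dict(DEFAULT_STATS, **(stats or {}))
    for attr, (lo, hi) in ranges.items():
        if lo >= hi:
            raise ValueError(f"invalid range for {attr}: min {lo} >= max {hi}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for attr in ATTRIBUTES:
        lo, hi = ranges[attr]
        if distribution == "uniform":
            cols[attr] = rng.uniform(lo, hi, size=n)
        elif distribution == "truncnorm":
            mu, sd = stats[attr]
            vals = np.empty(n)
            filled = 0
            while filled < n:
                draw = rng.normal(mu, sd, size=2 * (n - filled))
                draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
                vals[filled : filled + len(draw)] = draw
                filled += len(draw)
            cols[attr] = vals
        else:
            raise ValueError("distribution must be 'uniform' or 'truncnorm'")
    return pd.DataFrame(
        {
            "fruit_id": np.arange(1, n + 1),
            "variety": [_VARIETIES[i % len(_VARIETIES)] for i in range(n)],
            "firmness": cols["firmness"],
            "ssc": cols["ssc"],
            "ph": cols["ph"],
        }
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _continuum(wl: np.ndarray) -> np.ndarray:
    # smooth fruit-flesh continuum: low in the blue, broad peak near 820 nm
    return 0.45 + 0.25 * np.exp(-0.5 * ((wl - 820.0) / 260.0) ** 2)


def _dip_profiles(cfg: SceneConfig) -> np.ndarray:
    """(n_centers, n_bands) unit-depth Gaussian dip shapes."""
    wl = cfg.wavelengths
    centers = np.asarray(cfg.absorption_centers)[:, None]
    widths = np.asarray(cfg.absorption_widths)[:, None]
    return np.exp(-0.5 * ((wl[None, :] - centers) / widths) ** 2)


def attribute_unit_dip(cfg: SceneConfig, attribute: str) -> np.ndarray:
    """d(spectrum)/d(attribute): the spectral signature of one attribute unit."""
    link = np.asarray(cfg.link_coefficients.get(attribute, np.zeros(len(cfg.absorption_centers))))
    return -(link @ _dip_profiles(cfg))


def attribute_to_spectrum(attrs, cfg: SceneConfig) -> np.ndarray:
    """Noise-free reflectance spectrum of one fruit.

    ``attrs`` is a mapping / table row with firmness, ssc and ph.  The
    spectrum is the continuum minus one Gaussian dip per absorption center
    whose depth is the link-weighted sum of the attribute values, clipped at
    1 from above.  A configuration whose dips drive reflectance to <= 0
    anywhere is rejected.
    """
    depths = np.zeros(len(cfg.absorption_centers))
    for attr in ATTRIBUTES:
        link = cfg.link_coefficients.get(attr)
        if link is not None:
            depths += np.asarray(link) * float(attrs[attr])
    spectrum = _continuum(cfg.wavelengths) - depths @ _dip_profiles(cfg)
    if np.any(spectrum <= 0):
        raise ValueError(
            "link coefficients drive reflectance <= 0; weaken the links or raise the continuum"
        )
    return np.minimum(spectrum, 1.0)


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------

def _place_disks(cfg: SceneConfig, rng: np.random.Generator, max_attempts: int = 200):
    """Non-overlapping disk centers; grid layout jittered, retried, bounded."""
    lines, samples = cfg.image_shape
    r = cfg.fruit_radius
    n = cfg.n_fruits
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    if ncols * (2 * r + 2) > samples or nrows * (2 * r + 2) > lines:
        raise ValueError(f"{n} disks of radius {r} do not fit in {cfg.image_shape}")
    for _ in range(max_attempts):
        centers = []
        for k in range(n):
            i, j = divmod(k, ncols)
            cy = (i + 0.5) * lines / nrows + rng.uniform(-2, 2)
            cx = (j + 0.5) * samples / ncols + rng.uniform(-2, 2)
            centers.append((cy, cx))
        ok = all(
            (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2 > (2 * r + 1) ** 2
            for ai, a in enumerate(centers)
            for b in centers[ai + 1 :]
        ) and all(r <= c[0] <= lines - 1 - r and r <= c[1] <= samples - 1 - r for c in centers)
        if ok:
            return centers
    raise RuntimeError("could not place non-overlapping fruits within attempt budget")


def generate_scene(
    cfg: SceneConfig, table: pd.DataFrame
) -> tuple[Hypercube, Hypercube, Hypercube, SceneTruth]:
    """Render one scan: (raw, dark, white) cubes plus ground truth.

    Fruit pixels carry the fruit's linked spectrum (optionally with a
    within-fruit attribute gradient); background pixels sit at a flat low
    reflectance.  Reflectance is re-encoded as raw counts through the dark and
    white frames that are returned alongside, with i.i.d. Gaussian noise of SD
    ``cfg.noise_sd`` (reflectance units) added to the raw frame only.
    """
    if len(table) < cfg.n_fruits:
        raise ValueError("reference table has fewer rows than n_fruits")
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths
    lines, samples = cfg.image_shape
    nb = len(wl)

    dark = np.full((lines, samples, nb), cfg.dark_level)
    white = cfg.white_scale * (0.85 + 0.15 * np.exp(-0.5 * ((wl - 900.0) / 400.0) ** 2))
    white = np.broadcast_to(white, (lines, samples, nb)).copy()

    refl = np.full((lines, samples, nb), cfg.background_level)
    labels = np.zeros((lines, samples), dtype=np.int32)
    pixel_attr = np.full((lines, samples), np.nan)

    centers = _place_disks(cfg, rng)
    yy, xx = np.mgrid[0:lines, 0:samples]
    unit_dip = attribute_unit_dip(cfg, cfg.gradient_attribute)
    for k, (cy, cx) in enumerate(centers):
        row = table.iloc[k]
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.fruit_radius**2
        labels[inside] = k + 1
        base = attribute_to_spectrum(row, cfg)
        attr0 = float(row[cfg.gradient_attribute])
        # linear left-to-right ramp of the gradient attribute across the disk
        ramp = cfg.gradient * attr0 * (xx[inside] - cx) / cfg.fruit_radius
        refl[inside] = base[None, :] + ramp[:, None] * unit_dip[None, :]
        pixel_attr[inside] = attr0 + ramp
    if np.any(refl[labels > 0] <= 0):
        raise ValueError("gradient drives fruit reflectance <= 0; reduce cfg.gradient")

    raw = dark + refl * (white - dark)
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd, raw.shape) * (white - dark)

    truth = SceneTruth(labels=labels, pixel_attribute=pixel_attr, attribute=cfg.gradient_attribute)
    return (
        Hypercube(raw, wl, kind="raw"),
        Hypercube(dark, wl, kind="dark"),
        Hypercube(white, wl, kind="white"),
        truth,
    )


def write_scene(
    cfg: SceneConfig,
    table: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "scene",
) -> dict[str, Path]:
    """Generate and persist one scene: ENVI triplet + reference CSV + config JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw, dark, white, truth = generate_scene(cfg, table)
    paths = {
        "raw": write_envi(raw, out_dir / f"{prefix}_raw.hdr"),
        "dark": write_envi(dark, out_dir / f"{prefix}_dark.hdr"),
        "white": write_envi(white, out_dir / f"{prefix}_white.hdr"),
    }
    ref_path = out_dir / f"{prefix}_reference.csv"
    table.iloc[: cfg.n_fruits][["fruit_id", "variety", "firmness", "ssc", "ph"]].to_csv(
        ref_path, index=False
    )
    cfg_path = out_dir / f"{prefix}_config.json"
    cfg.to_json(cfg_path)
    paths["reference"] = ref_path
    paths["config"] = cfg_path
    return paths
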