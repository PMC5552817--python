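"""ENVI hypercube I/O, reflectance calibration, binning and spectral trimming.

A hypercube is a 3-D block of line-scan imagery: two spatial axes (lines,
samples) and one spectral axis (bands), with a wavelength in nm attached to
every band.  Raw camera counts are converted to relative reflectance with the
standard dark/white reference correction

    I = (I_raw - I_dark) / (I_white - I_dark)

where the dark frame captures sensor thermal signal (0 % reflectance) and the
white frame a near-perfect diffuse reflector (~99 % reflectance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Hypercube",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "bin_cube",
    "trim_range",
    "band_index",
]

# ENVI data type codes <-> numpy dtypes (little-endian written by default)
_ENVI_DTYPES = {
    1: np.dtype(np.uint8),
    2: np.dtype(np.int16),
    3: np.dtype(np.int32),
    4: np.dtype(np.float32),
    5: np.dtype(np.float64),
    12: np.dtype(np.uint16),
    13: np.dtype(np.uint32),
    14: np.dtype(np.int64),
    15: np.dtype(np.uint64),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}

_KINDS = ("raw", "dark", "white", "reflectance")
_INTERLEAVES = ("bil", "bip", "bsq")


@dataclass
class Hypercube:
    """3-D spectral image block with a per-band wavelength axis.

    ``data`` is indexed ``(line, sample, band)`` regardless of the on-disk
    interleave; ``wavelengths`` are nm, strictly increasing.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    interleave: str = "bil"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (lines, samples, bands), got {self.data.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} != band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.interleave not in _INTERLEAVES:
            raise ValueError(f"interleave must be one of {_INTERLEAVES}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, nm: float) -> np.ndarray:
        """Single-band image at the band nearest to ``nm`` (tolerance rule)."""
        return self.data[:, :, band_index(self.wavelengths, nm)]


def band_index(wavelengths: np.ndarray, nm: float, tol_factor: float = 0.5) -> int:
    """Nearest-neighbor band lookup with a local-spacing tolerance.

    Named wavelengths (e.g. the 700 nm masking band) need not coincide with
    band centers; a request is honored if it falls within ``tol_factor``
    times the local band spacing of the nearest center (default: half a
    spacing).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    i = int(np.argmin(np.abs(wavelengths - nm)))
    if len(wavelengths) == 1:
        tol = np.inf
    elif i == 0:
        tol = tol_factor * (wavelengths[1] - wavelengths[0])
    elif i == len(wavelengths) - 1:
        tol = tol_factor * (wavelengths[-1] - wavelengths[-2])
    else:
        tol = tol_factor * (wavelengths[i + 1] - wavelengths[i - 1]) / 2
    if abs(wavelengths[i] - nm) > tol:
        raise ValueError(
            f"no band within tolerance of {nm} nm (nearest: {wavelengths[i]:.2f} nm)"
        )
    return i


# ---------------------------------------------------------------------------
# ENVI read/write
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    """Parse an ENVI .hdr into a flat dict (values: str or list of str)."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict = {}
    # brace-delimited values may span lines; normal values end at newline
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)\s*$", re.S | re.M)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            items = [v.strip() for v in val[1:-1].replace("\n", " ").split(",")]
            fields[key] = [v for v in items if v]
        else:
            fields[key] = val
        pos = m.end()
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI header + flat binary pair into a :class:`Hypercube`.

    The binary path is the header path with its ``.hdr`` suffix removed (or
    ``.img`` appended when the header has no such suffix).  Byte order and
    interleave are honored bit-exactly.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required field '{req}'")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = str(fields["interleave"]).lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = _ENVI_DTYPES[int(fields["data type"])]
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", 0))
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if len(wavelengths) != bands:
        raise ValueError("wavelength list length does not match band count")

    bin_path = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path.with_suffix(".img")
    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    if raw.size != lines * samples * bands:
        raise ValueError(
            f"binary size {raw.size} elements does not match header dims "
            f"{lines}x{samples}x{bands}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)
    kind = fields.get("kiwispec kind", "raw")
    if kind not in _KINDS:
        kind = "raw"
    return Hypercube(np.ascontiguousarray(data), wavelengths, kind=kind, interleave=interleave)


def write_envi(cube: Hypercube, header_path: str | Path, interleave: str | None = None) -> Path:
    """Write ``cube`` as an ENVI header + flat binary pair; returns header path."""
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(header_path.suffix + ".hdr")
    interleave = interleave or cube.interleave
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    data = np.asarray(cube.data)
    dtype = data.dtype.newbyteorder("=")
    base = np.dtype(dtype.str[1:])
    if base not in _DTYPE_CODES:
        data = data.astype(np.float64)
        base = np.dtype(np.float64)
    lines, samples, bands = data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[base]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"kiwispec kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    out.astype(base.newbyteorder("<")).tofile(header_path.with_suffix(""))
    return header_path


# ---------------------------------------------------------------------------
# Calibration, binning, trimming
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: Hypercube, dark: Hypercube, white: Hypercube) -> Hypercube:
    """Dark/white reference correction: I = (raw - dark) / (white - dark).

    Values are not clipped: noisy pixels with raw < dark legitimately map to
    reflectance < 0 (clipping, if wanted, belongs to display).
    """
    if not (raw.shape == dark.shape == white.shape):
        raise ValueError("raw, dark and white cubes must share one shape")
    for other in (dark, white):
        if not np.array_equal(raw.wavelengths, other.wavelengths):
            raise ValueError("raw, dark and white cubes must share one wavelength axis")
    denom = white.data.astype(np.float64) - dark.data.astype(np.float64)
    bad = np.nonzero(np.any(denom.reshape(-1, raw.n_bands) <= 0, axis=0))[0]
    if bad.size:
        nm = raw.wavelengths[bad[0]]
        raise ValueError(
            f"white - dark is non-positive at band {bad[0]} ({nm:.1f} nm): "
            "saturated or defective reference frame"
        )
    refl = (raw.data.astype(np.float64) - dark.data) / denom
    return Hypercube(refl, raw.wavelengths.copy(), kind="reflectance", interleave=raw.interleave)


def bin_cube(cube: Hypercube, spatial_factor: int = 1, spectral_factor: int = 1) -> Hypercube:
    """Non-overlapping block means over space and spectrum.

    Spatial binning applies the same factor to lines and samples (the camera's
    n x n binning); the binned wavelength is the mean of the constituent band
    centers.  Trailing blocks that do not fill a factor are dropped.
    """
    if spatial_factor < 1 or spectral_factor < 1:
        raise ValueError("binning factors must be >= 1")
    lines, samples, bands = cube.shape
    if spatial_factor > min(lines, samples) or spectral_factor > bands:
        raise ValueError("binning factor exceeds cube dimension")
    nl = lines // spatial_factor
    ns = samples // spatial_factor
    nb = bands // spectral_factor
    d = cube.data[: nl * spatial_factor, : ns * spatial_factor, : nb * spectral_factor]
    d = d.reshape(nl, spatial_factor, ns, spatial_factor, nb, spectral_factor)
    data = d.mean(axis=(1, 3, 5))
    wl = cube.wavelengths[: nb * spectral_factor].reshape(nb, spectral_factor).mean(axis=1)
    return Hypercube(data, wl, kind=cube.kind, interleave=cube.interleave)


def trim_range(obj, lo: float, hi: float):
    """Keep bands with lo <= wavelength <= hi (inclusive).

    Accepts a :class:`Hypercube` (returns a trimmed cube) or an
    ``(X, wavelengths)`` pair of a 2-D spectra matrix and its axis (returns
    the trimmed pair).  The leading/trailing bands of both camera ranges are
    noisy, hence the standard working windows 450-1000 nm and 951-1670 nm.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if isinstance(obj, Hypercube):
        wl = obj.wavelengths
        keep = (wl >= lo) & (wl <= hi)
        if not keep.any():
            raise ValueError(f"no bands in [{lo}, {hi}] nm")
        return Hypercube(obj.data[:, :, keep], wl[keep], kind=obj.kind, interleave=obj.interleave)
    X, wl = obj
    wl = np.asarray(wl, dtype=float)
    keep = (wl >= lo) & (wl <= hi)
    if not keep.any():
        raise ValueError(f"no bands in [{lo}, {hi}] nm")
    return np.asarray(X)[..., keep], wl[keep]
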