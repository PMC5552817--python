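"""Access to the shipped reference fixtures (published dataset statistics and
effective-wavelength lists for the 133-kiwifruit reference dataset)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

__all__ = ["reference_statistics", "published_effective_wavelengths"]


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("kiwispec.data").joinpath(name).open() as fh:
        return json.load(fh)


def reference_statistics() -> dict:
    """Summary statistics of the reference dataset and its headline models
    (prediction-set SDs, SEPs and printed RPDs)."""
    return _load("reference_statistics.json")


def published_effective_wavelengths() -> dict:
    """Published EW selections per attribute and selector (comparison only)."""
    return _load("published_effective_wavelengths.json")
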