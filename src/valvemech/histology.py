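"""Histology matrix composition by color separation and thresholding.

Stained sections (Movat pentachrome, Masson's trichrome, Verhoeff-van
Gieson) are separated into per-constituent grayscale channels, thresholded
into binary masks, and quantified as area fractions of the leaflet region;
the collagen/GAG fractional ratio is the headline composition statistic.

The leaflet mask is an input (manually outlined or generated); automatic
leaflet detection is out of scope.  Channel rules per stain live in an
editable :class:`StainProfile`, since published color-splitting workflows
name the channel splitter but rarely the per-constituent rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidMaskError, NormalizationError, StainConfigError


@dataclass(frozen=True)
class ChannelRule:
    """How one constituent is extracted from an RGB slide.

    ``space`` selects the grayscale transform:

    * ``cmyk_y`` — the CMYK yellow channel (yellow-stained collagen);
    * ``rgb_diff`` — difference of two RGB channels, ``params = (plus, minus)``
      with channel indices (blue-stained GAGs or connective tissue: B - R);
    * ``lum_inv`` — inverted luminance (dark stains such as VVG elastin);
    * ``rgb`` — a single RGB channel, ``params = (index,)``.

    ``threshold`` is ``"otsu"`` or a fixed value on the channel's 0-1 scale.
    """

    space: str
    params: tuple = ()
    threshold: str | float = "otsu"

    _KNOWN = ("cmyk_y", "rgb_diff", "lum_inv", "rgb")

    def __post_init__(self) -> None:
        if self.space not in self._KNOWN:
            raise StainConfigError(f"unknown channel space {self.space!r}")


@dataclass(frozen=True)
class StainProfile:
    """Per-constituent color classification rules for one stain."""

    stain_name: str
    rules: Mapping[str, ChannelRule]

    def __post_init__(self) -> None:
        if not self.rules:
            raise StainConfigError("profile defines no constituents")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StainProfile":
        raw = yaml.safe_load(Path(path).read_text())
        rules = {
            name: ChannelRule(
                space=r["space"],
                params=tuple(r.get("params", ())),
                threshold=r.get("threshold", "otsu"),
            )
            for name, r in raw["rules"].items()
        }
        return cls(stain_name=raw["stain_name"], rules=rules)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "stain_name": self.stain_name,
            "rules": {
                name: {"space": r.space, "params": list(r.params), "threshold": r.threshold}
                for name, r in self.rules.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


#: Built-in profiles.  Movat: collagen stains yellow/orange, GAGs blue/green;
#: trichrome: connective tissue stains blue; VVG: elastin stains purple/black.
DEFAULT_PROFILES: dict[str, StainProfile] = {
    "movat": StainProfile(
        "movat",
        {
            "collagen": ChannelRule("cmyk_y"),
            "gag": ChannelRule("rgb_diff", params=(2, 0)),  # B - R
        },
    ),
    "trichrome": StainProfile(
        "trichrome",
        {"connective": ChannelRule("rgb_diff", params=(2, 0))},
    ),
    "vvg": StainProfile("vvg", {"elastin": ChannelRule("lum_inv")}),
}

#: Canonical paint colors used by the synthetic slide generator, chosen to be
#: separable by the default profiles above.  ``__background__`` is the pale
#: unstained tissue inside the leaflet.
_PAINT_COLORS: dict[str, dict[str, tuple[int, int, int]]] = {
    "movat": {
        "collagen": (230, 200, 60),
        "gag": (70, 110, 200),
        "__background__": (235, 228, 220),
    },
    "trichrome": {
        "connective": (90, 120, 210),
        "__background__": (240, 225, 225),
    },
    "vvg": {
        "elastin": (60, 35, 70),
        "__background__": (235, 220, 215),
    },
}


def stain_paint_colors(stain: str) -> dict[str, tuple[int, int, int]]:
    """Canonical RGB paint colors of a stain (for the synthetic generator)."""
    try:
        return _PAINT_COLORS[stain]
    except KeyError:
        raise StainConfigError(f"unknown stain {stain!r}") from None


@dataclass(frozen=True)
class CompositionFractions:
    """Per-constituent area fractions of the leaflet, plus the collagen/GAG ratio.

    ``collagen_gag_ratio`` is None (undefined) when either fraction is
    missing or the GAG fraction is zero.
    """

    fractions: Mapping[str, float]
    leaflet_area: int
    collagen_gag_ratio: float | None = None


def _channel(rgb: np.ndarray, rule: ChannelRule) -> np.ndarray:
    """Grayscale channel in [0, 1] per the rule, higher = more constituent."""
    img = np.asarray(rgb, dtype=float) / 255.0
    if rule.space == "cmyk_y":
        k = 1.0 - img.max(axis=2)
        denom = np.maximum(1.0 - k, 1e-9)
        return (1.0 - img[..., 2] - k) / denom
    if rule.space == "rgb_diff":
        plus, minus = rule.params
        return np.clip(img[..., plus] - img[..., minus], 0.0, 1.0)
    if rule.space == "lum_inv":
        lum = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        return 1.0 - lum
    if rule.space == "rgb":
        return img[..., rule.params[0]]
    raise StainConfigError(f"unknown channel space {rule.space!r}")


def split_constituents(
    rgb: np.ndarray, profile: StainProfile
) -> dict[str, np.ndarray]:
    """Per-constituent binary masks of an RGB slide.

    Each constituent's grayscale channel is thresholded (Otsu by default,
    fixed-value override in the rule).  A channel with negligible dynamic
    range (blank slide, absent constituent) yields an empty mask rather than
    a meaningless Otsu split.
    """
    from skimage.filters import threshold_otsu

    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an RGB raster of shape (h, w, 3)")
    masks = {}
    for name, rule in profile.rules.items():
        chan = _channel(rgb, rule)
        if isinstance(rule.threshold, (int, float)):
            masks[name] = chan > float(rule.threshold)
        elif np.percentile(chan, 99.5) - np.percentile(chan, 0.5) < 0.15:
            # channel carries no stain signal (blank slide or absent
            # constituent): an Otsu split would threshold background tint
            masks[name] = np.zeros(chan.shape, dtype=bool)
        else:
            masks[name] = chan > threshold_otsu(chan)
    return masks


def area_fractions(
    masks: Mapping[str, np.ndarray], leaflet_mask: np.ndarray
) -> CompositionFractions:
    """Constituent area fractions normalized to the leaflet area.

    fraction = |mask AND leaflet| / |leaflet|; the collagen/GAG ratio is
    attached when both constituents are present and GAG is nonzero.
    """
    leaflet = np.asarray(leaflet_mask, dtype=bool)
    n_leaflet = int(leaflet.sum())
    if n_leaflet == 0:
        raise InvalidMaskError("leaflet mask is empty")
    fractions = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != leaflet.shape:
            raise InvalidMaskError(f"mask {name!r} shape {mask.shape} != leaflet {leaflet.shape}")
        fractions[name] = float((mask & leaflet).sum() / n_leaflet)
    ratio = None
    if "collagen" in fractions and "gag" in fractions and fractions["gag"] > 0:
        ratio = fractions["collagen"] / fractions["gag"]
    return CompositionFractions(fractions=fractions, leaflet_area=n_leaflet, collagen_gag_ratio=ratio)


def normalize_to_reference(
    values: Mapping[str, np.ndarray], reference_group: str
) -> dict[str, np.ndarray]:
    """Scale per-specimen fractions so the reference-group mean is exactly 1.

    Mirrors reporting conventions where the wild-type mean is set to 1 and
    other genotypes are expressed relative to it.
    """
    if reference_group not in values:
        raise NormalizationError(f"reference group {reference_group!r} not in table")
    ref = np.asarray(values[reference_group], dtype=float)
    if len(ref) == 0:
        raise NormalizationError("reference group is empty")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise NormalizationError("reference group mean is zero")
    return {g: np.asarray(v, dtype=float) / ref_mean for g, v in values.items()}


def quantify_slide(
    rgb: np.ndarray,
    leaflet_mask: np.ndarray,
    profile: StainProfile | str = "movat",
) -> CompositionFractions:
    """Convenience path: split an RGB slide and return its area fractions."""
    if isinstance(profile, str):
        profile = DEFAULT_PROFILES[profile]
    return area_fractions(split_constituents(rgb, profile), leaflet_mask)


def composition_frame(
    results: Mapping[str, CompositionFractions], stain: str
) -> pd.DataFrame:
    """Tidy table ``specimen_id, stain, constituent, fraction, ratio_collagen_gag``."""
    rows = []
    for sid, comp in results.items():
        for name, frac in sorted(comp.fractions.items()):
            rows.append(
                {
                    "specimen_id": sid,
                    "stain": stain,
                    "constituent": name,
                    "fraction": frac,
                    "ratio_collagen_gag": comp.collagen_gag_ratio,
                }
            )
    return pd.DataFrame(
        rows, columns=["specimen_id", "stain", "constituent", "fraction", "ratio_collagen_gag"]
    )
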