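"""Threat-magnitude classification, the multi-threat combiner and summaries.

The five-class magnitude scale (No threat, Low, Medium, High, Very high)
cuts the sensitivity-weighted intensity at 0.01, 0.11, 0.31 and 0.71 as
printed to two decimals; internally the class boundaries sit at the
midpoints 0.105, 0.305 and 0.705 so that any value rounding to a printed
bound lands in the printed class.  Per-species maps from the six individual
threats are combined by taking the per-pixel maximum and applying the
'3-5 rule' upgrades (three Highs make a Very high; five Mediums make a
High).  Summary products report per-class area percentages over each
species' distribution, the multi-species severe-threat hotspot count and
the modelled species richness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import (
    CLASS_HIGH,
    CLASS_MEDIUM,
    CLASS_NAMES,
    CLASS_VERY_HIGH,
    ClassLayer,
    GridLayer,
)

#: Upper class boundaries on the weighted-intensity scale (lower-exclusive,
#: upper-inclusive); the top class runs to 1.
CLASS_BREAKS = (0.01, 0.105, 0.305, 0.705)


def classify_magnitude(value, capped: bool = False) -> np.ndarray | int:
    """Map weighted intensity in [0, 1] to an ordinal magnitude class.

    ``capped`` lowers 'Very high' to 'High' (used for cotton, whose source
    map cannot resolve production peaks).
    """
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("intensity values must lie in [0, 1]")
    codes = np.searchsorted(CLASS_BREAKS, arr, side="left").astype(np.int16)
    if capped:
        codes = np.minimum(codes, CLASS_HIGH)
    return codes if codes.shape else int(codes)


def species_threat_map(
    intensity,
    sensitivity: float,
    distribution: GridLayer,
) -> ClassLayer:
    """Classify sensitivity x intensity inside the species' distribution.

    ``sensitivity`` is the species' normalized (0-1) sensitivity weight for
    species-specific threats, or 1.0 for generic ones.  Cells outside the
    distribution mask are left unmasked: a threat is undefined where the
    species does not occur.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must lie in [0, 1]")
    layer = intensity.layer if hasattr(intensity, "layer") else intensity
    capped = getattr(intensity, "capped", False)
    codes = classify_magnitude(np.clip(layer.values * sensitivity, 0.0, 1.0), capped)
    mask = layer.mask & (distribution.values > 0) & distribution.mask
    return ClassLayer(layer.spec, np.where(mask, codes, 0), mask)


def combine_codes(codes: np.ndarray) -> np.ndarray:
    """Combine six stacked class-code arrays (shape (6, ...)).

    Per cell: the maximum of the six codes, upgraded to Very high when at
    least three layers are High, else upgraded to at least High when at
    least five layers are Medium.
    """
    codes = np.asarray(codes)
    if codes.shape[0] != 6:
        raise ValueError("exactly six threat layers are required")
    out = codes.max(axis=0)
    n_high = (codes == CLASS_HIGH).sum(axis=0)
    n_medium = (codes == CLASS_MEDIUM).sum(axis=0)
    out = np.where(n_high >= 3, np.maximum(out, CLASS_VERY_HIGH), out)
    out = np.where((n_high < 3) & (n_medium >= 5), np.maximum(out, CLASS_HIGH), out)
    return out.astype(np.int16)


def combine_threats(layers: list[ClassLayer]) -> ClassLayer:
    """Combined threat map from the six individual per-threat class maps."""
    if len(layers) != 6:
        raise ValueError(f"exactly six threat layers are required, got {len(layers)}")
    spec = layers[0].spec
    for l in layers[1:]:
        if l.spec != spec:
            raise ValueError("all layers must share one grid")
    stacked = np.stack([l.classes for l in layers])
    mask = np.logical_and.reduce([l.mask for l in layers])
    combined = combine_codes(stacked)
    return ClassLayer(spec, np.where(mask, combined, 0), mask)


def class_percentages(layer: ClassLayer) -> pd.Series:
    """Percent of masked (distribution) cells in each of the five classes."""
    inside = layer.classes[layer.mask]
    if inside.size == 0:
        raise ValueError("empty distribution mask")
    counts = np.bincount(inside, minlength=5)[:5]
    return pd.Series(100.0 * counts / inside.size, index=list(CLASS_NAMES))


def severe_percentage(layer: ClassLayer) -> float:
    """Percent of masked cells at severe level (High or Very high)."""
    inside = layer.classes[layer.mask]
    if inside.size == 0:
        raise ValueError("empty distribution mask")
    return float(100.0 * (inside >= CLASS_HIGH).mean())


def scope_table(
    per_threat: dict[str, ClassLayer], combined: ClassLayer
) -> tuple[pd.Series, pd.Series]:
    """Per-threat severe percentages and the combined five-class breakdown.

    Returns ``(severe_by_threat, combined_class_percentages)``; the latter
    sums to 100 up to rounding of the cell counts.
    """
    severe = pd.Series(
        {threat: severe_percentage(layer) for threat, layer in per_threat.items()}
    )
    return severe, class_percentages(combined)


def hotspot_map(combined_by_species: dict[str, ClassLayer]) -> GridLayer:
    """Per-cell count of species whose combined threat there is severe.

    A species contributes only where it is present (its layer's mask);
    masked-out cells contribute zero.
    """
    if not combined_by_species:
        raise ValueError("need at least one species")
    layers = list(combined_by_species.values())
    spec = layers[0].spec
    count = np.zeros(spec.shape)
    for layer in layers:
        count += ((layer.classes >= CLASS_HIGH) & layer.mask).astype(float)
    return GridLayer(spec, count)


def richness_map(presence_by_species: dict[str, GridLayer]) -> GridLayer:
    """Per-cell count of species with predicted suitable habitat."""
    if not presence_by_species:
        raise ValueError("need at least one species")
    layers = list(presence_by_species.values())
    spec = layers[0].spec
    count = np.zeros(spec.shape)
    for layer in layers:
        count += ((layer.values > 0) & layer.mask).astype(float)
    return GridLayer(spec, count)
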