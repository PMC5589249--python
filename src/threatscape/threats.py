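"""Per-threat intensity and class layers.

Six threats are mapped: four quantitative intensities rescaled to [0, 1]
(overexploitation from the human-footprint index, overgrazing from tropical
livestock units, fire from seasonal-weighted detection frequency, cotton
from province production spread over cotton-growing cells) and two directly
classified layers (mining presence, climate-change scenario outcomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import (
    CLASS_NO_THREAT,
    CLASS_VERY_HIGH,
    ClassLayer,
    GridLayer,
    GridSpec,
    normalize_minmax,
    pixel_area_km2,
    rasterize_points,
    resample_bilinear,
    sqrt_transform,
)

logger = logging.getLogger(__name__)

#: Tropical-livestock-unit conversion factors (grazing equivalents of a
#: 250 kg ruminant).
TLU_CATTLE = 0.7
TLU_GOAT = 0.1
TLU_SHEEP = 0.1

#: Fire detections at or below this confidence (percent) are discarded.
FIRE_CONFIDENCE_CUTOFF = 30.0

#: Months counted as late-season fires (peak of the dry season); late fires
#: carry double weight because tree mortality can be twice as high.
LATE_FIRE_MONTHS = frozenset({1, 2, 3})
LATE_FIRE_WEIGHT = 2.0

#: Mining-point status values treated as active threats.
ACTIVE_MINING_STATUS = frozenset({"active", "prospect"})


@dataclass
class ThreatIntensity:
    """A [0, 1] intensity surface for one threat."""

    threat: str
    layer: GridLayer
    species_specific: bool
    capped: bool = False  # capped threats cannot classify above 'High'

    def __post_init__(self) -> None:
        inside = self.layer.masked_values()
        if inside.size and (inside.min() < -1e-9 or inside.max() > 1 + 1e-9):
            raise ValueError(f"{self.threat}: intensity outside [0, 1]")


def overexploitation_intensity(
    footprint: GridLayer, target: GridSpec | None = None
) -> ThreatIntensity:
    """Human-footprint index resampled to the analysis grid and min-max
    normalized."""
    if footprint.masked_values().size and footprint.masked_values().min() < 0:
        raise ValueError("footprint values must be non-negative")
    layer = footprint
    if target is not None and target != footprint.spec:
        layer = resample_bilinear(layer, target)
    return ThreatIntensity("overexploitation", normalize_minmax(layer), True)


def tlu(cattle: GridLayer, goats: GridLayer, sheep: GridLayer) -> GridLayer:
    """Tropical livestock units per cell: 0.7*cattle + 0.1*goats + 0.1*sheep."""
    for name, layer in (("cattle", cattle), ("goats", goats), ("sheep", sheep)):
        vals = layer.masked_values()
        if vals.size and vals.min() < 0:
            raise ValueError(f"negative {name} density")
    vals = TLU_CATTLE * cattle.values + TLU_GOAT * goats.values + TLU_SHEEP * sheep.values
    mask = cattle.mask & goats.mask & sheep.mask
    return GridLayer(cattle.spec, np.where(mask, vals, 0.0), mask)


def overgrazing_intensity(tlu_layer: GridLayer) -> ThreatIntensity:
    """Square-root transform (the TLU distribution is heavily right-skewed)
    followed by min-max normalization."""
    return ThreatIntensity(
        "overgrazing", normalize_minmax(sqrt_transform(tlu_layer)), True
    )


def fire_frequency(
    events: pd.DataFrame,
    grid: GridSpec,
    years: tuple[int, int],
    *,
    late_months: frozenset[int] = LATE_FIRE_MONTHS,
    confidence_cutoff: float = FIRE_CONFIDENCE_CUTOFF,
    area_mode: str = "nominal",
) -> GridLayer:
    """Mean annual seasonally weighted fire frequency per km².

    Detections with confidence <= cutoff are discarded; late-season fires
    (default January-March) get double weight; events outside the year
    window are dropped with a logged count.  Per cell the weighted count is
    divided by the number of years and the cell area in km².
    """
    start, end = years
    if end < start:
        raise ValueError("empty year window")
    dates = pd.to_datetime(events["date"])
    conf_ok = events["confidence"].to_numpy() > confidence_cutoff
    year_ok = (dates.dt.year >= start) & (dates.dt.year <= end)
    n_outside = int((conf_ok & ~year_ok).sum())
    if n_outside:
        logger.info("fire_frequency: dropped %d event(s) outside %d-%d", n_outside, start, end)
    keep = conf_ok & year_ok.to_numpy()

    weights = np.where(dates.dt.month.isin(late_months), LATE_FIRE_WEIGHT, 1.0)
    counts = rasterize_points(
        events["lon"].to_numpy()[keep],
        events["lat"].to_numpy()[keep],
        grid,
        weights=weights[keep],
    )
    n_years = end - start + 1
    if area_mode == "nominal":
        area = pixel_area_km2(grid, 0.0, mode="nominal")
        freq = counts.values / (n_years * area)
    else:
        lats = grid.cell_center_lats()
        areas = np.array([pixel_area_km2(grid, lat) for lat in lats])
        freq = counts.values / (n_years * areas[:, None])
    return GridLayer(grid, freq, counts.mask)


def fire_intensity(freq: GridLayer) -> ThreatIntensity:
    """Same transform chain as overgrazing: square root then min-max."""
    return ThreatIntensity("fire", normalize_minmax(sqrt_transform(freq)), True)


def cotton_intensity(
    province_stats: pd.DataFrame,
    cotton_mask: GridLayer,
    province_map: GridLayer,
) -> ThreatIntensity:
    """Province production divided equally over that province's cotton cells,
    then min-max normalized.  Flagged ``capped`` so classification cannot
    exceed 'High' (the source map cannot resolve production peaks)."""
    layer = cotton_allocation(province_stats, cotton_mask, province_map)
    return ThreatIntensity(
        "cotton", normalize_minmax(layer), species_specific=False, capped=True
    )


def cotton_allocation(
    province_stats: pd.DataFrame,
    cotton_mask: GridLayer,
    province_map: GridLayer,
) -> GridLayer:
    """Raw per-cell production allocation (before normalization); cell values
    sum to the total production of provinces that have cotton cells."""
    stats = province_stats.set_index("province")["production"]
    pid = province_map.values.astype(int)
    cotton = cotton_mask.values.astype(bool) & cotton_mask.mask
    vals = np.zeros(cotton_mask.spec.shape)
    for p in np.unique(pid[cotton]):
        if p not in stats.index:
            raise ValueError(f"cotton cells in province {p} but no production record")
        cells = cotton & (pid == p)
        vals[cells] = stats.loc[p] / cells.sum()
    return GridLayer(cotton_mask.spec, vals, cotton_mask.mask.copy())


def mining_class(
    mining_points: pd.DataFrame,
    grid: GridSpec,
    active_status: frozenset[str] = ACTIVE_MINING_STATUS,
) -> ClassLayer:
    """Cells containing at least one active site (or prospect) are 'Very
    high'; everywhere else 'No threat'.  One coarse pixel per site covers the
    degraded surroundings, so no further spreading is applied."""
    active = mining_points[mining_points["status"].isin(active_status)]
    counts = rasterize_points(active["lon"].to_numpy(), active["lat"].to_numpy(), grid)
    classes = np.where(counts.values >= 1, CLASS_VERY_HIGH, CLASS_NO_THREAT)
    return ClassLayer(grid, classes)


def climate_class_codes(
    p45: np.ndarray, p85: np.ndarray, n45: np.ndarray, n85: np.ndarray
) -> np.ndarray:
    """Ordered climate-threat decision rules on boolean arrays.

    1. habitat already lost under the moderate scenario (RCP 4.5 absent)
       -> Very high;
    2. both scenarios retain habitat but only under novel regional climate
       in both -> High;
    3. RCP 4.5 retains habitat under novel climate (RCP 8.5 absent or not
       novel in agreement) -> Medium;
    4. RCP 4.5 retains habitat, RCP 8.5 loses it -> Low;
    5. otherwise (both retain habitat, not both novel) -> No threat.
    """
    p45, p85, n45, n85 = (np.asarray(a, dtype=bool) for a in (p45, p85, n45, n85))
    out = np.zeros(p45.shape, dtype=np.int16)
    rule1 = ~p45
    rule2 = ~rule1 & p85 & n45 & n85
    rule3 = ~rule1 & ~rule2 & n45
    rule4 = ~rule1 & ~rule2 & ~rule3 & ~p85
    out[rule4] = 1
    out[rule3] = 2
    out[rule2] = 3
    out[rule1] = 4
    return out


def climate_class(
    pres_45: GridLayer, pres_85: GridLayer, novel_45: GridLayer, novel_85: GridLayer
) -> ClassLayer:
    """Climate-change threat classes from scenario presence and novelty maps."""
    spec = pres_45.spec
    for layer in (pres_85, novel_45, novel_85):
        if layer.spec != spec:
            raise ValueError("all scenario layers must share one grid")
    codes = climate_class_codes(
        pres_45.values > 0, pres_85.values > 0,
        novel_45.values > 0, novel_85.values > 0,
    )
    mask = pres_45.mask & pres_85.mask & novel_45.mask & novel_85.mask
    return ClassLayer(spec, codes, mask)
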