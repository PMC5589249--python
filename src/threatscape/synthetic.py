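"""Synthetic study-area generator.

Emulates every input of the threat-assessment pipeline on a miniature grid:
smooth bioclimatic gradients with future warming/drying scenarios, species
occurrences drawn from a known Gaussian niche, spatially structured threat
surfaces (human footprint, livestock densities, fire detections, cotton
provinces, mining points) and expert survey ratings generated under a
cultural-consensus model (shared truth plus competence-scaled noise).

Every generator is a pure function of its parameters and seed, and the
underlying truth (suitability surface, expert competences) is returned
alongside the data so downstream estimators can be scored on parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridLayer, GridSpec

#: The eight candidate bioclimatic variables used by the suitability models.
CLIMATE_VARIABLES = ("BIO1", "BIO3", "BIO5", "BIO12", "BIO13", "BIO14", "LLDS", "PET")

#: Additive (+) or multiplicative (x) scenario shifts per variable:
#: moderate mid-century warming/drying, and a stronger high-emission variant.
RCP45_SHIFTS = {
    "BIO1": ("+", 1.5),
    "BIO3": ("+", 0.5),
    "BIO5": ("+", 1.8),
    "BIO12": ("x", 0.90),
    "BIO13": ("x", 0.90),
    "BIO14": ("x", 0.85),
    "LLDS": ("+", 8.0),
    "PET": ("+", 60.0),
}
RCP85_SHIFTS = {
    "BIO1": ("+", 3.0),
    "BIO3": ("+", 1.0),
    "BIO5": ("+", 3.6),
    "BIO12": ("x", 0.80),
    "BIO13": ("x", 0.80),
    "BIO14": ("x", 0.70),
    "LLDS": ("+", 16.0),
    "PET": ("+", 120.0),
}


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian niche: per-variable optimum and tolerance, multiplied across
    variables and scaled to ``max_suitability``."""

    optima: dict[str, float]
    tolerances: dict[str, float]
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.tolerances):
            raise ValueError("optima and tolerances must name the same variables")
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be positive")
        if not 0 < self.max_suitability <= 1:
            raise ValueError("max_suitability must lie in (0, 1]")

    def suitability(self, env: dict[str, GridLayer]) -> GridLayer:
        """True suitability surface under this niche on the given climate."""
        first = next(iter(env.values()))
        s = np.full(first.spec.shape, self.max_suitability)
        mask = first.mask.copy()
        for name, opt in self.optima.items():
            layer = env[name]
            z = (layer.values - opt) / self.tolerances[name]
            s = s * np.exp(-0.5 * z**2)
            mask &= layer.mask
        return GridLayer(first.spec, s, mask)


@dataclass(frozen=True)
class PanelSpec:
    """Cultural-consensus data-generating model for an expert survey block."""

    competences: tuple[float, ...]
    truth: tuple[float, ...]
    sigma0: float = 2.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(not 0 <= c <= 1 for c in self.competences):
            raise ValueError("competences must lie in [0, 1]")
        if any(not 1 <= t <= 5 for t in self.truth):
            raise ValueError("truth scores must lie in [1, 5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_experts(self) -> int:
        return len(self.competences)

    @property
    def n_items(self) -> int:
        return len(self.truth)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float = 4.0) -> np.ndarray:
    """Spatially autocorrelated unit-variance noise (Gaussian-filtered white noise)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="nearest")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _apply_shift(values: np.ndarray, shift: tuple[str, float]) -> np.ndarray:
    op, amount = shift
    if op == "+":
        return values + amount
    if op == "x":
        return values * amount
    raise ValueError(f"unknown shift op {op!r}")


def gen_climate(
    spec: GridSpec,
    seed: int,
    noise_sd: float = 0.3,
    shifts_rcp45: dict | None = None,
    shifts_rcp85: dict | None = None,
) -> dict[str, dict[str, GridLayer]]:
    """Current climate plus two future scenarios.

    The current surfaces are smooth latitudinal gradients (hotter and drier
    to the north, like the Sahelian-to-Sudanian rainfall gradient) with
    low-amplitude spatially correlated noise.  Futures apply the configured
    per-variable shifts to the current fields, so scenario differences are
    exactly the configured shifts.
    """
    rng = np.random.default_rng(seed)
    shifts_rcp45 = RCP45_SHIFTS if shifts_rcp45 is None else shifts_rcp45
    shifts_rcp85 = RCP85_SHIFTS if shifts_rcp85 is None else shifts_rcp85

    _, lat = spec.cell_centers()
    south, north = lat.min(), lat.max()
    t = (lat - south) / max(north - south, 1e-12)  # 0 at south edge, 1 at north

    base = {
        "BIO1": 26.0 + 3.0 * t,        # deg C, warmer north
        "BIO3": 60.0 + 10.0 * t,       # %, higher isothermality north
        "BIO5": 36.0 + 4.0 * t,        # deg C
        "BIO12": 1100.0 - 700.0 * t,   # mm/yr, drier north
        "BIO13": 260.0 - 150.0 * t,    # mm
        "BIO14": 12.0 - 10.0 * t,      # mm
        "LLDS": 150.0 + 90.0 * t,      # days
        "PET": 1600.0 + 300.0 * t,     # mm/yr
    }
    # Noise amplitude per variable at the reference noise_sd of 0.3, chosen
    # as roughly a tenth of each gradient's range.
    amplitude = {
        "BIO1": 0.4, "BIO3": 1.2, "BIO5": 0.5, "BIO12": 70.0,
        "BIO13": 15.0, "BIO14": 1.0, "LLDS": 9.0, "PET": 30.0,
    }

    current: dict[str, GridLayer] = {}
    for name in CLIMATE_VARIABLES:
        noise = _smooth_noise(rng, spec.shape) * amplitude[name] * (noise_sd / 0.3)
        current[name] = GridLayer(spec, base[name] + noise)

    def project(shifts: dict) -> dict[str, GridLayer]:
        out = {}
        for name, layer in current.items():
            vals = layer.values
            if name in shifts:
                vals = _apply_shift(vals, shifts[name])
            out[name] = GridLayer(spec, vals, layer.mask.copy())
        return out

    return {"current": current, "rcp45": project(shifts_rcp45), "rcp85": project(shifts_rcp85)}


def gen_occurrences(
    niche: NicheSpec,
    env: dict[str, GridLayer],
    n: int,
    seed: int,
    species: str = "synthetic_species",
) -> pd.DataFrame:
    """Occurrence records sampled cell-wise with probability proportional to
    the true niche suitability; duplicates collapse to unique cell records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = niche.suitability(env)
    probs = np.where(truth.mask, truth.values, 0.0).ravel()
    total = probs.sum()
    if total <= 0:
        raise ValueError("niche has zero suitability everywhere on the grid")
    rng = np.random.default_rng(seed)
    idx = rng.choice(probs.size, size=n, replace=True, p=probs / total)
    rows, cols = np.unravel_index(np.unique(idx), truth.spec.shape)
    lons = truth.spec.cell_center_lons()[cols]
    lats = truth.spec.cell_center_lats()[rows]
    return pd.DataFrame(
        {"species": species, "lon": lons, "lat": lats, "source": "synthetic"}
    )


def gen_provinces(spec: GridSpec, n_x: int = 4, n_y: int = 3) -> GridLayer:
    """Axis-aligned partition of the grid into ``n_x * n_y`` integer-coded
    'provinces' (only per-province totals matter downstream)."""
    rows = np.minimum(np.arange(spec.n_rows) * n_y // spec.n_rows, n_y - 1)
    cols = np.minimum(np.arange(spec.n_cols) * n_x // spec.n_cols, n_x - 1)
    ids = rows[:, None] * n_x + cols[None, :]
    return GridLayer(spec, ids.astype(float))


def gen_threat_inputs(spec: GridSpec, seed: int, n_fires: int = 400, n_mines: int = 12) -> dict:
    """All non-climate threat inputs on the given grid.

    Footprint is 0-100 with a handful of urban hotspots; livestock densities
    are right-skewed (lognormal) with a north-heavy gradient; fire detections
    span November-March with uniform 0-100 confidence; cotton occupies a
    contiguous south-west block of provinces; mining points are sparse.
    """
    rng = np.random.default_rng(seed)
    west, east, south, north = spec.extent()
    lonc, latc = spec.cell_centers()

    # Human footprint: background + smooth field + urban hotspots.
    foot = 15.0 + 12.0 * _smooth_noise(rng, spec.shape, sigma_cells=6)
    n_cities = 5
    for _ in range(n_cities):
        r = rng.integers(0, spec.n_rows)
        c = rng.integers(0, spec.n_cols)
        rr, cc = np.ogrid[: spec.n_rows, : spec.n_cols]
        dist2 = (rr - r) ** 2 + (cc - c) ** 2
        foot = foot + 70.0 * np.exp(-dist2 / (2 * 5.0**2))
    footprint = GridLayer(spec, np.clip(foot, 0.0, 100.0))

    # Livestock: lognormal heads/cell, denser toward the north.
    t = (latc - latc.min()) / max(latc.max() - latc.min(), 1e-12)
    livestock = {}
    for name, mu in (("cattle", 3.0), ("goats", 3.3), ("sheep", 3.2)):
        field_ = np.exp(
            mu + 0.8 * t + 0.9 * _smooth_noise(rng, spec.shape, sigma_cells=3)
            + 0.5 * rng.standard_normal(spec.shape)
        )
        livestock[name] = GridLayer(spec, field_)

    # Fire detections: Nov-Mar season, biased toward the wetter south.
    fire_lon = rng.uniform(west, east, n_fires)
    p_south = 0.75
    u = rng.uniform(size=n_fires)
    fire_lat = np.where(
        u < p_south,
        rng.uniform(south, south + 0.5 * (north - south), n_fires),
        rng.uniform(south + 0.5 * (north - south), north, n_fires),
    )
    months = rng.choice([11, 12, 1, 2, 3], size=n_fires, p=[0.2, 0.2, 0.25, 0.2, 0.15])
    years = rng.integers(2007, 2013, size=n_fires)
    days = rng.integers(1, 29, size=n_fires)
    dates = pd.to_datetime(
        {"year": years, "month": months, "day": days}
    )
    fire_events = pd.DataFrame(
        {
            "lon": fire_lon,
            "lat": fire_lat,
            "date": dates,
            "confidence": rng.uniform(0, 100, n_fires),
        }
    )

    # Cotton: contiguous south-west block of provinces.
    province_map = gen_provinces(spec)
    pid = province_map.values.astype(int)
    n_provinces = pid.max() + 1
    sw_provinces = sorted(
        np.unique(pid[spec.n_rows // 2 :, : spec.n_cols // 2]).tolist()
    )
    cotton_cells = np.isin(pid, sw_provinces)
    # thin to a subset of cells within those provinces
    cotton_cells &= rng.uniform(size=spec.shape) < 0.6
    production = np.zeros(n_provinces)
    for p in sw_provinces:
        if (cotton_cells & (pid == p)).any():
            production[p] = rng.uniform(50.0, 300.0)
    cotton_stats = pd.DataFrame(
        {"province": np.arange(n_provinces), "production": production}
    )

    # Mining: sparse points, mixed status.
    mine_lon = rng.uniform(west, east, n_mines)
    mine_lat = rng.uniform(south, north, n_mines)
    status = rng.choice(["active", "prospect", "inactive"], size=n_mines, p=[0.5, 0.25, 0.25])
    mining_points = pd.DataFrame({"lon": mine_lon, "lat": mine_lat, "status": status})

    return {
        "footprint": footprint,
        "cattle": livestock["cattle"],
        "goats": livestock["goats"],
        "sheep": livestock["sheep"],
        "fire_events": fire_events,
        "cotton_mask": GridLayer(spec, cotton_cells.astype(float)),
        "cotton_stats": cotton_stats,
        "province_map": province_map,
        "mining_points": mining_points,
    }


def gen_expert_panel(panel: PanelSpec, seed: int) -> pd.DataFrame:
    """Experts x items rating matrix under the consensus model.

    rating(i, j) = round(clamp(truth_j + eps_ij, 1, 5)) with
    eps_ij ~ Normal(0, (sigma0 * (1 - competence_i))^2); entries are then
    dropped independently at ``missing_rate`` (NaN).
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(panel.truth, dtype=float)
    comp = np.asarray(panel.competences, dtype=float)
    noise = rng.standard_normal((panel.n_experts, panel.n_items)) * (
        panel.sigma0 * (1.0 - comp)[:, None]
    )
    ratings = np.clip(np.round(truth[None, :] + noise), 1, 5)
    if panel.missing_rate > 0:
        drop = rng.uniform(size=ratings.shape) < panel.missing_rate
        ratings = np.where(drop, np.nan, ratings)
    return pd.DataFrame(
        ratings,
        index=[f"expert_{i + 1}" for i in range(panel.n_experts)],
        columns=[f"item_{j + 1}" for j in range(panel.n_items)],
    )


def default_niches(env: dict[str, GridLayer], n_species: int = 3) -> dict[str, NicheSpec]:
    """A small set of contrasting niches spanning the synthetic climate space."""
    bio1 = env["BIO1"].masked_values()
    bio12 = env["BIO12"].masked_values()
    t_lo, t_hi = np.percentile(bio1, [20, 80])
    p_lo, p_hi = np.percentile(bio12, [20, 80])
    anchors = [
        (t_lo, p_hi),  # cool & wet (southern)
        (t_hi, p_lo),  # hot & dry (Sahelian)
        ((t_lo + t_hi) / 2, (p_lo + p_hi) / 2),  # transitional
    ]
    niches = {}
    for k in range(n_species):
        topt, popt = anchors[k % len(anchors)]
        niches[f"species_{chr(ord('A') + k)}"] = NicheSpec(
            optima={"BIO1": float(topt), "BIO12": float(popt)},
            tolerances={"BIO1": float(bio1.std() * 0.8), "BIO12": float(bio12.std() * 0.8)},
        )
    return niches
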