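"""End-to-end orchestration: synthetic demo runs and user-data runs.

The full chain is: climate stacks -> per-species ensemble suitability (four
candidate map variants: two predictor subsets x two presence thresholds) ->
expert-consensus selection of the best variant and per-threat sensitivity
scores -> six per-threat class layers -> combined map, per-class area
summaries, hotspot and richness maps.  ``run_all`` drives the whole chain
from a :class:`RunConfig` and writes text rasters (.asc), summary CSVs and
a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combine as cmb
from . import consensus as cns
from . import sdm, synthetic, threats
from .grid import ClassLayer, GridLayer, GridSpec
from .raster_io import write_ascii_grid

logger = logging.getLogger(__name__)

THREAT_NAMES = ("overexploitation", "overgrazing", "fire", "cotton", "mining", "climate")
SENSITIVITY_THREATS = ("overexploitation", "overgrazing", "fire")

#: The four distribution-map variants offered to the expert panel:
#: (predictor subset, threshold rule).
SDM_VARIANTS = (
    ("all_vars", "tpr90"),
    ("all_vars", "minimum"),
    ("pruned", "tpr90"),
    ("pruned", "minimum"),
)


@dataclass
class RunConfig:
    """Run parameters; the numeric defaults are the study's printed values."""

    out_dir: str = "runs/demo"
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(
        n_rows=60, n_cols=80, origin_lon=-6.0, origin_lat=15.5
    ))
    n_species: int = 3
    n_experts: int = 15
    n_background: int = sdm.DEFAULT_N_BACKGROUND
    n_folds: int = sdm.DEFAULT_N_FOLDS
    n_repeats: int = sdm.DEFAULT_N_REPEATS
    vif_threshold: float = sdm.DEFAULT_VIF_THRESHOLD
    min_unique_obs: int = sdm.MIN_UNIQUE_OBSERVATIONS
    n_occurrences: int = 200
    sensitivity_normalization: str = "affine"
    late_fire_months: tuple[int, ...] = (1, 2, 3)
    fire_years: tuple[int, int] = (2007, 2012)

    def __post_init__(self) -> None:
        for name in ("n_background", "n_folds", "n_repeats", "min_unique_obs",
                     "n_occurrences", "n_species", "n_experts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def manifest(self) -> dict:
        d = asdict(self)
        d["grid"] = asdict(self.grid)
        blob = json.dumps(d, sort_keys=True, default=str)
        d["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return d


@dataclass
class SpeciesResult:
    species: str
    best_variant: str
    sensitivities: pd.Series
    distribution: GridLayer
    threat_maps: dict[str, ClassLayer]
    combined: ClassLayer
    severe_by_threat: pd.Series
    combined_percentages: pd.Series


def validate_inputs(
    occurrences: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    fire_events: pd.DataFrame | None = None,
) -> list[str]:
    """Schema checks on the tabular inputs; returns violations (non-fatal)."""
    violations: list[str] = []
    if occurrences is not None:
        for col in ("species", "lon", "lat"):
            if col not in occurrences.columns:
                violations.append(f"occurrences: missing column '{col}'")
        if "lon" in occurrences and ((occurrences["lon"].abs() > 180).any()):
            violations.append("occurrences: longitude outside [-180, 180]")
        if "lat" in occurrences and ((occurrences["lat"].abs() > 90).any()):
            violations.append("occurrences: latitude outside [-90, 90]")
    if ratings is not None:
        vals = ratings.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 1) | (finite > 5)).any():
            violations.append("ratings: values outside the 1-5 scale")
    if fire_events is not None:
        for col in ("lon", "lat", "date", "confidence"):
            if col not in fire_events.columns:
                violations.append(f"fire_events: missing column '{col}'")
        if "confidence" in fire_events and (
            (fire_events["confidence"] < 0) | (fire_events["confidence"] > 100)
        ).any():
            violations.append("fire_events: confidence outside [0, 100]")
    return violations


def _species_seed(base: int, k: int, salt: int) -> int:
    return (base * 1009 + k * 97 + salt) % (2**31 - 1)


def _expert_truth_for_variants(best_index: int, rng: np.random.Generator) -> np.ndarray:
    """Latent 1-5 quality of the four SDM variants with one clear winner."""
    truth = rng.uniform(1.5, 3.0, size=4)
    truth[best_index] = rng.uniform(4.0, 4.8)
    return truth


def run_all(config: RunConfig) -> dict:
    """Synthetic end-to-end run; returns the in-memory artifact bundle and
    writes rasters, summary CSVs and the run manifest under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    spec = config.grid

    logger.info("generating synthetic climate and threat inputs")
    climate = synthetic.gen_climate(spec, seed=_species_seed(config.seed, 0, 1))
    inputs = synthetic.gen_threat_inputs(spec, seed=_species_seed(config.seed, 0, 2))
    niches = synthetic.default_niches(climate["current"], config.n_species)

    # Generic threat intensities shared by all species.
    over_int = threats.overexploitation_intensity(inputs["footprint"], spec)
    tlu_layer = threats.tlu(inputs["cattle"], inputs["goats"], inputs["sheep"])
    graze_int = threats.overgrazing_intensity(tlu_layer)
    freq = threats.fire_frequency(
        inputs["fire_events"], spec, config.fire_years,
        late_months=frozenset(config.late_fire_months),
    )
    fire_int = threats.fire_intensity(freq)
    cotton_int = threats.cotton_intensity(
        inputs["cotton_stats"], inputs["cotton_mask"], inputs["province_map"]
    )
    mining = threats.mining_class(inputs["mining_points"], spec)

    pruned = sdm.vif_stepwise(climate["current"], config.vif_threshold)
    variable_sets = {"all_vars": list(synthetic.CLIMATE_VARIABLES), "pruned": pruned}

    results: dict[str, SpeciesResult] = {}
    presence_by_species: dict[str, GridLayer] = {}
    combined_by_species: dict[str, ClassLayer] = {}

    for k, (species, niche) in enumerate(niches.items()):
        logger.info("species %s: occurrences and ensemble calibration", species)
        occ = synthetic.gen_occurrences(
            niche, climate["current"], config.n_occurrences,
            seed=_species_seed(config.seed, k, 3), species=species,
        )

        models = {}
        fitted_by_subset: dict[str, sdm.EnsembleModel] = {}
        for v_idx, (subset, threshold) in enumerate(SDM_VARIANTS):
            if subset not in fitted_by_subset:
                fitted_by_subset[subset] = sdm.calibrate_ensemble(
                    occ, climate["current"], variable_sets[subset],
                    n_background=config.n_background, n_folds=config.n_folds,
                    n_repeats=config.n_repeats, min_unique_obs=config.min_unique_obs,
                    seed=_species_seed(config.seed, k, 100 + v_idx),
                )
            models[f"{subset}:{threshold}"] = (fitted_by_subset[subset], threshold)

        # Expert evaluation of the four variants under the consensus model.
        best_true = int(rng.integers(0, 4))
        panel_spec = synthetic.PanelSpec(
            competences=tuple(np.linspace(0.3, 0.95, config.n_experts)),
            truth=tuple(_expert_truth_for_variants(best_true, rng)),
            missing_rate=0.1,
        )
        ratings = synthetic.gen_expert_panel(
            panel_spec, seed=_species_seed(config.seed, k, 4)
        )
        ratings.columns = list(models)
        sdm_consensus = cns.analyze_panel(ratings)
        best_variant = sdm_consensus.select_best()
        model, threshold = models[best_variant]

        distribution = sdm.predict_presence(model, which_threshold=threshold)
        presence_by_species[species] = distribution

        # Threat-sensitivity survey block for this species.
        sens_spec = synthetic.PanelSpec(
            competences=panel_spec.competences,
            truth=tuple(rng.uniform(1.5, 4.6, size=len(SENSITIVITY_THREATS))),
            missing_rate=0.1,
        )
        sens_ratings = synthetic.gen_expert_panel(
            sens_spec, seed=_species_seed(config.seed, k, 5)
        )
        sens_ratings.columns = list(SENSITIVITY_THREATS)
        sens_consensus = cns.analyze_panel(sens_ratings)
        sens_norm = cns.normalize_sensitivities(
            sens_consensus.scores, config.sensitivity_normalization
        )

        # Future scenario presence and novelty for the climate threat.
        pres45 = sdm.predict_presence(model, climate["rcp45"], threshold)
        pres85 = sdm.predict_presence(model, climate["rcp85"], threshold)
        novel45 = sdm.detect_novel(climate["current"], climate["rcp45"], model.retained_variables)
        novel85 = sdm.detect_novel(climate["current"], climate["rcp85"], model.retained_variables)
        climate_cls = threats.climate_class(pres45, pres85, novel45, novel85)

        threat_maps = {
            "overexploitation": cmb.species_threat_map(
                over_int, float(sens_norm["overexploitation"]), distribution
            ),
            "overgrazing": cmb.species_threat_map(
                graze_int, float(sens_norm["overgrazing"]), distribution
            ),
            "fire": cmb.species_threat_map(
                fire_int, float(sens_norm["fire"]), distribution
            ),
            "cotton": cmb.species_threat_map(cotton_int, 1.0, distribution),
            "mining": ClassLayer(
                spec, mining.classes,
                mining.mask & (distribution.values > 0) & distribution.mask,
            ),
            "climate": ClassLayer(
                spec, climate_cls.classes,
                climate_cls.mask & (distribution.values > 0) & distribution.mask,
            ),
        }
        combined = cmb.combine_threats([threat_maps[t] for t in THREAT_NAMES])
        combined_by_species[species] = combined
        severe, pct = cmb.scope_table(threat_maps, combined)

        results[species] = SpeciesResult(
            species=species,
            best_variant=best_variant,
            sensitivities=sens_consensus.scores,
            distribution=distribution,
            threat_maps=threat_maps,
            combined=combined,
            severe_by_threat=severe,
            combined_percentages=pct,
        )

        for threat, layer in threat_maps.items():
            write_ascii_grid(layer, out / f"{species}_{threat}.asc")
        write_ascii_grid(combined, out / f"{species}_combined.asc")
        write_ascii_grid(distribution, out / f"{species}_presence.asc")

    hotspots = cmb.hotspot_map(combined_by_species)
    richness = cmb.richness_map(presence_by_species)
    write_ascii_grid(hotspots, out / "hotspots.asc")
    write_ascii_grid(richness, out / "richness.asc")

    severe_table = pd.DataFrame(
        {s: r.severe_by_threat for s, r in results.items()}
    ).T.round(1)
    combined_table = pd.DataFrame(
        {s: r.combined_percentages for s, r in results.items()}
    ).T.round(1)
    severe_table.to_csv(out / "severe_by_threat.csv", index_label="species")
    combined_table.to_csv(out / "combined_classes.csv", index_label="species")

    manifest = config.manifest()
    manifest["species"] = {s: r.best_variant for s, r in results.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "results": results,
        "hotspots": hotspots,
        "richness": richness,
        "severe_table": severe_table,
        "combined_table": combined_table,
        "manifest": manifest,
    }
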