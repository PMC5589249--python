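# Methods

This note documents the models and procedures implemented in `threatscape`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Analysis grid

All layers live on one geographic (lat/lon) grid, cell-registered at the
north-west corner with row 0 northernmost; the default cell is 2.5
arc-minutes (~4.5 km at the equator). Every input is forced onto this grid
before raster arithmetic: mixed-resolution inputs are resampled by bilinear
interpolation of cell centers, with target cells outside the source's
center envelope (or touching masked-out source cells) masked out. Point
records fall into cells under a half-open membership rule — [west, east) in
longitude, (south, north] in latitude — so a point on a shared edge lands
in exactly one cell, deterministically.

Cell areas are available in two modes: *geodesic*
(cell° · 111.32 km · cos φ × cell° · 111.32 km) and *nominal*, which uses
the conventional 4.5 km side (20.25 km² for a 2.5′ cell) independent of
latitude. Fire frequencies default to the nominal area so that per-km²
rates match figures quoted at that rounding; the geodesic mode is there for
work where the ~4% equator-to-15°N distortion matters.

Rasters are serialized as ESRI ASCII grids (`.asc`): a plain-text,
GIS-readable format. Class layers use nodata 255, float layers −9999.

Min–max normalization is computed over the study-area mask per layer. A
constant layer normalizes to all zeros with a logged warning rather than
erroring, so degenerate synthetic inputs flow through the pipeline. The
human-footprint layer is normalized the same way as the other quantitative
layers for uniformity, rather than divided by its native 0–100 range; with
a footprint layer spanning its full range the two coincide.

## Synthetic study area

The generator emulates the statistical structure each downstream stage
relies on, not any real geography:

- **Climate**: eight bioclimatic surfaces (BIO1, BIO3, BIO5, BIO12, BIO13,
  BIO14, longest-dry-season length, PET) as smooth latitudinal gradients —
  hotter and drier northward, like the Sahelian-to-Sudanian transition —
  plus spatially autocorrelated noise (Gaussian-filtered white noise, ~10%
  of each gradient's range). Future scenarios apply per-variable shifts to
  the current fields (defaults: +1.5 °C BIO1 and −10% precipitation for the
  moderate scenario; +3.0 °C and −20% for the high-emission scenario, with
  proportional shifts for the remaining variables), so scenario differences
  are exactly the configured shifts and the high-emission change dominates
  cell-wise by construction.
- **Occurrences**: cells are drawn with probability proportional to a known
  Gaussian niche (per-variable optimum and tolerance, multiplied across
  variables); duplicates collapse to unique cell records. The truth surface
  is retained so the ensemble can be scored on parameter recovery.
- **Threat inputs**: a 0–100 footprint with urban hotspots; lognormal
  (right-skewed) livestock densities with a north-heavy gradient; fire
  detections spanning November–March with uniform 0–100 confidence; cotton
  confined to a contiguous south-west block of axis-aligned "provinces"
  (only per-province totals matter downstream); sparse mining points with
  active/prospect/inactive status.
- **Expert panels**: rating(i, j) = round(clamp(truth_j + ε_ij, 1, 5)) with
  ε_ij ~ N(0, (σ₀ (1 − competence_i))²), σ₀ = 2.0, and independent dropout
  at the configured missing rate.

All generators are pure functions of (parameters, seed).

What the generator does *not* emulate: real spatial autocorrelation
structure, road networks, realistic livestock magnitudes (the lognormal
tail can exceed observed TLU ranges; only the post-sqrt relative pattern
matters downstream), or inter-variable climate covariance beyond the shared
latitudinal driver. Passing recovery tests therefore show the estimators
invert the assumed generative structure — they do not validate the method
against real field data.

A subtlety of the expert model: because ratings are clamped to the 1–5
scale, an expert with competence 0 is *attenuated*, not uncorrelated —
clamping preserves some ordering information (measured Spearman against
truth ≈ 0.5 at σ₀ = 2). Competence estimation still separates good from bad
informants (recovery ≈ 0.8 on average; see below), but absolute weights for
incompetent experts do not shrink to zero.

## Ensemble distribution model

- **Collinearity pruning**: stepwise VIF elimination at ceiling 20. VIFs
  are computed by ordinary least squares of each variable on the rest over
  masked cells; perfectly collinear variables get infinite VIF and drop
  first. Retained sets always satisfy max VIF ≤ 20 (re-verified by
  brute-force regression in the tests).
- **Candidates**: a pluggable registry of 12 algorithms — logistic
  regression (linear), logistic with quadratic terms, spline-basis additive
  logistic, classification tree, random forest, gradient-boosted trees,
  k-nearest-neighbours, Gaussian naive Bayes, a rectilinear
  percentile-envelope model, a Mahalanobis-distance envelope, a quadratic
  flexible discriminant on polynomial features, and a small neural network.
  Each exposes fit(X, y) on presence/background rows and score(X) → [0, 1].
- **Calibration**: per repeat, 2000 background cells are sampled without
  replacement from masked cells *excluding* presence cells (avoiding label
  noise at the scale of the analysis; if fewer are available, all are
  used). Presences and backgrounds are split into 4 random folds; each
  candidate is fit on 3 folds and scored on the held-out fold by
  Mann–Whitney AUC; fold AUCs are averaged, then averaged over 5 repeats.
  A candidate that raises an error scores AUC 0 and cannot be retained; if
  fewer than 10 survive, the survivors' weights are renormalized (logged).
  Ties at the retention cut break by registry order, deterministically.
- **Prediction**: each repeat's kept candidates are refit on that repeat's
  full data; the ensemble surface is their AUC-weighted average, and the
  final suitability is the mean over repeats. Future projection scores a
  new climate stack with the same fitted candidates and weights.
- **Thresholds** are computed once, on the final averaged surface (rather
  than per repeat and averaged): *minimum* is the smallest presence score;
  *tpr90* is the largest threshold retaining ≥ 90% of presence scores,
  computed directly on the unique score values (for n presences this is the
  (⌊0.1 n⌋+1)-th smallest score). By construction the minimum threshold
  covers all training presences and tpr90 covers at least 90%.
- **Species rule**: fewer than 30 unique presence cells raises
  `SpeciesRejected` naming the rule.
- **Novel climate**: a cell is novel iff at least one variable's future
  value falls strictly outside the closed current min–max range over the
  reference mask (default: the full valid calibration extent).

Four candidate distribution maps per species come from the config matrix
{all 8 variables, VIF-pruned subset} × {minimum, tpr90}; one calibration
per predictor subset serves both thresholds.

Measured on the default synthetic niche (200 presences, 60×80 grid, default
configuration), Spearman correlation between ensemble suitability and the
generating truth is ≈ 0.96, and exactly 10 of the 12 candidates carry
weight.

## Expert consensus

Pairwise-complete Spearman correlations between experts (minimum overlap 2
items; ties use average ranks; zero-variance experts yield undefined
correlations and are flagged). Experts with fewer than 2 usable ratings are
dropped and excluded from the valid-expert count.

Competence weights are the loadings of a **one-factor maximum-likelihood
factor analysis** of the correlation matrix: Σ = λλ′ + diag(1 − λ²), fit by
L-BFGS-B on the standard ML discrepancy log|Σ| + tr(RΣ⁻¹) − log|R| − p with
loadings bounded in (−1, 1), started from the principal eigenvector. The
sign is fixed so the loading sum is positive, and negative loadings are
floored at 0 (an anti-consensus expert gets no voice). Missing correlations
are imputed with the mean of the two experts' available off-diagonal
correlations. On non-convergence the principal-eigenvector loadings are
used (logged); with fewer than 3 experts the fallback is each expert's mean
correlation with the others, floored at 0. The implementation reproduces
the closed-form compound-symmetry solution (all off-diagonals ρ → loadings
√ρ) to 4 decimals. Loadings (not squared loadings) are used as weights, the
standard choice in consensus analysis; the first factor's variance share is
reported as the consensus rate, and the mean weight over valid experts as
the average concordance.

Item scores are weight-normalized means over the experts who rated each
item; scores are invariant to positive rescaling of the weights and stay in
[1, 5]. Best-item selection is argmax with ties going to the lowest item
index (logged).

Sensitivity scores are normalized to [0, 1] as (S − 1)/4 by default,
mapping the ends of the printed 1–5 scale to 0 and 1; S/5 and min–max over
the score set are available as configuration because the choice is not
uniquely determined by the magnitude-rating scale and materially shifts how
much of a species' range reaches the top classes.

Consensus is run separately per species and per survey block (the four
distribution-map items; the three threat-sensitivity items), so expert
counts and concordance are reported per species and block.

## Threat layers

- **Overexploitation**: footprint resampled to the analysis grid, min–max
  normalized; species-specific (sensitivity-weighted).
- **Overgrazing**: TLU = 0.7·cattle + 0.1·goats + 0.1·sheep per cell;
  square-root transform (the distribution is heavily right-skewed) then
  min–max; species-specific.
- **Fire**: detections with confidence ≤ 30% discarded (strictly-above
  rule); weight 2 for late-season months (default January–March — the peak
  of the dry season; configurable) and 1 otherwise, including any event
  outside a nominal fire season (conservative); events outside the year
  window dropped with a logged count; per cell, weighted count divided by
  (years × cell area in km²); then sqrt + min–max. Frequencies are computed
  directly on the analysis grid rather than on a ~1 km detection grid first
  — at the analysis resolution the two differ only through the resampling
  kernel.
- **Cotton**: province production split equally over that province's
  cotton cells (a cotton cell whose province lacks a statistics record is
  an error); the allocation conserves province totals before normalization;
  classification capped at 'High' because the source map cannot resolve
  production peaks. Absolute production units do not affect classes — only
  the post-normalization relative pattern does.
- **Mining**: any cell holding ≥ 1 active site or prospect is 'Very high',
  everything else 'No threat'; one coarse pixel covers the degraded
  surroundings, so no spreading or intermediate classes.
- **Climate**: ordered decision rules (see below); enters combination as a
  class layer directly, as does mining — neither is sensitivity-weighted,
  since both act on habitat regardless of species identity.

### Climate decision rules

The published rule list is overlapping as printed (a cell losing habitat
only under the high-emission scenario matches both a 'Very high' and a
'Low' phrasing). The implementation resolves this as an ordered rule list
anchored to the interpretation that the *moderate* scenario already
predicting unsuitable habitat is what warrants the top class:

1. RCP 4.5 predicts absence → Very high
2. both scenarios predict presence, both in novel climate → High
3. RCP 4.5 predicts presence in novel climate → Medium
4. RCP 4.5 presence, RCP 8.5 absence → Low
5. otherwise (both present, not both novel) → No threat

The full 16-case truth table is exercised in the tests against a literal
transcription of these rules; the three cases with unambiguous published
outcomes (both-present/no-novelty → No threat; RCP 4.5 absent → Very high;
both-present-both-novel → High) are asserted explicitly.

## Magnitude classification and combination

The five-class scale is printed to two decimals with gaps (0.1 vs 0.11).
Boundaries are placed at the midpoints 0.01, 0.105, 0.305, 0.705 with a
lower-exclusive/upper-inclusive convention, preserving the printed
two-decimal semantics exactly: 0.10 → Low, 0.11 → Medium, 0.70 → High,
0.71 → Very high. The classifier is total and monotone on [0, 1]; the
capped variant (cotton) never returns Very high.

The magnitude concept combines severity and geographic scope: severity is
the per-pixel class; scope is reported as area percentages. No pixel-level
scope multiplier is applied, consistent with producing per-pixel maps.

Combination takes the per-pixel maximum of six class layers and applies the
3–5 rule (≥ 3 Highs → Very high; else ≥ 5 Mediums → High). The
implementation is verified exhaustively against an independently coded
literal-rule oracle on all 5⁶ = 15 625 combinations, and is monotone: no
single input-class increase can lower the combined class.

Cells outside a species' distribution are unmasked (a threat is undefined
where the species is absent) and excluded from all percentages and from
hotspot counting. Per-threat summaries report the percentage of
distribution cells at severe level (High + Very high); combined summaries
report all five class percentages, which partition to 100% up to floating
rounding; severe% ≡ High% + Very high% by construction.

## Orchestration, determinism, problem sizes

`RunConfig` holds the method constants (2000 background points, 4 folds, 5
repeats, VIF ceiling 20, 30-observation minimum) as defaults. `run_all`
executes the synthetic end-to-end chain and writes class rasters, summary
CSVs and a JSON manifest (config hash, seed, chosen variant per species);
identical config + seed reproduce byte-identical summary CSVs. All
randomness flows through numpy `default_rng` seeded from the run seed;
stochastic sklearn candidates carry fixed random states, and candidate
ranking ties break by registry order, so runs are fully deterministic.

Stochastic checks in the test suite use a 60×80-cell study area with 200
presences for ensemble recovery and 50 panels of 15 experts × 12 items for
competence recovery — sizes at which the recovery statistics are stable
across seeds while the full default-configuration calibration (12
candidates × 5 repeats × 5 fits) completes in well under a minute. The
end-to-end pipeline test uses a 24×30 grid with 1 calibration repeat; the
ensemble demo in `examples/` uses 2 repeats and says so.

## Known limitations

- Candidate submodels are idiomatic scikit-learn implementations of the
  named algorithm families, not replicas of any particular SDM package's
  numerics; the ensemble weighting, retention and thresholding logic is
  what this package specifies.
- The one-factor consensus model assumes a single shared answer key per
  block; panels with genuine sub-cultures (multi-factor structure) will
  blur competence estimates.
- The sensitivity normalization is configurable because no single choice is
  canonical; downstream class shares depend on it.
- Novel-climate detection is a min–max envelope per variable; it ignores
  multivariate novelty (new combinations of individually seen values).
- Geographic cell areas use a spherical approximation; no projection
  support beyond geographic lat/lon.
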