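# Methods

## Count model and occupancy

Counts of one species at one station are modelled negative-binomial with
mean `μ·A` (true density μ in individuals m⁻², sampled area A in m², default
A = 2/112 m², i.e. two cores of 1/112 m²) and aggregation parameter `k`
(Poisson when `k = ∞`). The presence probability is

    ψ(μ, k, A) = 1 − (1 + μA/k)^(−k),      ψ(μ, ∞, A) = 1 − e^(−μA),

strictly increasing in `k` at fixed μ·A: clumping depresses occupancy at a
given density. Optional zero inflation (probability `p_zero` of a structural
zero per station) scales occupancy by `1 − p_zero` and models unsuitable
habitat for rare, patchy species.

The generator's closed-form regression target uses the exact,
distribution-free identity `E[count | count > 0] = μA / P(count > 0)`, so
the expected local mean density over occupied stations is `μ/ψ` and the
theoretical abundance–occupancy slope is the OLS slope of `log₁₀(μ/ψ)` on
`logit(ψ)` across a density gradient. Recovery tests compare pipeline
estimates against this target.

## Survey geometry and design

Stations sit on a square lattice with 0.5-km spacing, both extent edges
inclusive (a 2×2-km basin yields a 5×5 = 25-station grid), plus
`round(random_fraction × grid count)` extra stations placed uniformly on
randomly chosen gridlines (default fraction 0.175, the middle of the 15–20 %
design range). The default configuration has ten basins and eight yearly
campaigns; the easternmost basin is unsampled in the first campaign and the
final campaign is subsampled to 30 % of stations, reproducing the
unbalanced coverage such monitoring programmes show in practice. Default
basin extents give ≈ 1,150 stations per full campaign — a deliberately
down-scaled but structurally faithful version of a survey an order of
magnitude larger; extents scale linearly via one argument.

All randomness flows from a single seeded `numpy` generator in a documented
draw order (geometry, subsample selection, then counts and individuals per
year × species), so equal seeds give byte-identical tables.

## Individual masses and their failure modes

Masses follow `m = flesh_fraction · a·Lᵇ · exp(ε)`, lengths lognormal per
species, `ε ~ N(0, mass_cv²)` with default `mass_cv = 0.2` (residual spread
in log₁₀ units ≈ 0.087, residual IQR ≈ 0.12 — the scale at which a ×100
gross error, a 2-decade shift, is unambiguous). Three failure modes are
injected as disjoint fractions of individuals: gross outliers
(default 1 %, mass ×100, flagged in the truth column), missing mass
(default 2 %), and missing everything (mass and length/size class,
default 0.9 %, matching the removal rate such datasets show). Species styles:
`length` (bivalve-like, shell length recorded), `size_class`
(polychaete-like, only juvenile/adult recorded, classed by a length
threshold), `none` (no size information). Gastropod-style species carry
`flesh_fraction = 0.17` (shell and flesh ashed together); the generator
records flesh mass directly, so the pipeline's flesh-fraction step applies
only to external data and is guarded by a per-table applied flag against
double application.

## Quality control

Per species with lengths, a loess-type smoother of log₁₀ mass on log₁₀
length: local quadratic regression, tricube weights, span 0.75 (fraction of
nearest neighbours), no robustness iterations; above 1,000 distinct lengths
the smoother is evaluated on 1,000 quantile knots and linearly interpolated,
as standard loess implementations do. These settings are recorded in the
fitted curve for provenance and are configurable; with fewer than 30 paired
records the fit falls back to a global log–log power law (logged). Species
without lengths use the mean log₁₀ mass per size class (or per species) as
the reference.

The outlier rule is two-sided and strict: flag iff |log₁₀ residual| >
2 × IQR of the residuals, with the linear-interpolation quantile convention
throughout the package, plus a 1e-10 absolute floor on the threshold so an
exactly noise-free fit (IQR ≈ float epsilon) flags nothing. One pass only —
no re-fitting after replacement — but imputation references (class/species
means) exclude flagged records. Imputation: curve prediction at the
record's length (nearest-endpoint extrapolation outside the observed range,
logged); geometric mean of the size class; species geometric mean (outliers
only — a record of a classless species without a mass has nothing to impute
from and is removed). Internally all fits and means run on value-sorted
data, so flags and imputed values are independent of record order.

Choices left open by the QC design and resolved here: the rule is read as
two-sided (gross errors can be under- as well as over-estimates), "exceeds"
as strict inequality, and the smoother as local *quadratic* at span 0.75 —
common defaults, recorded in provenance, since exact replication of any
particular historical script is not claimed.

## Aggregation

Station × species tables are dense over visited stations × the species
universe (all species observed anywhere in the dataset): absence is a
statement about a visited station. Abundance = count/A; biomass =
Σ mass/A; presence is count-based. Scale summaries report
`occupancy = n_present / n_stations` and local means over occupied stations
only; units where the species is absent carry occupancy 0 and missing local
means. Unsampled basin-years are excluded from numerator and denominator
alike — including them as absences would bias both occupancy and the
≥ 6-years inclusion filter. The spatial scale reuses the basin × year
summaries regrouped per year: computed once, viewed twice.

## Regression models

Per analysis set: `y = log₁₀(local mean abundance or biomass)`,
`x = logit(occupancy)` in natural log. Zero handling follows the analysis
design: if any response is 0 (species absent in a unit), the smallest
positive response in the set is added to *all* responses (a uniform,
order-preserving shift); an occupancy of exactly 0 (or 1) is moved by
± 0.5/n of that unit's station count — only offending units are adjusted,
each with its own n. Adjustments are recorded in the fit provenance and are
zero when the set has no zeros (at the regional scale they rarely trigger).

OLS via statsmodels; R² = 1 − SSR/SST clipped to [0, 1]; RMSE = √(SSR/n) by
default (prediction-error reading), with √(SSR/(n−2)) exposed as an option
and named in every output row; `RMSE_bt = (10^RMSE − 1)·100` %. Slope
p-values are plain two-sided OLS t-tests (no heteroskedasticity correction),
α = 0.05. Degenerate sets (< 3 units, constant occupancy, all-zero
response) surface as skipped rows with reasons, never silent drops; a
perfect fit (SSR = 0) reports p = 0 and, when SST = 0 as well, R² = 1.
Classification uses strict comparisons at R² = 50 % and RMSE_bt = 50 %.
Medians and IQRs across basins (local) or years (spatial) use the same
quantile convention as QC.

## What the synthetic generator does and does not emulate

It reproduces the survey's sampling design (grid + random extras, basin
structure, unbalanced coverage), NB clumping per station, allometric mass
structure with realistic noise, gross outliers, missing data, and zero
inflation. It does **not** simulate spatially autocorrelated density
surfaces within basins, tidal-elevation covariates, species interactions,
temporal autocorrelation beyond the deterministic density trajectories, or
imperfect detection. Passing recovery tests therefore demonstrates that the
pipeline measures what the count model produces — not that real communities
satisfy that model.

## Problem sizes

Defaults keep every experiment desk-scale: the default survey ≈ 1,150
stations × 8 campaigns × 8 species (~125 k individuals, full pipeline in a
few seconds); occupancy consistency at 4,000 stations; slope recovery over
100–200 surveys of 4,000 stations × 8 years (tens of seconds); QC recovery
at ~2,000 individuals per replicate. These are the package's chosen
experiment sizes and all scale up through configuration.

## Known limitations

- The loess smoother is a fresh implementation (local quadratic, tricube,
  span as nearest-neighbour fraction) — numerically close to, but not
  bit-identical with, other loess variants; cross-checked in the tests
  against an independent per-point weighted-least-squares oracle.
- With heavy mass ties (many identical lengths) the bandwidth can collapse
  to zero; the smoother then falls back to the local mean at that point.
- `R²` of a zero-variance response is defined as 1 (perfectly predicted by
  the mean); other conventions return NaN.
- The ≥ 6-years filter counts observation years without reference to the
  number of *sampled* years, so a basin sampled only six times and occupied
  each time passes; an alternative proportional rule is not implemented.
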