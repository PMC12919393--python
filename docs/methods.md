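# Methods

This note documents the models implemented in `soilpte`, the defaults they
ship with, the numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Scope and data model

The package analyses soil surveys of nine potentially toxic elements
(Hg, As, Zn, Pb, Co, Cd, Ni, Cr, Cu; this ordering is fixed for every
matrix layout) over five land-use classes (coal mine CM, agricultural AG,
residential RD, forest FT, roadside RS).  The canonical container is a
validated pandas DataFrame (`SoilDataset`) with planar coordinates in
metres, six continuous physicochemical covariates, three categoricals
(land use, texture, depth class) and one concentration column per element
in mg kg⁻¹, plus optional below-detection-limit flags.  All I/O is
delimited text at ≥ 12 significant digits, so read/write round trips
preserve values to far better than 1e-9 relative.

Reference tables (geochemical backgrounds, Hakanson toxic-response
coefficients, guideline values, method detection limits) ship as YAML and
are overridable per key; a standalone (non-merging) mode requires a
complete table and rejects missing elements.  The toxic-response defaults
are the Hakanson coefficients (Hg 40, Cd 30, As 10, Pb = Cu = Ni = Co 5,
Cr 2, Zn 1); they are an assumption of convention, not a site-specific
calibration.

## Pollution and ecological indices

Per sample and element: CF = C/Bₙ; Igeo = log₂(C/(1.5 Bₙ)) (the 1.5 factor
buffers natural background fluctuation); ER = Tᵣ·CF.  Per sample:
PLI = (∏ CF)^(1/9) and PERI = Σ ER.  Classification bands follow the
Müller (Igeo, 7 classes), Hakanson (ER, PERI) and Tomlinson (PLI ≤ 1
unpolluted) conventions, with CF banded low/moderate/considerable/severe;
all interval boundaries are lower-closed, and an operational CF > 5
"severe contamination" screen is reported separately per land use as a
percentage of samples.  Zero concentrations are rejected for Igeo/PLI
unless an MDL substitution policy (value as reported, MDL/2, or MDL) is
applied first — a geometric mean is meaningless with zeros.

## Positive matrix factorization

The receptor model X ≈ G F (G n×k ≥ 0 site contributions, F k×9 ≥ 0
profiles) minimises Q = Σ ((x−GF)/u)².  Design choices:

- **Uncertainties.** u = √((EF·c)² + (0.5·MDL)²) above the detection
  limit, u = ⅚·MDL at or below it; EF defaults to 0.1 per element
  (config-overridable).  Elements flagged "weak" carry tripled
  uncertainty.  A cell at or below an MDL of zero is an error (it would
  get zero uncertainty and infinite weight).
- **Optimiser.**  Multiplicative updates adapted to element-wise weights
  1/u² (the weighted Lee–Seung rules).  They preserve non-negativity and
  are monotone in Q; the per-iteration Q history is retained and the
  monotonicity is asserted in tests.  Convergence: relative ΔQ < 1e-8
  (default), max 20,000 iterations; 20 random starts by default, best Q
  kept, all seeds derived from one `SeedSequence` so fits are bitwise
  reproducible.
- **Robust mode** (default on): after a converged sweep, cells with
  |e/u| > 4 get effective uncertainty |e|/4 and the fit resumes, up to
  five reweighting rounds.  The reported Q is measured against the final
  effective uncertainties (`Q_true` against the inputs), so the
  independent-oracle identity Q = q_value(X, GF, U_eff) holds exactly.
- **Scale convention.**  `PMFSolution.normalized()` rescales G columns to
  mean one and F rows inversely, leaving GF and Q unchanged; profiles then
  carry concentration units and the mean-one contributions are the
  quantity mapped by kriging.
- **Factor count.**  Each k in the candidate range is fit and the smallest
  k whose Q/Q_expected (Q_expected = nm − k(n+m)) lies within 10% of the
  range minimum is selected, with a 1e-3 absolute floor so that near-exact
  fits (noise-free data, Q ≈ 0) count as ties and the smallest adequate k
  wins rather than the largest.
- **Diagnostics.**  Bootstrap: rows resampled with replacement, refit
  warm-started from the base solution, factors mapped back by Hungarian
  assignment on cosine similarity (mapped when ≥ 0.6); the percentage of
  runs mapping each factor is reported, degenerate all-identical resamples
  are skipped and counted.  Displacement: the strongest profile entry of
  each factor is displaced up/down by grid fractions (default 10% and
  25%), the model refit with the entry held, and the probe records the
  relative *drop* in Q (a drop means the base was not the optimum) and
  whether factor identities survive re-matching; stable means max drop
  < 1% and zero swaps.  The drop denominator is floored at one
  scaled-residual unit so near-zero-Q bases do not produce spurious
  percentages.  These are deliberately simplified re-implementations of
  the EPA BS/DISP ideas, not the full ME-2 displacement machinery.
- **Outlier pre-screen.**  An optional interquartile-range filter flags
  samples with any element outside [Q1 − 1.5 IQR, Q3 + 1.5 IQR]; off by
  default in the library, on in the pipeline preset (flagged counts are
  reported; rows are not silently dropped).

## Geostatistics

Empirical semivariograms use 12 equal-width bins to half the maximum
pairwise distance by default (the common working rule); empty bins are
reported as NaN with zero pair count, never as zero.  The spherical model
is fit by pair-count-weighted least squares with non-negativity bounds and
a deterministic multi-start over a range grid; a partial-sill penalty of
order 1e-4 resolves the pure-nugget degeneracy (a flat semivariogram is
otherwise fit equally well by any nugget/sill split once the range drops
below the first lag) without measurably biasing genuinely structured fits.

Ordinary kriging solves the (n+1) semivariance system with a Lagrange
multiplier; weights therefore sum to one by construction (asserted per
cell) and prediction is exact at data points when the nugget is zero.  The
whole survey is used as the neighbourhood — appropriate at n ≈ 120 — and
the system matrix is LU-factorised once per surface.  Duplicate
coordinates under a zero nugget make the system singular; point prediction
raises an error naming the pair, grid prediction jitters the duplicates by
1e-6 of the range with a warning.  Surfaces export as ESRI ASCII grids
(north-up row order) plus long-format tables.

## Random-forest prediction

Targets are winsorized at the 5th/95th percentiles (linear-interpolated
order statistics).  Note that this operation is only *approximately*
idempotent: re-clipping moves the boundary by about range/n on
distinct-valued data, so the guarantee is that interior points are
untouched and values stay within the original bounds.  Winsorization is
applied to the full vector before the 70/30 split by default, mirroring
the preprocessing order stated for the analysis; this leaks a small amount
of test information into the clip bounds, and a train-only switch is
provided.

Continuous predictors (covariates plus coordinates) are z-scored with
stored means/sds (n−1 denominator); categoricals are one-hot encoded with
a dropped reference level (CM for land use) and unseen transform-time
levels are errors; constant encoded columns are dropped.  PMF contribution
columns F1..Fk come from the fitted G matrix of the same survey — a
structural circularity inherent to the design, which is why a
no-PMF-features ablation switch exists.

The ensemble is 300 bagged regression trees with mtry = ⌈p/3⌉ random
features per split and minimum leaf size 5, built on
`sklearn.ensemble.BaggingRegressor` over `DecisionTreeRegressor` (whose
public `estimators_samples_` exposes the bootstrap records needed for OOB
work).  The ensemble prediction is exactly the mean of the per-tree
predictions (asserted to 1e-12).  Metrics: R² against the test mean, Q²
against the *training* mean, RMSE in mg kg⁻¹.  Permutation importance is
the mean OOB squared-error increase over repeats; partial dependence is
the brute-force marginal mean.

## Health risk

Average daily doses follow the RAGS forms given in the README; AT is
ED·365 for non-carcinogens and the configured lifetime (70 y = 25,550
days) for carcinogens; HQ/HI and CR/TCR are sums over routes and elements.
Cancer risk is evaluated over the ingestion and inhalation routes by
default: dermal slope factors require gastrointestinal-absorption
extrapolation that is unavailable for most of these elements, so dermal
contributes to hazard only (configurable).

Two packaged parameterizations exist because the deterministic and
probabilistic conventions in this literature genuinely differ, and the two
sets of published headline numbers they correspond to cannot be produced
by a single table:

- **Point set** (`exposure_point.yaml` / `toxicity_point.yaml`): RAGS
  residential intake defaults (IngR 200/100 mg d⁻¹, InhR 7.6/20 m³ d⁻¹,
  SA 2800/5700 cm², AF 0.2/0.07, EF 350 d y⁻¹, BW 15/70 kg,
  PEF 1.36×10⁹ m³ kg⁻¹), receptor durations from the study-design age
  bands (child 17 y, adult 47 y), and the oral slope-factor convention
  that includes Co (9.8) and Ni (1.7) alongside As (1.5), Pb (8.5×10⁻³)
  and Cr(VI) (0.5).
- **Monte-Carlo set** (`exposure_mc.yaml` / `toxicity_mc.yaml`): EPA
  default durations (6/24 y), IngR log-normal (arithmetic mean at the
  point value, CV 0.3), EF uniform(180, 365), BW normal; oral slope
  factors restricted to the EPA-established trio (As, Pb, Cr) with Co, Cd
  and Ni carried as inhalation-route carcinogens, and the Co dermal
  reference dose taken as the inhalation-derived 5.7×10⁻⁶ mg kg⁻¹ d⁻¹
  (a convention that appears in the probabilistic soil-risk literature;
  the point set uses 1.6×10⁻² instead).

All reference doses are the IRIS/PPRTV/CalEPA-lineage values standard in
soil health-risk tables.  Both files are plain YAML and meant to be
replaced wholesale when site-specific or supplementary parameter tables
are available; results under the shipped files should be read as an
"EPA-default parameterization".

The Monte-Carlo engine draws every exposure parameter per iteration
(10,000 by default), holds concentrations at their central values (an
option samples them empirically instead), computes the full pipeline per
draw, and reports means, medians and 5th/95th percentiles plus per-element
shares of HI and TCR.  With all distributions degenerate it reproduces the
deterministic engine exactly — this equivalence is a test.  Supported
families: point, normal (truncated at zero), log-normal (parameterised by
arithmetic mean/sd), uniform, triangular.

### Known limitations of the risk defaults

Under the RAGS dose forms with shared per-receptor parameters, the
child/adult HI ratio is bounded by the ingestion intake ratio
(IngR/BW)_child / (IngR/BW)_adult ≈ 9.3; dermal gives ≈ 6.6 and inhalation
≈ 1.8.  Published analyses sometimes report larger ratios, which implies
receptor-specific frequencies or intakes that cannot be recovered from
headline numbers alone.  Similarly, the Cr share of the total cancer risk
is ≈ 87% under the EPA-strict oral slope-factor trio and ≈ 67% when a Cd
oral slope factor (6.1) is added; intermediate published shares imply yet
other table variants.  The shipped defaults are fixed, documented choices,
not fits.

## Statistical screening

Shapiro–Wilk per element (scipy) with the ordinary 0.05 level; when any
element rejects normality the pipeline describes inter-element association
with Spearman's tie-corrected rank correlation (average ranks), flagged at
0.05/0.01, reported raw and Holm-adjusted.

## Synthetic-data generator

The generator emulates a stratified survey of a 10 km × 10 km area tiled
into five equal land-use strips, 24 samples per class by default (n = 120).
Latent structure: each (land use, factor) pair places one Gaussian-kernel
hotspot (range 1,500 m by default) inside its strip with amplitude equal
to the configured source intensity, plus a small positive baseline; the
contribution of factor f at a site is the sum over hotspots.  This gives
spatial autocorrelation for the kriging stage and land-use structure for
the indices/prediction stages at a fraction of the cost of a Gaussian
process, which is all the downstream tests require.  The four default
profiles sketch a Pb-dominated traffic source, a Cr/Cu/Ni/As mining
source, a Zn/Cd/Cu mixed urban source and an Hg/Co agrochemical source,
constructed so every pairwise cosine similarity is ≤ 0.8 (identifiability).

Concentrations are X = G F under multiplicative log-normal noise with
configurable CV (default 0.2; mean one, so expectations are preserved);
with CV = 0 the matrix equals the clean mixture exactly, which anchors the
parameter-recovery tests.  Values below the MDL are flagged and optionally
substituted.  Covariates are drawn from land-use-specific normal
distributions chosen to reproduce the qualitative contrasts of degraded
mine soils versus fertile forest soils (acidic low-CEC CM, alkaline RD,
high-OM FT).

What the generator does *not* emulate: real spatial geometry (strips, not
digitised polygons), anisotropy, censoring heavier than the tiny default
MDLs, covariate–concentration dependence beyond what the shared land-use
strata induce, and measurement error structure beyond i.i.d. multiplicative
noise.  Passing recovery tests on this generator therefore demonstrates
correctness of the algorithms under a known model, not field performance on
any particular survey.

## Reproduction script and problem sizes

`scripts/acceptance.py` recomputes the headline quantities from the
packaged land-use mean concentration table: contamination factors directly
from means and backgrounds; Monte-Carlo risk at the study-area grand mean
with 10,000 iterations per receptor; deterministic risk from the CM means.
All randomness derives from `--seed` via a `SeedSequence` fan-out.  The
test suite exercises PMF at n = 120 with k up to 5 and a handful of
starts, kriging on grids up to 21×21, and forests of 30–300 trees — sizes
chosen so the full suite and the end-to-end pipeline each run in minutes
on a single CPU while still operating at the study's sample size.
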