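# soilpte

Integrated analysis of potentially toxic elements (PTEs) in multi-land-use
soils: pollution and ecological-risk indices, uncertainty-weighted positive
matrix factorization (PMF) for source apportionment, ordinary kriging of
concentrations and source contributions, a PMF-informed random-forest
prediction stage, and deterministic plus Monte-Carlo human-health risk
assessment.

The package is aimed at environmental geochemists and risk assessors working
with soil surveys of the kind collected around industrial or mining sites: a
few hundred georeferenced samples, each with physicochemical covariates and
a nine-element concentration vector (Hg, As, Zn, Pb, Co, Cd, Ni, Cr, Cu in
mg kg⁻¹).  Because such surveys are rarely deposited publicly, the package
ships a synthetic-data generator with a known non-negative source-mixing
structure, spatial autocorrelation and land-use effects, so every stage can
be validated against ground truth.

## The models

**Indices.**  Per sample and element, the contamination factor CF = C/Bₙ
(Bₙ the geochemical background), the Müller geo-accumulation index
Igeo = log₂(C / 1.5 Bₙ), and the Hakanson ecological risk factor
ER = Tᵣ · CF; per sample the Tomlinson pollution load index
PLI = (∏ CF)^(1/n) and the potential ecological risk index PERI = Σ ER,
each classified on the standard band sets.

**Source apportionment.**  PMF decomposes the n×m concentration matrix as
X ≈ G F with non-negative site contributions G (n×k) and source profiles
F (k×m), minimising the uncertainty-weighted objective
Q = Σᵢⱼ ((xᵢⱼ − (GF)ᵢⱼ)/uᵢⱼ)², with per-cell uncertainties built from the
method detection limit and an error fraction
(u = √((EF·c)² + (0.5·MDL)²) above the MDL, u = ⅚·MDL at or below it).
Optimisation is by weighted multiplicative updates with multi-start; a
robust mode caps scaled residuals at |e/u| ≤ 4.  Factor-count selection,
bootstrap factor mapping and a displacement (DISP-style) stability
diagnostic are included, as are contribution summaries (percentage of each
element per factor, total mass share per factor).

**Geostatistics.**  Empirical semivariograms, pair-count-weighted spherical
model fits (nugget/sill/range), and ordinary kriging with the Lagrange
unbiasedness constraint (weights sum to one), exact at data points when the
nugget is zero.  Surfaces export as ESRI ASCII grids.

**Prediction.**  A bagged regression-tree ensemble (300 trees, random
feature subset per split, mtry = ⌈p/3⌉) predicts element concentrations
from covariates, coordinates, one-hot land use/texture/depth, and PMF
contribution columns; evaluated by R², the predictive squared correlation
Q² (against the training mean) and RMSE, with OOB error curves, permutation
importance and partial dependence.

**Health risk.**  US EPA RAGS average daily doses for soil ingestion,
particulate inhalation and dermal contact, for child and adult receptors;
hazard quotients HQ = ADD/RfD, hazard index HI = Σ HQ, cancer risk
CR = ADD·SF and TCR = Σ CR.  The Monte-Carlo engine draws exposure
parameters from configurable distributions (10,000 iterations by default)
while holding concentrations at their central values.

## Worked example

```python
import numpy as np
from soilpte import core, indices, pmf, risk, synthetic

refs = core.load_reference_tables()
spec = synthetic.make_default_sourcespec(k=4, seed=42, noise_cv=0.2)
ds, truth = synthetic.synthesize_dataset(spec, n_per_landuse=24,
                                         mdl=refs.mdl, seed=42)
print(f"samples: {ds.n} ({ds.landuse_counts()})")

table = indices.index_table(ds, refs)
pli = table.per_sample.groupby("land_use")["PLI"].mean()
print("mean PLI by land use:", {k: round(v, 2) for k, v in pli.items()})

U = pmf.build_uncertainty_matrix(ds, error_fraction=0.1, mdl=refs.mdl)
sol = pmf.fit_pmf(ds.concentrations(), U, k=4, n_starts=10, seed=7).normalized()
print(f"PMF: Q = {sol.Q:.1f}, Q/Qexp = {sol.Q / sol.Q_expected:.2f}")
perm, cos = pmf.match_factors(truth.F_true, sol.F)
print("matched-profile cosines vs truth:", np.round(cos, 3))
print("factor shares (%):", np.round(pmf.factor_total_share(sol.G, sol.F), 1))

grand = core.landuse_means(ds)[1].to_dict()
mc = risk.monte_carlo_risk(grand, risk.load_exposure("mc"),
                           risk.load_toxicity("mc"), "child",
                           n_iter=10_000, seed=7)
s = mc.summary["HI"]
print(f"child MC HI: mean {s['mean']:.2f} [p5 {s['p5']:.2f}, p95 {s['p95']:.2f}]")
```

which prints:

```
samples: 120 ({'CM': 24, 'AG': 24, 'RD': 24, 'FT': 24, 'RS': 24})
mean PLI by land use: {'AG': 1.47, 'CM': 1.62, 'FT': 0.7, 'RD': 1.01, 'RS': 0.61}
PMF: Q = 1962.5, Q/Qexp = 3.48
matched-profile cosines vs truth: [0.997 0.992 0.98  0.985]
factor shares (%): [22.9 16.7 18.8 41.6]
child MC HI: mean 0.97 [p5 0.56, p95 1.52]
```

The coal-mine and agricultural strips come out as the polluted classes
(mean PLI > 1), the four generating source profiles are recovered from the
noisy mixture with cosine similarity ≥ 0.98, and the simulated child
hazard index straddles the HI = 1 threshold of concern — the qualitative
behaviour the generator is designed to produce.

The same stages are available from the shell:

```bash
soilpte simulate --k 4 --n-per-landuse 24 --noise-cv 0.2 --seed 42 --out samples.csv
soilpte pmf --in samples.csv --k 4 --starts 20 --seed 7 --out solution/
soilpte krige --in samples.csv --var Zn --nlags 12 --out zn.asc
soilpte risk --in samples.csv --mode mc --iters 10000 --seed 7 --receptor child --out risk.csv
soilpte run-all --seed 42 --out bundle/
```

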