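# acertail

Extreme-value prediction for **many cross-correlated time series at
once**: pooled conditional-exceedance (ACER) estimation, sub-asymptotic
tail extrapolation with confidence bands, and return-level inversion.

The motivating application is epidemiological risk: given annual cancer
death rates for ~195 countries over 30 years, estimate the death rate (as
a fraction of local population) that some country will exceed on average
once per 100 years. The same machinery applies to any panel of
non-negative component series with per-component critical thresholds —
structural loads, environmental extremes, regional health indicators.

## The method in brief

Each component X is scaled by its failure limit η_X (for mortality, the
country population), so every series shares the unified limit 1. All
local maxima are merged, in time order, into one vector R₁…R_N. For a
scaling parameter λ that lowers every limit at once, the average
conditional exceedance rate at conditioning level k is

    p_k(λ) = #{ j : R_j > η_j λ,  R_{j−1} ≤ η_{j−1} λ, …, R_{j−k+1} ≤ η_{j−k+1} λ } / (N − k + 1),

with the system non-exceedance probability P_k(λ) ≈ exp(−N p_k(λ)).
Above a cut-on λ₀ the rate follows the sub-asymptotic Weibull-type form

    p_k(λ) ≈ exp{ −(aλ + b)^c + d },   λ ≥ λ₀,

fitted by confidence-weighted least squares on ln p (multistart
trust-region solver). The T-year return level inverts in closed form at
the target rate p\* = 1/(ν·T), ν = pooled events per year:

    λ* = ((d − ln p*)^{1/c} − b) / a,

with an uncertainty interval from extrapolating the 95 % confidence band
with the same tail family. Because the method is multi-dimensional and
sub-asymptotic, it works directly on short records (30 annual values per
component) without GEV/GPD asymptotics.

## Worked example

Fit the full pipeline on a seeded synthetic mortality panel (195
countries × 30 years of death rates in per cent of local population,
cross-correlated through a common annual factor):

```python
from acertail import CancerPanelSpec, gen_cancer_like_panel
from acertail.model import AcerModel

panel = gen_cancer_like_panel(CancerPanelSpec(seed=1))
res = AcerModel.from_panel(panel).fit(k=3, return_period=100.0)
print(res.summary())
```

```
ACER tail model results
==========================================================
Pooled maxima N                                       5850
Components                                             195
Observation span T (years)                            30.0
Events per year                                     195.00
Conditioning level k                                     3
Tail cut-on lambda0                                0.2426%
Tail points used                                        93
ln-ln linearity R^2                                0.99455
----------------------------------------------------------
a                  1128.55    b             -2.38904
c                  3.79779    d             -1.80012
----------------------------------------------------------
Return period (years)                                  100
Convention                             expected_exceedance
Target probability p*                            5.128e-05
Return level lambda*                               0.3653%
95% CI for lambda*                        [0.3496, 0.3728]
==========================================================
Levels expressed in % of failure limit.
```

Reading the table: 5850 pooled annual maxima (195 countries × 30 years)
give 195 events per year, so the 100-year target rate is
p\* = 1/19500 ≈ 5.1·10⁻⁵. The tail was fitted above λ₀ = 0.2426 % of
population on 93 levels; the double-log diagnostic is nearly perfectly
linear (R² = 0.995). The predicted 100-year death rate is **0.365 % of
local population**, with a 95 % interval of [0.350 %, 0.373 %].

The paper-style validation — refit on every second pooled point and
check the prediction against the full-data interval:

```python
v = res.validate_half_data()
v.lambda_half, v.inside        # (0.003607..., True)
```

A command-line interface wraps the same pipeline:

```bash
acertail simulate --kind cancer --out panel.csv --seed 1
acertail fit --input panel.csv --k 3 --outdir run/     # summary + plots + JSON
acertail validate --input panel.csv --k 3 --outdir val/
acertail diffplot --input run/merged_vector.csv --outdir dp/
```

`fit` also reads long-format "causes of death" CSVs in the
Entity/Code/Year dialect (`--cause-column`, `--population-column`,
`--start-year/--end-year`, `--exclude` for outlier entities).

## Layout

| module | contents |
|---|---|
| `acertail.panel` | panel readers (OWID-style long + wide CSV), validation, failure limits, scaling |
| `acertail.merge` | local-maxima extraction, pooled merged vector |
| `acertail.exceedance` | p_k estimation, convergence in k, mixtures, confidence bands |
| `acertail.tailfit` | cut-on selection, tail fitting, band extrapolation, return levels |
| `acertail.model` | `AcerModel` / `AcerResults` (fit, summary, validation, plots) |
| `acertail.synthetic` | seeded Gaussian-MDOF, mortality-like and exact-tail generators |
| `acertail.diffplot` | SODP/TODP/FODP difference clouds |
| `acertail.cli` | `acertail` command-line tool |

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
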