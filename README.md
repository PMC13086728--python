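# qbd — quality-by-design analytics for nanoparticle formulation

`qbd` implements the computational side of a quality-by-design (QbD)
formulation study: it builds and validates three-level Box–Behnken designs,
fits coded-variable response-surface models with the diagnostics DoE
practitioners expect (PRESS, predicted R², adequate precision), finds the
optimal formulation by Derringer–Suich desirability optimization, and
extracts drug-release kinetics and Franz-diffusion-cell permeation
parameters. It is written for pharmaceutical scientists who develop
drug-loaded nanoparticles (or any formulation optimized over a small factor
space) and want the whole design → fit → optimize → validate loop as
scriptable, tested Python instead of point-and-click DoE software.

The package ships the complete design/response table of a published study —
dapoxetine hydrochloride–loaded PLGA nanoparticles for intranasal delivery,
a 15-run Box–Behnken design over PLGA amount (25–75 mg), PVA concentration
(1–2 % w/v) and internal aqueous volume (0.5–1 ml), with entrapment
efficiency, particle size, 8-h release and 24-h permeation as responses —
and reproduces that study's regression equations, diagnostics and optimum
end to end.

## The model

Factors are coded so that low = −1, center = 0, high = +1. Each response y
is fitted by ordinary least squares to a polynomial in the coded factors
x = (x_A, x_B, x_C):

    ŷ = β₀ + Σᵢ βᵢxᵢ                          (linear)
      + Σᵢ<ⱼ βᵢⱼxᵢxⱼ                          (2FI)
      + Σᵢ βᵢᵢxᵢ²                             (quadratic)

Diagnostics use the corrected total sum of squares: adjusted
R² = 1 − (SSE/(n−p))/(SST/(n−1)); PRESS = Σ(eᵢ/(1−hᵢᵢ))² over the leverages
hᵢᵢ, predicted R² = 1 − PRESS/SST; adequate precision =
(max ŷ − min ŷ)/√(p·MSE/n), with > 4 conventionally deemed adequate.

Each response gets a desirability dᵢ ∈ [0,1] from a linear ramp over its
observed range (rising for "maximize", falling for "minimize"), and the
composite desirability D = (Π dᵢ^rᵢ)^(1/Σrᵢ) is maximized over the coded
cube by a deterministic 5×5×5 multi-start Nelder–Mead search.

Release profiles are fitted on the linearizing axes of the zero-order
(Q vs t), first-order (ln(100−Q) vs t) and Higuchi (Q vs √t) models, the
winner chosen by R². Permeation profiles yield steady-state flux Jss (slope
of the terminal linear regime), lag time (its x-intercept), permeability
coefficient Kp = Jss/C_donor and enhancement index EI = Kp/Kp_control.

## Worked example

```python
import qbd
from qbd import datasets

study = datasets.load_formulation_study()      # 15-run BBD with 4 responses

ee = qbd.fit_model(study, "EE_pct", "quadratic")
print(round(ee.coef("Intercept"), 2), round(ee.coef("PLGA"), 2))
print(round(ee.stats.adj_r2, 4), round(ee.stats.pred_r2, 4),
      round(ee.stats.adequate_precision, 2))

orders = datasets.default_model_orders()
fits = [qbd.fit_model(study, r, o) for r, o in orders.items()]
result = qbd.optimize(fits, datasets.response_goals(study),
                      specs=datasets.factor_specs())
print({k: round(v, 3) for k, v in result.natural_optimum.items()})
print(round(result.composite_D, 4))
```

prints

```
62.94 9.54
0.9395 0.6813 15.05
{'PLGA': 25.0, 'PVA': 1.846, 'Vaq': 0.5}
0.9976
```

i.e. the entrapment-efficiency surface has intercept 62.94 % and a PLGA
main effect of +9.54 % per coded unit, the fit explains the data well
(adjusted R² 0.9395) with acceptable predictive power (predicted R² 0.6813,
adequate precision 15.05 ≫ 4), and the most desirable formulation uses
25 mg PLGA, ≈1.85 % w/v PVA and 0.5 ml internal aqueous phase with composite
desirability ≈ 0.998 — the fabricated optimum of the source study.

The same workflow is available from the shell:

```sh
qbd design --factors factors.csv --center 3 --out design.csv
qbd fit --design design.csv --response EE_pct --order quadratic
qbd pipeline --config study.toml --design design.csv
qbd release --profile release.csv
qbd permeation --profile permeation.csv --donor-concentration 1000
qbd simulate bbd --seed 1 --noise-sd 3 --out synthetic.csv
```

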