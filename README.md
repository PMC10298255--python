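# capsuledry

Drying kinetics of HPMC-based hard-capsule gel films: a 1-D Fickian
thin-layer drying model with a moisture- and temperature-dependent effective
diffusivity, least-squares fitting of the diffusivity law to drying curves,
and proton-density MRI moisture quantification — with a synthetic-data
generator that emulates the capsule drying experiment so the whole pipeline
runs without any external data.

## The problem

Hard capsules made from hydroxypropyl methylcellulose (HPMC) gels are dried
as ~0.2 mm films on mold pins. Improper drying (too hot, too dry) causes
cracks and layered structure; modeling the moisture transport helps choose
conditions. The film is a thin slab: moisture moves only from the inner
(pin-side) face to the outer (air-side) face, which equilibrates with the
drying air instantly. The governing model is Fick's second law with a
state-dependent effective diffusivity,

    dM/dt = d/dx( D_eff(M, T) dM/dx ),    0 < x < L,
    M(x, 0) = M0,   dM/dx|_{x=0} = 0,   M(L, t) = M_e,

with dry-basis moisture M [g water / g dry matter], shell thickness
L = 0.0002 m, initial moisture M0 = 8.44 g/g and equilibrium moisture M_e
set by the air temperature and relative humidity. The diffusivity law is

    D_eff(M, T) = D0 · exp( −Ea/(R·T) + a·M − b·M² ),

an Arrhenius factor modulated by the moisture state (rise-then-fall with a
peak at M = a/(2b)). Setting a = b = 0 gives the conventional
constant-diffusivity benchmark. The PDE is solved by an explicit
finite-difference march on Z = 4 layers with the stability-bounded step
Δt ≤ Δl²/(6·D_eff); the four parameters (D0, Ea, a, b) are estimated by
bounded derivative-free least squares against observed drying curves, and
fits are scored with R² and RMSE.

Proton-density-weighted MRI reads the same physics from images: the
spin-echo signal I = k·ρ_H·(1 − e^(−TR/T1))·e^(−TE/T2) is linear in water
content, so normalizing a zone's mean signal between the first frame
(100 %) and the equilibrium frame (0 %) yields a moisture percentage, per
shell layer if the shell annulus is segmented radially.

## Worked example

```python
from capsuledry import fit_variable, fit_constant, compare_models, pooled_rmse
from capsuledry.synthetic import GeneratorConfig, generate_drying_experiment

cfg = GeneratorConfig()          # five study conditions, 5 % noise
curves = generate_drying_experiment(cfg)
fit_v = fit_variable(curves)     # moisture-dependent law, joint fit
fit_c = fit_constant(curves)     # one constant D per condition
print(compare_models(fit_v, fit_c).summary)
```

prints (seed 20230605, the default):

```
fitted law: D0=1.459e-06 m^2/s  Ea=31013 J/mol  a=0.279  b=0.0667
condition  R2_variable  R2_constant  RMSE_variable  RMSE_constant
 35C_RH40       0.9971       0.9777         0.1543         0.4312
 35C_RH50       0.9998       0.9887         0.0403         0.2911
 35C_RH60       0.9937       0.9733         0.2053         0.4221
 40C_RH60       0.9994       0.9844         0.0682         0.3486
 45C_RH60       0.9983       0.9956         0.1106         0.1759
pooled RMSE: variable 0.1300 vs constant 0.3468 g/g
```

The variable-diffusivity model halves the pooled RMSE relative to the
constant-diffusivity benchmark on the same observations — the moisture
dependence of D_eff matters for these films. `fit_v.params` is the fitted
law; `fit_v.per_condition` carries R²/RMSE per condition;
`fit_v.estimator` is the underlying scikit-learn-style estimator
(`VariableDiffusivityModel`), usable directly with `fit`/`predict`/`score`.

The command-line pipeline wraps the same stages:

```
capsuledry full --outdir run1 --seed 20230605
```

writes synthetic curves, both fits, the model-comparison tables, average
and per-layer diffusivity tables, a quantified MRI phantom series, and a
manifest with content hashes (runs are deterministic per seed).

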