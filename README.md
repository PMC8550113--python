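# fslmm — Fisher scoring for crossed-factor linear mixed models

`fslmm` estimates linear mixed models whose random effects are grouped by
one or more **crossed** factors — groupings whose levels are not nested,
such as *subject* × *location* or *student* × *teacher* — and performs
approximate t-tests on the fixed effects with closed-form Satterthwaite
degrees of freedom.  It is written for biostatisticians and quantitative
researchers who need mixed-model estimation built from plain dense linear
algebra: every operation is a matrix product, inversion or reshape, with
no sparse solvers, sweep operators or derivative-free optimizers.

## The model

For `n` observations,

```
Y = X β + Z b + ε,     ε ~ N(0, σ² Iₙ),     b ~ N(0, σ² D),
```

where factor *k* (of *r*) groups `q_k` random effects over `l_k` levels and
`D = ⊕ₖ (I_{l_k} ⊗ D_k)` with an unknown symmetric `q_k × q_k` block `D_k`
per factor.  Writing `V = Iₙ + Z D Z'` and `e = Y − Xβ`, the log-likelihood
(constants dropped) is

```
l(θ) = −½ { n log σ² + σ⁻² e'V⁻¹e + log|V| },
```

with a restricted (ReML) variant `l_R = l + ½(p log σ² − log|X'V⁻¹X|)`.

Estimation is by **Fisher scoring**: closed-form score vectors and expected
information matrices in three flattenings of the covariance blocks —
`vech(D_k)` ("half"), `vec(D_k)` ("full") and `vech(Λ_k)` with
`D_k = Λ_kΛ_k'` ("Cholesky") — drive five algorithm variants:

| method | update |
|--------|--------|
| `fs`   | joint scoring step on (β, σ², vech(D₁), …) |
| `ffs`  | joint step in the full flattening via the invertible scoring matrix F |
| `sfs`  | GLS for (β, σ²), then per-factor scoring on vech(D_k) |
| `fsfs` | GLS plus per-factor steps on vec(D_k) via F |
| `csfs` | GLS plus per-factor steps on vech(Λ_k); D_k is PSD by construction |

All five work exclusively through the **product forms**
`P=X'X, Q=X'Y, R=X'Z, S=Y'Y, T=Y'Z, U=Z'Z`: after these are built, no
object with an `n`-sized dimension is ever touched, the only inversion is
of the `q × q` matrix `I + DU`, and per-level sums of Kronecker products
are evaluated by cached permuted reshapes instead of loops.

Constrained covariance structures (diagonal, compound symmetry, scaled
identity, user-supplied Jacobians) and the **ACE twin model**
(`D_k = τ_a²K^a_k + τ_c²K^c_k` with kinship and shared-environment
matrices) are supported through constraint (Jacobian) matrices.  Inference
uses the approximate T-statistic `T = Lβ̂ / √(σ̂² L(X'V̂⁻¹X)⁻¹L')` with
"direct" Satterthwaite degrees of freedom: the gradient of
`S² = σ̂²L(X'V̂⁻¹X)⁻¹L'` over the variance parameters is evaluated in
closed form and combined with the inverse expected information.

## Worked example

```python
from fslmm import CrossedLMM
from fslmm.cli import design_to_frame
from fslmm.simulate import preset_setting, generate_dataset

design, truth = generate_dataset(preset_setting(2, n=600, l=(30, 15)), seed=7)
df = design_to_frame(design)
model = CrossedLMM.from_dataframe(
    df, response="y", fixed=["x1", "x2", "x3"],
    factors={"f0_level": (["f0_z1", "f0_z2"], True),   # intercept + 2 slopes
             "f1_level": (["f1_z1"], True)},            # intercept + 1 slope
)
res = model.fit(method="fsfs", reml=True)
print(res.summary())
```

```
Crossed-factor linear mixed model
================================================================
Method: FSFS     Criterion: ReML   Converged: True (iter 8)
Log-likelihood (ReML, constants dropped): -477.292049
Residual variance sigma2: 1.048393

Fixed effects
----------------------------------------------------------------
const        coef     0.6434  se   0.2396  t    2.685  dof     32.0  p   0.0114
x1           coef    -0.3126  se   0.0464  t   -6.730  dof    496.1  p   0.0000
x2           coef     0.7883  se   0.0476  t   16.566  dof    502.5  p   0.0000
x3           coef    -0.0031  se   0.0454  t   -0.068  dof    494.5  p   0.9460

Random-effect covariances (sigma2 * D_k)
----------------------------------------------------------------
f0_level:
       0.7801     0.2729    -0.1059
       0.2729     0.7051    -0.0812
      -0.1059    -0.0812     0.5863
f1_level:
       0.6335     0.3041
       0.3041     0.5939
```

The data were generated with `β = (0.5, −0.3, 0.8, 0.0)`: the two real
covariate effects are recovered with hundreds of denominator degrees of
freedom (n = 600 minus what the 105 random effects absorb), the intercept
is tested against far fewer (its variance is dominated by the random
intercepts), and the truly-null `x3` is correctly not rejected
(`t = −0.07`, `p = 0.946`).

```python
res.t_test([0, 0, 0, 1])   # single-contrast approximate t-test
# t = -0.0678, dof = 494.48, p = 0.9460
```

A command line wraps the same pipeline
(`fslmm fit data.csv model.json --criterion reml --contrast "0,0,0,1"`,
plus `simulate`, `benchmark` and `dof` subcommands); see
`fslmm --help` and the JSON model-description format in `fslmm/cli.py`.

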