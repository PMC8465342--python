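# ipinsulin

Compartmental modeling of **intraperitoneal (IP) insulin absorption and
whole-body insulin kinetics** in type 1 diabetes, with Bayesian Maximum a
Posteriori (MAP) identification and a runs-test / precision / BIC model
selection protocol.

Insulin delivered into the peritoneal cavity by an implanted pump is
absorbed toward the liver, restoring the portal–peripheral insulin gradient
that subcutaneous delivery lacks. This package implements a nine-model
battery for that process — three linear IP absorption structures crossed
with three descriptions of hepatic insulin extraction — together with a
synthetic-data generator that emulates a hospitalized 24-h open-loop study
day (basal-bolus IP delivery, frequent plasma insulin sampling with known
measurement SD), so the full identification and selection pipeline can be
exercised and validated without access to restricted patient data.

## The models

**IP absorption** (insulin masses in mU, rates in min⁻¹, infusion `Inf(t)`
in mU/min, `RaI` the flux into the liver):

- **M1** — one compartment:
  `Q̇ip1 = −ka1·Qip1 + Inf`, `RaI = ka1·Qip1`
- **M2** — two compartments in cascade (`kd ≥ ka2` by convention, the two
  being interchangeable):
  `Q̇ip1 = −kd·Qip1 + Inf`, `Q̇ip2 = kd·Qip1 − ka2·Qip2`, `RaI = ka2·Qip2`
- **M3** — two compartments, absorption from both:
  `Q̇ip1 = −(ka1+ka2)·Qip1 + Inf`, `Q̇ip2 = ka2·(Qip1 − Qip2)`,
  `RaI = ka1·Qip1 + ka2·Qip2`

**Whole-body kinetics** (two compartments; IP insulin appears in the liver):

```
Q̇p = −(m2 + m4)·Qp + m1·Ql            Ip = Qp / VI
Q̇l = −(m1 + m3(t))·Ql + m2·Qp + RaI   m3(t) = HE(t)/(1 − HE(t)) · m1
```

with `m2 = 0.268 min⁻¹` fixed (all variants are structurally identifiable
once it is known) and the post-hepatic clearance decomposition
`CL = (HEb·m2 + m4)·VI`. Hepatic extraction `HE(t)` is **A** constant
(`HEb`), **B** glucose-controlled (`HE = −aG·(G − Gb) + HEb`), or **C**
controlled by hepatic insulin mass (`HE = −aI·(Ql − Qlb) + HEb`).

**Identification** is MAP: weighted least squares under the known-SD
Gaussian error model plus log-normal priors on `VI, m1, CL, HEb`; IP
absorption parameters may vary meal-by-meal. Two structural simplification
rules are applied post-fit: in M2, `kd` collapses onto `ka2` when their
relative difference is below 1%; in M3, `ka1` collapses to 0 below
10⁻³ min⁻¹. **Selection** keeps the models with the most subjects passing
the runs test on weighted residuals, then those within 2 points of the best
fraction of parameters with CV < 100%, then picks the lowest median
`BIC = WRSS + P·ln(N)`.

## Worked example

```python
import numpy as np
from ipinsulin import (
    AbsorptionParams, KineticsParams, ModelSpec, FitConfig, PriorSpec,
    VirtualSubject, build_open_loop_design, generate_dataset, fit_map,
)

# the selected model (3C) at its published median parameters
kin = KineticsParams(VI=3.4, m1=0.15, CL=1.16, HEb=0.59, aI=16e-5)
absorption = [AbsorptionParams(ka1=a, ka2=b)
              for a, b in [(0.018, 0.028), (0.004, 0.028), (0.012, 0.024)]]
subject = VirtualSubject(kinetics=kin, absorption=tuple(absorption))

design = build_open_loop_design(daily_dose=0.60, body_mass=75.0)  # 45 U/day
dataset = generate_dataset(subject, ModelSpec.from_string("3C"), design,
                           cv=0.06, seed=42)

priors = PriorSpec.for_kinetics(VI=3.4, m1=0.15, CL=1.16, HEb=0.59, cv=1.0)
fit = fit_map(ModelSpec.from_string("3C"), dataset, priors,
              FitConfig(restarts=1, seed=0))
print(f"ka2 (breakfast) = {fit.estimates['ka2_m1']:.4f} 1/min "
      f"(CV {fit.cv['ka2_m1']:.0f}%)")
print(f"HEb = {fit.estimates['HEb']:.3f}   CL = {fit.estimates['CL']:.3f} L/min")
print(f"WRSS = {fit.wrss:.1f} on {fit.n_obs} samples, {fit.n_free} free parameters")
```

Output:

```
ka2 (breakfast) = 0.0287 1/min (CV 10%)
HEb = 0.598   CL = 1.156 L/min
WRSS = 103.3 on 145 samples, 11 free parameters
```

The breakfast-period absorption rate, basal hepatic extraction and
clearance land close to the generating values (0.028, 0.59, 1.16); a WRSS
near the sample count says the residuals are the size the error model
predicts. A command-line interface mirrors the library:
`ipinsulin simulate|generate|fit|battery|recover --config cfg.yaml`.

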