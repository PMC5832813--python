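# sedimet

Scaling the effect of sediment-dwelling bioturbators on cohesive-sediment
resuspension to the metabolic rate of their populations.

Burrowing and deposit-feeding macrofauna (lugworms, cockles, tellinid and
venerid bivalves) loosen the surface layer of muddy seabeds and increase the
mass of sediment that a given hydrodynamic stress can hold in suspension.
`sedimet` implements an energetic framework for predicting that effect: the
activity of a bioturbator population is summarised by its areal metabolic
rate, and the equilibrium mass of resuspended sediment is modelled as a
linear function of it.

The chain of models is

- **Individual metabolism.** Body mass *M* (mg AFDW) is obtained from a size
  measurement through a per-species power law, and the individual metabolic
  rate *I* (mW) from the allometric law *I = aM^b* (default *b* = 0.75) or
  from a configurable ln-linear empirical respiration model. 95% confidence
  half-widths are propagated through every conversion step (first-order delta
  method, with a Monte Carlo audit).
- **Population metabolism.** *I*<sub>TOT</sub> = *N·I* (mW m⁻²) for *N*
  individuals m⁻².
- **Resuspension scaling.** *R*<sub>TOT</sub> = *c* + *d·I*<sub>TOT</sub>,
  fitted by OLS; variants with functional-group intercepts and slopes are
  compared by bidirectional stepwise selection on AIC
  (= −2 logLik + 2(p+1)). The per-milliwatt biotic effect
  *R*<sub>BIO</sub> = (*R*<sub>TOT</sub> − *R*<sub>CONTROL</sub>)/*I*<sub>TOT</sub>
  is analysed against density and body size the same way.
- **Temperature projection.** The biotic term scales with the
  Boltzmann–Arrhenius factor e^(−E/k·(1/T − 1/T_ref)) (default
  *E* = 0.65 eV); the abiotic baseline *c* does not.

The package ships the 32-treatment annular-flume dataset (six species spanning
deep, intermediate and shallow bioturbation modes, densities 13–382 ind. m⁻²,
body masses 10–970 mg AFDW, bed shear stress 0.18 Pa) as its dataset of
record, plus a synthetic-experiment generator with known ground truth for
validating the whole pipeline.

## Worked example

```python
from sedimet import ResuspensionScaling, TemperatureScenario

model = ResuspensionScaling.from_fixture()   # packaged 32-treatment dataset
res = model.fit_stepwise()                   # AIC selection over group variants
print(res.summary())
```

```text
Resuspension-metabolism scaling (OLS)
============================================================
stepwise trace:
  Rtot_g_m2 ~ functional_group + Itot_mW_m2 + functional_group:Itot_mW_m2 AIC= 270.396
  Rtot_g_m2 ~ functional_group + Itot_mW_m2               AIC= 268.132
  Rtot_g_m2 ~ Itot_mW_m2                                  AIC= 265.710 <- selected
------------------------------------------------------------
Rtot_g_m2 ~ Itot_mW_m2
  Intercept                                    35.107  [  28.507,   41.707]  p=6.43e-12
  Itot_mW_m2                                    0.357  [   0.266,    0.448]  p=5.84e-09
  n=32  R2=0.682/0.672  F=64.431 (p=5.84e-09)  AIC=265.710
```

The selection drops the functional-group terms: once population metabolism is
accounted for, deep, intermediate and shallow bioturbators do not differ
detectably. The fitted abiotic baseline (35.1 g m⁻², CI 28.5–41.7) is
consistent with the 32.25 g m⁻² resuspended in defaunated control runs, and
each mW m⁻² of population metabolism adds ≈ 0.36 g m⁻² of resuspended
sediment (R² = 0.68).

Projecting the fitted line to other water temperatures:

```python
print(res.project([TemperatureScenario(7.2,  label="winter"),
                   TemperatureScenario(21.0, label="warming_+3C")]))
```

```text
      label  T_ref_C  T_target_C  activation_energy_eV   factor  metabolic_change_pct  Rtot_mean_g_m2
     winter     18.0         7.2                  0.65 0.368588                   -63       40.958445
warming_+3C     18.0        21.0                  0.65 1.302436                    30       55.782937
```

Winter cooling (18 → 7.2 °C) cuts metabolic rates — and hence the biotic
contribution to resuspension — by 63%; a +3 °C warming raises them by 30%.

The same pipeline is available from the shell:

```bash
sedimet fit --fixture --out results/
sedimet project --fixture --out projection.csv
sedimet simulate --seed 1 --out synthetic.csv
sedimet recover --seed 1 --replicates 500 --out recovery.csv
sedimet report --fixture
```

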