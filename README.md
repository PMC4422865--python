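# adcpk

Semi-mechanistic, multiple-analyte population pharmacokinetics of an
MMAE antibody-drug conjugate (ADC) in cynomolgus monkeys.

ADCs are dosed as a mixture of drug-to-antibody-ratio (DAR) species
(0–8 drugs per antibody, mean ≈ 3.5 here).  Three analytes are assayed
in plasma/serum: total antibody (**Tab**, µg/mL), antibody-conjugated
MMAE (**acMMAE**, nM) and unconjugated **MMAE** (nM).  The package
implements, simulates and fits a mechanistic model that links all
three: each DAR species distributes two-compartmentally and is lost
from the central compartment by saturable proteolytic degradation
(Michaelis–Menten, releasing all n drugs) and by sequential
deconjugation DAR *n* → *n*−1 whose rate constant follows a Weibull
density in DAR,

    K_ADCn = K·(κ/λ)·(x/λ)^(κ−1)·exp(−(x/λ)^κ),   x = 8 − n,  K = 1 h⁻¹.

Released drug feeds a linear two-compartment model of circulating
MMAE through pathway-specific bioavailable fractions Fmp (proteolysis)
and Fmd (deconjugation).  The model answers a design-relevant
question: *which catabolic pathway supplies the toxic free drug in the
circulation?*

The package is aimed at pharmacometricians and ADC modellers: it
provides the ODE core, a synthetic-study generator reproducing the
monkey study design (no animal data are public), an ITS/EM-type
population fitting routine with censored-data (M3) likelihood, and
reporting tools (VPC, goodness-of-fit, pathway attribution, DAR 0
accumulation).  See `docs/methods.md` for the model, the estimation
algorithm and its assumptions.

## Worked example

```python
import numpy as np
from adcpk import (DoseEvent, default_dar_distribution,
                   default_population_parameters, simulate_individual,
                   two_compartment_halflives)
from adcpk.simulate import pathway_attribution, average_dar_profile

pop = default_population_parameters()

# free-MMAE half-lives from the typical disposition parameters
print(two_compartment_halflives(2.27, 1.00, 23.0, 88.4))
# (0.02717475475457613, 29.935316934498456)  -> 0.0272 h and 29.9 h

# a typical monkey given a single 0.3 mg/kg IV dose of conjugate
times = np.linspace(0.0, 1008.0, 201)
prof = simulate_individual(
    [DoseEvent(0.0, "conjugate", 0.3, 2.5)],
    pop.adc, pop.mmae, times, dist=default_dar_distribution(),
)
att = pathway_attribution(prof)
print(round(att.percent_proteolysis, 1))
# 98.9   -> ~99% of circulating free MMAE came via proteolysis

i = 1  # 5.04 h
print(prof.analytes["tab"][i], prof.analytes["mmae"][i])
# 5.392 ug/mL   0.0397 nM
print(average_dar_profile(prof)[i])
# 2.862  -> the average DAR has already fallen from 3.52 at t=0
```

The attribution number is the model's central finding: although
deconjugation strips drug off the antibody faster than proteolysis
early after dosing (the DAR 7 species sheds at 0.37 h⁻¹ per site
versus a proteolytic capacity of 0.0407 nmol/h), almost none of the
deconjugated material appears as plasma MMAE (Fmd ≈ 0.024 vs
Fmp ≈ 0.78), so the free drug in the circulation is essentially all
proteolysis-derived.

A command-line umbrella mirrors the library:

```bash
adcpk make-data --seed 1 --out data.csv          # synthetic 52-monkey study
adcpk fit --data data.csv --out fit.json         # population fit (M3 censoring)
adcpk attribute --dose 0.3 --horizon 1008        # pathway attribution table
adcpk vpc --data data.csv --seed 1 --n-sim 200 --out vpc.csv
adcpk report --out-dir report/                   # deconjugation + DAR0 tables
```

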