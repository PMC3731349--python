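# ceusperf

Quantitative renal-perfusion analysis for contrast-enhanced ultrasound
(CEUS). The package turns ROI-averaged cine loops into time–intensity
curves (TICs), fits the lagged gamma-variate indicator-dilution model

    I(t) = A (t − t0) e^{−α (t − t0)} + C,   t ≥ t0,

derives the five perfusion indices — wash-in slope scale **A**, wash-out
rate constant **α**, area under the curve **AUC = A/α²**, derived peak
intensity **DPI = A/(α·e)**, and time to peak **TTP = 1/α** — and tests,
on an irregular longitudinal cohort with staggered dropout, at which week
each index first changes significantly from the pre-operative baseline
(random-intercept feasible GLS, per-week Wald tests, P < .05).

It is aimed at imaging researchers studying chronic renal hypoperfusion
in small longitudinal cohorts, where perfusion indices move weeks before
blood chemistry does. A synthetic-data module generates TICs, two-region
kidney cines and drifting cohorts with the statistical structure the
analysis assumes, so the whole pipeline is testable with no scanner and
no data download.

## Worked example

Simulate the default ischemia cohort, fit every TIC, and find the
earliest significant week per index:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_fit.py
python analysis/03_week_effects.py
```

which prints (seed 1):

```
simulated 58 subject-weeks for 5 subjects
last observed weeks: [6, 6, 12, 13, 16]
...
fitted 58 TICs; median r^2 = 0.9940
  A: median |relative error| vs truth = 0.277%
  alpha: median |relative error| vs truth = 0.200%
  AUC: median |relative error| vs truth = 0.220%
  DPI: median |relative error| vs truth = 0.136%
  TTP: median |relative error| vs truth = 0.200%
...
earliest significant week per index (P < 0.05):
  A: 3
  alpha: 2
  AUC: 4
  DPI: 4
  TTP: 3
```

Five subjects are observed weekly; two drop out after week 6, the others
after weeks 12, 13 and 16, so the panel is irregular. Each subject-week
TIC (160 s at 10 Hz, 10% multiplicative speckle noise on linear power)
is fitted to sub-percent index accuracy (median r² 0.994), and the
week-effect model then detects the wash-out indices (α, TTP) earliest —
the kinetic signature of progressive ischemia: a slower, later, larger
enhancement (AUC, DPI, TTP rise) with a flattening wash-in (A falls).

The same stages are available as a CLI (`ceusperf simulate / extract /
fit / cohort / run`) and as library calls:

```python
from ceusperf import (GammaVariateParams, AcquisitionSpec, NoiseModel,
                      simulate_tic, fit_gamma_variate)

truth = GammaVariateParams(A=3.93, alpha=0.111, t0=5.0, C=0.5)
tic = simulate_tic(truth, AcquisitionSpec(), NoiseModel("multiplicative-linear", 0.1, seed=7))
fit = fit_gamma_variate(tic)
print(fit.indices.TTP, fit.indices.DPI)   # ~9.0 s, ~13.0 dB
```

`docs/methods.md` describes the model, the estimators, the synthetic
generator's assumptions and the known limitations.

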