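# phenoqc

Data-quality estimation for periodically sampled smartphone sensor
streams, and mixed-model analysis of how that data quality relates to
later self-reported symptoms.

Smartphone digital-phenotyping studies sample battery-hungry sensors on
an alternating on/off-cycle schedule — e.g. accelerometer at 10 Hz for
60 s followed by 60 s of rest, GPS at 1 Hz for 60 s followed by 600 s of
rest — and deliver brief symptom surveys (EMA) on the phone. What
actually arrives is messier than the design: whole on-cycles go missing,
bursts are cut short, and sampling rates drift by device. `phenoqc` is
for researchers running such studies who need (a) principled per-day
measures of how much of the designed data they actually received, and
(b) a way to test whether those measures — which are metadata, collected
for free — carry signal about future clinical state.

## The estimators and the model

For a schedule with within-burst frequency *f* (pings/s), on-cycle
duration *d* (s) and rest *r* (s), the design implies *b* = *S*/(*d*+*r*)
bursts per day (*S* = 86,400 s) and *p* = *f·d·b* pings per day. The
observed ping stream of each day is split into bursts wherever the gap
between consecutive pings exceeds a threshold (30 s by default; a gap
exactly equal to the threshold does not split). From the bursts of day
*i* we estimate the burst count *b̂ᵢ*, per-burst ping counts *p̂ᵢⱼ* and
durations *d̂ᵢⱼ*, the mean duration *d̂ᵢ*, the mean within-burst
frequency *f̂ᵢ = p̂ᵢ/(b̂ᵢ·d̂ᵢ)*, and the total daily coverage

  *Ĉᵢ = p̂ᵢ/p = (b̂ᵢ/b)·(d̂ᵢ/d)·(f̂ᵢ/f)*.

Daily coverage and per-survey latency metrics are averaged within
subject-weeks, giving covariates *A* (accelerometer coverage), *G* (GPS
coverage), *V* (delivery→first-view latency), *C* (first-view→submit
latency) and *T* (surveys completed). The weekly mean symptom score
*Y* in each domain is modelled on these covariates lagged *l* weeks:

  *Yᵢⱼ = β₀ + μᵢ + β₁A + β₂G + β₃V + β₄C + β₅T + εᵢⱼ*,  μᵢ ~ N(0, σ²_μ)

fitted by REML with Wald z tests, one model per domain × lag. The
resulting grid of signed −log₁₀ p-values is corrected for multiple
testing with the Benjamini–Hochberg–Yekutieli step-up procedure at
FDR 0.05, which is valid under arbitrary dependence between the cells.

Because real cohort data of this kind is access-restricted, the package
ships a synthetic-cohort simulator (`phenoqc.simulate`) that emulates
the sampling schedules, burst dropout/truncation/thinning, thrice-weekly
prompts, bimodal view latencies, and survey scores generated from the
regression above with known coefficients — so every stage of the
pipeline is testable against ground truth.

## Worked example

```python
import numpy as np
from phenoqc import ACCELEROMETER, segment_bursts, daily_coverage
from phenoqc.simulate import TruthConfig, simulate_weekly_table
from phenoqc.model import SymptomLagModel

exp = ACCELEROMETER.expected
print(f"expected bursts/day b = {exp.b:.0f}, expected pings/day p = {exp.p:.0f}")

bursts = segment_bursts([0, 10, 50, 100, 130], threshold=30)
day = daily_coverage(bursts, ACCELEROMETER)
print(f"b_hat={day.b_hat}  p_hat={day.p_hat}  d_hat={day.d_hat:.2f}s  "
      f"gap_hat={day.gap_hat:.1f}s  coverage={day.coverage:.2e}")

truth = TruthConfig(beta0=0.5, beta=(-0.3, 0.2, 0.001, 0.002, -0.1),
                    sigma_subject=0.3, sigma_resid=0.2, true_lag=1)
table = simulate_weekly_table(50, 12, truth, np.random.default_rng(1))
result = SymptomLagModel.from_weekly(table, "overall", lag=1).fit()
print(result.summary().round(4))
```

prints

```
expected bursts/day b = 720, expected pings/day p = 432000
b_hat=3  p_hat=5  d_hat=13.33s  gap_hat=45.0s  coverage=1.16e-05
           estimate      se         z  pvalue  ci_low  ci_high
Intercept    0.6302  0.0761    8.2789  0.0000  0.4810   0.7794
A           -0.3004  0.0766   -3.9225  0.0001 -0.4505  -0.1503
G            0.0779  0.0706    1.1036  0.2698 -0.0605   0.2163
V            0.0010  0.0000  580.5370  0.0000  0.0010   0.0010
C            0.0019  0.0001   37.3913  0.0000  0.0018   0.0020
T           -0.1005  0.0140   -7.1970  0.0000 -0.1279  -0.0731
```

The five timestamps [0, 10, 50, 100, 130] split into three bursts at the
30 s threshold (gaps of 40 s and 50 s exceed it), giving 5 pings against
the 432,000 the accelerometer design expects — hence the ~1.2×10⁻⁵
daily coverage. In the fitted model, each slope estimate lands within
two standard errors of the coefficient the generator used (e.g.
Â = −0.30 against a true −0.3), and the weak GPS effect is correctly
not significant at this sample size.

The same analysis runs from the shell:

```
phenoqc simulate --subjects 16 --weeks 13 --seed 1 --out study
phenoqc coverage --study study --out analysis
phenoqc survey   --study study --out analysis
phenoqc features --study study --out analysis
phenoqc fit      --out analysis --lags 4
phenoqc report   --out analysis --fdr 0.05 --plot
```

writing daily metrics, weekly features, per-model coefficient tables and
the BY-corrected significance grid as CSV, with the exact run
configuration recorded alongside.

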