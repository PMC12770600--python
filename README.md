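# neurotimescales

Intrinsic neural timescales (INT) and long-range temporal correlations for
longitudinal resting-state fMRI cohorts, with an excitable-network
criticality model that explains why those timescales lengthen when cortical
excitability rises — as observed after ischemic stroke.

## Who this is for

Researchers studying slowed BOLD dynamics in clinical populations
(stroke, epilepsy, neurodegeneration) who need (i) reference
implementations of the standard ACF-based timescale metrics, (ii) a
synthetic longitudinal cohort with known ground-truth timescale structure
to validate an analysis pipeline end to end, and (iii) a
branching-process simulator linking neuronal excitability to BOLD-level
timescales.

## The quantities at the core

For a regional time series *y₁…y_T* the sample autocorrelation at lag *k*
uses a single global mean and the full-sample denominator:

    ACF_k = Σ_{t=k+1}^{T} (y_t − ȳ)(y_{t−k} − ȳ) / Σ_{t=1}^{T} (y_t − ȳ)²

and the intrinsic neural timescale is the area under the positive initial
segment of that curve,

    INT = TR · Σ_{k=1}^{n_lag − 1} ACF_k,   with ACF_{n_lag} < 0 the first negative lag.

Six companion measures cross-validate INT: the thresholded areas INT₀.₁ and
INT₀.₅ (sums truncated where the ACF first decays to 0.1 / 0.5), the
autocorrelation windows ACW₀, ACW₀.₁, ACW₀.₅ (linearly interpolated lags of
the corresponding first crossings) and the DFA-1 Hurst exponent (slope of
log RMS fluctuation vs log window size; 0.5 for uncorrelated noise).

On the modelling side, a Kinouchi–Copelli network of *N* excitable neurons
(quiescent → spike → refractory) on a directed Erdős–Rényi graph with mean
degree *K* propagates spikes with probability λ per edge and receives weak
Poisson drive (*h* = 1 − e^(−r·δt)). The branching ratio σ = K·λ controls
the distance to criticality DTC = |1 − σ|; critical slowing down makes all
seven timescale metrics peak near σ = 1. A canonical double-gamma
haemodynamic response function bridges the 1-ms neuronal activity density
to TR-sampled BOLD-like series.

## Worked example

```python
import numpy as np
from neurotimescales import (
    CohortSpec, KCConfig, ar1_series, branching_ratio,
    compute_all_metrics, generate_cohort,
)
from neurotimescales.pipeline import analyze_cohort, cohort_metric_table

# A persistent AR(1) series sampled at TR = 2 s
series = ar1_series(phi=0.8, n=200, seed=1, dt=2.0)
print(compute_all_metrics(series))
# TimescaleSet(int=8.094..., int01=4.376..., int05=1.223...,
#              acw0=48.934..., acw01=14.605..., acw05=3.116..., hurst=0.955...)

# The branching ratio at the critical parameterisation
print(branching_ratio(mean_degree=10, lambda_prop=0.1))
# CriticalityParams(sigma=1.0, dtc=0.0)

# A full synthetic cohort (15 controls, 15 patients x 5 sessions)
table = cohort_metric_table(generate_cohort(CohortSpec(seed=0)))
res = analyze_cohort(table)
print(res["session_contrasts"][["label", "statistic", "p_adjusted"]].head(2))
#          label  statistic    p_adjusted
# 0  CTR vs PAT1 -37.761...  2.5e-15
# 1  CTR vs PAT2  -6.460...  3.3e-05
print(round(res["hierarchy"].rho, 2))   # -1.0  (reversed network hierarchy)
```

The negative t statistics say patients' global INT exceeds controls' at
every session; the hierarchy rho near −1 says the control network ordering
(cerebellar shortest … default-mode longest) is reversed one month
post-stroke, both by construction of the generator and recovered by the
estimator.

Command-line equivalents: `neurotimescales generate-cohort / metrics /
analyze / simulate / sweep / to-bold / run-empirical / run-model`.

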