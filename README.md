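# tagrecover

Estimate how long a tagged marine animal takes to return to baseline
behaviour after capture, instrumentation and release.

Capture and tagging of whales and other marine animals induces a transient
stress response: immediately after release the animal moves differently
and dives differently, and any analysis of "natural" behaviour must first
decide how much of the record to discard.  `tagrecover` implements two
complementary, transparent estimators of that recovery time from the two
standard biologging streams, for researchers working with depth and
accelerometer records from animal-borne tags:

**Quantile regression on accelerometer metrics.**  Movement metrics —
VeDBA (vectorial dynamic body acceleration, a proxy for energy
expenditure), ODBA, and jerk (norm of the acceleration derivative, a
proxy for rapid movement) — are modelled at a chosen quantile level τ as

```
log Y_τ(t) = β_ind + α_g · z,        z = 1/(t+1),
```

with one offset β per animal (its baseline), one slope α per animal group
(the tagging effect; e.g. short vs long handling time), and t hours since
release.  On the natural scale the effect is a multiplicative factor
exp(α·z) that decays to 1.  The return time at tolerance δ ∈ (0,1) solves
exp(α·z) = δ:

```
t_R = max(0, |α| / |ln δ| − 1),        default δ = 0.25.
```

Working at quantiles rather than the mean separates typical behaviour
(τ = 0.5) from vigorous activity (τ = 0.9), which can recover at very
different rates.  Fits minimize the pinball loss; intervals and slope
tests use a cluster bootstrap with the animal as resampling unit.

**Relative entropy on dive profiles.**  Each hour's dives are summarized
as a probability vector P_t over three target-depth categories (Shallow /
Medium / Deep, duration-weighted).  A baseline distribution Q is a
weighted average of the hourly distributions in an a-priori "normal
region" t > t_N, weighted by how many tags were still transmitting (tags
drop off at staggered times).  The divergence J(P_t ‖ Q) is the
Jensen–Shannon relative entropy (base 2, so J ∈ [0,1]).  A leave-one-out
95% band of normal-region divergences — the *region of recovery* (RoR) —
defines which divergences are typical; hours are labelled +1 (inside) or
−1 (outside), and the return time is the knot of a segmented regression
on the cumulative label sum, averaged over block-bootstrap replicates.

The package also ships the full preprocessing chain (moving-quantile
zero-offset depth correction, dive segmentation, low-pass static/dynamic
acceleration split, metric aggregation) and a seeded synthetic-cohort
generator with closed-form ground truth, so every stage is testable
without any data download.

## Worked example

```python
import numpy as np
from tagrecover import (
    AccelScenario, QRDesign, simulate_accel,
    fit_quantile_model, recovery_time, bootstrap_ci,
)

sc = AccelScenario(                      # two handling-time groups,
    n_animals=10, duration_h=100.0,      # 10 animals each, 100 h records,
    obs_per_h=60,                        # one VeDBA value per minute
    slopes={"Long": (-2.5, -1.0), "Short": (-0.5, -1.0)},
    seed=42,
)
series, group_of, truth = simulate_accel(sc)

design = QRDesign.from_series(series, group_of, tau=0.5)
fit = fit_quantile_model(design)
print({g: round(a, 3) for g, a in fit.alpha.items()})
est = recovery_time(fit, "Long", delta=0.25)
ci = bootstrap_ci(design.subset(design.group == "Long"), fit, "Long",
                  n_boot=200, seed=0)
print(round(est.t_r, 2), (round(ci.ci_lower, 2), round(ci.ci_upper, 2)))
```

prints

```
{'Long': -2.497, 'Short': -0.494}
0.8 (0.78, 0.82)
```

The fitted median slopes match the generating values (−2.5 and −0.5); the
"Long" group's median response needs t_R ≈ 0.8 h to come within 25% of
baseline (the generator's closed-form truth is 0.803 h), and the "Short"
group's |α| is below |ln 0.25| ≈ 1.386, so its t_R is 0: within tolerance
from release.  The same cohort's dive stream is analysed with
`hourly_distributions` → `reference_distribution` → `region_of_recovery`
→ `label_series` → `block_bootstrap_breakpoint`; see `docs/methods.md`.

## Command line

```
tagrecover simulate --out bundle/ --seed 1          # synthetic cohort
tagrecover preprocess --config run.yaml             # raw traces -> tables
tagrecover qr       --config run.yaml --seed 1      # accelerometer arm
tagrecover entropy  --config run.yaml --seed 1      # dive-profile arm
tagrecover all      --config run.yaml --seed 1 --plots
```

The config is YAML (`input_dir`, `species`, `taus`, `t_n`, `t_upper`,
`block_h`, bootstrap sizes, `seed`, ...).  Outputs are CSV tables (one
row per metric × τ × group, and one per group for the dive arm), JSON
results, and a reproducibility manifest with the config hash and package
versions.

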