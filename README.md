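# aacsim

Simulation and single-case statistics for approach–avoidance conflict
behaviour.

In a widely used virtual foraging paradigm, a player leaves a safe place
to collect reward tokens while a "sleeping predator" may wake — with a
constant hazard of 0.1, 0.2 or 0.3 per 100 ms depending on threat level —
and forfeit everything collected in the current round.  A companion task
asks the player to *expose* the predator (up to six attempts per round,
each succeeding with the same probabilities), revealing whether key
presses are driven by irrelevant token appearances.  Lesion-patient
studies with this paradigm need analysis machinery that ordinary group
statistics do not provide: single cases compared across *different*
control groups, and model-based decomposition of response-timing
differences.

`aacsim` provides that machinery end to end, for simulated cohorts in
which the ground truth is known:

- **Generative simulator** for both tasks — 45-epoch blocks, six
  exponential token cycles per epoch (mean availability 1.25 s, waits
  +500 ms), discrete per-100-ms predation hazard, logistic
  approach policies and exGauss/uniform press timing — with control and
  lesion agents whose policy parameters are individually perturbed.
- **Readout extraction**: the cumulative decision reconstruction (six
  records per uncaught epoch), strictly windowed approach/return
  latencies (150 < AL < 2000 ms, 0 < RL < 2000 ms, sixth token excluded),
  true catch rates, and >4 SD leave-one-out performance QC.
- **Condition effects**: mixed-model F tests for the 3 (threat) × 6
  (potential loss) design with random subject intercepts,
  Greenhouse–Geisser correction, optional Satterthwaite df via lmerTest,
  and per-subject linear coefficients.
- **Ordinal dissociation test**: percentile ranks of patients within
  their own control groups and a rank-based bootstrap comparing two
  patient groups against 10,000 simulated control cohorts of the same
  sizes, backed by an exact-enumeration oracle.
- **Exposure-time mixture model**: `p(t) = w·f_null + (1−w)·exGauss(mu,
  sigma, lam)` over times since the last token onset, fitted by
  multi-start bounded MLE in shared or group-split variants and compared
  with `LBF = 0.5·(BIC_ref − BIC)` (|ΔLBF| > 3 decisive).

## Worked example

Rank three patients (each at the 100th percentile of their 10-control
groups) against two patients ranked within control groups of 9 and 24:

```python
from aacsim import ordinal_dissociation_test

res = ordinal_dissociation_test(
    ranks_a=[100.0, 100.0, 100.0], control_sizes_a=[10, 10, 10],
    ranks_b=[100.0, 45.8],         control_sizes_b=[9, 24],
    n_sim=10_000, sidedness="one", seed=11)
print(res.summary())
```

```
Ordinal dissociation test (one-sided, n_sim=10000, seed=11)
  group A mean rank: 100.0 (n=3, controls (10, 10, 10))
  group B mean rank: 72.9 (n=2, controls (9, 24))
  observed rank difference: 27.10
  null difference: mean 0.21, sd 28.33
  p = 0.1763
```

A mean-rank gap of 27 points is well inside the spread that two control
cohorts of these sizes produce by exchangeability alone (null SD 28.3),
so this pattern alone is no evidence for a dissociation.

Fit the exposure-time mixture to simulated Task-2 cohorts in which the
patient agents' simple-response decay is genuinely slower (exponential
time constant 900 ms vs 400 ms):

```python
from aacsim import (TaskConfig, ExposurePolicy, ExposureMixtureModel,
                    build_null_distribution, compare_models,
                    exposure_latencies)
from aacsim.exposure import merge_latency_sets
from aacsim.simulate import simulate_task2_block

cfg = TaskConfig()
null = build_null_distribution(cfg, n_sim=5000, seed=0)
lat = lambda logs: merge_latency_sets(
    [exposure_latencies(lg) for lg in logs]).latencies
ctrl = [simulate_task2_block(cfg, ExposurePolicy(), s) for s in range(8)]
pat = [simulate_task2_block(cfg, ExposurePolicy(lam=1/900), 100 + s)
       for s in range(3)]

model = ExposureMixtureModel({"control": lat(ctrl), "patient": lat(pat)}, null)
fits = model.fit_all(n_starts=6, seed=1)
print(compare_models(fits).round(2).to_string(index=False))
print(fits["split_lambda"].summary())
```

```
       variant  n_params  log_likelihood      bic   lbf  converged
  split_lambda         5        -6781.07 13595.89 11.16       True
split_lambda_w         6        -6781.06 13602.63  7.79       True
       split_w         5        -6784.99 13603.73  7.24       True
      combined         4        -6795.60 13618.21  0.00       True
   split_sigma         5        -6794.43 13622.62 -2.21       True
      split_mu         5        -6795.02 13623.79 -2.79       True

Exposure mixture fit: variant=split_lambda (k=5, n=855)
  logL = -6781.07   BIC = 13595.89
  LBF vs reference = 11.16
  [control] w=0.407  mu=369.7 ms  sigma=91.8 ms  lam=0.00304 /ms (tau=329 ms)
  [patient] w=0.407  mu=369.7 ms  sigma=91.8 ms  lam=0.00123 /ms (tau=810 ms)
```

The lambda-split model wins with LBF 11.2 over the shared-parameter
reference and a decisive 3.4-point margin over the runner-up, and the
fitted decay constants (329 ms vs 810 ms) recover the generative
difference — the model correctly localizes the group difference to the
decay of the token-triggered response, not to the weight of the
token-unrelated process.

A full seeded pipeline — simulate cohorts (by default 3 MTL-like, 1
HC-like and 1 amygdala-like agent with control groups of 10, 9 and 24),
extract tables, fit condition effects, rank patients, run the
dissociation test and the exposure model — is one command:

```bash
aacsim run --out results/ --seed 11
aacsim dissociate --ranks-a 100,100,100 --nctrl-a 10,10,10 \
                  --ranks-b 100,45.8 --nctrl-b 9,24 --nsim 10000 --seed 11
```

## Layout

| module | contents |
| --- | --- |
| `aacsim.config` | task constants, agent policies, cohort specs (YAML) |
| `aacsim.events` | timestamped event logs, JSONL/CSV serialization |
| `aacsim.simulate` | Task-1/Task-2 generative engine, cohorts, ratings |
| `aacsim.extract` | decisions, latencies, catch rates, QC |
| `aacsim.effects` | mixed-model F tests, GG epsilon, subject summaries |
| `aacsim.singlecase` | percentile ranks, ordinal dissociation test |
| `aacsim.exposure` | T2 latencies, nulls, KS tests, mixture model, LBF |
| `aacsim.pipeline` | seeded end-to-end orchestration, run manifests |
| `aacsim.cli` | `aacsim` command group |

See `docs/methods.md` for the modelling assumptions, numerical choices
and limitations.
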