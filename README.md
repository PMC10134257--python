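# nsclc-cea

A Markov cohort cost-effectiveness model comparing seven first-line
treatment strategies for advanced non-small cell lung cancer (NSCLC) —
six immunotherapy regimens (pembro-chemo, nivo-ipi, nivo-ipi-chemo,
atezo-chemo, atezo-beva-chemo, single-agent pembrolizumab) against
platinum-doublet chemotherapy — across PD-L1 expression strata
(all, <1%, 1–49%, ≥50%), from a US health-care-sector perspective.

It is written for health-economics researchers who want a tested, scriptable
version of this class of analysis: three-state cohort model
(progression-free → progressive disease → dead), survival-curve
calibration, hazard-ratio arm construction, discounted half-cycle-corrected
cost/QALY accrual, ICER/dominance frontier, and deterministic + probabilistic
sensitivity analyses.

## The model in brief

Per 6-week cycle, with PF→PD probability `p_t` derived from the reference
PFS curve and PD→death probability `q_t` calibrated to the OS curve:

```
pf[t+1]   = pf[t](1 − p_t)
pd[t+1]   = pd[t](1 − q_t) + pf[t] p_t
dead[t+1] = dead[t] + pd[t] q_t
```

Immunotherapy arms scale each transition on the rate scale,
`p' = 1 − (1 − p)^HR`, using per-endpoint hazard ratios vs chemotherapy.
Outcomes are discounted at 3%/year; ICERs are computed against the next
costliest undominated strategy after strong and extended dominance
screening; PSA draws utilities ~ Beta, costs ~ Gamma, histology ~ Dirichlet
and hazard ratios ~ lognormal-from-CI.  See `docs/methods.md` for the full
account and `docs/parameter_file.md` for the input schema.

The trial-curve coordinates behind the original analysis are not publicly
deposited; the package ships a synthetic curve generator with the exact
structure the model assumes (see `nsclc_cea.synthetic`), plus the published
parameter table and base-case results table as validation inputs.

## Worked example

```python
import nsclc_cea as n

ps = n.fixture_parameter_set(seed=1)   # shipped costs/HRs + synthetic curves
result = n.basecase(ps, "ge50")        # PD-L1 >= 50% stratum
print(result.to_frame().round(2).to_string(index=False))
```

prints

```
      strategy      cost  life_years  qalys   icer_ly  icer_qaly              label
  chemotherapy 156930.24        1.79   1.34       NaN        NaN          reference
 pembrolizumab 215938.90        2.36   1.80 103891.38  128879.92        on_frontier
      nivo_ipi 391176.73        2.61   2.01       NaN        NaN   weakly_dominated
   atezo_chemo 402352.98        3.07   2.33       NaN        NaN   weakly_dominated
nivo_ipi_chemo 410234.14        2.71   2.06       NaN        NaN strongly_dominated
  pembro_chemo 506693.65        3.84   2.91 197241.95  260895.30        on_frontier
```

Reading: on this synthetic study, single-agent pembrolizumab buys 0.46
QALYs over chemotherapy at $128,880 per QALY (on the frontier, under a
$150,000/QALY threshold); pembro-chemo adds more QALYs but at $260,895 per
QALY; the other regimens are dominated.  Absolute numbers depend on the
synthetic curves — the structure (who is dominated, frontier ordering) is
the reproducible part.

The `examples/` scripts walk each capability: synthetic study generation,
base-case frontiers, validation against the published base-case table,
tornado/threshold-price analysis, and PSA with acceptability curves.  A thin
CLI wraps the same pipeline:

```
nsclc-cea fixture --out study --seed 1
nsclc-cea basecase --config study/study.yaml --stratum ge50 --out results
nsclc-cea ceac --config study/study.yaml --stratum ge50 --iterations 1000 --seed 1 --out results
```

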