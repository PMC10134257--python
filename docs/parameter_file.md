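# Parameter file schema

A study is a YAML file (plus optional curve CSVs referenced by relative
path).  The shipped table `src/nsclc_cea/data/strategy_parameters.yaml` is a
complete example; `nsclc_cea.make_fixture_study()` writes a loadable study
directory with synthetic curves.

## Sections

### `econ`
Global economics.  Keys and defaults:

| key | default | meaning |
|---|---|---|
| `cycle_length_weeks` | 6 | Markov cycle length |
| `annual_discount` | 0.03 | discount rate for costs and effects |
| `wtp` | 150000 | willingness-to-pay, USD/QALY |
| `admin_cost_per_cycle` | 678 | administration cost per 6 weeks |
| `bsc_cost_per_cycle` | 4574 | best supportive care per 6 weeks (PD state) |
| `utility_pd` | 0.72 | utility in progressive disease (all strategies) |
| `squamous_fraction` | 0.28 | histology split weighting the chemo backbone |
| `secondline_unit_costs` | — | map `{chemo, immunotherapy, targeted}` → USD/6 wk |
| `secondline_duration_cycles` | 4 | cycles priced into the second-line lump |
| `horizon_max_years` | 30 | lifetime horizon |
| `stop_alive_fraction` | 1e-4 | early stop once the cohort is effectively dead |
| `bsc_in_pf` | false | also accrue BSC in the progression-free state |

### `drug_costs`
Per-6-week drug costs (USD): `pembrolizumab`, `nivolumab`, `ipilimumab`,
`atezolizumab`, `bevacizumab`, `pemetrexed`, `carboplatin`, `paclitaxel`,
`docetaxel`, `erlotinib`.  Per-cycle strategy costs are derived from these
(see `chemo_backbone` below), so sensitivity analyses address drug costs
directly.

### `strategies`
One entry per regimen; `chemotherapy` (the reference) is mandatory.

| key | meaning |
|---|---|
| `io_drugs` | list of drug names whose summed cost is the per-cycle immunotherapy cost |
| `io_max_cycles` | immunotherapy cap (17 = 2 years of 6-week cycles) |
| `induction_chemo_cycles` | 6-week cycles with platinum-doublet cost (0, 1 or 2) |
| `chemo_backbone` | `none`, `histology_weighted` or `paclitaxel_carboplatin` |
| `pemetrexed_maintenance` | non-squamous-weighted pemetrexed until progression |
| `bevacizumab_maintenance` | bevacizumab until progression (after induction) |
| `utility_pf` | progression-free utility in [0, 1] |
| `secondline_mix` | map class → proportion (each in [0,1], sum ≤ 1) |
| `ae_lump_cost` | one-time adverse-event cost at model entry |

### `hazard_ratios`
`strategy → stratum → {pfs: [point, lo, hi], os: [point, lo, hi]}` with
strata `all`, `lt1`, `1to49`, `ge50`.  **Presence encodes availability**:
a strategy without an entry for a stratum is not evaluated there.  The
reference strategy takes no entry (HR ≡ 1).

### `curves` (optional)
`stratum → {pfs: path-or-inline, os: path-or-inline}`.  Paths are relative
to the YAML file and point at two-column delimited text
(`time_weeks,survival`; comma or tab; header optional).  Inline form:
`{times: [...], survival: [...]}`.  A file without this section is a
parameters-only table (loadable, but not evaluable until curves are added).

### `distributions`
PSA sampling specs keyed by dotted parameter path:
`{family: beta|gamma|dirichlet|lognormal_from_ci|fixed, params: [...]}`.
Gamma is (shape, scale); Dirichlet samples report the first component.
Hazard ratios need no entry — they are always sampled lognormal-from-CI.

### `dsa_ranges`
`path: [low, high]` — the ranges swept by the one-way DSA/tornado.

## Dotted parameter paths

Everything a sensitivity analysis can vary is addressed uniformly:

```
econ.admin_cost_per_cycle
econ.secondline_unit_costs.chemo
drug_costs.pemetrexed
strategy.pembro_chemo.utility_pf
strategy.chemotherapy.secondline_mix.immunotherapy
hr.nivo_ipi.lt1.os            # the point estimate
hr.nivo_ipi.lt1.os.low        # a CI bound
```
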