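# Methods

## The model

`nsclc_cea` implements a three-state Markov cohort model for treatment-naive
advanced non-small cell lung cancer (NSCLC) without actionable mutations:
**progression-free (PF) → progressive disease (PD) → dead**.  The cohort
enters in PF; death occurs only via PD (background mortality in metastatic
NSCLC is negligible over the relevant horizon, so none is modelled).  The
cycle length is 6 weeks — the administration interval of the least frequent
regimen component (ipilimumab); 3-weekly drugs are costed per 6 weeks.

Seven first-line strategies are compared: platinum-doublet chemotherapy
(the reference), pembrolizumab + chemotherapy, nivolumab + ipilimumab with
and without chemotherapy, atezolizumab + chemotherapy with and without
bevacizumab, and single-agent pembrolizumab.  Availability per PD-L1
stratum (`all`, `lt1`, `1to49`, `ge50`) is encoded by the presence of
hazard ratios: single-agent pembrolizumab only for PD-L1 ≥ 1%,
atezo-beva-chemo only for `all`/`lt1`.

## Transition probabilities

The chemotherapy arm is calibrated to reference PFS/OS curves:

* **PF → PD** is read directly off the PFS curve at cycle boundaries,
  `p_t = [S(t) − S(t+1)] / S(t)` (0 once the curve is exhausted).  Curves are
  step functions (Kaplan–Meier estimates are step functions), so boundary
  values use last-value-carried-forward interpolation of the digitised
  points.
* **PD → death** is calibrated cycle-by-cycle so the modelled OS tracks the
  OS curve.  We use *level targeting*: `q_t` is chosen so cumulative
  modelled deaths reach `1 − S_OS(t+1)` given the modelled PD occupancy.
  Whenever the model tracks the curve this reduces to the increment form
  `q_t = [S_OS(t) − S_OS(t+1)] / PD(t)`, but unlike the increment form it
  recovers from boundaries where the demanded deaths are structurally
  infeasible (PD occupancy ≈ 0, notably cycle 0, where `q` is carried
  forward from the previous cycle, starting at 0).  Infeasible `q` are
  clipped into [0, 1] and counted; more than 5% clipped cycles fails
  calibration, signalling inconsistent input curves.  OS below PFS — a
  digitisation artifact, structurally impossible — is repaired by raising
  OS to PFS, with a warning.

Immunotherapy arms are built by scaling each transition on the rate scale:
`r = −ln(1 − p)`, `r' = HR·r`, `p' = 1 − e^{−r'} = 1 − (1 − p)^{HR}`, with
the PFS hazard ratio on PF → PD and the OS hazard ratio on PD → death.
Applying the OS HR to the PD → death transition hazard is not mathematically
identical to scaling the hazard of the OS *curve* (death is reachable only
through PD); with two transitions and per-endpoint hazard ratios it is the
natural reading, and we use it for all arms over the whole horizon
(constant-HR assumption).  Hazard ratios are inputs (from a network
meta-analysis in the source setting); no meta-analysis is performed here.

Beyond trial follow-up, each probability vector is held at the arithmetic
mean of its last `tail_window = 3` observed values (single-cycle tails of
digitised curves are noisy).  No parametric (Weibull/log-normal) fitting is
done anywhere — extrapolation from terminal transition probabilities is the
modelling choice this package implements.

## Accrual

Cohorts run to 30 years (260 cycles) or until the alive fraction drops
below 1e-4.  Life years and QALYs use trapezoidal half-cycle correction
(average of adjacent boundary occupancies; the standard discrete-time
equivalent of a half-cycle shift) and are discounted at 3%/year at the
cycle of accrual: `(1.03)^{−t·6/52}`.

Costs per PF cycle: administration ($678) plus the immunotherapy drug cost
up to a 2-year cap (17 six-week cycles, 104/6 truncated), the
platinum-doublet backbone during induction (2 cycles = 12 weeks for
pembro-chemo / atezo(±beva)-chemo / chemotherapy, 1 cycle for
nivo-ipi-chemo, 0 for IO-only regimens), then maintenance pemetrexed
(weighted by the 72% non-squamous fraction) and/or bevacizumab until
progression.  The backbone cost is histology-weighted:
`0.28·(paclitaxel+carboplatin) + 0.72·(pemetrexed+carboplatin)`; the
atezo-beva-chemo backbone is paclitaxel+carboplatin for all histologies.
Costs per PD cycle: best supportive care ($4,574).  Whether BSC also
accrues in PF is exposed as `econ.bsc_in_pf` (default off: the active
regimen is the PF cost).  One-time costs: an adverse-event lump at entry,
and at each PD entry an expected second-line lump = Σ(class mix × per-cycle
unit cost × 4 cycles), with administration cost added per cycle for the
intravenous classes (docetaxel-priced chemotherapy, nivolumab-priced
immunotherapy) but not oral erlotinib.  The 4-cycle duration is a modelling
choice (the cohort does not track time-in-state and no durations are
reported); it is configurable and exposed to DSA.  One-time costs are
discounted at the cycle of accrual but not half-cycle corrected.

## Frontier

Strategies are sorted by cost.  Strong dominance: cheaper-or-equal with
more QALYs (equal-cost ties resolved toward the higher-effect strategy).
Extended dominance: sequential ICERs over the survivors must strictly
increase; violators are removed iteratively.  ICERs (per QALY and per life
year) are reported against the next costliest undominated strategy, with
the comparator chosen on the QALY scale for both.  A post-hoc assertion
checks strict ICER monotonicity on every call, and the net-monetary-benefit
maximiser at any willingness-to-pay provably lies on the QALY frontier
(tested on a dense WTP grid).

## Sensitivity analyses

* **HR-bound scenarios**: all hazard ratios set simultaneously to their
  lower or upper 95% CI bound, frontier recomputed.
* **One-way DSA / tornado**: one parameter at an end of its declared range,
  everything else at base; pairwise ICER at each end; bars ordered by span.
  Ranges are the published ones where given; costs without published ranges
  (the synthetic adverse-event lumps) use ±20%, matching the pattern of the
  published cost ranges (e.g. 543–814 around 678).
* **Threshold pricing**: bisection on a cost parameter until the pairwise
  ICER is within $1 of the willingness-to-pay, with an explicit
  non-monotonicity check and a reported failure if even a zero price cannot
  reach the threshold.
* **PSA**: utilities and second-line proportions ~ Beta, costs ~ Gamma,
  squamous fraction ~ Dirichlet(163, 419) (first component), hazard ratios
  ~ lognormal with `μ = ln(point)`, `σ = [ln(hi) − ln(lo)]/3.92` (the
  standard choice for ratio parameters reported with a 95% CI).  PFS and OS
  hazard ratios of the same strategy are sampled independently — no joint
  distribution is reported; a documented limitation.  Sampled second-line
  mixes summing above 1 (rare) are renormalised.  The default is 1000
  iterations; only parameters with declared distributions (plus HRs) vary.
* **CEAC**: at each WTP on a $0–300,000 grid ($10,000 steps, anchored at
  the $150,000/QALY threshold) the probability a strategy is cost-effective
  is the fraction of draws in which it attains the maximal net monetary
  benefit; exact ties split equally (a measure-zero event under continuous
  sampling, deterministic on degenerate fixtures).

## Synthetic data

The reference-arm curve coordinates behind the published analysis (digitised
from trial figures) are not deposited, so the generator supplies stand-ins
with the structure the analysis assumes:

* `make_survival_curve`: piecewise-exponential `S(t) = exp(−∫λ)`, optional
  truncated multiplicative digitisation jitter.
* `make_cohort_curves`: a PFS/OS pair produced by the two-transition cohort
  itself — PFS is piecewise-exponential PF occupancy, OS is PF+PD occupancy
  under a piecewise-exponential PD→death hazard.  A *pure*
  piecewise-exponential OS is structurally unreachable by this model (no
  deaths can occur in cycle 0 because PD starts empty), so exactness claims
  (calibration fidelity to 1e-10) are made on cohort-consistent curves; the
  pure generator is used where exactness is not claimed.
* `make_fixture_study`: a loadable study directory — the shipped parameter
  table plus per-stratum curves and a seed-recording manifest.  Default
  medians loosely echo a chemotherapy arm (PFS ≈ 5.5, OS ≈ 14 months for
  `all`, slightly worse for `lt1`, slightly better for `ge50`), chosen once
  as plausible values; the PD→death hazard is set from the OS−PFS median
  gap, so the realised OS median is approximate.  Everything is labelled
  synthetic and claims no trial fidelity.

Because the curves are synthetic, absolute costs/QALYs computed on the
fixture do **not** reproduce the published base-case table; what passing
tests show is that the *machinery* is correct (calibration fidelity,
closed-form accrual, dominance logic on the printed triples, sampling
moments, monotonicity), plus qualitative agreement of the fixture results
(e.g. pembrolizumab on the `ge50` frontier at both HR bounds, drug costs
and utilities dominating the tornado).

## Numerical choices and edge cases

* Probabilities are propagated with `log1p`/`expm1` to avoid cancellation.
* Degenerate inputs: exhausted PFS curves give `p = 0` thereafter; empty-PD
  cycles carry the previous `q`; equal-effect ICERs raise a dedicated
  error that frontier code treats as a dominance case; identical
  (cost, effect) duplicates keep the first.
* Problem sizes: fidelity checks use ~25 observed cycles over ~3 synthetic
  follow-up years; microsimulation checks use 100,000 patients × 30 cycles
  × 20 random schedules; sampling-moment checks use 10,000 draws — sizes at
  which Monte-Carlo error bounds (3 binomial/standard errors) are tight.

## Known limitations

* Constant hazard ratios over the full horizon.
* No individual-level heterogeneity, no background mortality.
* Adverse-event costs are a per-strategy synthetic placeholder lump (the
  source cost table is not public); treat absolute fixture costs
  accordingly.
* Second-line therapy is a one-time expected lump, not a modelled state.
* The published absolute results are reproducible only where they depend on
  printed inputs (the frontier/ICER table); curve-dependent magnitudes are
  validated structurally, not numerically.
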