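# Methods

## Model structure

Two strategy-specific state-transition models share a 3-month cycle, an
index patient (age 71, cT2-4aN0M0 urothelial carcinoma, fit for surgery,
radiation and cisplatin), a 5-year base-case horizon (10 years as a
sensitivity horizon) and the assumption of equivalent oncologic efficacy:
progression-to-metastasis and background mortality use the same parameter
keys in both arms.

**TMT arm (9 states).** Entry in *no progression* (bladder-preserved
surveillance), which fires the initial treatment cost ($41 777) as a
one-time toll at model entry. From surveillance, patients may move to:
*short-term toxicity* (reachable only during the treatment phase, cycles
0–2, mean sojourn ≈1 cycle); *long-term GU/GI toxicity* (chronic);
*recurrent NMIBC* (induction BCG: one-time cost and QALY toll, mean sojourn
≈1.6 cycles, may progress to MIBC); *recurrent MIBC*, treated with salvage
cystectomy — modelled as a persistent post-cystectomy state that fires the
**RC initial-cost parameter** as its entry toll and thereafter carries
post-cystectomy utility and RC surveillance cost (the same parameter keys as
the RC arm, so a change in the cost of cystectomy propagates into the TMT
arm through salvage); *metastatic first line* (gemcitabine/cisplatin) →
*second line* (pembrolizumab) → *terminal care* → death; and *death*.

**RC arm (6 states).** Entry in *no progression* (post-cystectomy
surveillance; initial cost $19 923 at entry); *short-term (perioperative)
toxicity* reachable in cycles 0–1; *long-term toxicity*, whose per-cycle
cost and disutility are the equal-weighted composition of three tracked
complication categories (small-bowel obstruction, parastomal hernia,
uretero-enteric anastomotic complication) plus a one-time intervention cost
on onset; *metastatic first line* → *second line* → death (progression on
second-line therapy is not tracked as a separate state; its hazard adds to
the second-line exit-to-death rule). Long-term toxicity is modelled as an
exclusive health state per arm rather than as co-occurring attribute flags:
that keeps the cohort occupancy vector an exact description of the process
and the state roster explicit; category co-occurrence is second-order at
the observed incidences.

Death is the unique absorbing state in both arms, reachable from every
state (checked by `validate_model`). Per-state outgoing probabilities are
validated to sum to ≤ 1 in every cycle regime; the residual mass is the
stay probability.

## Accrual, discounting, conversions

* State membership at the start of a cycle earns the state's full per-cycle
  cost and utility×Δ, valued at the cycle-start discount time
  `(1.03)^(−t)`. No half-cycle correction by default (an optional
  `half_cycle_correction` flag averages start/end occupancy for sensitivity
  checking). The death state accrues nothing.
* One-time tolls (costs, QALY decrements) fire on the transition into a
  state, at the destination cycle's discount time. The entry state's tolls
  (initial treatment) fire at model entry only — returning to surveillance
  after a toxicity or recurrence episode does not re-bill the initial
  treatment. Re-entering a recurrence state does re-fire its tolls (each
  NMIBC recurrence is treated again).
* Probabilities stated per year or as 5-year cumulative risks convert to
  per-cycle probabilities under a constant-hazard assumption,
  `p_cycle = 1 − (1−p)^(Δ/basis)`. The same per-cycle hazard is used beyond
  the basis interval when the horizon is 10 years (an extrapolation; see
  limitations). The TMT metastasis-risk-reduction lever is an absolute
  reduction applied on the 5-year cumulative scale before conversion,
  clipped to [0, 1]; its base value is 0 (equivalent efficacy).
* The microsimulation samples individual trajectories from exactly the
  per-cycle matrices the cohort solver iterates, with identical accrual
  rules, so its means converge to the cohort totals (tested at 3 Monte
  Carlo standard errors); the cohort solver is the base-case reporting
  engine and the per-draw engine inside the PSA.

## Parameters

Every input carries `base`, `low`, `high`, a time basis and a PSA
distribution family (beta for probabilities/utilities/disutility tolls,
gamma for costs; `fixed` values are excluded from PSA). A low–high range is
read as a 95% interval, `se = (high − low)/(2·1.96)`, and distributions are
fitted by the method of moments. Utilities at exactly 0 or 1 are nudged by
1e-6 before beta fitting to keep the moments feasible.

Anchored values: initial treatment costs ($41 777 TMT, $19 923 RC), the
5-year salvage-cystectomy probability (13%), the 3%/year discount rate and
the $100 000/QALY threshold. The remaining defaults are set once to
literature-plausible magnitudes: 5-year cumulative metastasis 20%; age-71
background mortality 2.5%/year; metastatic line transitions giving ≈15
months median metastatic survival; NMIBC recurrence 25% at 5 years;
long-term toxicity 15% (TMT) and 22% (RC) at 5 years; near-equal baseline
utilities between arms (0.96 bladder-intact vs 0.945 post-cystectomy,
reflecting published elicitations that find similar values across
modalities — the QALY advantage of TMT is driven mostly by the toxicity
burden difference, not the baseline gap); pembrolizumab ≈$29k per 3-month
cycle (ASP-based with realistic dose intensity); gemcitabine/cisplatin ≈$6k
per cycle all-in. Uncertainty ranges: ±25% for probabilities and most
costs, ±50% for the two initial treatment costs (payer-to-payer variation
in bundled surgical/radiation reimbursement is large, and the published
one-way ranges clearly extend far beyond ±25%), ±0.075 absolute for
utilities (clipped to [0, 1]) and ±50% for disutilities and tolls.

## Calibration

The published 5-year cells (RC $40 489 / 3.87 QALY; TMT $71 014 / 3.94
QALY) are the fit surface. Free keys — the smallest set spanning the
targets without touching the anchored initial costs — are the per-arm
surveillance per-cycle costs, the long-term toxicity disutilities (TMT
GU/GI plus the two leading RC categories) and background mortality. The
objective is the sum of squared *relative* residuals on the four cells plus
weighted (×3) residuals on the incremental cost and incremental QALY: the
decision statistics are small differences of similar-sized totals, and the
published cells are rounded to 0.01 QALY — coarse relative to ΔE ≈ 0.066 —
so the printed ICER ($464 291/QALY) pins the incremental QALY at
ΔC/ICER = 0.0657 where the rounded cells alone would imply 0.07.
Optimisation is bounded least squares (trust-region reflective,
finite-difference Jacobian) started from the generated base values, with
each free key bounded by its low–high range extended by 50% of its width;
it is deterministic, converges in <1 s, and a finite-difference influence
check warns if a free key moves no target. Convergence requires every
relative residual ≤ 1% (achieved: ≤ 0.06%). If a verbatim transcription of
the original input tables is supplied as a CSV/YAML parameter file, it is
used directly and calibration is skipped.

The calibrated set is evaluated out-of-sample at 10 years, where it
reproduces the qualitative ordering (TMT costlier and more effective) and
an ICER of ≈$282k/QALY against the published $309k/QALY — within the
uncertainty one should expect when the 5-year fit is extrapolated with
constant hazards.

## Sensitivity analyses

* **One-way / tornado.** Each non-fixed parameter is pinned at its low and
  high values with everything else at base. The bar metric is the span of
  the incremental NMB (TMT − RC) at the WTP threshold — stable where the
  raw ICER changes sign near ΔE = 0 — with the end-point ICERs emitted
  alongside. A degenerate range yields a zero-width bar.
* **Threshold.** Brent bisection on the incremental NMB as a function of
  one parameter, to $1 for costs and 1e-4 for probabilities; requires that
  the decision differ at the bracketing bounds. The metastasis-risk
  reduction lever has a fixed PSA distribution but a non-degenerate sweep
  range, so it participates in threshold and two-way analyses while staying
  out of the tornado row set and the PSA.
* **Two-way.** The decision at the WTP threshold over a (default 101×101)
  Cartesian grid of two parameters' ranges, evaluated with the vectorised
  batch cohort solver.

## Probabilistic sensitivity analysis

Each of `n` draws samples all non-fixed parameters independently (no
correlation structure is imposed) from their fitted distributions and
evaluates both strategies with the deterministic cohort solver — one
expected-value evaluation per Monte Carlo simulation, the tractable reading
of a 100 000-simulation PSA. Acceptability curves report, on a $0–$250 000
grid in $5 000 steps, the fraction of draws in which each strategy attains
the maximal NMB (exact ties split equally); the acceptability value at the
threshold equals the NMB tally of the scatter draws by construction. The
95% confidence ellipse on the (ΔE, ΔC) plane uses the bivariate-normal
approximation: centre at the sample mean, axes along the covariance
eigenvectors with semi-axes `sqrt(eigval · χ²₂(0.95))`; a singular
covariance sets a degenerate flag. Monte Carlo standard errors at
n = 100 000 are ≈0.1 percentage points on the acceptability fractions; a
10 000-draw run reproduces them to a few tenths of a point.

## What the synthetic generator does and does not emulate

The generator reproduces the published analysis's *structure* (per-state
per-cycle probabilities with ranges, nonnegative costs, utilities and
tolls) and, after calibration, its deterministic 5-year base case. It does
not reproduce the original analysis's input values themselves — where
those differ from the defaults here, the calibrated surrogate compensates
through the free keys. Passing tests therefore demonstrate that the model
machinery reproduces the published *results* under a plausible input set,
not that the individual inputs equal the originals; conclusions about any
single input's value should not be read off the synthetic table. Real
claims data also exhibit correlated costs, time-varying hazards and
practice variation in TMT delivery, none of which the independent-draw,
constant-hazard machinery represents.

## Numerical choices and degenerate inputs

* Horizons must be whole multiples of the cycle length (validated).
* Batch and single-evaluation cohort paths share one implementation
  (B = 1); PSA, two-way grids and the microsimulation reuse the same
  compiled per-cycle matrices.
* If a sampled draw pushes a state's outgoing mass above 1 (possible only
  in extreme tails), the outgoing row is rescaled to 1 and the stay
  probability floored at 0; base values are validated to make this a
  tail-only safeguard.
* Transitions made at the end of the final cycle fire no tolls (the
  destination time lies outside the horizon), identically in cohort and
  microsimulation.
* Seeds: every stochastic entry point (`simulate_individuals`, `run_psa`,
  the stress-profile generator) takes an explicit integer seed and is
  bit-reproducible; nothing reads global random state.

## Problem sizes used in the shipped tests and reproduction script

Cohort evaluations use 20 cycles (5 y) or 40 cycles (10 y). The test suite
runs PSA at 2 000–10 000 draws and microsimulations at 20 000–50 000
individuals; the reproduction script (`scripts/acceptance.py`) runs the PSA
at the full 100 000 draws per horizon. These sizes hold every Monte Carlo
check well inside its stated tolerance.

## Known limitations

* Equivalent-efficacy assumption: progression and survival inputs are
  shared between arms; any true oncologic difference enters only through
  the explicit risk-reduction lever.
* Constant hazards within (and beyond) each parameter's stated basis;
  no semi-Markov sojourn-time effects.
* Independent PSA draws; no correlation between, e.g., the two arms' cost
  inflation or toxicity rates.
* Medicare payer perspective only; no patient out-of-pocket or societal
  costs, no neoadjuvant chemotherapy (assumed equal between arms), no
  cisplatin-ineligible or newer first-line metastatic regimens.
* The 10-year results extrapolate a model calibrated at 5 years and should
  be read as a sensitivity horizon, not a lifetime analysis.
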