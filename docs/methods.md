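# Methods

`psmcea` implements a partitioned-survival cost-effectiveness analysis of
first-line pembrolizumab + trastuzumab + chemotherapy (the *PEM* arm)
against trastuzumab + chemotherapy (the *TRAS* arm) in advanced
HER2-positive gastric / gastro-esophageal-junction adenocarcinoma, from a
healthcare-system perspective with all costs in 2024 USD.  This note
documents the model, its assumptions, the synthetic data that drives the
shipped analyses, and the numerical choices that matter.

## Model structure

A partitioned survival model (PSM) derives state occupancy directly from two
survival curves per strategy rather than from transition probabilities.
With S_PFS the progression-free survival function and S_OS overall survival,
the cohort at time *t* splits into three mutually exclusive states:

    PFS(t)   = min(S_PFS, S_OS)(t)
    PD(t)    = S_OS(t) − PFS(t)          (progressed, pre-death)
    death(t) = 1 − S_OS(t)

The `min` clamp guards against extrapolated tails crossing: PD occupancy can
never go negative.  Patients enter in PFS and cannot regress.

Time runs in 21-day cycles (matching the dosing schedule) over a 30-year
horizon — long enough that residual survival under the heavy-tailed
log-logistic extrapolation is ~1% and economically negligible, while keeping
the trace at 522 cycles.  The half-cycle correction is realized by
evaluating occupancies at cycle midpoints t_mid = (i + 0.5)·21 days; this
matches the assumption that transitions occur mid-cycle and equals the
trapezoid correction to first order (halving the cycle length moves
undiscounted life-years by < 0.2%).  Both costs and outcomes are discounted
at 5%/year through continuous compounding, df = 1.05^(−t_mid/365.25) —
exact at annual boundaries and smooth at midpoints.  Extrapolated survival
is *not* capped by general-population mortality; over a 30-year horizon for
this population the uncapped tail is small, and the simplification is
deliberate and visible here.

## From published curves to survival functions

**Digitized inputs.**  The pipeline consumes (time, survival) coordinates
read off published Kaplan–Meier plots plus the number-at-risk table printed
beneath them — four curves (OS/PFS × two arms) per population.

**Pseudo-IPD reconstruction.**  Individual patient times and event flags are
reconstructed with the standard iterative interval-allocation scheme: within
each interval between consecutive at-risk times, events are placed at the
digitized drop times with integer counts chosen so the running
product-limit estimate tracks the digitized values; censorings are spread
deterministically at evenly spaced times in the interval, and their number
is iterated until the reconstructed at-risk count (records with time ≥ t)
reproduces the published number exactly.  Residual off-by-one drift from
integer rounding is closed by a repair pass that shifts single events at
the digitized times where the change least distorts the fit.  Two
conventions make the procedure fully deterministic: ties between candidate
event counts are broken toward *fewer* events (conservative survival), and
subjects still under observation after the last risk time are censored at
the last digitized time.  Total-event counts, which publications often omit,
are not used, so no final event-rescaling pass is applied.  On synthetic
curves (350 subjects/arm, ~30% censoring, monthly digitization) the
round-trip error |KM(reconstructed) − input| stays below 0.01 and at-risk
counts are exact.

**Parametric fitting.**  Six families are fitted to each reconstructed
dataset by right-censored maximum likelihood: exponential, gamma, Gompertz,
Weibull, log-logistic and log-normal, in the parameterizations spelled out
in `psmcea.survival` (conversion helpers cover the common alternative
conventions).  Event times are floored at 1e−6 months before density
evaluation because digitized grids can emit exact zeros where several
densities are unbounded.  Optimization runs five moment/quantile-based
starts per family through Nelder–Mead polished by L-BFGS-B on
log-transformed positive parameters (the Gompertz shape, which may
legitimately be negative, stays untransformed); the exponential rate uses
its closed form events/exposure.  Families are ranked by AIC (BIC is
computed and reported alongside; the configuration can switch the
criterion), ties broken by fewer parameters, then a fixed family order.
"Visual inspection" cannot be automated, so the pipeline exports the
fitted-curve overlays as CSV for a human to inspect while selection
defaults to the statistical criterion.  Medians use closed forms where they
exist (exponential ln2/λ, Weibull σ·ln2^{1/κ}, log-logistic α, log-normal
e^μ) and analytic/numeric inversion for gamma and Gompertz; a defective
Gompertz whose survival never reaches 0.5 raises an explicit
undefined-median error.

## Valuation

While progression-free, patients accrue the arm's first-line regimen:
pembrolizumab 200 mg flat (PEM arm only), trastuzumab 6 mg/kg with an
8 mg/kg first-cycle loading dose, and a regimen-mix-weighted chemotherapy
backbone (fluorouracil 800 mg/m²×5 + cisplatin 80 mg/m², or capecitabine
1000 mg/m² twice daily ×14 days + oxaliplatin 130 mg/m²), plus an
administration fee — all for at most 35 cycles, after which only follow-up
cost continues for life.  Dosing uses the reference 60 kg / 1.6 m² patient.
Pricing is linear in the dose (cost = dose/unit_size × unit price summed
over scheduled administrations); ceiling-to-vial wastage is available as a
flag but off by default.  Oral capecitabine shares the single aggregate
per-cycle administration fee — a documented simplification, since the fee
is not itemized by route.

After progression, the arm-specific subsequent-treatment proportion (0.39
PEM / 0.47 TRAS) receives ramucirumab 8 mg/kg ×2 + paclitaxel 80 mg/m² ×3
per 28-day cycle, pro-rated ×21/28 onto the model cycle and applied for the
whole of PD occupancy (no stated duration exists; this choice also gives
the subsequent-treatment proportion the dominant tornado leverage expected
of it); the remainder receives best supportive care.  Treating the two as
mutually exclusive alternatives is the default; an additive-BSC toggle
exists.  Grade ≥ 3 adverse events with incidence ≥ 5% enter once, in the
first cycle, as expected cost Σ incidence×cost and expected QALY loss
Σ incidence×disutility×(one cycle = 21/365.25 y); an absolute-decrement
alternative is a toggle.  A one-off end-of-life cost attaches to the
incident-death mass of every cycle.  QALYs weight occupancy by state
utilities (PFS 0.797, PD 0.577).

**Assistance program.**  Pembrolizumab is covered by a patient-assistance
scheme whose exact mechanics are not public; the model implements a
configurable `free_after_n` scheme — the first N self-paid cycles (default
4), every later cycle of the course program-funded — plus an `off` mode.
The default reproduces the scale of the published incremental cost, which
implies roughly four self-paid cycles in total; an annual-window variant
was considered and rejected because re-charging four cycles every 12 months
is inconsistent with both the program's design and the published
incremental cost.

Every Table-1-style number — unit prices, utilities, AE blocks, rates,
body metrics, discount rate — enters through the validated YAML
configuration (`psmcea/data/paper_like.yaml` is the reference set); nothing
is hard-coded, and unknown keys are rejected.

## Uncertainty analysis

* **Incremental comparison** — ΔCost, ΔQALY, ΔLY from unrounded totals;
  ICER = ΔCost/ΔQALY (undefined at ΔQALY = 0, with dominance labels when
  signs permit); NMB = WTP·ΔQALY − ΔCost.  The WTP anchor is three times
  2024 Chinese per-capita GDP, $39,999.86/QALY.
* **One-way DSA** — every ranged parameter set to its low and high bound in
  turn (others at base), the full deterministic model re-run, entries
  ranked by ICER span for the tornado.  Ordinary parameters carry ±20%
  ranges; the discount rate varies over 0–8% (applied jointly to costs and
  outcomes; separate variation is a flag) and the subsequent-treatment
  proportions over 0–100%.  Any rerun failure is annotated in the output,
  never silently dropped.
* **PSA** — Monte-Carlo resampling (default 1000 iterations, seeded):
  costs and AE disutilities from moment-matched Gamma (shape = m²/v,
  scale = v/m), utilities and AE incidences from moment-matched Beta
  (ν = m(1−m)/v − 1); printed ranges are treated as 95% intervals, so
  sd = (high − low)/(2·1.96).  Parameters marked fixed (discount rate, body
  metrics, regimen mix, subsequent-treatment rates) stay at base in the PSA
  though the DSA varies them.  Survival-curve parameters are held fixed —
  the published parameter table assigns them no distributions — which
  understates decision uncertainty and is a documented limitation.  Outputs
  are the incremental scatter and the CEAC over a 0–60,000 USD/QALY grid in
  500-unit steps (spanning 1–3× per-capita GDP).  Infeasible sampling
  configurations (e.g. a Beta variance exceeding m(1−m)) fail fast at
  validation, not mid-run.
* **Scenario analysis** — every curve refitted under a forced family
  (default log-normal, the strongest competitor to the log-logistic base
  case) and the ICER recomputed; the signed relative change is reported.

## Synthetic data and fixtures

`simulate_ipd` draws right-censored records from a declared family by
inverse-survival sampling, censoring at the minimum of an administrative
cut-off and an independent exponential dropout — the simplest mechanism
satisfying the random right-censoring assumed by the product-limit
estimator.  `digitize` converts a sample into the published-figure product:
KM values on a time grid plus an at-risk table.  Defaults emulate a
KEYNOTE-811-scale trial: 350 subjects/arm, ~45 months of follow-up,
dropout ≈ 0.01–0.02/month giving ~30% censoring.

The `paper_like_total` and `paper_like_cps_ge_1` fixtures are complete
runnable bundles whose curves are *expected values* of a declared
log-logistic truth — the noise-free limit of a carefully digitized figure —
so every seed reproduces them.  Scales pin the medians: PEM OS 20.0 months
and PFS 9.84 months (the printed validation anchors); control-arm and
subgroup medians are documented assumptions (TRAS OS 16.8 / PFS 8.0;
subgroup 20.5/10.4 vs 15.8/7.6).  Shapes are calibrated by a deterministic
root-solve so the model's discounted state life-years reproduce the
published base-case split (PFS 1.52/1.13 y, totals 2.48/2.31 y, and the
subgroup analogues), making the fixture's incremental economics behave like
the original evaluation.  Risk tables are round(350·S(t)·e^{−0.02t}) every
3 months; curves are sampled every 0.25 months to 45 months.  The
digitization density matters: grid reconstruction places each event at the
right edge of its grid cell, biasing fitted times up by about half a grid
step (~+0.5 months on a monthly grid, ~+0.1 at 0.25 months), which is why
the fixtures digitize densely while the round-trip tests deliberately use
the coarser monthly grid.

What the fixtures do **not** emulate: sampling noise in the curves
themselves, informative censoring, covariates, arm-specific follow-up
schedules, and the real trial's curve shapes beyond the median/LY anchors.
Passing tests therefore certify the machinery — reconstruction fidelity,
estimator consistency, accounting identities, analysis behavior — not the
reproduction of the original trial-dependent results, which would require
the original digitized coordinates.

## Numerical choices and degenerate inputs

* Event-time floor 1e−6 months; survival evaluations guard logs of zero.
* Event-count rounding is half-away-from-zero; allocation ties prefer fewer
  events.
* Optimizer tolerances: Nelder–Mead xatol/fatol 1e−10 then L-BFGS-B
  ftol 1e−12; a family whose starts all fail is dropped from the ranking
  (fitting fails only if *every* family fails); all-censored data raises a
  no-events error before any optimization.
* Occupancy conservation holds to 1e−12 per cycle by construction; report
  totals are exact component sums at full precision, with half-away-from-
  zero rounding to two decimals applied only at render time, and the ICER
  always computed from unrounded deltas (published component tables that
  round before summing cannot reproduce their own printed ratios — e.g. a
  printed QALY column that sums to 1.77 against a printed 1.76 total — so
  the unrounded path is the only self-consistent one).
* Degenerate PSA (all parameters fixed, or variances → 0) collapses exactly
  onto the deterministic base case; this is tested.

## Known limitations

Survival uncertainty is excluded from the PSA; no background-mortality cap;
no vial wastage by default; second-line duration uncapped; AE burden is a
single first-cycle lump; the assistance-program mechanics are an assumption
with a documented toggle; fixture curves are noise-free expected values.
Each limitation is either a configuration toggle or clearly scoped here.
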