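# Methods

## Model structure

The model is a cohort expectation (no microsimulation) over 14 enumerated
states: {NSR, ST-episodic, LT-persistent} × ablation counts {0,1,2,3},
plus permanent AF and death. The first model year is a decision-tree
phase realised as four 3-month cycles with year-one-specific transition
inputs, so that first-year costs and QALYs discount on the same clock as
the Markov phase; the occupancy vector at cycle 4 is the tree's 12-month
endpoint allocation. An explicit endpoint allocation can be supplied
instead (`year1_allocation`), in which case the tree is a validated
pass-through. The cohort enters in ST-episodic-0 (symptomatic PAF at
randomisation, index treatment at model start).

Within a cycle, death competes first. Among survivors of ST-episodic or
LT-persistent states below the arm's ablation cap, a re-ablation occurs
with the uptake probability; success moves the patient to NSR with the
sub-state incremented, failure leaves the health state but still
increments the count. Non-ablated mass follows recurrence
(NSR→ST-episodic), spontaneous resolution (ST-episodic→NSR), and
progression (ST-episodic→LT-persistent, LT-persistent→permanent).
LT-persistent cannot resolve without ablation, and permanent AF admits no
return to rhythm control and no re-ablation. Relative-risk modifiers by
ablation count multiply recurrence, resolution and re-ablation success;
they default to 1 and exist for scenario analysis.

No half-cycle correction is applied: occupancy at the start of a cycle
accrues that cycle's full costs and QALYs, discounted at the cycle-start
time with factor (1 + r)^(−t). This matches the spreadsheet convention
this model family descends from; the flag `half_cycle_correction` is
reserved in the settings for sensitivity work.

## Adverse events and mortality

Stroke: annual probability = Σ_s P(CHA₂DS₂-VASc = s) × q(s), multiplied
by a health-state relative risk and converted to a 3-month probability by
1 − (1 − q)^¼. The score distribution advances with the cohort's age
component (+1 at 65, +2 at 75). Heart failure: age-banded annual
incidence × state RR, converted by 1 − exp(−r/4). All-cause death
composes, on the annual-rate scale, sex-weighted background mortality
(already net of stroke/HF deaths) plus case-fatality × event rate for
stroke and heart failure.

Survivors of incident events join prevalent post-stroke (by severity) and
heart-failure (by NYHA class, fixed at onset) fractions that decay with
the cohort's overall per-cycle survival — an approximation that applies
average rather than event-specific subsequent mortality to these
fractions — and accrue ongoing costs (€756 and €909 per cycle) and
long-term disutilities.

## Costs and utilities

Five discounted cost categories per arm; the index procedure (€4,554)
falls at cycle 0 in the cryoablation arm only. Per-cycle pharmaceutical
prices (€64 cryo, €89 AAD) apply to **all alive states in both arms**:
the published cost breakdown pins this down, since the ratio of the two
pharmaceutical totals equals the price ratio times (essentially equal)
discounted survival. QALYs multiply occupancy by (age- and sex-weighted
baseline utility − state decrement), minus short-term stroke decrements
at the event cycle and prevalent long-term stroke/NYHA decrements, times
0.25 years and the discount factor.

## Input provenance and calibration

Unit costs, per-cycle prices and the published utility decrements are
data. Everything the original analysis derived from private
patient-level data or unavailable supplementary tables — transition
probabilities, year-one inputs, contact rates, the CHA₂DS₂-VASc
distribution and per-score risks, state RRs, severity/NYHA splits, case
fatalities, background mortality, baseline utilities, demographics — is
shipped in the fixture with provenance flags (`synthetic` / `assumed`).
These values were chosen in a single calibration pass against the
published aggregate tables and then frozen; the calibrated fixture
reproduces the published deterministic structure closely (incremental
cost −€2,654 vs −€2,519; incremental QALYs 0.146 vs 0.159; NSR years
22.5/20.3 vs 22.50/20.38; re-ablations 0.07/0.25 at 12 months and
0.29/1.23 lifetime vs 0.07/0.25 and 0.28/1.20; stroke NNT 76 vs 73) and
the full qualitative scenario pattern (dominant in 15 of 16 rows;
cost-effective but non-dominant at a 10-year horizon).

Two modelling choices deserve note. The ST-episodic utility decrement is
not published; it is set to 0.09, consistent with the original analysis'
stated assumption that ST-episodic and LT-persistent (0.08) decrements
are equivalent — a non-zero value here is the only way the published
incremental QALYs can arise, because most of the between-arm difference
in occupancy is NSR vs ST-episodic time. Second, the published DKK→EUR
presentation rate (0.13) is not the reciprocal of the EUR→DKK rate
(7.45); conversions therefore pivot through DKK with exact reciprocals
so that round trips are identities, and 0.13 is retained only as a
stored presentation constant.

## Synthetic patient-level data and estimation

The generator emulates the statistical skeleton the estimation layer
assumes: 703 patients in three studies (218/203/282), 1:1 arm allocation
within study, a study-level ECG-monitoring method, normal study random
intercepts on the link scale, Poisson contact counts with log-exposure
offsets, Bernoulli per-interval recurrence/re-ablation, beta-distributed
EQ-5D utilities affinely mapped from [−0.59, 1], exponential dropout
(hazard 0.01/month), and the two cleaning rules (30-day exclusions,
optional 12-week blanking). Default effect sizes (e.g. hospitalisation
rate ratio 0.6, recurrence odds ratio e^−0.8 for cryoablation) are
realistic for first-line ablation trials but are not fitted to the
source trials; the layer is validated by parameter recovery (coverage
and bias over 200 replicates at n = 703), not by matching unpublished
regression tables. It does not emulate baseline covariate tables,
Kaplan–Meier shapes, the EQ-5D 5L→3L crosswalk, or informative
missingness (dropout is completely at random). Passing tests therefore
demonstrate correctness of the estimation machinery on data satisfying
its own assumptions, not fidelity to the real trials.

Because each study used a single ECG method, study fixed effects are
perfectly aliased with the ECG confounder; the default regression design
is `outcome ~ arm + ecg_method` (ECG always included), with study
entering only when explicitly requested on designs where it is not
aliased. The blanking-period scenario ships as frozen per-arm recurrence
scale factors (0.767 cryo, 0.762 AAD) derived once from 20 seeded
blanked-vs-unblanked re-estimations of the synthetic pipeline, keeping
the scenario layer purely declarative.

## Probabilistic sensitivity analysis

Gamma distributions for costs and rates, beta for probabilities and
decrements, both moment-matched; parameters without estimate-level
uncertainty default to a standard error of 20% of the mean (configurable
per class in the fixture's `psa` block; baseline utility uses an absolute
SE of 0.012 applied as a common shift across age bands). Regression
coefficient blocks, when supplied by the estimation layer, are sampled
jointly as multivariate normal via the Cholesky factor. One master seed
spawns a substream per iteration, so results are bitwise reproducible
and independent of execution order. Invalid draws are rejected and
logged; more than 1% rejections aborts. 95% credible intervals are
equal-tailed (2.5/97.5 percentiles). The default iteration count is
5,000; the acceptance script uses 1,000, at which the Monte-Carlo error
of the incremental means is well below the reported precision.

## Numerical choices and limitations

Transition rows are validated to sum to 1 within 1e−8 at assembly and
1e−9 along the trace; occupancy is kept in double precision and the
cohort size is only a reporting scale. Probabilities are clipped to
[0, 1] after relative-risk multiplication. Ages beyond the last table
band clamp to it. The model inherits the original structure's
limitations: no recurrent-stroke modelling beyond prevalence
bookkeeping, no anticoagulation, no NYHA transitions after onset, no
societal-perspective costs, and calibrated rather than estimated inputs
wherever the source data are private.
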