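# Methods

## The monitored process

One analytical run per day; in each run a control material is measured at
two concentration levels (L1 near the reference interval, L3 in the
pathological range).  Each result is normalised against the control
material's target mean and SD, z = (x − μ)/σ, and the run is judged by
the Westgard rule set in force.  A study is divided into consecutive
phases (A = baseline, B, C, D here), each with its own per-analyte rule
assignment; phase boundaries are run indices, not calendar dates, because
every rule window is defined over consecutive runs.  Input files may
carry ISO dates; they are ranked into dense 0-based run ordinals at read
time.

## Rule semantics

| rule | trigger |
|------|---------|
| 1_3s | any single result with \|z\| > 3 |
| 1_2s | warning only: any single result with \|z\| > 2 |
| R_4s | within one run, levels on opposite sides with spread ≥ 4 SD (hi ≥ +2, lo ≤ −2) |
| 2_2s | 2 consecutive results with z beyond 2 SD, same side |
| 2/3_2s | ≥ 2 of the last 3 beyond 2 SD, same side |
| 3_1s / 4_1s | 3 / 4 consecutive beyond 1 SD, same side |
| 8_x / 10_x / 12_x | 8 / 10 / 12 consecutive on one side of the mean |

Numerical conventions, chosen once:

- **Strict thresholds.**  "Beyond 2 SD" means \|z\| > 2 exactly on a
  limit does not trigger (conventional Levey-Jennings practice; boundary
  cases are measure-zero under a continuous error model).  The one
  exception is R_4s, whose "at least 4 SD" spread is read inclusively:
  hi ≥ +2 and lo ≤ −2 (so {+2.1, −2.0} triggers).  The pure-range
  variant (any spread ≥ 4 SD, same side allowed) is available as
  `RuleSet(r4s_pure_range=True)`.
- **Window pooling.**  Counting rules pool both control levels by
  default, interleaved by run then level, and span consecutive runs —
  the common multirule reading with N = 2 per run.  Whether commercial
  QC software pools levels or keeps per-level windows varies and is
  rarely documented, so both are flags on `RuleSet` (`cross_level`,
  `cross_run`); no particular vendor convention is asserted.
- **Reset on rejection.**  After a rejected run all counting windows
  restart empty, modelling the corrective action a laboratory takes
  before the next run.  Without a reset a single outlier contaminates
  windows for up to 12 subsequent runs and the x-rules cascade.
  Configurable off (`reset_on_reject=False`).
- **Phase boundaries reset windows** — the rule set changes there, and a
  12-run window that no rule set in force ever requested should not fire
  retroactively.
- **Rules are evaluated independently**; a 1_2s warning never gates
  which rejection rules run.  At most one violation per rule per run is
  attributed, to the earliest triggering window.
- A single-level run cannot evaluate R_4s; a window shorter than a
  counting rule's length is "not evaluable", never a violation.

`reject_stream` is the same decision process over bare z arrays (no
violation attribution); a test asserts its masks equal `apply_plan`'s
decisions on random streams.

## Performance statistics

- CV% = 100·SD/mean with the **sample SD (n−1)**; QC software convention,
  and unbiased enough at the n ≈ 20–30 of monthly windows.
- bias% = 100·(lab mean − group mean)/group mean, signed; the group mean
  is the peer-group (inter-laboratory) mean for the same method.
- TEa% = z·(imprecision goal %) + (bias goal %); the z-score defaults to
  1.65 (95th percentile, one-sided) where a configuration does not say.
- sigma = (TEa% − |bias%|)/CV%.  The formula is computed on the percent
  scale throughout, and with the **magnitude** of bias, so that bias of
  either sign consumes error budget; published per-phase sigma values are
  only consistent with this reading.  The signed variant is available via
  `signed_bias=True`.
- Phase summaries are **per-phase windows** (results whose run index
  falls in the phase), not cumulative-to-date; `cumulative=True` gives
  the other convention.
- Metrics are reported at one configured level per analyte (the level
  whose performance triggered the rule change); both levels are always
  evaluated by the rule engine.
- Rounding for reports: CV to 1 decimal (2 below 1%), bias and sigma to
  2 decimals; cross-analyte mean rows are computed on unrounded values
  and rounded last.  Improvement counts use strict comparisons (lower
  CV, lower |bias|, higher sigma); ties count as no change.

## Monte-Carlo power model

In-control z ~ N(0,1) independently per level and run.  A systematic
error adds `shift_sd` to z; a random error multiplies its SD by
`re_factor` — the standard Westgard power-function model.  Pfr is the
rejected fraction of simulated in-control runs; Ped the fraction of
replicates with ≥ 1 rejection within a `horizon_runs` window after
onset (default 10 runs ≈ two working weeks).  The simulated process
includes the reset-on-reject behaviour, so estimates describe the same
procedure the rule engine applies to data.

Common random numbers: estimates for different rule sets under the same
seed share identical standard-normal draws.  Before any rejection the
window state of nested rule sets is identical, so a superset rejects no
later than its subset on every draw — paired comparisons are exact in
that sense, not merely statistical.  Binomial standard errors are
reported; no ARL confidence bands.  Calibration anchor: Pfr of {1_3s} has
the closed form 2·(1−Φ(3)) per level (≈ 0.0027; ≈ 0.0054 for two
levels), which the simulator must hit within 3 binomial SE.

"More efficient monitoring" is operationalised here as higher Ped at
comparable Pfr; that criterion is this package's choice of yardstick, and
`compare_phase_rulesets` reports both quantities with paired differences
against the baseline phase rather than a single verdict.

## Synthetic studies

`generate_study` draws values per (analyte, level, run) from
N(μ + shift·σ, (σ·re)²), where shift and re come from the condition
active in that run's phase (and an optional reagent-lot change, modelled
as a step in the true mean only — SD unchanged).  The default conditions
are the study design the fixtures describe: 5 analytes × 2 levels ×
4 phases × 22 daily runs (~4 working weeks per phase), in control, with
no injected conditions.  Default control targets are plausible adult
serum-protein concentrations in g/L with baseline CVs of ~3–5% (AAT and
Lp(a) worst) and sub-3% peer biases; they are synthetic — the monitored
study published no control-material targets — and live in
`data/study_config.yaml`, where TEa goals were back-solved from the
baseline-phase summary rows via TEa = sigma·CV + |bias|.

The peer group is a scalar: group mean = true mean · (1 + offset).  No
peer laboratories, no minimum-data-requirement logic, no assay chemistry
are simulated.  Ground truth (`TruthRecord`) logs run-weighted true mean,
true SD and true bias per (analyte, level, phase) so recovery tests can
compare estimates against truth at 3-standard-error tolerance.

What passing tests show — and don't.  The generator's Gaussian,
serially-independent model is exactly the model the rule predicates and
power functions assume, so tests demonstrate correctness of the
machinery, calibration against closed forms, and recoverability of
injected effects.  Real IQC data have drift, autocorrelation from
reagent/calibrator lots, non-Gaussian tails and occasional re-runs after
rejection; agreement here does not certify behaviour under those
features.

## Problem sizes

Defaults keep every computation interactive: rule evaluation is linear in
results with ≤ 12-observation windows; power estimates use 10⁵ simulated
runs for Pfr (SE ≈ 2·10⁻⁴ at Pfr ≈ 0.005) and 500–2000 replicates for
Ped (SE ≤ 0.011); recovery tests use 30 runs per phase.  The pipeline's
phase comparison deduplicates identical rule sets before simulating.

## Known limitations

- The rule engine is batch-oriented; no streaming/LIS integration.
- Sequential gating variants of multirule logic (1_2s as a gate for the
  rejection rules) are not implemented; rules are independent.
- Ped/Pfr are Monte-Carlo only; no Markov-chain closed forms.
- The bundled published summary matrix carries printed (rounded) values;
  roll-ups computed from it inherit that rounding, which is also how the
  original report derived its mean rows.
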