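# Methods

## The estimation problem

A focal dolphin group is scan-sampled on a fixed 3-min grid; at each scan the
predominant behavioural state is recorded (foraging, milling, resting,
socialising, travelling), together with every non-research vessel within
300 m, its category and speed, the instants at which vessels cross the 300 m
radius, and any swim attempts made from tour vessels. The question is whether
vessel presence alters the group's behaviour, and by how much, once the
serial dependence of behaviour is taken into account.

The model is a pair of first-order Markov chains on the ethogram: one chain
generates transitions while only the research vessel is present (control),
the other while at least one other vessel is within 300 m (interaction).
Resting and socialising are too rare to support transition estimates, so
analysis runs on the three-state subset {foraging, milling, travelling};
every transition into or out of a rare state is dropped and the sequence is
split there, so no spurious transition bridges a removal. Tied "double
states" are removed the same way, and only sequences with at least five
transitions (>15 min) are retained. The stage order — doubles, then state
restriction, then the length filter — is fixed, because it affects which
sequences survive.

## Chain construction around vessel events

The condition a scan belongs to is ambiguous around approaches and
departures. Two schemes bracket the reasonable choices:

* **Conservative.** Every ambiguous scan is discarded: when a crossing falls
  strictly between two scans, the first scan under the new condition goes;
  when a crossing coincides with a scan instant, that scan goes.
* **Less conservative.** The behavioural transition at the onset of the
  interaction is itself treated as affected: the interaction chain is seeded
  with the last control scan preceding the approach (a scan exactly at the
  approach instant counts as that last pre-approach scan), and only the
  first post-departure scan is discarded. The transition from the preceding
  control run into the seed scan is not counted anywhere — the control run
  simply ends one scan earlier.

Behaviour is assumed still affected for 15 min after the last vessel leaves.
We implement this by letting the departure take effect 15 min late: scans in
the window join the interaction run as one contiguous sequence and the
departure-side discard fires at the window's expiry. This resolves an
ambiguity the construction schemes leave open (whether the sample discarded
at departure is reinstated when a window is used); treating the condition as
unchanged until the window expires avoids a one-sample hole inside a chain.
The window is a parameter (`post_window`), so the schematic window-free
scenarios run with `post_window = 0`. Overlapping per-vessel intervals are
merged before any of this; approach = first instant any vessel is inside
300 m, departure = last.

## Markov summaries

With transition counts `a_ij` pooled over same-condition sequences
(transitions never cross a sequence boundary), the estimates are

* transition probabilities `p_ij = a_ij / Σ_j a_ij` (rows with no outgoing
  transitions are refused, naming the state);
* behavioural budget `π` = stationary distribution, computed as the left
  eigenvector of the dominant eigenvalue of `P`, sign-fixed and normalised
  to sum to one; reducible chains are refused, and a power-iteration
  fallback covers complex-contaminated solver output (imaginary parts below
  1e-10 are truncated);
* recovery time `E(T_j) = 1/π_j` in transition units, times the 3-min
  interval for minutes;
* bout length `t̄_ii = 1/(1 − p_ii)` — the mean of the geometric sojourn
  implied by the self-transition probability.

## Statistical comparisons

Budgets and individual transition probabilities are compared between
conditions with a two-sample Z-test for proportions: pooled variance for the
statistic, unpooled for the 95% CI on the difference. The effective sample
size is the total transition count per condition for budgets, and the row
total `a_i·` for transition cells — the only sample sizes the sequence data
define. `diff` is interaction minus control while `z` is computed control
minus interaction, so a drop under interaction gives a positive z. Bout
lengths are compared with a two-sample t: the binomial SE of `p_ii`
propagates by the delta method, `SE(t̄) = SE(p)/(1−p)²`, with
`df = n_c + n_i − 2` on the row totals. A Pearson χ² (df = states − 1)
compares the state distributions produced by the two construction schemes,
and Kruskal–Wallis (tie-corrected, χ² p-value) compares vessel categories.
p-values are reported unadjusted; no multiple-testing correction is applied.

**Known limitation — budget-test calibration.** The binomial variance
treats the eigenvector budget as if it were a simple proportion of `n`
independent trials. For sticky chains (self-transitions 0.61–0.92 here) the
true sampling variance of the plug-in stationary distribution is roughly
five times larger, so the budget Z-test is anticonservative: in simulation
at study-scale n its empirical size at nominal α = 0.05 is ≈ 0.28–0.42 per
state (the inflation persists under independent multinomial row sampling,
so it is intrinsic to the statistic, not to serial dependence in the null).
We keep the convention because it is the field's, and report it as a
limitation; a calibrated test would need an effective n about five times
smaller, at a corresponding cost in power. The transition-cell tests do not
share the problem — their binomial model is exact given row totals.

## Cumulative exposure

The interaction budget is instantaneous; seasonal impact mixes it with the
control budget in proportion to traffic intensity `a` (the share of time
spent with vessels within 300 m, measured as the share of exposed scan
intervals): `cumulative = a·interaction + (1−a)·control`. Sweeping `a` over
a 0.5%-step grid and Z-testing the cumulative budget against the control
budget per state locates the critical intensity — the smallest `a` that is
significant — refined by bisection to 0.1%. The effective n behind the
cumulative proportion is the exposure-weighted blend
`round(a·n_int + (1−a)·n_ctl)`; the convention is isolated in one function
(`effective_n`) so it can be swapped. At `a = 0` and `a = 1` the cumulative
budget equals the control and interaction budgets exactly, and for a
fixed-sign difference the p-value curve is non-increasing in `a`.

## Compliance rules

Five coded rules: no-wake speed (5 kt) within 300 m, at most 3 vessels
engaged, 90 min of interaction per vessel, 60 min of swimming per trip, no
swimming with calves; plus an optional harbour-area rule driven by a boolean
flag per scan rather than geometry. "Engaged" means within 300 m at the
same scan instant — the only observable in scan-sampled data. Speed
compliance is judged per 3-min speed sample, as recorded. Encounter time
per vessel uses exact event intervals where logged, otherwise one sampling
interval per within-300 m observation; repeat encounters of the same vessel
with the same group are summed. In the swim summary, neutral-presence and
neutral-absence merge into one "neutral" cell only for the three-category
goodness-of-fit χ² (against equal expected counts, df = 2).

## Synthetic data generator

The generator emulates the study conditions with known ground truth:

* **Behaviour.** A 3-state control chain built by `solve_transition_matrix`
  from a target stationary vector (0.26/0.15/0.59) and target diagonals
  matching mean bout lengths of 4.05/2.58/7.86 sampling units; fixing both
  leaves one degree of freedom, exposed as `mixing` over its feasible
  interval. The interaction chain targets 0.135/0.175/0.69 with longer
  travelling bouts — mass moves from foraging to travelling. Each core row
  leaks 3% (split evenly) into resting/socialising, which persist briefly
  and return; because the leak scales each row uniformly, conditioning on
  the core recovers the designed 3-state chain exactly, so the restricted
  pipeline's estimand equals the design and the combined rare-state budget
  stays under the observed 13.5% ceiling.
* **Vessels.** Poisson arrivals with log-normal dwell times (median 15 min),
  arrival rate set so the stationary busy fraction of the M/G/∞ union
  matches the target traffic intensity (21% by default); the process starts
  eight mean-durations before the follow so presence is stationary from the
  first scan. Neither the arrival law nor the dwell law is identified by
  the summary statistics the study reports; both are exposed as parameters.
  Behaviour switches to the interaction chain while any vessel is present
  and for `effect_carryover` = 15 min afterwards — the assumption that
  motivates the post-interaction window, made literal.
* **Observables.** Per-scan vessel speeds are log-normal, parameterised by
  per-category median/IQR; double states are injected at 2% per scan; swim
  attempts occur during tour-vessel presence at 1.5/h with log-normal
  durations (mean ≈ 5 min) and fixed response/end-reason probabilities.
  Follow lengths are log-normal with mean ≈ 46 scans, so 55 follows total
  ≈ 7,600 min. Named scenarios: `default`, `null` (interaction = control),
  `high-traffic`, `no-traffic`, and `compliant` (speeds capped below 5 kt,
  ≤3 concurrent vessels, encounters < 90 min, swims < 60 min, no calves).

What the generator does **not** emulate: observer error in state
assignment, group fission/fusion, spatial structure (vessel distance is
binary at 300 m), diurnal or seasonal non-stationarity in behaviour, and
dependence of vessel behaviour on dolphin behaviour. Tests that pass on
these data therefore validate the estimation machinery under the model's
own assumptions, not robustness to field conditions.

## Numerical and scale choices

* One-decimal, half-away-from-zero rounding for reported percentages and
  minutes (the reporting convention of the field's tables).
* Budget recovery experiments use 100 end-to-end replicates at 55 follows;
  at that scale (~1,250 control transitions) per-state budget SDs are
  0.019–0.033, so the travelling budget — the stickiest state — sits at the
  edge of a ±0.05 recovery band: its long-run coverage is ≈ 0.89, and a
  100-replicate estimate of that coverage straddles 0.90.
* Long-run chain checks use 10⁵–10⁶ simulated steps (a compiled inner loop
  makes these cheap); eigenvector–power-iteration agreement is asserted at
  1e-10.
* Degenerate inputs: zero-count rows, reducible chains, `π = 0`, `p_ii = 1`
  and empty strata raise typed validation errors rather than propagating
  NaNs; Kruskal–Wallis on wholly tied data returns H = 0, p = 1.
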