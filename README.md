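# delphis

Markov-chain behavioural-impact analysis for cetacean focal-follow data.

`delphis` is for marine-mammal researchers and managers who scan-sample the
behaviour of a focal dolphin group (every 3 min) while logging the vessels
around it, and who want to know whether — and at what traffic intensity —
vessel interactions alter the group's behaviour. It implements the full
analysis chain used in vessel-disturbance studies of delphinids, plus a
rule engine for tour-regulation compliance and a synthetic-data generator
with known ground truth for validating the machinery.

## The model

Behavioural state sequences are modelled as first-order Markov chains, one
per condition: *control* (research vessel only) and *interaction* (≥1 other
vessel within 300 m). From transition counts `a_ij` pooled over sequences:

- transition probabilities `p_ij = a_ij / Σ_j a_ij`;
- behavioural budget `π` (long-run share of time per state) as the left
  eigenvector of the dominant eigenvalue of `P` (Perron–Frobenius);
- recovery time `E(T_j) = 1/π_j` transition units (×3 min);
- bout length `t̄_ii = 1/(1 − p_ii)` (geometric sojourn mean).

Because the condition of scans recorded around a vessel approach or
departure is ambiguous, chains can be built under a **conservative** scheme
(discard every ambiguous scan) or a **less conservative** one (count the
onset transition as affected); a 15-min post-interaction window treats the
group as still affected after the last vessel leaves. Conditions are
compared with two-proportion Z-tests (budgets, individual transitions) and
a delta-method t-test (bout lengths); the *cumulative* budget
`a·interaction + (1−a)·control` is swept over traffic intensity `a` to
locate the critical exposure at which each state's time share is
significantly altered. Compliance rules checked per follow: 5-kt no-wake
speed within 300 m, ≤3 vessels engaged, 90-min encounter and 60-min swim
limits, and no swimming with calves.

See `docs/methods.md` for assumptions, conventions, and known limitations
(in particular the anticonservative calibration of the budget Z-test on
sticky chains).

## Worked example

Simulate a study-scale dataset (55 focal follows, ~7,600 min, ~21% vessel
exposure) and run the conservative pipeline:

```python
import delphis as dp
from delphis import Approach, Condition

params = dp.default_parameters("default")
follows, truth = dp.simulate_dataset(params, n_follows=55, seed=5)

print(dp.traffic_intensity(follows)[0].a)           # realised exposure
_, counts = dp.build_condition_counts(follows, Approach.CONSERVATIVE)
sc = dp.summarize(counts[Condition.CONTROL])
si = dp.summarize(counts[Condition.INTERACTION])
r = dp.compare_budgets(counts[Condition.CONTROL],
                       counts[Condition.INTERACTION])[sc.states[0]]
swp = dp.sweep(counts[Condition.CONTROL], counts[Condition.INTERACTION])
```

Output (formatted; exactly what the code printed for seed 5):

```
traffic intensity a = 20.4% (1548 of 7590 min)
transitions: control n = 1290, interaction n = 580
FORAGING    budget  26.6% ->  14.8%   E(T)  11.3 ->  20.2 min   bout 3.83 -> 5.73
MILLING     budget  16.1% ->  15.2%   E(T)  18.7 ->  19.8 min   bout 2.67 -> 3.52
TRAVELLING  budget  57.3% ->  70.0%   E(T)   5.2 ->   4.3 min   bout 7.89 -> 17.65
foraging budget change: -11.8 pp (95% CI -15.6 to -8.0, z = 5.61, p < 0.001)
critical traffic intensity, foraging  : 29.8%
critical traffic intensity, milling   : not reached
critical traffic intensity, travelling: 31.4%
regulation violations flagged: 443
```

Reading this: in the presence of vessels the group's foraging share drops
from 26.6% to 14.8% of time and, once disrupted, the expected time to
return to foraging nearly doubles (11.3 → 20.2 min), while travelling
absorbs the difference. The sweep says that if the group spent more than
about 30% of its time with vessels, its cumulative foraging and travelling
budgets would differ significantly from undisturbed behaviour; milling is
never significantly affected. The generating truth behind this dataset is
a control budget of 0.26/0.15/0.59 and an interaction budget of
0.135/0.175/0.69, so the pipeline recovers the design within sampling
error.

A command-line interface mirrors the library:

```sh
delphis simulate --n-follows 55 --seed 5 --out data/
delphis build-chains --dataset data/ --approach both --out chains/
delphis markov --dataset data/ --out markov.json
delphis compare --dataset data/ --out compare.csv
delphis sweep --dataset data/ --out sweep.csv
delphis compliance --dataset data/ --out violations.csv
delphis report --dataset data/ --out report.json
```

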