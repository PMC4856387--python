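# stereomet

Behavioural-computation toolkit for mouse stereotypy phenotyping. Cage-induced
stereotypies (bar-mouthing, back-flipping, cage-top twirling, route-tracing,
circling) are studied alongside two cognitive read-outs — recurrent
perseveration in an adaptive two-choice guessing task, and judgement
(cognitive) bias in an eight-arm radial maze — plus one-zero scoring of
home-cage behaviour. This package implements the computational core of that
battery for experimenters and simulation studies:

- **Guessing-task controller.** On each trial one of two goal compartments is
  baited; the probability of baiting *right* equals the proportion of *left*
  responses in the previous twenty trials (all previous trials before trial
  20), so side biases are counteracted and responding to both sides equally —
  randomly or not — maximises reward. A shaping mode closes any side chosen
  three times in succession.
- **Perseveration metrics.** For a choice sequence `x_1..x_n`, a 3rd-order
  Markov-chain test tabulates, for each 3-choice context `c`, the observed
  next-choice counts `O(c, x)` against `E(c, x) = n(c)·m̂(x)` with `m̂` the
  sequence's marginal side proportions; `χ² = Σ (O−E)²/E`, `p` its upper-tail
  probability, and the perseveration score is `logit(P)` with `P = 1 − p`.
  Secondary measures: the distribution of the 77 overlapping tetragrams of an
  80-trial sequence over the 16 possible configurations (uniform expectation
  77/16 = 4.8 under random responding), pure repetitions (`LLLL`+`RRRR`),
  pure alternations (`LRLR`+`RLRL`), side bias, and correct-choice proportion.
- **Cognitive-bias scores.** From timed arm visits:
  `positive = (T_pos − T_neg)/(T_pos + T_neg)`,
  `reference = (T_ref − T_amb)/(T_ref + T_amb)`,
  `ambiguous = (T_npos − T_nneg)/(T_npos + T_nneg)`, all in [−1, 1], plus
  relative times, relative entries and total entries (activity).
- **Ethogram scoring.** Stereotypic-bout classification (continuous ≥ 3 s for
  bar-mouthing; ≥ 3 repetitions with pauses ≤ 3 s for discrete forms),
  one-zero sampling at 15-s intervals over 2 days × 4 × 15-min blocks
  (480 data points per subject), and stereotypy level as the proportion of
  active intervals flagged per form.
- **Synthetic data.** Choice agents (i.i.d.-biased, order-1 repeat,
  alternator, win-stay/lose-shift), renewal-process maze sessions with target
  role occupancies, and Poisson bout streams with analytic expected levels —
  every analysis stage has a known-ground-truth test surface.

## Worked example

```python
import stereomet as sm

agent = sm.make_agent(sm.AgentSpec(kind="markov_repeat",
                                   params={"p_repeat": 0.9}, seed=1))
seq = sm.run_session(agent, sm.ControllerConfig(n_trials=80, seed=2))
res = sm.markov_perseveration(seq)
table = sm.tetragram_counts(seq)
print(f"side bias        {sm.side_bias(seq):.3f}")
print(f"chi-square       {res.chi_sq:.2f}  (df={res.df}, p={res.p:.2e})")
print(f"logit[P]         {res.logitP:.2f}")
print(f"pure repetitions {sm.pure_repetitions(table)}")
print(f"correct choices  {sm.correct_choice_proportion(seq):.3f}")
```

```
side bias        0.212
chi-square       37.88  (df=6, p=1.19e-06)
logit[P]         13.64
pure repetitions 58
correct choices  0.250
```

An agent that repeats its previous choice 90% of the time produces a heavily
patterned sequence: 58 of its 77 tetragrams are pure repetitions (random
expectation ≈ 4.8 for `RRRR` and `LLLL` each), the independence test rejects
decisively (`logit[P] = 13.6`), and the adaptive controller punishes the
pattern — only 25% correct choices against the ~50% earned by unbiased
responding.

The same API covers the other stages (`sm.bias_scores(log, roles)`,
`sm.one_zero_sample(events, scheme)`), and the `stereomet` CLI wraps them for
TSV pipelines:

```
stereomet synth guessing --n-subjects 10 --seed 1 --out-dir data/
stereomet perseveration --in data/trials.tsv --out scores.tsv
stereomet bias-scores --visits visits.tsv --roles roles.json --out bias.tsv
stereomet ethogram --events events.tsv --scheme scheme.json --out levels.tsv
stereomet run --config pipeline.json
```

## Layout

- `src/stereomet/guessing.py` — trial types, baiting rule, session simulation
- `src/stereomet/perseveration.py` — Markov test, tetragrams, side bias
- `src/stereomet/bias.py` — arm-visit types, role maps, the three arm scores
- `src/stereomet/ethogram.py` — bout classifier, one-zero sampler, levels
- `src/stereomet/synth.py` — agents and generators with known ground truth
- `src/stereomet/io.py`, `pipeline.py`, `cli.py` — TSV/JSON schemas, tables,
  the `stereomet` command
- `docs/methods.md` — model details, defaults and their rationale, limitations
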