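# Methods

## The guessing-task controller

The two-choice guessing task presents a left and a right goal compartment; on
every test trial exactly one is baited, and the animal is rewarded iff it
chooses the baited side. The controller sets

```
P(bait right at trial t) = proportion of LEFT responses in trials t−20 .. t−1
```

using all previous trials while fewer than twenty exist, and 0.5 on trial 1
(no history; symmetry is the only defensible default). Trial 20 is assigned
to the all-previous regime, which coincides with the 20-trial window anyway.
Because baiting tracks the *opposite* of the animal's recent bias, any
strategy that favours one side is starved of reward, and choosing both sides
equally often — whether randomly or in a rigid pattern — maximises expected
reward at 50%. The bait is drawn before the choice each trial and is never
observable by the agent, matching the live protocol's information structure.

Sessions always run the configured number of trials (80 by default); early
termination by time-out or off-task behaviour is an experimental contingency,
not a computational one, and is not modelled. In shaping mode both pots are
baited (every completed trial is rewarded) and a side chosen three times in
succession is closed on the next trial; baiting probabilities play no role in
shaping.

One subtlety worth knowing when validating against simulations: a strict
alternator enjoys a small reward surplus during the first twenty trials,
because an odd-length alternating history leaves the window tipped toward the
side the alternator will choose next. Once the 20-trial window fills, its
history is always balanced and its reward rate is exactly 1/2. Tests of the
"equal responding earns half" property therefore score trials after the
warm-up.

## The Markov-chain perseveration score

Recurrent perseveration is read out as sequential dependence in the binary
choice sequence. For order `k` (default 3) every occurring length-`k` context
`c` contributes a 2-cell row: observed counts `O(c, x)` of the next choice
`x ∈ {L, R}`, expected counts `E(c, x) = n(c)·m̂(x)`. Under the default
`marginal` null, `m̂` is the side proportion of the whole sequence, so plain
side bias — which the battery reports separately — contributes nothing to the
statistic, and only structure beyond bias is detected. A `fair` null
(`m̂ = 0.5`) is available for sensitivity analyses, as is the order.

The statistic is `χ² = Σ (O−E)²/E` over cells with `E > 0`. Degrees of
freedom count one per occurring context, **minus one under the marginal
null** because `m̂` is estimated from the same sequence; this is the classical
result for testing order 0 against order `k` on a binary alphabet
(`2^k − 1` when every context occurs) and is floored at 1. The subtraction
matters in practice: Monte-Carlo calibration on 10,000 fair 80-trial
sequences puts the empirical rejection rate at the 0.05 level near 0.04 with
it, versus ~0.023 without it (counting the estimated marginal as a free
degree of freedom makes the test conservative). Both variants were measured
with the brute-force contingency oracle used in the tests; the package ships
the calibrated convention.

`p` is the chi-square upper-tail probability of `χ²`, the perseveration
probability is `P = 1 − p`, and the score is `logit(P)` after clamping `P`
into `[ε, 1−ε]` with `ε = 1e−12`; results flag when the clamp binds (fully
one-sided sequences have `χ² = 0`, `P = 0`). No burn-in trials are discarded:
tetragram counts and the contingency table come from the same full choice
string. The chi-square approximation is rough for an 80-trial sequence
(expected cell counts near 5); the calibration test quantifies exactly how
rough, and the score is used as a graded outcome measure, not as a formal
hypothesis test.

The tetragram distribution cuts the sequence into overlapping 4-windows
(stride 1): 77 windows for 80 trials, 16 configurations, uniform expectation
77/16 ≈ 4.81 under random responding. Pure repetitions and alternations are
the two patterned extremes and the secondary perseveration measures.

## Radial-maze cognitive-bias scores

The three scores are normalised time contrasts with arm-time-only
denominators — central-arena time is reported separately and never enters a
denominator. A zero denominator yields `NaN` rather than 0: an animal that
never entered the ambiguous arms has an *undefined* judgement-bias score, not
an indifferent one, and conflating the two would bias group means toward
zero. Visits whose exit is missing (session ended inside an arm) are
truncated at the session end by the reader. Training sessions reuse the same
operations with a four-arm role map (ambiguous arms closed); `session_id`
is carried through the long-format output so habituation trends can be
tabulated downstream.

All scores are antisymmetric under swapping the paired roles, invariant to
uniform time rescaling, and bounded in [−1, 1]; these are enforced as
property tests.

## Ethogram scoring

Behaviour events carry a label, start/end times, and an optional repetition
count (laps, flips, twirls). Bout classification follows the two-part
criterion: bar-mouthing (a continuous behaviour) qualifies at ≥ 3 s duration;
discrete-repetition forms qualify when consecutive events accumulate ≥ 3
repetitions with inter-event pauses of at most 3 s — a pause of exactly 3 s
keeps the run ("without pauses longer than 3 s" admits 3 s), strictly longer
breaks it. An event recorded with `repeat_index = 3` qualifies on its own,
which also makes the classifier idempotent on its own output spans. Whether a
circling "repetition" is a full lap or a direction-consistent arc is decided
upstream by whoever scores the video; the repetition count is taken as
ground truth.

One-zero sampling uses half-open intervals `[t, t+15)`; a span touching a
boundary belongs to the later interval. A form flags an interval iff a
qualifying bout overlaps it. An interval is *inactive* when the animal is
motionless throughout it, brief twitches excepted; since event streams carry
no twitch label, the package treats any non-inactive event of ≤ 5 s as a
twitch (it does not break inactivity), while longer non-inactive events and
any qualifying bout mark the interval active. Stereotypy level is flagged
intervals divided by *active* intervals — interval counts, not summed
seconds, matching the one-zero design — and is `NaN` for a subject with no
active intervals. Levels of different forms are not additive; `all` takes
the union of flags. The square-root transform of levels customarily applied
before model fitting is exported as a convenience column; inference on real
data is out of scope.

## Synthetic generators

The generators' defaults are the study conditions, not tuning knobs:
80-trial sessions with a 20-trial window; 600-s maze sessions; the
2 × 4 × 900 s observation scheme.

**Agents.** `iid_biased` (Bernoulli sides), `markov_repeat` (repeat previous
choice with `p_repeat`; order-1 dependence), `alternator`, and
`win_stay_lose_shift`. Agents see their own history and rewards, never the
bait.

**Maze sessions.** An alternating renewal process: exponential centre stays
and exponential arm visits, the visit's role drawn proportionally to its
target occupancy fraction and the arm uniformly within the role. All roles
share one mean visit duration, chosen so expected occupancies match the
profile; with equal means the second-order (delta-method) bias of the ratio
scores cancels, so Monte-Carlo means recover the analytic scores to within
sampling error — the property the end-to-end tests rely on. Default
occupancies (positive 0.25, negative 0.10, near-positive 0.20, near-negative
0.15, centre 0.30) give the ~30% centre time and 50–75 entries per session
typical of the task; the paper provides no within-session dynamics, so the
renewal model is the simplest generator consistent with the summaries it
reports.

**Ethogram streams.** Per-form Poisson bout onsets over each observation
block extended backwards by one bout span, so edge intervals see the
stationary overlap rate and the flag probability of every interval is
exactly `1 − exp(−λ(15 + d))` for onset rate `λ` and bout span `d`. Bout
durations are fixed (default 10 s continuous; 4 repetitions of 1 s with 1-s
gaps for discrete forms) precisely so this ground truth stays analytic.
Activity is an alternating exponential renewal process with a target active
fraction (default: fully active during observation blocks, reflecting
dark-phase observation windows).

What the generators do *not* emulate: individual differences and cage or
replicate structure, habituation within or across sessions, correlations
between stereotypy forms, observer error in event streams, and time-of-day
effects. Passing recovery tests therefore demonstrates that the analysis
code measures what the generators encode — not that real mice satisfy the
generators' independence assumptions.

## Numerical and interface choices

- Sides are case-sensitive single characters `L`/`R` everywhere; times are
  seconds as decimals; proportions live in [0, 1] (percent only in display).
- `logit(P)` clamp `ε = 1e−12`; chi-square cells with `E = 0` are skipped;
  df floor 1.
- File formats are TSV with headers plus small JSON configs; every writer's
  output is re-readable by its reader (round-trip tested). Schema errors
  name the offending row; CLI exit codes: 0 ok, 2 schema error, 3 config
  error.
- Outputs are long-format (subject, session, metric, value) so mixed-model
  fitting in any statistics environment needs no reshaping; this package
  deliberately does no group-level inference.
- Reported simulation sizes (500–1,000 sessions for controller and recovery
  checks, 10,000 sequences for null calibration, 150–400 subjects for
  occupancy and level recovery) were chosen so Monte-Carlo standard errors
  are small against the effects being verified while the whole suite runs in
  seconds.

## Known limitations

- The chi-square tail probability is an asymptotic approximation; at 80
  trials the test is slightly conservative even with the df correction
  (empirical size ≈ 0.04 at nominal 0.05). Comparisons *between* animals
  scored on the same design are unaffected.
- The one-zero activity rule (5-s twitch threshold at the event level) is an
  operationalisation of an interval-level definition; streams annotated with
  different conventions should be harmonised before scoring.
- `markov_perseveration` requires only `n ≥ k + 1`, but scores from very
  short sequences are dominated by the clamp and df floor; the battery's
  intended regime is the 80-trial session.
- The maze generator draws visits independently; it cannot produce the
  sequential arm-choice strategies (e.g. serial visiting) real mice show,
  which affect entry-based measures more than time-based ones.
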