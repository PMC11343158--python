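# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, in the order a reader meets them.

## Yield counting

Counts are of *directed* probed connections: a paired recording of cells A
and B contributes two probes (A→B and B→A), so every count is even and
`paired_recordings = count / 2`.

**Traditional strategy.** Cells are patched in disjoint groups of `p` and
every ordered pair within a group is probed: `(n/p)(p² − p)` when `p | n`.
When `p ∤ n` the integer count uses `⌊n/p⌋` full groups plus one remainder
group of `r = n mod p` cells contributing `r² − r`; a single leftover cell
contributes nothing (71 cells with two pipettes → 35 pairs).

**Patch-walking.** The initial group of `p` co-held cells yields `p² − p`;
each subsequent cell is probed bidirectionally against the `p − 1` cells
still held, adding `2(p − 1)` each: total `(p − 1)(2n − p)`. The ratio to
the traditional count is `2 − p/n`, approaching a doubling for long walks.

`improvement(n, p)` returns the closed-form ratio `1 − p/n` (the form in
which the 80–92% practical range is quoted, e.g. 80% at n=10, p=2 and 92%
at n=100, p=8). When `p ∤ n` this is flagged with a warning because the
realized integer-count ratio differs (it is available from
`compare_yields`, which always uses the remainder-aware counts).

`yield_matrix` materializes which ordered pairs each strategy can probe:
block-diagonal groups for traditional, a sliding window of `p` co-held
cells for the walk. Matrix sums equal the closed forms by construction and
by test.

## Distance-dependent connectivity

Local cortical connection probability decreases with intersomatic
distance. We use a two-parameter exponential, `P(d) = a·exp(−d/λ)`,
because two published anchor points exactly identify it and it is monotone
with the right tail behavior:

- `P(91.6 µm) = 0.169` — the expected connection probability at the mean
  intersomatic distance of a two-pipette walk;
- `P(200 µm) = 0.10` — the practical screening-radius threshold.

Solving gives `λ ≈ 206.6 µm` and `a ≈ 0.263` (the zero-distance
probability). Outputs are clipped to [0, 1]; negative distances are a
domain error. The model object is pluggable — any object with a
`probability(distance)` method can replace it, so logistic or piecewise
forms can be swapped in without touching the simulator.

The 16.9% figure is treated as a *per-directed-probe* probability. The
literature's own usage is ambiguous (it is quoted per "paired recording"
in one place but applied per probe with m = 29 pairs in the 89%
computation). Both readings are computable with `prob_at_least_k`; note
that the "majority chance after three pairs" claim holds only under the
per-direction reading (6 probes → 67%) and not per pair (3 probes → 43%).

Binomial tails are computed by exact summation of `C(m, j) q^j (1−q)^(m−j)`
over the shorter tail (no normal approximation), cross-checked in tests
against `scipy.stats.binom` and a seeded Monte Carlo estimate.

## Walk coordination

The scheduler encodes the two-pipette control flow as a pure state machine
(`WalkCoordinator`), so the simulator and scripted tests drive it
identically:

- cell coordinates live in a queue; an available pipette is assigned the
  queued cell nearest its *home position* (Euclidean, ties to lowest id);
- hunting needs the microscope stage and camera, so at most one pipette
  hunts at a time; the other waits for the stage;
- a failed attempt consumes the cell (no re-attempt), routes the pipette
  through cleaning, and assigns the next nearest cell;
- when both pipettes hold whole-cell recordings the pair is screened in
  both directions; afterwards the pipette whose `whole_cell_since` is
  earliest is released, cleaned, and reassigned — the walk rule;
- cells are held at most `hold_limit_min` (default 45 min) waiting for a
  partner; expiry releases the hold;
- a pipette retires when no eligible cell remains; the run ends when both
  retire.

An optional minimum tip-separation constraint (off by default for two
pipettes) skips candidate cells within a configurable radius of the other
pipette's held cell, reflecting the collision caution relevant to larger
rigs.

`pairs_from_log` recovers paired recordings from an event log alone: one
pair per maximal interval during which two distinct cells are co-held,
with screen outcomes attached when a completed screen falls inside the
interval and `untested` probes otherwise (intervals shorter than a screen
naturally carry untested probes). This means summaries are a function of
the log, not of simulator internals.

## Patch-attempt stage rules

All stage rules are pure predicates over measurements, with the thresholds
used by the automated rig:

- **hunting**: detection when tip resistance rises ≥ 0.2 MΩ over 5
  consecutive 0.1 µm descending steps. The criterion is evaluated as the
  endpoint difference of the 5-step window (the cumulative-vs-endpoint
  choice is not specified by the source protocol; endpoint difference is
  deterministic and robust to step noise). Detection is translation
  invariant in baseline resistance.
- **gigaseal**: resistance ≥ 1000 MΩ ("reaches 1 GΩ" read inclusively);
  the controller waits 5 s before suction.
- **break-in**: suction pulses of 100–1000 ms at −345 mbar (the number of
  pulses before declaring failure is a simulator parameter, default 3);
  success when resistance < 800 MΩ (strict) and holding current ≥ −200 pA
  at −70 mV.
- **recording QC**: include while all access-resistance readings stay
  below 40 MΩ; stop the recording (keeping earlier data) when any reading
  exceeds 50 MΩ; the 40–50 MΩ band marks seal degradation and defaults to
  exclude-from-analysis (configurable to stop).

Stimulus builders produce the standard current-clamp protocols: a 3 s
whole-cell check (1 s at 0 pA, 1 s step within ±300 pA, 1 s at 0 pA) and a
16-sweep f–I family (3 s pulses, −20 to +280 pA in 20 pA steps, each
preceded by a 2 s −20 pA hyperpolarizing step ending 500 ms before pulse
onset). Waveforms are sample-exact at the configured rate (default
10 kHz, a conventional value; the source protocol does not state one).

## Connection screening

A screen runs two protocols, one per direction: five presynaptic action
potentials at 20 Hz while the postsynaptic cell is voltage clamped at
−70 mV. Synthetic postsynaptic sweeps are 500 ms at 10 kHz with stimulus
onset at 50 ms; a connection adds an inward difference-of-exponentials
current (rise 1 ms, decay 10 ms, latency 2 ms, amplitude-normalized) after
each spike, over white Gaussian noise. Three sweeps are averaged pointwise.

Classification: baseline mean and noise SD come from the 50 ms
pre-stimulus window of the raw average; per-spike evoked amplitude is the
most negative baseline-subtracted excursion in the 2–20 ms post-spike
window, measured on a 1 ms boxcar-smoothed copy; the direction is
connected when the mean evoked amplitude exceeds 3× the baseline SD. The
smoothing step is deliberate: the raw extremum of wide-band noise over a
180-sample window is a biased amplitude estimate and alone pushes the
pure-noise false-positive rate to ~6–8%; measuring the trough on a lightly
smoothed copy (short relative to the 10 ms decay, so the true peak is
preserved) brings the false-positive rate to well under 5% per direction
while a 50 pA PSC still reports ≈50 pA. All constants (baseline window,
evoked window, threshold multiple, smoothing width) are arguments.

## Experiment simulation

`simulate_experiment` is a seeded next-event loop (a heap of timestamped
completions) driving the coordinator. Stochastic elements:

- attempt outcomes: Bernoulli at `success_prob`, default 0.522 — the
  observed two-pipette whole-cell rate (71/136);
- stage durations: gamma distributions (positive support, two-parameter
  mean/SD). Defaults — hunt 3.0 ± 1.5, gigaseal 2.5 ± 1.5, break-in
  0.5 ± 0.2, clean 1.5 ± 0.5, screen 2.0 ± 0.5 min — were chosen once so
  that the *emergent* time between paired recordings lands in the
  ~10-minute regime a real two-pipette walk operates in (mean observed
  12.6 ± 7.5 min); that emergent quantity is reported by
  `summarize_log`, not fed in;
- connection outcomes: each directed probe of a screened pair is Bernoulli
  at the distance model's probability for that pair's 3-D intersomatic
  distance.

Simplifications: a failed attempt consumes the same drawn stage durations
as a successful one (per-stage failure times are not modeled); screens
consume screen time but always complete; the traditional strategy forms
groups of *successful* cells (each pipette retries through cleaning until
whole cell), which is what makes 71 successful cells correspond to 35
traditional pairs; hold limits are enforced during the walk, where holds
can be long, and not within traditional rounds, where partners arrive
within a round. The walk coordinator drives exactly two pipettes — the
apparatus the method was demonstrated on; the yield model covers 2–8
pipettes analytically, and the traditional simulator accepts general `p`.

`compare_strategies` runs paired-seed replicates: each replicate seeds
both strategies identically, so they see the same cell map and the same
stochastic stream, and the yield difference isolates the scheduling
policy. Same seed ⇒ bit-identical logs.

## Synthetic data: what it does and does not emulate

Cell maps are uniform rejection samples of 8–10 somata over a
200 × 200 µm field, 20–100 µm below the slice surface, with a 15 µm
minimum separation (about one soma diameter; the protocol specifies the
field and depth band but not a separation). Pipette homes default to
opposite field edges. The generator reproduces the *geometry* of target
selection — mean pairwise distances land near the ~90 µm operating regime —
but not tissue realism: no cell-health variation, no depth-dependent
success rates, no tissue deformation disturbing held pipettes, no
layer- or type-specific connectivity. Hunt traces are baseline-plus-ramp
caricatures adequate for exercising the detector, not seal physics.
Passing tests therefore validate the *logic and statistics* of the method
(counting, scheduling, detection calibration), not biological yields.

## Numerical and degenerate-input choices

- Binomial tails sum the shorter tail with `math.fsum` for accuracy;
  `k ≤ 0` → 1, `k > m` → 0.
- Rejection sampling caps at 10,000 draws before declaring a packing
  infeasible.
- Tie-breaks everywhere are by lowest cell id / pipette label, making runs
  reproducible without hidden state.
- CSV floats are written at 17 significant digits and parsed with
  round-trip precision, so write→read is the identity on positions and
  samples.
- Empty queues retire pipettes rather than raising; empty logs summarize
  to zeros; an evoked window extending past the sweep end is an error
  rather than a silent truncation.
- Problem sizes in the test suite (walks of 4–25 cells, 2,000-pair
  screen-recovery checks, 10⁵-draw Monte Carlo cross-checks) were chosen
  as the smallest sizes at which the statistical assertions have
  comfortable power.

## Known limitations

- The realized pair count of a multi-day campaign (e.g. 44 pairs from 71
  cells) depends on per-slice walk lengths and failure timing that are not
  modeled; only aggregate identities (35 traditional pairs, the 9-pair
  surplus arithmetic) are reproduced.
- The distance-decay calibration rests on two anchor points; no fitting to
  raw connectivity datasets is provided, by design.
- Collision geometry for more than two pipettes and optimal (non-greedy)
  route planning are out of scope; the greedy nearest-cell rule is the
  implemented policy.
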