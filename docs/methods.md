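# Methods

## The model

The range model treats production of a musical sequence as incremental
retrieval under graded contextual activation.  For the event at position
*i*, every other event at signed distance *x* contributes activation
`S_x * M_x(i)`, the product of two components:

* **Serial proximity** `S_x = a^(|x|/t)`.  Activation decays exponentially
  with event distance.  The decay is controlled by the memory parameter
  `a` (dimensionless, 0.8 < a <= 1.0; larger values mean a slower drop-off
  and hence a wider span of co-active events) and by the event duration
  `t` (the interonset interval in seconds, 0.1 < t <= 2.0; slower playing
  leaves more time to retrieve context, flattening the decay).  The
  component is symmetric in the sign of `x`: past and future context are
  equally active on average.

* **Metrical similarity** `M_x(i) = 1 - |m_i - m_{i+x}| / (m_i + m_{i+x})`,
  a Weber-law similarity between accent strengths.  Accent strengths come
  from a nested binary metrical grid: level 1 is the sixteenth-note pulse
  (period 1), each higher level doubles the period, and position *i*'s
  strength is the weighted count of levels accenting it,
  `m_i = sum_j w_j g_ji`.  The level weights sum to 1; the tactus (level
  2, the eighth-note level, in all default grids here) may carry an
  elevated weight `w2` in [0.25, 0.99], the remaining levels sharing
  `(1 - w2)/(k - 1)`.  With `k = 4` levels and equal weights the grid
  cycle of strengths is `1, .25, .5, .25, .75, .25, .5, .25`.

The **absolute activation** of the current event is the squared sum of its
contextual activations, `Event(0) = B (sum_{x!=0} S_x M_x(i))^2` with `B`
a pure output scale (default 1, never fitted).  Squaring makes activation
grow faster than linearly with context, which is why the model predicts
that an excerpt embedded in a long context (33 events per hand) reaches
higher current-event activation than the same excerpt in a short context
(17 events per hand) at every admissible `(a, t)` — the package asserts
this property over a parameter grid rather than assuming it.

Normalising `S_x * M_x` over the +-8-event window (one full metrical
cycle), summing the +x and -x contributions into absolute-distance bins
and averaging over the excerpt positions yields the **predicted movement
gradient**: the conditional probability that a serial-ordering error
arises from each source distance 1..8, given that an error occurred.
Positions whose window crosses a sequence boundary contribute only their
existing pairs — no phantom events, no per-position renormalisation
(a single normalisation happens at the end); a flag can restrict
evaluation to interior positions instead.

## Error coding

Performed trials are aligned to the score per hand with a two-pass
Needleman–Wunsch alignment: pass one aligns on pitch identity alone to
estimate the trial's time anchor robustly (insertions and deletions shift
raw onset offsets by whole IOIs, so the anchor is the median offset over
pass-one matches); pass two adds a small temporal-proximity cost
(0.02 per IOI of deviation from the nominal onset) that breaks ties
deterministically.  Costs: match 0, substitution 1, insertion/deletion
1.45 each — substitution is cheaper than an indel pair, so a wrong pitch
at the right time is always described as a substitution.  A performance in
which fewer than half of all score positions can be matched raises an
alignment failure with diagnostics.

Coding rules, applied after alignment:

* **Exchange**: two adjacent substitutions whose intruders are each
  other's targets collapse to one contextual error at distance 1.
* **Chord error**: incorrect keystrokes within 94 ms of each other (half
  the fastest IOI) collapse to one error; the representative intruder is
  the member nearest in pitch height to the target.  Correct keystrokes
  never merge.
* **Contextual source**: the intruder's source is the nearest
  octave-specific occurrence of that pitch anywhere in the stimulus
  (either hand); exact two-sided ties prefer the anticipatory (future)
  source and are flagged.  Sources beyond 8 events leave the record
  contextual but without a gradient-eligible distance.
* **Noncontextual** errors are deletions, additions of pitches absent
  from the stimulus, and substitutions by absent pitches.
* **Exclusion filters** mark, never delete: (a) errors at a position that
  also erred in the learning phase of the same stimulus and in at least
  half of its eight test performances (mislearning, not planning); and
  (b) corrected errors.  A correction is operationalised as a
  correct-pitch keystroke serving the error's position within one nominal
  IOI of the erroneous keystroke *and* arriving at least 0.25 IOI later
  than the position's nominal onset — the lateness requirement separates
  a genuine re-strike (which displaces the position's timing) from an
  on-time correct keystroke that merely neighbours a plain addition.

Per-record flags include the key membership of the intruder (7-tone
scale, harmonic minor for minor keys), tonic-triad membership, semitone
distance, same-finger identity, and hand — each with an analytic chance
reference (7/12, 3/12, 1/2) for uniform chromatic intrusions.

Both error-rate tallies (with and without deletions) are available, since
"all pitch errors" is ambiguous about deletions; the headline rate
includes them.

## Fitting

Fits minimise the SSE between an observed 8-bin gradient and the model
prediction, with a deterministic exhaustive grid (step 1e-3) plus
golden-section refinement inside the winning cell; identical inputs give
identical estimates.  The two-step procedure fits `a` per condition with
equal weights, averages `a` over a participant's available conditions,
then fits `w2` per condition at that average.  Goodness of fit is VAF,
defined as the squared Pearson correlation between observed and predicted
bins — this definition is chosen because the critical value 0.50 equals
the squared critical correlation for 8 points at alpha = .05, which a
1 − SSE/SST definition would not license — and the Gaussian-SSE AIC
`n ln(SSE/n) + 2p`.  Model comparison fits three variants: serial-only
(S, p = 1), serial x metrical with equal weights (p = 1), and serial x
metrical with `w2` free (p = 2, sharing the fixed variant's `a` so its
SSE can never be worse).  Flat observed gradients fit (pinned at a = 1,
flagged at-bound) but have undefined VAF.

A caveat the package measures rather than hides: applied to data generated
with an elevated tactus weight, the equal-weights first step absorbs part
of the metrical structure into `a` (noise-free: a_hat 0.876 at a_true
0.85), and `w2` conditioned on that inflated `a` is attenuated (~0.42 at
0.48).  With `a` held at its generating value, `w2` recovers exactly.
`recovery_study(mode="matched")` therefore evaluates each estimator under
the generating assumptions of its own step; `mode="two_step"` reports the
full procedure, attenuation included.

## The synthetic study

The generator emulates the study design the analysis was built for: 8
excerpts (half major, half harmonic-minor keys) of 8 sixteenth notes per
hand, each embedded in a long (12+8+13) and a short (4+8+5) per-hand
context; the short layout is generated first and the long one extends it
by 8 events per side, so the excerpt and its immediate flanks are
identical across the pair.  Pitch material is diatonic in a one-octave
band per hand (right hand from C4, left from C2 — disjoint registers, so
octave-specific identity never crosses hands), with no immediate repeats
and a mean nearest-recurrence distance constrained to [5, 7] events
(target ~6) by bounded rejection sampling.  The roster crosses 2 contexts
x 2 tempi (fast 187.5 ms, medium 225 ms per sixteenth) x 4 blocks x 2
repetitions = 64 test trials per pianist, tempo alternating every trial,
context order and tempo assignment counterbalanced by participant and
block parity; 26 pianists by default, plus 3 slow (429 ms) learning
performances per stimulus.

Performances are sampled from the model itself.  The per-event error
probability is

```
p_err(i) = base * exp(-lambda * (E_cond - E_ref)) * exp(-beta * (c_i - c_bar))
```

with `base = 0.115`, `lambda = 0.5`, `beta = 0.23`, `E_cond` the
condition's mean excerpt `Event(0)`, `E_ref` the grand mean over the four
design cells, `c_i` the accent count and `c_bar = 1.875` its cycle mean.
The first factor carries the activation account of tempo and context
(faster playing -> lower activation -> more errors); the second carries
the accent effect (strong positions err less).  The two are separated
deliberately: per-position `Event(0)` is *higher* at weakly accented
positions (their lag-2 neighbours are metrically identical, so M = 1),
so a naive per-position activation link would invert the observed
accent–error relation.  `lambda` and `beta` were set once from the
published effect magnitudes (fast/medium rate ratio ~1.4; accent-1 vs
accent-4 rate ratio ~2).

Given an error, the intruder is contextual with probability 0.81, its
source position drawn proportionally to `S_x * M_x(i)` over the signed
window, restricted to distances that nearest-source coding would return
unchanged (the sampled pitch must not occur nearer, and two-sided ties
must be anticipatory).  Otherwise the error is a deletion (0.60), an
out-of-stimulus substitution (0.25) or an out-of-stimulus addition
(0.15) — deletion-heavy, as noncontextual errors are.  Anticipatory
distance-1 substitutions complete into exchanges with probability 0.3.
Velocities are linear in accent count (3.5 MIDI units per level, sd 4)
around hand means of 74.7 (right) and 58.8 (left); onsets carry Gaussian
jitter (sd 8 ms); corrections are planted with probability 0.04 at half
an IOI after the error.  The generating tactus weight is
context-dependent — 0.48 in long contexts, 0.40 in short — mirroring the
model's account that longer contexts give the metrical hierarchy more
time to instantiate; this is the mechanism behind the generator's
long-vs-short differences in planning range and metrically similar
errors.  All randomness flows from the cohort seed through per-trial
substreams `(seed, participant, trial)`, so any single trial is
reproducible in isolation.

Two structural properties of the generator matter for interpretation:

* **Minimal-edit identifiability.**  The coder describes a trial by its
  cheapest edit script.  Certain clusters of planted errors admit a
  cheaper description than the planted one (a swap adjacent to a
  deletion; a deletion and an addition within two positions; two swaps
  within four; unit-distance substitutions between a deletion/addition
  pair).  The generator spaces such interacting types (one-event
  refractory period after any error; an explicit shifted-alignment
  safety predicate before planting deletions/additions; wide spacing
  around exchanges), so the planted taxonomy is the unique minimal-cost
  description and coded records round-trip exactly on jitter-free,
  correction-free trials.  This is a property of the generator, not a
  restriction on the coder.
* **Availability truncation.**  A sampled far source often has a nearer
  same-pitch occurrence; nearest-source coding would re-attribute it, so
  the generator restricts sampling to codable distances.  The observed
  gradient is therefore steeper than the model's unconstrained
  prediction, which biases full-pipeline estimates of `a` downward — the
  same pitch-recurrence confound real stimuli impose.  Parameter-recovery
  checks consequently use gradient cohorts drawn multinomially from the
  model's own predictions at the design's error counts; the full pipeline
  is validated by round-trip exactness, directional context effects, and
  AIC model selection instead.

What the generator does not emulate: expressive timing beyond Gaussian
jitter, learning dynamics across blocks, fingering-driven error
likelihoods, ternary or mixed meters, and hand asymmetries in error rates.
Passing tests therefore certify the pipeline's correctness and the
model's internal consistency on data obeying the model's own assumptions,
not the model's truth for human performers.

## Chance baseline

The Monte-Carlo baseline plants errors on excerpt events with probability
0.10 and draws intruders uniformly from the multiset of all stimulus
pitches (a set-based toggle exists), coding distances exactly as the
observed-gradient coder does (nearest same pitch; identity draws source
from the pitch's nearest other occurrence; no source within 8 -> dropped;
chance errors are not passed through the exclusion filters, toggle
provided).  One thousand simulations per stimulus by default, per-
simulation proportions averaged, per-bin Monte-Carlo standard errors
reported.  Because pitch recurrence concentrates nearest sources at short
distances, the chance gradient declines monotonically — odd bins
(distances 1, 3, 5, 7) mechanically exceed even bins, so a raw even-vs-odd
mean comparison does not test for meter.  The meaningful flatness checks,
used in the acceptance suite, are that AIC prefers the serial-only model
over serial x metrical on chance gradients, and that the even-distance
share of meter-generated errors exceeds the chance sampler's.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale cohorts chosen once: the full
26-participant study for the headline summary script; 12 participants x
20 seeds for the directional context-effect checks; 10 participants for
the model-selection cohorts; 20 gradient cohorts at ~20 errors per
participant-condition (pooled ~500 per condition, matching the published
error yield) for recovery.  Optimiser grid step 1e-3 with golden-section
refinement to 1e-7; activation oracle agreement asserted to 1e-12;
weights sum to 1 within 1e-12; gradient normalisation within 1e-9.
Onsets are kept in float milliseconds internally and written to text with
millisecond precision; Standard MIDI File output quantises to 480 ticks
per quarter (~1 ms at the study tempi).  Degenerate inputs signal rather
than silently default: empty gradients raise, zero-variance gradients
have undefined VAF, all-zero activation fields refuse to normalise.
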