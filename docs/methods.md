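# Methods

## The screening model

Delayed echoes are identified by consensus: an utterance enters the candidate
set only if *both* trained coders independently flagged it as possible
delayed echolalia, and it survives only if the parent reports having heard
the child repeat it (Monthly, Weekly or Daily; "Never" excludes it).  The
frequency scale is ordered (Never < Monthly < Weekly < Daily) but only the
Never/non-Never distinction gates inclusion.  Parents can add phrases that
never appeared in the language samples; these become confirmed candidates in
their own right.

Two choices here were genuinely open and are deliberate:

- **Phrase matching is a normalized exact match** (case-fold, strip
  punctuation, collapse whitespace; `MatcherConfig`).  The checklist is
  constructed from the candidate list, so fuzzy matching would add failure
  modes without adding coverage, and exact matching keeps every
  include/exclude decision auditable.
- **Imageability is an input, not an inference.**  Whether "froggy" can be
  pictured is a human judgment; the per-child lexicon file carries it
  (`word`, `word_class`, `imageable`, plus optional per-word overrides).
  Multiword names ("Mickey Mouse", "Keepy Uppy", "Wheel of Fortune") are
  single lexicon tokens matched greedily longest-first within a phrase.
  A phrase may yield 0, 1 or several targets; phrases with no imageable word
  (e.g. "I have a surprise for you and you are really gonna like it!") are
  logged and contribute nothing.

Whether an echo is verbatim or mitigated is recorded as a free-text note and
never gates inclusion.

## Task construction

Targets are placed into yoked pairs (each target always appears with the same
distractor).  The task is three contiguous blocks — "Find (the) X",
"Look at (the) X", then primer + bare word — each containing every target
exactly once as the named target.  Constraints, enforced by seeded rejection
sampling and re-checked by an independent validator in the test suite:

- per-block left/right target placements are equal;
- target-side runs never exceed `max_run` (default 3, checked across block
  boundaries) — "target location varied throughout" made operational;
- the same image pair never appears on consecutive trials (when ≥ 2 pairs);
- the single-word block splits its primers evenly between "Ooh" and "Look".

Audio scripts follow the determiner rule observed in the published tables:
common nouns take "the" ("Find the dog"); verbs, proper nouns and fixed
expressions do not ("Find jump", "Find Mickey Mouse") — with per-word lexicon
overrides (`use_determiner`) for exceptions such as "Find the Jackpot".
Proper nouns keep their capitalization in audio; other classes are spoken
lowercase ("Find keepy uppy").  A per-word `audio_form` override exists for
surface forms neither rule covers.  Given a seed, generated tasks are
byte-identical across runs.

`parse_task_table` loads published tables as-is: the target side is inferred
from which image name the audio script ends with (longest match wins), and
constraint violations in historical tables are warnings, never errors.  One
published row prints a lowercase "find"; matching is case-insensitive so the
row loads, and exact audio re-rendering is asserted only for the table whose
typography is consistent.

## Gaze coding and alignment

Hand-coded gaze arrives frame by frame (default 30 fps) with codes left,
right, away (neither image, per coder judgment) and off (not codable /
off-screen).  Both away and off count against the screen-time criterion and
are excluded from accuracy; only left/right are "on screen" — the
conservative reading, configurable via the alias map.  Side labels are from
the child's perspective as coded from face video; the reader applies no
mirror flip.

Each trial's critical onset is `audio_start_ms + target_onset_ms` from the
stimulus-timing table (each audio script must match exactly one timing
entry).  Alignment subtracts the onset from every frame time, keeps pre-onset
frames (negative times) for time-course plotting, and maps codes to roles via
the trial's target side.  Role mapping is a pure function of (code, side):
flipping the side swaps target and distractor exactly.

## Analysis

- **Exclusion**: trials with on-screen fraction strictly below
  `screen_threshold` (default 0.5) of *all* frames (pre-onset included) are
  dropped; exact equality is kept ("less than" is strict).
- **Window**: half-open [300, 1800) ms after onset by default — half-open
  avoids double counting at bin edges; a closed variant is available for
  sensitivity analysis.
- **Accuracy**: target / (target + distractor) frames in the window; away/off
  frames affect neither numerator nor denominator, which is what makes 0.5
  the chance level.  A trial with no on-screen frame in the window has
  undefined accuracy and is excluded from the mean with a logged reason.
- **Test**: one-sample two-sided Student *t* of per-trial accuracies against
  chance, df = n_trials − 1.  Per-trial is the conservative standard unit; a
  frame-pooled alternative (`test_unit="frames"`) is exposed because the unit
  behind published *t* statistics of this kind is often unstated.  "Above
  chance" additionally requires the mean to exceed chance.  A zero-variance
  vector off chance is reported significant by construction with an explicit
  note (the statistic diverges).
- **Time course**: pooled target/(target+distractor) per `bin_ms` bin over
  [−500, 2500) ms, with per-bin contributing-trial and frame counts.  When
  the bins tile the window exactly, the denominator-weighted bin mean equals
  the frame-pooled window accuracy (asserted in the tests).

## The synthetic gaze generator

`simulate_trial` is a minimal orienting model, not a cognitive-process model:
gaze starts on the target side with probability `pre_onset_bias` (0.5: no
pre-onset preference), shifts at onset + latency to the target with
probability `p_know` (else to the distractor) and stays; on-screen frames
enter away/off episodes with per-frame hazard `p_away_per_frame`, and
episodes end geometrically with mean `away_dur_mean_ms`.

Defaults, chosen once as realistic for toddler LWL data: lognormal latency
with mean 400 ms and sd 150 ms (heavy right tail, typical shift latencies),
`p_away_per_frame` 0.02 and mean episode 500 ms (≈ 77% expected screen time,
so the 50% exclusion rule fires occasionally, as in real sessions), 30 fps,
4,000 ms trials, 36-trial sessions (6 pairs).  With `p_know = 0.5` the
generator *is* the chance model — equal looks to target vs. distractor — and
serves as the null for calibration.  Expected window accuracy has the closed
form

    E[acc] = (1 − f)·pre_onset_bias + f·p_know,

with `f` the mean latency CDF over the window; `recover_parameters` compares
estimates to it and inverts it to an implied `p_know`.

Determinism: per-trial random substreams derive from `(seed, trial_number)`,
so adding trials never perturbs earlier ones, and identical seeds give
byte-identical emitted files.

What the generator does **not** emulate: anticipatory looks driven by trial
structure, saccade dynamics, drift back to a preferred image, side biases,
fatigue across the session, or coder disagreement/noise.  Passing tests
therefore show that the pipeline's bookkeeping, exclusion, windowing and
inference behave correctly under a known data-generating process — not that
real children satisfy that process.

## Calibration and problem sizes

`calibrate_test` runs the full pipeline per replicate and reports the
directional rejection rate (significant *above* chance at two-sided
α = 0.05; nominal 0.025 under the null).  The shipped acceptance run uses
2,000 replicate 36-trial null sessions (pooled across the three trial types,
6,000 tests), 1,000 seeded builder runs against the independent constraint
checker, and 10,000 simulated trials for the null-accuracy check — sizes at
which Monte-Carlo error is a fraction of the tolerance bands while the whole
run stays under a minute.  Per-trial-type accuracies are near-binary under
this generator (most of the window lies after the shift), so the t-test runs
on roughly Bernoulli data at n ≈ 12; its measured null rate is nevertheless
close to nominal, which the calibration check makes explicit rather than
assumes.

## Known limitations

- The analysis implements windowed means and one-sample tests only; no
  growth-curve, cluster-permutation or mixed-effects time-course inference,
  and no reaction-time/onset-contingent measures.
- The screening stage consumes transcripts and codes; it does not detect
  echolalia from audio or prosody.
- Published task tables can be loaded and re-rendered, but published
  accuracy/t values from real children cannot be recomputed without the raw
  gaze recordings, which are not part of this package; the simulator is a
  stand-in with known truth, not a reproduction of child data.
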