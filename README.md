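# lwl-echo

Tools for testing whether a child understands the individual words inside the
phrases they repeat as **delayed echolalia** — repetitions of previously heard
speech produced some time after the original model.  A popular clinical
hypothesis ("gestalt language processing") holds that such echoed chunks are
stored as unanalyzed wholes, without comprehension of their component words.
This package implements a pipeline for probing that claim with eyegaze
methods, aimed at developmental psycholinguists and speech-language
researchers working with young autistic children:

1. **Echo screening** (`lwl_echo.screen`) — identify confirmed delayed echoes
   from two independent coders' annotations of naturalistic language samples
   (consensus = both coders flag the utterance), checked against a
   parent-report checklist (phrases the parent *never* heard the child repeat
   are excluded; parents may add phrases seen only at home), then extract the
   imageable nouns/verbs from each confirmed echo using an explicit per-child
   imageability lexicon.
2. **Task construction** (`lwl_echo.task`) — build a personalized
   two-alternative **Looking-While-Listening (LWL)** task from the target
   words: yoked target–distractor pairs, three sequential blocks
   ("Find (the) X" → "Look at (the) X" → primer + bare word), pseudo-randomized
   target sides balanced left/right with bounded runs, and rendered audio
   scripts.
3. **Gaze alignment** (`lwl_echo.gaze`) — read frame-coded gaze exports
   (30 fps hand coding: left / right / away / off), compute each trial's
   critical onset from a stimulus-timing table, and re-reference frames to it
   while mapping screen sides to target/distractor roles.
4. **Analysis** (`lwl_echo.analysis`) — exclude trials with less than 50%
   screen time, compute per-trial accuracy

   *acc* = n(target) / (n(target) + n(distractor))

   over the standard analytical window 300–1,800 ms after target onset, test
   each trial type against chance (0.5) with a one-sample Student *t*
   (t = (x̄ − 0.5)/(s/√n), df = n − 1), and produce proportion-of-looks time
   courses.
5. **Simulation** (`lwl_echo.simulate`) — a synthetic gaze generator with
   known ground truth (orientation probability `p_know`, lognormal shift
   latency, Markov away episodes) for validating every stage without child
   data, including Monte-Carlo calibration of the chance-level test.

## Worked example

Simulate a child who knows most of their echoed words (`p_know = 0.85`) and
analyze the session:

```python
from lwl_echo import GazeModelParams, simulate_session, run_pipeline

session = simulate_session(GazeModelParams(p_know=0.85, seed=7), n_pairs=6)
report = run_pipeline(session.task, session.gaze, session.timing)
print(report.to_text())
```

```
trials: 36 total, 33 usable, 3 excluded
analytical window: 300-1800 ms
carrier1: mean accuracy 87.41% (n = 10, t = 3.82, df = 9, p = 0.004; above chance 0.5)
carrier2: mean accuracy 91.30% (n = 12, t = 4.97, df = 11, p < 0.001; above chance 0.5)
single_word: mean accuracy 81.78% (n = 11, t = 3.01, df = 10, p = 0.013; above chance 0.5)
```

The 36-trial task (6 yoked pairs × 3 blocks) lost 3 trials to the 50%
screen-time rule; in every trial type the child looked at the named image
well above the 50% chance level, i.e. the session shows comprehension of the
individual words.  `report.write("out/")` additionally writes per-trial and
summary CSVs and a time-course figure with the chance line and window
markers.

The same steps are available from the shell:

```sh
lwl-echo screen --utterances U.tsv --annotations A.tsv --checklist C.csv --lexicon L.tsv -o echoes.csv
lwl-echo build-task --targets targets.tsv --seed 7 -o task.csv
lwl-echo analyze --task task.csv --gaze gaze.csv --timing timing.tsv -o report/
lwl-echo simulate --pairs 6 --p-know 0.8 --seed 11 -o sim/
lwl-echo calibrate --null 0.5 --reps 2000 -o calib.txt
```

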