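# ticlab

A headless, testable toolkit for gamified tic-suppression training sessions:

* **`ticlab.reward_core`** — the differential-reinforcement (DRO) reward
  algebra: points accrue once per tic-free interval of `level` seconds at the
  current rate, the rate then grows by `level²` (capped at `10 × level²`), a
  tic resets the rate and streak to zero, and a level-up fires whenever
  points exceed `1000 × level²`, paying a coin bonus of the previous level
  squared.  Coins are redeemable for medals.
* **`ticlab.ncr`** — the masked noncontingent-reward control condition:
  exponential inter-reward delays with mean `initial_mean_interval × level`,
  level-scaled point payloads, and the same level-up processing, so the
  user-facing event stream is schema-identical across conditions.
* **`ticlab.session`** — session lifecycle state machine (start, trainer
  tic/heartbeat/end presses, 60-second inactivity timeout, deterministic
  replay) plus the birthdate anonymizer (uniform jitter within ±45 calendar
  days of the 15th of the supplied birth month).
* **`ticlab.log_io`** — bit-exact reader/writer for the session-log TSV
  dialect, with deterministic archive filenames carrying the session end
  time, forward-compatible handling of unknown event kinds, and transparent
  gzip reads.
* **`ticlab.analytics`** — per-session metrics (tic frequency, longest
  tic-free interval, disjoint 10-second tic-free windows, reward counts,
  personal records), Fano-factor scaling analysis of inter-tic structure
  (fractal positive control supported), and a circular-shift permutation
  test of tic timing versus reward timing with Benjamini–Hochberg
  correction.
* **`ticlab.simulator`** — seeded synthetic tic streams (Poisson, suppressed
  Poisson, heavy-tailed Pareto renewal), full simulated sessions in either
  condition, and suppression-factor recovery with a session-level bootstrap.

## CLI

All subcommands print machine-readable output (JSON or paths) to stdout and
diagnostics plus the resolved configuration to stderr.

```sh
# simulate and archive a session log
ticlab simulate --condition dro --duration-s 1200 --seed 7 --out-dir logs

# verify a log by replaying its input events through the engine
ticlab replay logs/session_user0_*.tsv

# per-session summary metrics
ticlab metrics logs/session_user0_*.tsv

# Fano-factor scaling of the inter-tic intervals
ticlab fractal logs/session_user0_*.tsv --window-sizes 5,10,20,40 --seed 1

# tic timing vs reward timing (circular-shift null)
ticlab reward-timing logs/session_user0_*.tsv --lag-bins 0,5,10,20 --seed 1

# suppression-factor estimate from a set of archived logs
ticlab recover logs/*.tsv --seed 1

# anonymized birthdate for a given birth month/year
ticlab anonymize --month 3 --year 2007 --seed 11
```

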