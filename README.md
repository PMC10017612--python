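# switcherr

Simulation and analysis pipeline for error types in cued task switching.

Errors in task switching can arise from selecting the wrong task or from
executing the wrong response within the correct task. `switcherr`
implements the full desk pipeline for studying this distinction:

- **design** — three paradigm definitions (`univalent` 6-key,
  `bivalent_congruency` 3-key with congruent/incongruent stimuli,
  `three_key` target/distractor) and lawful sequence generation:
  task switches on every trial, exact per-block ABA/CBA triplet balance,
  no stimulus repeats at lags 1–2.
- **simulate** — synthetic participants from a latent two-stage process
  (task selection with probability `T`, response selection with
  probability `R`, random execution 0.5), plus a lognormal RT model with
  post-error slowing, an injectable N-2 repetition cost, and a slow
  error-correction mechanism gated on the N-1 response time.
- **classify** — maps each key press to `correct` / `task_confusion` /
  `response_confusion` / `mixed` under the paradigm's scheme and
  tabulates per-participant counts.
- **mpt** — the two saturated multinomial-processing-tree models,
  per-participant maximum-likelihood fitting of `(T, R)`, G² fit
  statistics, derived conditional failure probabilities
  (e.g. P(task-selection failure | response-confusion error) = 1 − T),
  and the direct estimators available under univalent mappings.
- **trim** — trial-level removal flags (block starts, post-error,
  timeouts and fast guesses with their two-trial windows, optional slow
  cutoff) and participant-level exclusion (fast-guess rate, error rate,
  minimum trials per analysis cell). Trials are flagged, not dropped, so
  removed trials remain available as N-1/N-2 context.
- **seqcost** — sequence labelling (ABA vs CBA with N-2 category and N-1
  speed by participant-level median split), per-participant cost tables,
  fully-within repeated-measures ANOVA with partial and generalized
  eta-squared, paired contrasts with Cohen's dz, and exact/Monte-Carlo
  permutation tests.

## CLI

The `switcherr` entry point chains the pipeline through CSV files:

```bash
switcherr design   --paradigm three_key --participants 10 --blocks 12 \
                   --block-length 144 --seed 1 --out design.csv
switcherr simulate --design design.csv --paradigm three_key \
                   --t 0.93 --r 0.93 --seed 2 --out trials.csv
switcherr classify --trials trials.csv --paradigm three_key \
                   --out classified.csv --counts-out counts.csv
switcherr fit-mpt  --counts counts.csv --model exp3_three_key \
                   --out fits.csv --summary-out summary.json
switcherr trim     --trials classified.csv --out trimmed.csv
switcherr n2cost   --trials trimmed.csv --out-costs costs.csv \
                   --out-anova anova.json
switcherr compare  --a fits_a.csv --b fits_b.csv --column p_tsf_given_tc --seed 3
switcherr report   --trials trimmed.csv --out report.json
```

Add `-v` before the subcommand for per-stage INFO logging.

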