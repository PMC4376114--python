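# sepsispomdp

A tested pipeline for POMDP-based clinical decision support on sepsis
trajectories:

1. **State labeling** (`sepsispomdp.states`) — ten clinical states (no-SIRS,
   SIRS, sepsis, septic shock, bacteremia, three "probable" states produced
   by missing vitals, and absorbing death/dismissal) assigned from SIRS
   criteria, blood-culture results and hypotension; a 32-action antibiotic
   combination encoding (all non-empty subsets of the five most frequent
   antibiotics plus one catch-all); and a 6250-cell observation
   discretization (five vitals x five bins x binary culture flag).
2. **Model estimation** (`sepsispomdp.estimation`) — transition tensors from
   (state, action, next-state) frequencies with optional smoothing/shrinkage,
   and a factorized observation model from per-state AIC-selected
   normal/lognormal/gamma fits integrated over equal-width bins.
3. **POMDP solving** (`sepsispomdp.solver`) — belief updates, exact MDP value
   iteration (used as an oracle in tests), and a Perseus-style randomized
   point-based value iteration producing an action-tagged alpha-vector
   policy.
4. **Retrospective evaluation** (`sepsispomdp.evaluation`) — the
   policy-followed rule (one overlapping antibiotic suffices),
   better/same/worse transition statistics per arm, >=90% trajectory-level
   buckets, patient-level k-fold cross-validation, data-size robustness
   curves, and one-sided hypergeometric enrichment tests with
   Benjamini-Hochberg correction.
5. **Synthetic EHR generation** (`sepsispomdp.synthetic`) — latent ten-state
   Markov cohorts with known ground truth (strong-signal, null-signal and
   paper-like scenarios), state-conditional vitals emissions, culture
   signals, and missingness that produces the probable states; used for
   parameter-recovery and end-to-end tests.

`sepsispomdp.pipeline` wires these together (cohort -> model -> policy ->
evaluation report); `sepsispomdp.cohort` reads/writes the plain-CSV
trajectory layout.

## CLI

```bash
# generate a synthetic cohort with ground truth
sepsispomdp simulate --scenario strong_signal --patients 500 --seed 7 \
    --out cohort.csv --truth-out truth.json

# cross-validated retrospective policy evaluation
sepsispomdp evaluate --cohort cohort.csv --folds 5 --seed 42 --out report.json

# export state/action/observation code books
sepsispomdp codebooks --out codebooks.json
```

`evaluate` accepts `--config config.yaml` with solver knobs
(`gamma`, `shrinkage`, `n_beliefs`, `max_stages`, `tolerance`,
`reward_overrides`, ...) mirroring `sepsispomdp.pipeline.SolverConfig`.

## Cohort file format

CSV with columns `patient_id, timestamp, temperature, heart_rate,
respiratory_rate, wbc, map, sbp, blood_culture {pos,neg,NA}, antibiotics
(semicolon-joined), outcome {none,death,dismissal}`. Missing numeric values
are empty cells; a terminal death/dismissal event is a row with the
`outcome` column set.

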