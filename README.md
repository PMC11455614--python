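# explorekit

Reusable, tested implementations of a behavioral-neuroscience +
transcriptomics analysis stack:

- **`bandit_task`** — two-armed bandit environment with block-wise reward
  reversals (fixed 20-trial blocks, or variable 20/30/40 blocks drawn with
  probabilities 0.43/0.32/0.25), CSV session logs.
- **`qlearning`** — Q-learning choice model (learning rate α, forgetting
  rate ζ, inverse temperature β, bias b), analytic-gradient maximum-likelihood
  fitting with a 75/25 contiguous trial-quarter train/held-out split, and
  agent simulation.
- **`behavior_metrics`** — normalized reward rates, p(high) transition
  curves with exponential-τ fits, conditional switch probabilities over
  2-trial outcome histories, performance criterion.
- **`pseudocell_de`** — random aggregation of nuclei into ~30-nucleus
  pseudocells, counts-per-100k log2 normalization, moderated-t differential
  expression with an empirical-Bayes variance trend, cross-condition
  sample-pair robustness scores, responsive-gene calling, Spearman/Ward
  cross-cell-type correlation, and disruption regression.
- **`syllable_metrics`** — run-length-encoded syllable instance streams,
  global 1% usage filter, usage entropy and outgoing-transition entropy (bits).
- **`ephys_fit`** — 10-ms integrated-charge quantification, Hill-sigmoid
  response-profile fitting (saturation amplitude / half-maximum power /
  slope), fold changes vs control medians, paired-pulse ratios with
  single-pulse subtraction, recording QC predicates.
- **`synthetic_data`** — seeded generators for all of the above with ground
  truth (Q-agents with a treatment-epoch β shift, negative-binomial counts
  with spiked effects, Hill sweeps, Markov syllable streams).

## CLI

```bash
explorekit make-synth --seed 1 --out data/          # full synthetic study
explorekit fit-q --sessions data/sessions.csv --out fits/
explorekit behavior-stats --sessions data/sessions.csv --out stats/
explorekit de --mtx data/counts.mtx --genes data/genes.tsv \
              --meta data/nuclei_meta.tsv --out de/
explorekit syllables --streams data/syllables.csv --out syl/
explorekit ephys --sweeps data/sweeps.csv --out eph/
```

Every command is deterministic given its seed (one global seed is expanded
into per-module child seeds via `numpy.random.SeedSequence.spawn`) and
writes a `manifest.json` (config hash, version, seeds) next to its outputs.
`make-synth` accepts a YAML file with `cohort:`, `counts:`, `sweeps:` and
`syllables:` sections overriding generator defaults; unknown sections are
rejected.

## Conventions worth knowing

- The softmax reference spout is **right**: `P(R) = σ(β(Q_R − Q_L) + b)`.
  Flipping the convention flips only the sign of b.
- Q-values reset to 0 at the start of each session; timeout trials are
  excluded from both the likelihood and value updates.
- The Hill sigmoid is `amp / (1 + (half_power/x)^slope)`, so the fitted
  curve equals `amp/2` at `x = half_power` by construction.
- Switch-history keys (`RR`, `RU`, `UR`, `UU`) are ordered older → newer;
  histories with ≤ 50 occurrences per mouse are flagged excluded.
- Robustness scores count **cross-condition** sample pairs only; a score of
  ±0.5 corresponds to 75% concordance in a 4-vs-4 design.
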