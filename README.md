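# mesostate

Linear state-space modelling of EEG correlation-network dynamics for
neurofeedback-training (NFT) sessions, with adaptive process-noise
removal, per-session feature-space alignment, CNN-based brain-state
classification, and mass-univariate statistics.

A session of repeated training runs is modelled as a short Markov chain
of *observation matrices* — four labelled Spearman-correlation blocks
over seven harmonized EEG channels (motor sub-network, occipital
sub-network, the cross block, and a mesoscale network over region-pooled
signals). Each chain is assumed to be driven by a constant
block-structured linear map `x_k = A x_(k-1) + w_(k-1)`; the fitting
loop estimates `A`, measures the spread of the per-transition estimates
(the `f1` loss), and removes trial-to-trial process noise `w` with a
fuzzy-rule step size until the chain is self-consistent. A per-session
bias `b0` aligns feature spaces across sessions (the `f2` loss). The
resulting transition matrices are the classification features.

Because the clinical recordings behind the original analysis are not
publicly deposited, a first-class synthetic generator replaces them:
network-level chains with exact linear dynamics (for estimator tests)
and signal-level 7-channel band-limited EEG whose empirical Spearman
network approaches a prescribed target (for end-to-end tests), including
the alpha-suppression feedback statistic at Pz.

## Layout

| module                  | purpose                                             |
|-------------------------|-----------------------------------------------------|
| `mesostate.types`       | block-matrix types, recordings, chains              |
| `mesostate.synth`       | synthetic sessions (network level and signal level) |
| `mesostate.preprocess`  | resample, zero-phase band-pass, CAR, ICA cleanup, channel alignment, segmentation, baseline, session z-score |
| `mesostate.networks`    | Spearman networks, sub-network extraction, region pooling, mesoscale network |
| `mesostate.dynamics`    | transition estimation, `f1`/`f2` losses, fuzzy noise update, session fitting and alignment |
| `mesostate.classify`    | session-level splits, transition tensors, numpy CNN (2 conv / 2 pool / 2 FC), metrics |
| `mesostate.stats`       | Welch t-tests per weight, Benjamini–Hochberg FDR, condition weight ratios with bootstrap CI |
| `mesostate.cli`         | `mesostate` command line, pipeline orchestration    |

## CLI

Every stage is a subcommand; `run` ties them together from a YAML config
with config-hash caching and an artifact manifest:

```sh
# generate a labelled two-class synthetic dataset (JSON)
mesostate simulate --n-sessions 40 --seed 1 --out dataset.json

# fit each session chain (adaptive noise removal)
mesostate fit --networks dataset.json --out fits.json

# classify NFT vs resting from transition tensors, session-level 7:1:2 split
mesostate classify --fits fits.json --split-seed 1 --report report.json

# weight-wise condition statistics with BH-FDR and ratios
mesostate stats --fits fits.json --alpha 0.05 --out stats.json

# or end to end:
mesostate run --config pipeline.yaml --out results/ --stages simulate,fit,classify,stats
```

Example `pipeline.yaml`:

```yaml
seed: 1
simulate: {n_sessions: 40, process_noise_sd: 0.01}
classify: {epochs: 300}
stats: {alpha: 0.05}
```

Signal-level recordings travel as a CSV sample matrix plus JSON sidecar
(`mesostate preprocess --in <prefix> --out <dir>` followed by
`mesostate networks --in <dir> --out chains.json`).

## Acceptance

Acceptance for this project is property-based (the source study's
headline numbers require clinical data that is not deposited); the
properties live in `tests/test_acceptance.py`. The report script is
still provided and writes the (empty) target map:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
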