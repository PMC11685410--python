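# emgintent

Offline decoding of motor intent from surface electromyography (sEMG), built
around the question that matters for pediatric prosthesis fitting: **which
signal features, which classifier, and how many distinguishable movements?**

The package implements a complete, deterministic evaluation pipeline:

* **`synth`** — a seeded synthetic sEMG generator: band-limited (20–450 Hz)
  Gaussian carriers amplitude-modulated by trapezoidal contraction envelopes,
  following a repeated contract/relax recording protocol with a controllable
  between-movement separability knob (`sep`). `sep=0` produces classes that
  are statistically identical (a true null); large `sep` produces cleanly
  separable classes.
* **`segment`** — 15% cropping of each 3-s contraction, 300 ms sliding
  windows with 150 ms increments (13 windows per contraction), and rest
  windows harvested from the relaxation phases, so every class — including
  rest — contributes the same number of windows.
* **`features`** — a 49-entry feature registry: 31 time-domain, 9
  frequency-domain (FFT periodogram) and 9 time–frequency (level-4 Coiflet-4
  DWT) features, each with a declared amplitude-scale behavior and a stable
  catalog index used for deterministic tie-breaking everywhere.
* **`classify`** — five classifier configurations with their normalization
  contracts: LDA, 1-NN with norm-log scaling, a regulatory feedback network
  (RFN) with class-mean weights and multiplicative-feedback inference, an RBF
  SVM (kernel scale 5.9, one-vs-one) on [-1, 1]-scaled features, and a Gini
  decision tree capped at 100 splits. All are scikit-learn estimators or
  pipelines.
* **`evaluate`** — repeated stratified 60–40 random splits (100 by default);
  the overall accuracy is the *unweighted mean of per-movement accuracies*.
  An optional repetition-grouped split removes the train/test leakage caused
  by 50%-overlapping windows.
* **`select`** — sequential forward/backward wrapper searches arbitrated by a
  Mahalanobis separability-index filter (pseudoinverse covariances), plus
  three built-in named sets: `CFS`, `EFS` and `HDS`.
* **`rankstats`** — Friedman rank test in its improved (Iman–Davenport) F
  form with Nemenyi post-hoc critical distances.
* **`reduce`** — rest-preserving movement reduction: iteratively drop the
  worst-classified movement and re-evaluate, tracking accuracy against an
  85% usability threshold.
* **`cli` / `experiment`** — an `emgintent` command-line tool and a JSON-
  configured multi-stage experiment runner.

## Worked example

```python
import json
from emgintent import (ProtocolSpec, SegmentationConfig, build_windowset,
                       default_separability, generate_recording,
                       extract_matrix, get_spec, NAMED_SETS,
                       ClassifierSpec, CVConfig, cross_validate)

protocol = ProtocolSpec(n_channels=7, fs=2000.0, n_movements=4, n_reps=4)
model = default_separability(n_movements=4, n_channels=7, sep=0.05, seed=42)
recording = generate_recording(protocol, model, seed=42)

windows = build_windowset(recording, SegmentationConfig())
matrix = extract_matrix(windows, [get_spec(f) for f in NAMED_SETS["CFS"]])
print("windows:", matrix.values.shape[0], " columns:", matrix.values.shape[1])

result = cross_validate(matrix, ClassifierSpec("KNN"),
                        CVConfig(n_rand=10, seed=0, group_by_repetition=True))
print(json.dumps(result.to_json(), indent=2))
```

Output (accuracies in percent; classes `0` = rest, `1..4` = movements):

```
windows: 260  columns: 49
{
  "classes": [0, 1, 2, 3, 4],
  "per_movement": [100.0, 100.0, 96.923077, 96.153846, 99.230769],
  "overall": 98.461538,
  "spread": 1.025641,
  "train_time_ms": 2.7,
  "test_time_ms": 3.19,
  "n_rand": 10
}
```

The same pipeline from the shell:

```sh
emgintent synth --channels 7 --movements 4 --reps 4 --fs 2000 \
                --sep 0.05 --seed 42 --out session.csv
emgintent evaluate --session session.csv --feature-set CFS --classifier KNN
emgintent select   --session session.csv --domain time --classifier LDA
emgintent reduce   --session session.csv --feature-set CFS --classifier LDA
emgintent run      --config experiment.json --out results/
```

`--feature-set` accepts a named bundle (`CFS`/`EFS`/`HDS`) or comma-separated
feature ids from the registry (`emgintent` feature ids are short tags like
`tmabs`, `twl`, `fmd`, `tfstd`; see `emgintent.REGISTRY`).

## A note on overlapping windows

Adjacent 300 ms windows share 50% of their samples. Under window-level
random splits, near-duplicate windows land on both sides of the train/test
boundary and inflate accuracy — most dramatically for 1-NN. The conventional
protocol (the default) keeps window-level splits; pass
`CVConfig(group_by_repetition=True)` to split whole repetitions instead,
which removes this leakage and is what the package's own null calibration
uses. See `docs/methods.md` for the quantitative rationale.

## Layout

```
src/emgintent/        library (synth, segment, features/, classify,
                      evaluate, select, rankstats, reduce, experiment, cli)
tests/                pytest suite incl. acceptance properties
scripts/acceptance.py standalone acceptance-target recomputation
docs/methods.md       model, assumptions and numerical choices
```
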