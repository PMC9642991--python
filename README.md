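# edgecode

Tools for analysing how single first-order tactile afferents of the human
fingertip — fast-adapting (FA-1) and slow-adapting (SA-1) type 1 neurons —
signal the orientation of fine raised edges (±5°, ±10° relative to the axis
perpendicular to the scan direction) scanned across their receptive fields at
speeds from 15 to 180 mm/s. It is aimed at researchers in tactile
neurophysiology and neural coding who want to run ideal-observer decoding and
spatial-precision analyses on drum-scanned microneurography data, or to
prototype them on simulated afferents with known ground truth.

## What it computes

Each afferent innervates many mechanoreceptive end organs, giving its
receptive field several sensitive "subfields". As an edge of orientation θ
sweeps across the skin at speed v, the sequence in which the subfields are
stimulated structures the spike train. The package implements:

- **Response measures** — peak firing rate (reciprocal of the shortest
  inter-spike interval), mean firing rate (spike count in the 8 mm response
  window ÷ traversal time), and the instantaneous firing-rate profile, the
  piecewise-constant signal equal to 1/ISI over each inter-spike interval,
  expressed over time or over drum position x (the *spatial domain*, where
  each spike is referenced to the stimulus position on the skin).
- **Ideal-observer decoding** — leave-one-trial-out classification of θ from
  intensities (nearest reference mean) or profiles (highest mean zero-lag
  Pearson correlation), within one speed or across speeds (chance 1/4), with
  an optional population-level linear speed normalization of intensities,
  pairwise decoding by angular difference Δθ ∈ {5, 10, 15, 20}° (chance 1/2),
  and a (θ, v) × (θ′, v′) confusion matrix.
- **Spatial precision ("best kernel")** — every spatial spike train is
  convolved with unit-mass Gaussians of SD σ ∈ [5, 1280] µm; for each σ the
  mean squared Pearson correlation R² between cross-speed trial pairs is
  averaged separately over same-orientation and different-orientation pairs.
  The σ* maximising the difference estimates the spatial precision of the
  action potentials, and converts to an equivalent sinusoidal spatial period
  P = 4.92 σ (least-squares match of a Gaussian to one raised-cosine cycle).
- **A subfield simulator** — generative FA-1/SA-1 models (FA-1 with roughly
  twice the subfields of SA-1) whose frozen subfield burst patterns make the
  spatial response structure speed invariant by construction, with
  controllable trial-to-trial jitter, firing rates that rise and spike counts
  that fall with speed, and full factorial datasets (4 orientations × 8
  speeds × 15 trials) written to a plain-text canonical format.

## Worked example

```
$ python examples/speed_invariance.py
across-speed decoding accuracy (chance 0.25), mean over 6 neurons:
  core speed   spatial  temporal
        15      0.418     0.222
        20      0.413     0.212
        30      0.411     0.215
        45      0.405     0.169
        60      0.395     0.165
        90      0.381     0.174
       120      0.326     0.153
       180      0.200     0.125
```

Each row classifies trials recorded at the core speed against reference
responses from the *other seven* speeds. Temporal-domain profiles hover at or
below chance (0.25): spike trains compress and dilate with speed, so time
courses do not align across conditions. The same spike trains re-expressed
over drum position decode well above chance at all but the fastest speeds —
the signature of a response structured by a subfield layout that is fixed on
the skin. The other scripts in `examples/` walk through simulation and the
canonical data format, within-speed decoding, the kernel-sweep precision
estimate, and pairwise Δθ decoding with per-speed above-chance tests;
`examples/full_pipeline.py` runs everything end to end and writes tidy CSVs,
quick-look figures and a manifest.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, at run time, the equivalent sinusoidal spatial period of the
reported type-level spiking precision: it averages the two published
type-level mean best-kernel SDs (66 and 73 µm), determines the
Gaussian-to-raised-cosine conversion constant by numerical least squares, and
writes the resulting period in millimetres as JSON.

## Layout

- `src/edgecode/data_model.py` — canonical types, plain-text dataset I/O,
  time→position conversion, 8 mm trial segmentation
- `src/edgecode/synthetic.py` — subfield models and the spike simulator
- `src/edgecode/features.py` — peak/mean rates and rate profiles
- `src/edgecode/classify.py` — all ideal-observer decoders
- `src/edgecode/kernel_precision.py` — kernel sweep, best kernel, period
  conversion
- `src/edgecode/report.py` — aggregation, above-chance t-tests, pipeline
- `src/edgecode/experiments.py` — self-contained reference experiments
- `docs/methods.md` — model assumptions, parameter choices, limitations
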