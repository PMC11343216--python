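# tempokit

Analysis toolkit for dual-channel optical voltage recordings: a
voltage-indicator (GEVI) fluorescence channel recorded alongside a
voltage-insensitive reference fluor, in fiber-photometry traces or
widefield movies.

The core algorithm is **frequency-dependent convolutional (Wiener)
unmixing**: a per-frequency complex regression between overlapping,
tapered segments of the two channels estimates the transfer from the
reference to the artifact content of the GEVI channel; the filter
amplitude is clipped relative to its value at the heartbeat fundamental,
inverse-transformed to a two-sided time-domain kernel, and the convolved
artifact estimate is subtracted from the GEVI trace. A
frequency-independent regression baseline is included for comparison.

Around it, the package implements the full downstream stack:

| module | contents |
| --- | --- |
| `tempokit.core_io` | trace/movie/electrode data model, CSV/HDF5/TIFF I/O, sync-based optical–electrical alignment, spatial binning |
| `tempokit.preprocess` | zero-phase notch/band filters, photobleach baselines (low-pass or multi-exponential fits) and dF/F detrending, fiber and movie decrosstalking |
| `tempokit.unmix` | Wiener filter estimation, trace and two-pass movie unmixing, heartbeat location, scalar-regression baseline, train/test parameter selection |
| `tempokit.denoise` | segment-wise rank-k SVD movie denoising with a pluggable per-component image denoiser |
| `tempokit.spectral` | Welch coherence magnitude/phase, analytic-Morlet wavelet spectrograms, band envelopes, event-triggered averages and event-related spectrograms |
| `tempokit.cfc` | trough-referenced carrier phase, phase-amplitude coupling profiles over two cycles, amplitude-peak timing offsets |
| `tempokit.events` | peak finding, sharp-wave-ripple detection (normalized squared signal), ictal spikes, theta-power locomotor-state masks, movie wave-event windows |
| `tempokit.waves` | seed-pixel delay maps + plane-fit flow fields, space-time projection + robust slowness regression, velocity distributions |
| `tempokit.delays` | decomposition of apparent inter-channel delays into nonnegative indicator delays plus one physiological delay (penalized weighted least squares + resampling) |
| `tempokit.synth` | synthetic trace/movie/experiment generators with known ground truth, and the shot-noise SNR design bound |
| `tempokit.cli` / `tempokit.pipeline` | `tempo` command-line interface and TOML-configured pipeline with provenance manifests |

## Quick start

```python
import numpy as np
from tempokit.synth import TraceSynthSpec, HeartbeatSpec, gen_trace_pair
from tempokit.unmix import WienerParams, unmix_trace

spec = TraceSynthSpec(
    duration=60, fs=500, oscillations=((40.0, 0.005),),
    heartbeat=HeartbeatSpec(f0=10.0,
                            gevi_gains=(0.01 * np.exp(1j * np.pi / 3),),
                            ref_gains=(0.02,)),
    noise_gevi=2e-4, noise_ref=2e-4, seed=1)
trace, truth = gen_trace_pair(spec)

res = unmix_trace(trace.gevi - 1.0, trace.reference - 1.0, trace.fs,
                  WienerParams(segment_len=1.0, overlap=0.75, alpha=1.1))
voltage = res.voltage          # artifact-free dF/F
transfer = res.filter.f        # complex transfer estimate per frequency
```

## CLI

```bash
tempo synth trace --seed 1 --out trace.h5
tempo preprocess trace.h5 detrended.csv --notch 300,600 --detrend lowpass:0.5
tempo unmix detrended.csv unmixed.csv --tau 1.0 --overlap 0.75 --alpha 1.1
tempo coherence unmixed.csv coherence.csv --win 1.0 --overlap 0.8
tempo ripples lfp.csv ripples.csv --band 120,200
tempo cfc unmixed.csv profile.csv --carrier 0.5,4 --amp 30,60 --bins 36
tempo waves movie.h5 events.csv --method spacetime
tempo delays fit observations.csv --lambda 0.01 --resamples 100 --seed 1
tempo run --config pipeline.toml --out results/
```

`tempo --help` lists every subcommand; each maps one-to-one onto a module
function.

## Tests

```bash
python -m pytest -q tests/
```

The suite contains per-module unit tests, property tests of the stated
invariants, and `tests/test_acceptance.py` with one test per acceptance
criterion, all driven by the synthetic generators (no data files needed).

One acceptance test is deliberately red:
`TestCriterion7Ripples::test_false_rate_on_pure_noise`. The ripple
detector min-max-rescales the normalized squared signal over the whole
recording, so its global maximum always has prominence ≈ 1 and the
relative prominence criterion necessarily fires on pure noise (in
practice this detector is followed by manual curation, which is out of
scope here). The test asserts the stated false-rate bound faithfully and
documents the failure.

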