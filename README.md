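# spikeloc

Spike source localization on high-density planar probes, with a synthetic
ground-truth recording simulator and an electrode-degradation benchmark.

Three localizers operate on per-channel peak-to-peak (ptp) amplitude
vectors:

- **COM** — center of mass: ptp-weighted average of electrode positions.
  Fast, but confined to the convex hull of the array.
- **MT** — monopolar triangulation: bounded nonlinear least-squares fit of
  a point source with 1/distance voltage decay (position + source
  constant), regularized by a local channel radius and a candidate window
  around the COM initialization.
- **GC** — grid convolution: scores a dense 5 µm lattice of candidate
  source positions against the amplitude vector with a Gaussian distance
  kernel and averages the top-scoring nodes.

The simulator renders point-source neurons with known positions and
Poisson spike trains onto a Neuropixels-like 384-channel (or arbitrary)
planar probe at 30 kHz, with per-spike amplitude modulation and 10 µV
Gaussian noise. Electrode degradation replaces a growing, nested fraction
of channels with 50 µV Gaussian noise. The benchmark runs
simulate → degrade → preprocess (300–3,000 Hz causal Butterworth + common
median reference + anomalous-channel detection) → waveform extraction →
localization, and reports accuracy within a radius, median localization
error, and template drift relative to the undegraded estimates.

## Library quick start

```python
import spikeloc as sl

probe = sl.make_probe(96)
units = sl.sample_ground_truth(probe, 10, duration_s=30.0, seed=0)
rec = sl.render_recording(units, probe, duration_s=30.0, seed=0)
degraded, plan = sl.degrade(rec, fraction=0.5, seed=0)

from spikeloc.benchmark import extract_features, run_degradation_sweep
from spikeloc.config import desk_preset

cfg = desk_preset()
feats = extract_features(degraded, units, cfg, degraded.dead_mask.copy())
table = sl.localize_many(feats.template_ptp, probe, "mt")   # or "com", "gc"

results = run_degradation_sweep(desk_preset())               # tidy DataFrame
```

## CLI

`spikeloc` exposes the pipeline stages as subcommands; all take
`--config` (YAML/JSON, sections `simulate` / `preprocess` / `localize` /
`benchmark`), `--seed`, and `--out`:

```sh
spikeloc simulate --seed 0 --out runs/sim        # recording.bin + geometry.csv + ground_truth.json
spikeloc degrade runs/sim/recording.bin --fraction 0.5 --seed 0 --out runs/deg
spikeloc preprocess runs/deg/recording.bin --out runs/pre   # + channel_status.csv
spikeloc extract runs/sim/recording.bin --ground-truth runs/sim/ground_truth.json --out runs/wf
spikeloc localize runs/sim/recording.bin --ground-truth runs/sim/ground_truth.json \
    --algorithm mt --out runs/loc
spikeloc sweep --out runs/sweep                  # degradation sweep -> sweep.csv + summary.json
spikeloc gridsearch --out runs/grid              # MT/GC parameter grid -> gridsearch.csv
```

Exit codes: 0 success, 2 config error (offending key named), 1 runtime
failure. Recordings are flat binary float32 (channel-major) with a JSON
sidecar; geometry is CSV (`channel_id,x,y,z`, µm) or an equivalent JSON
dialect; ground truth is JSON; estimates and metrics are CSV. Units are
fixed: µm, µV, seconds, Hz.

The default config is the full-scale setup (384 channels, 50 neurons,
90 s, 25 degradation levels 0–94 %, five seeds); `--preset desk` (the CLI
default) is the scaled version used by the tests.

## Notes

- Ground-truth spike trains are required inputs throughout — there is no
  spike detection or sorting, by design.
- Dead/anomalous channels can be excluded from localization
  (`preprocess.channel_exclusion: plan|detected|union`); the benchmark
  default (`none`) keeps them in the analysis, which is what makes the
  degradation comparison interesting.
- GC's node score is a unit-amplitude matched filter
  (`⟨ptp, a⟩ − ½‖a‖²`), which for µV-scale inputs is the plain dot product
  up to a negligible node offset but keeps the scoring identifiable in the
  axis orthogonal to the probe plane.
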