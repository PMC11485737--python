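# castream

A headless, real-time analysis engine for two-photon calcium imaging, built
for closed-loop all-optical experiments: it taps the raw image stream a
microscope writes to disk, turns it into per-neuron activity within a frame
time, and layers slower analyses on top — functional networks to pick
stimulation targets, synchrony tests, auditory tuning — down to computing
the spatial-light-modulator (SLM) phase masks that would photostimulate the
chosen cells. Everything a GUI would display is instead appended to a JSONL
event log, so the whole loop is scriptable and testable end to end against
synthetic movies with known ground truth.

## Who it is for

Systems neuroscientists running (or prototyping) experiments in which
analysis must keep up with acquisition: selecting photostimulation targets
from live functional connectivity, monitoring tuning as trials accumulate,
or validating a closed-loop design offline before an animal is ever on the
microscope. No hardware is required: raw-binary/TIF replay and a virtual
SLM make the full loop runnable on a laptop.

## The processing model

Per acquired frame (default 30 Hz):

1. **Registration** — x–y drift against a fixed template (mean of an
   initial batch) by single-step upsampled DFT cross-correlation, then
   correction by Fourier phase shift.
2. **Extraction** — each neuron has a ring-shaped soma ROI and a neuropil
   annulus (1 px beyond the ring out to 15 µm), overlap pixels excluded;
   `F_soma` and `F_NP` are the mask means.
3. **Neuropil correction** — `F = F_soma − α·F_NP`, α = 0.7 by default.
4. **Baseline and ΔF/F₀** — `F₀` is the mean of samples strictly below the
   50th percentile of the trailing 10 s window; `ΔF/F₀ = (F − F₀)/F₀`.

On slower cadences (all in stream time, so replay ≡ live):

- **1 Hz — functional network.** Pearson correlations ρ of the ΔF/F₀
  traces; either a minimum spanning tree on weights `w = 1 − |ρ|` (always
  N−1 edges, every cell kept) or a threshold graph `|ρ| ≥ θ`. Cells are
  ranked by degree; the top 5 are the automatic stimulation candidates.
- **30 s — synchrony.** Traces are deconvolved to spikes (sparse
  non-negative AR(1)), and the count of time bins with ≥ k coincident
  spikes (k = 2–4) is tested against circular-shift surrogates: enhanced
  (red) above the 97.5th surrogate percentile, suppressed (blue) below the
  2.5th.
- **Per completed trial — tuning.** With a tone schedule (typically eight
  half-octave frequencies × three sound levels × 10 repeats), receptive
  fields are running trial means of ΔF/F₀ during each presentation; the
  best frequency (BF) is the argmax over the grid.
- **On trigger — holography.** Target cells become disk or optical-vortex
  beamlets in the focal plane; the Gerchberg–Saxton algorithm retrieves a
  phase-only SLM mask whose far-field reproduces them, and the simulated
  intensity pattern and stimulation events (e.g. 30 ms pulses every 3 s)
  are logged.

The `synthetic` module generates the whole study from a config and a seed:
ring somata over a diffuse neuropil field, Poisson background spiking, a
correlated ensemble driven by latent population events, tone-locked tuned
responses, drift, and noise — with the ground truth (spike times, BFs,
drift, ensemble membership) serialized next to the movie.

## A worked example

```bash
cd examples
python 01_synthesize_session.py
python 02_run_pipeline.py
```

prints (15 cells, 60 s, cells 0–4 share a latent drive):

```
event counts: {'shift': 1800, 'traces': 120, 'network': 60, 'ranking': 60, 'synchrony': 2}
final ranking (top 5): [0, 2, 4, 1, 3]
```

1800 shift records = one registration per frame; 60 network records = one
update per second of stream time; 2 synchrony reports = one per 30 s. The
top-5 ranking is exactly the latent ensemble: every other cell's strongest
correlation points into the ensemble, so the spanning tree concentrates
degree there — these are the cells an experimenter would be offered as
stimulation targets. The other examples demo registration accuracy
(`03`), network construction (`04`), BF recovery from a full tone session
(`05`), hologram computation (`06`), and the synchrony readout (`07`).

The same loop is available as a CLI for shell use:

```bash
castream synth --config synth.yaml --seed 1 --out session/
castream run --config pipeline.yaml --replay
castream holo --targets targets.csv --shape vortex --L 5 --out mask.png
castream stim --cells 3,17,42 --control-dir run_out/control
```

## Layout

- `src/castream/` — `stream_io`, `registration`, `rois`, `traces`,
  `network`, `synchrony`, `tuning`, `holography`, `synthetic`, `pipeline`,
  `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameters, numerical choices, limitations
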