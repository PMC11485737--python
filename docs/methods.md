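# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not establish.

## Frame streams

Raw binary is headerless, frame-major, row-major, little-endian 16-bit —
the common denominator of the resonant-scanning acquisition packages that
append frames to a growing file. Two dialects: unsigned 16-bit, and signed
16-bit that must be mapped to the unsigned range. The signed→unsigned map
clamps negatives to zero: PMT samples below the offset carry no signal, and
clamping is the simplest monotone map (an offset-add variant would shift
every downstream baseline without changing ΔF/F₀ materially; the clamp is
the default and the conversion function is the single place to change it).

Live mode polls the file and yields frame *k* only once the file holds at
least (k+1)·H·W·2 bytes, so a partially written frame is never analyzed.
Geometry and frame rate come from the config, not from vendor metadata —
XML sidecar dialects are deliberately out of scope. A headless session
needs an end condition the acquisition software would normally provide:
an expected frame count (`n_frames`) and an idle timeout (default 5 s
without file growth) both stop the stream cleanly.

## Registration

Drift is estimated per frame against a *fixed* template — the pixelwise
mean of the initial batch (default 30 frames) — using single-step DFT
cross-correlation with matrix-multiply upsampling (`upsample` default 10,
i.e. 0.1 px precision). The template is never refreshed: a running
template would couple registration into activity and slowly absorb drift.
Estimates beyond `max_shift` (default 20 px) are clamped and flagged
rather than applied — a wild mis-registration must not corrupt traces.
Flat frames register as (0, 0) with a degenerate flag.

Correction translates by the negated drift via a Fourier phase ramp;
pixels that enter from outside the field of view are filled with the frame
median, which is neutral for percentile-based baselines. Two subtleties:

- The pure spectral translation operator (exposed as `translate`,
  `fill=None`) zeroes the Nyquist rows/columns, whose phase is ambiguous
  under fractional shifts; this makes it exactly compositional
  (0.5 px twice ≡ 1 px once to machine precision) and is what fixtures
  use to synthesize known drifts (periodic continuation, the standard
  convention for registration accuracy tests).
- The correction path (`apply_shift`) adds the median border fill, a
  non-linear edit whose ringing limits composition to ~1 % in the central
  region. That is a property of any boundary policy, not of the
  interpolation; tests assert both behaviors separately.

## ROIs

Somatic signal concentrates in a ring around the nucleus, so each cell's
soma mask is an annulus `r_inner ≤ d ≤ r_outer` of Euclidean
center-to-pixel-center distances (defaults 2 px and 6 px — a soma shell at
the default scale of 0.7227 µm/px, i.e. a ~370 µm field of view over
512 px; all of it configurable). Pixels claimed by two rings are removed
from both (cells emptied this way are flagged inactive). The neuropil
annulus runs from `r_outer + 1` px to `r_outer + 15 µm/pixel_size`,
excluding every cell's soma pixels — including the cell's own by
construction. "One pixel beyond" is implemented radially (+1 px on the
radius), not morphologically, to stay consistent with the purely radial
mask construction.

## Traces

`F = F_soma − α·F_NP` with α = 0.7 (adjustable; 0 disables correction).
The baseline window operates on the corrected series F — the baseline must
describe the same signal as the numerator — and spans the trailing 10 s
*including* the current sample; before 10 s of history exists, all
available samples are used, and the very first frame takes F₀ := F so the
loop can start immediately. F₀ is the mean of window samples strictly
below the window's 50th percentile (linear-interpolation percentile); a
constant window has no such samples and falls back to the window median.
Missing samples (failed registration, emptied masks) are excluded from
windows, and a non-positive F₀ marks the cell low-signal for that frame
rather than producing an infinite ΔF/F₀.

## Functional networks

Correlation is plain Pearson over the analysis window (cumulative by
default; a sliding window of any length is a config option), computed only
over frames where every cell has a defined ΔF/F₀ so all pairs share one
sample set; at least 30 usable frames are required before a matrix is
released. Zero-variance traces have undefined correlations.

The MST is built by Kruskal on `w = 1 − |ρ|` with edges pre-sorted by
(weight, min id, max id) — fully deterministic under ties. Undefined
correlations enter at weight 1, so flat cells attach last but are never
dropped. The threshold variant keeps `|ρ| ≥ θ` (absolute value, matching
the MST's use of |ρ|; a signed mode exists but is off by default) and
retains isolated nodes at degree 0. Ranking sorts by (degree ↓, id ↑);
the top 5 are the automatic display/stimulation candidates.

Ranking stability between successive updates is reported as top-k set
turnover (percentage of the top-10 replaced, averaged over adjacent
updates); positional change is a stricter alternative the JSON consumer
can derive from the logged rankings.

## Synchrony

ΔF/F₀ is deconvolved with a sparse non-negative AR(1) model solved by the
pool-adjacent-violators (OASIS-style) algorithm written here: minimize
`½‖c − y‖²` subject to `s_t = c_t − γ·c_{t−1} ≥ 0`, with an L1 weight set
to the trace's MAD-based noise sd. γ corresponds to a 1.5 s indicator
decay at the stream frame rate (`γ = exp(−1/(f·τ))`). Bins with
deconvolved increments above 3× the noise sd count as spikes; bin width is
one frame by default with optional rebinning.

The synchrony statistic is deliberately simple: the number of bins in
which ≥ k cells spike (k = 2, 3, 4), tested two-sided against a null of
200 independent circular shifts of each cell's train (shifts preserve
every single-cell statistic and destroy only cross-cell alignment).
Enhanced above the (1 − α/2) surrogate quantile, suppressed below α/2,
α = 0.05. **This surrogate-coincidence test is a stand-in** for richer
ensemble models (e.g. Markov point-process filtering of higher-order
correlations); it keeps the same report semantics — a verdict per order
every 30 s — and lives behind a single interface (`synchrony_test` /
`synchrony_report`) so a different statistic can be dropped in. Quantile
tests on discrete counts are conservative; the calibration test checks the
enhanced rate under a Poisson null against the binomial CI of α/2.

## Tuning

The tone grid is `f_k = f_start·2^(k/2)` (half-octave ladder; the standard
8-step grid from 4 kHz ends at 45.3 kHz) crossed with sound levels
(defaults 50/60/70 dB), 1 s tones, 3 s intertrial gaps, 10 repeats. A
trial's response is the mean ΔF/F₀ over the presentation window only — no
pre-stimulus subtraction by default (available as config), matching the
plain trial-average definition of the receptive field. Receptive fields
update as running means the moment a trial's window is fully acquired, and
equal batch recomputation exactly. BF is the frequency of the maximal
entry at any level; ties break toward the lower frequency. Displayed
frequencies round to 0.1 kHz; internal values are exact.

## Holography

The SLM sits in a Fourier plane of the objective, so mask computation uses
the single-lens far-field model: focal field = centered unitary 2-D DFT of
the SLM field. The relay optics of a real system reduce to this for mask
computation; wavelength-scale calibration is absorbed by an affine FOV→SLM
map (identity by default, fit by least squares from ≥ 3 correspondence
pairs). The virtual SLM grid is 512×512 for desk-scale work; a
hardware-scale 1536×1536 grid is a config away.

Targets superpose beamlet templates: a uniform disk of configurable
radius, or an optical-vortex ring of radius `r₀·√|L|` (r₀ = 3 px) carrying
spiral phase `exp(iLθ)` — the radius–mode relation is a documented
heuristic (vortex ring radius grows with the square root of topological
charge); the central phase singularity guarantees an on-axis null.
Gerchberg–Saxton alternates amplitude constraints between the planes,
initialized by the random-superposition scheme (seeded random diffuser
phase on the target support, back-propagated): a fully random SLM phase
leaves speckle lobes beside point targets that the projections cannot
remove, while the superposition start concentrates energy on the targets
from iteration one. 30 iterations by default; the focal-amplitude error is
non-increasing (error-reduction property) and determinism is exact for a
given (targets, seed).

Sequential stimulation precomputes one mask per target; dwell time is the
reciprocal of the user rate. Stimulation "events" in this headless build
are log records (cells, beamlet shape and parameters, pulse duration and
period — e.g. 30 ms every 3 s — and mask file references); laser-power
figures are metadata only and never enter any computation.

## The real-time loop

All cadences are measured in stream time (frame index / frame rate), never
wall clock, so a replayed session and a live session over the same bytes
produce identical event logs — this is also what makes the loop testable.
Stage failures are isolated: a failed network update logs a warning event
and the per-frame path continues. Stimulation triggers: manual (a control
file dropped by the CLI), automatic top-5, or a watch-group rule (mean
ΔF/F₀ of named cells above a threshold) with a 3 s refractory period.
On the 60-cell, 256×256 demo the loop processes 120 s of 30 Hz data in
well under real time on one CPU core.

## The synthetic generator

What it emulates, per (config, seed), fully deterministically:

- **Geometry** — cells placed by rejection sampling with a minimum spacing
  (default 22 px) inside a margin; ring somata rendered with the same
  radii the extraction defaults assume; a smooth neuropil field (sum of
  broad Gaussian aprons) under everything.
- **Activity** — independent Poisson background spiking
  (0.12 Hz/cell) plus latent population events (1.2 Hz) that recruit the
  designated ensemble with probability 0.8 (`group_coupling`) and every
  other cell with probability 0.25 (`global_coupling`). The weak global
  term is what makes the ensemble "most correlated with the rest of the
  population" — the property degree ranking measures; with it at zero the
  rest of the population carries no information about the ensemble and
  ranking recovery is ill-posed at any SNR. Spikes convolve with a
  difference-of-exponentials kernel (rise 50 ms, decay 1.5 s, unit peak).
- **Imaging** — soma brightness `gain·(0.5 + trace)` over a baseline-lit
  neuropil field modulated by a diluted mixture of all traces (dilution
  0.3 — strong enough that α = 0.7 correction visibly improves
  correlation-group recovery), optional drift (applied as a median-filled
  translation), Gaussian noise (sd 2 % of baseline), clipped to uint16.
- **Tuning** — tuned cells get a grid BF and tone-locked response
  probability with Gaussian falloff in log₂ frequency (width 0.5 octaves)
  scaled by level (0.6→1.0 across the level grid), with 0–2 frames of
  onset jitter. The 0.5-octave width reflects narrowly tuned primary
  auditory cortex neurons and makes exact-BF recovery identifiable at
  half-octave grid spacing over 10 repeats; at 1 octave, neighboring
  steps differ by well under the trial-to-trial noise.

Rates were chosen by analyzing identifiability under the session length
the demo uses: with a 1.5 s kernel, 120 s of trace yields only ~80
effective samples, so correlations between *independent* cells fluctuate
with ~0.3 tails across thousands of pairs; the population-event structure
is set to sit above that floor. These are the frozen study conditions for
all recovery experiments.

What it does **not** emulate: photon shot statistics, scattering/PSF
blur, bleaching, z-motion, or the morphological diversity of real
neuropil. Passing recovery tests therefore shows the pipeline's inference
chain is correct under its own model assumptions — not that the defaults
are optimal for any particular indicator or prep.

## Problem sizes used in the test suite

The canonical demo session is 60 cells, 256×256 px, 30 Hz, 120 s — chosen
to run end to end in about a minute per pipeline pass on one core while
keeping ≥ 1500 correlation pairs and four synchrony windows. Ensemble
recovery runs once on the rendered demo; BF recovery runs 50 trace-level
sessions through the full 8×3×10 tone design (no rendering, since the
receptive-field path consumes ΔF/F₀, not pixels); MST optimality is
checked against exhaustive spanning-tree enumeration for N ≤ 7 over 200
random matrices; synchrony calibration uses 100 null simulations × 200
surrogates; holography checks run at the full 512×512 default grid.

## Known limitations

- Rigid translation only; no non-rigid or z-drift handling.
- The fixed template can go stale over hours-long sessions.
- The synchrony statistic is the documented stand-in described above.
- The vortex ring-radius heuristic is not calibrated to any specific
  optical train.
- Live mode assumes sequential appends to one file; multi-file-per-frame
  acquisition dialects and socket interfaces are not supported.
- ROI geometry is circularly symmetric; no activity-based refinement or
  automatic segmentation (external center files are the interface).
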