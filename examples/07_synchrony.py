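"""Higher-order synchrony testing against circular-shift surrogates.

Builds a 20-cell spike raster, injects ten 4-cell coincidences, and runs
the surrogate test for orders k = 2..4.
"""

import numpy as np

from castream import synchrony

rng = np.random.default_rng(0)
T, n = 900, 20
spikes = (rng.random((T, n)) < 0.02).astype(np.int8)
for t in rng.choice(T, 10, replace=False):
    spikes[t, :4] = 1  # cells 0-3 fire together

sm = synchrony.SpikeMatrix(spikes, list(range(n)), bin_s=1 / 30)
report = synchrony.synchrony_report(sm, time_s=30.0, window=(0, T), seed=1)
for k, r in sorted(report.orders.items()):
    print(f"k={k}: observed {r.observed:3d} bins, surrogate {r.surrogate_mean:6.1f}"
          f" +- {r.surrogate_sd:4.1f}, z={r.z:+5.1f} -> {r.verdict}")
# The injected coincidences push the observed k=3 and k=4 counts far above
# anything circular shifting can produce (shifting preserves each cell's
# spike count but destroys cross-cell alignment), so those orders are
# flagged "enhanced" — the red readout of the live display.
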