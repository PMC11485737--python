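"""Generate a ground-truth imaging session and inspect what is in it.

Writes a small raw-binary movie with ring-shaped somata, a diffuse
neuropil background and a correlated 5-cell ensemble, plus the centers
CSV and ground-truth JSON the rest of the examples consume.
"""

from pathlib import Path

from castream import synthetic

out = Path("example_output/session")
cfg = synthetic.SyntheticConfig(
    height=128, width=128, n_cells=15, duration_s=60.0,
    min_center_spacing_px=18.0,
)
paths = synthetic.write_fixture_bundle(cfg, seed=42, out_dir=out)

gt = synthetic.generate_ground_truth(cfg, seed=42)
print(f"wrote {cfg.n_frames} frames of {cfg.height}x{cfg.width} to {paths['movie']}")
print(f"{cfg.n_cells} cells; ensemble cells {list(cfg.group_cells)} share a latent drive")
print(f"total ground-truth spikes: {int(gt.spikes.sum())} "
      f"({gt.spikes.sum() / cfg.n_cells / cfg.duration_s:.2f} Hz/cell)")
# The ensemble cells spike together on ~1 Hz latent events, so their
# calcium traces will be strongly correlated; everyone else only joins
# occasionally. That structure is what the network example recovers.
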