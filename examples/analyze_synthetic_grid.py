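"""Generate a small noisy recording grid and analyze it back.

Builds synthetic whole-cell recordings (per-cell scale variation, 1 kHz
Bessel filtering, 5 kHz sampling, additive noise) for two buffers and two
variants, then measures the extent of inactivation per cell — the loop a
real dataset would go through.
"""

import numpy as np

from cracdi import (
    BufferSpec,
    ConditionGrid,
    NoiseModel,
    builtin_protocol,
    extent_of_inactivation,
    generate_experiment,
)

grid = ConditionGrid(
    buffers=(BufferSpec.egta(10), BufferSpec.bapta(8)),
    ca_o=(20.0,),
    variants=("wt_like", "sensitized"),
    protocols=("cdi_family",),
    n_cells=4,
    base_seed=2024,
)
traces, manifest = generate_experiment(grid, NoiseModel())
print(f"generated {len(traces)} traces "
      f"({grid.n_cells} cells x {len(grid.buffers)} buffers x "
      f"{len(grid.variants)} variants)")

protocol = builtin_protocol("cdi_family")
step_windows = {
    seg.v_start: (t0, t1) for t0, t1, seg in protocol.segment_windows()
}
window = step_windows[-0.100]

print("\nextent of inactivation at -100 mV (mean +/- sd over cells):")
for variant in grid.variants:
    for buffer in grid.buffers:
        extents = [
            extent_of_inactivation(tr, window).extent
            for tr, (_, row) in zip(traces, manifest.iterrows())
            if row["variant"] == variant and row["buffer"] == buffer.label
        ]
        print(f"  {variant:<12} {buffer.label:<12} "
              f"{np.mean(extents):.3f} +/- {np.std(extents):.3f}")

print("\nThe buffer ordering flips between the variants even through the "
      "noisy recording chain.")
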