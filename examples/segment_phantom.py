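"""Segment all four retinal surfaces on a clean synthetic B-scan.

Builds a noiseless phantom with known boundary curves, runs the automatic
edge pipeline plus shortest-path tracing for ILM, ISe, RPE and BM, and
prints the RMSE of each traced boundary against the generator's truth.
Sub-pixel RMSE with zero grader intervention is the expected behaviour on
clean, lesion-free scans.
"""

import numpy as np

from octseg import LAYERS, default_profiles, segment_layer
from octseg.phantom import generate_bscan, random_phantom_spec

spec = random_phantom_spec(seed=3, speckle_variance=0.0)
image, truth = generate_bscan(spec)
profiles = default_profiles()

print(f"phantom: {image.shape[0]} rows x {image.shape[1]} cols, noiseless")
print(f"{'layer':>6} {'RMSE px':>9} {'RMSE um':>9} {'path cost':>10}")
for layer in LAYERS:
    result = segment_layer(image, profiles[layer])
    pos = result.boundary.positions
    ok = np.isfinite(pos)
    rmse = np.sqrt(np.mean((pos[ok] - spec.truth[layer][ok]) ** 2))
    print(
        f"{layer:>6} {rmse:9.3f} {rmse * spec.axial_spacing_um:9.3f} "
        f"{result.total_cost:10.2f}"
    )
print(
    "\nRMSE is the root-mean-square distance (pixels / micrometres) between "
    "the traced boundary\nand the true layer position; values well under one "
    "pixel mean the automatic trace needs no manual picks here."
)
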