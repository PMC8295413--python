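"""Measure cortical thickness from a three-class label volume.

Surfaces are extracted slice by slice with a Canny detector on the binary
outer-bone and marrow masks; the thickness at each outer-surface point is the
distance to its nearest marrow-surface point.  On a shell of known thickness
the mapped values recover the analytic answer to within about 0.1 mm at
0.3 mm voxels.
"""

import numpy as np

import condyseg as cs
from condyseg.thickness import (
    ThicknessReport,
    extract_surfaces,
    measure_thickness,
    thickness_distribution,
)

spec = cs.PhantomSpec(
    grid_shape=(64, 64, 64),
    core_radii_vox=(10.0, 12.0, 12.0),
    shell_thickness_fn=cs.HemisphericThickness(t_top_mm=1.2, t_bottom_mm=2.4),
    noise_sd=0.0,
    distractor_count=0,
)
_, labels = cs.generate_condyle_phantom(spec, seed=0)

outer, inner = extract_surfaces(labels)
print(f"outer surface: {len(outer)} points, marrow surface: {len(inner)} points")

tm = measure_thickness(outer, inner)
print(ThicknessReport.from_map(tm))
print(f"expected range: 1.2 mm (top pole) .. 2.4 mm (bottom pole)")

curve = thickness_distribution(tm, bin_width_mm=0.1)
peak = curve.bin_centers_mm[np.argmax(curve.density)]
print(f"distribution peak at {peak:.2f} mm over {len(curve.density)} bins")
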