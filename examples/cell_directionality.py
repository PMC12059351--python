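"""F-actin directionality of cells protruding towards the ECM bridge.

Generates treated (rod orientations concentrated along the bridge axis)
and control (uniform) scenes, extracts one orientation per protruding
cell, fits a Gaussian to the orientation histogram, and reports the
proportion of cells aligned with the bridge fiber angle within +-10 deg.
"""

import numpy as np

import ecmbridge as eb

cfg = eb.SceneConfig(image_shape=(3, 160, 480), pixel_size_xy=2.5,
                     fiber_density=0.3, seed=9)

for label, treated in (("TGFB-treated", True), ("control", False)):
    scene = eb.generate_bridge_scene(cfg, treated=treated, factin_kappa=8.0,
                                     cells_per_section=18,
                                     roi_size_um=(300.0, 80.0),
                                     render_viability=False)
    # reference angle: dominant fiber orientation measured in the bridge
    roi = scene.truth.roi_suggestion
    patch = roi.extract(scene.reflection.section(1))
    field = eb.orientation_field(patch, 3.0, cfg.pixel_size_xy)
    ref = eb.alignment.dominant_angle(field)

    per_z = [eb.cell_orientations(scene.factin.section(z),
                                  scene.truth.cluster_mask,
                                  cfg.pixel_size_xy)
             for z in range(scene.factin.n_sections)]
    fit = eb.fit_gaussian(eb.orientation_histogram(
        np.concatenate([np.asarray(a) for a in per_z]), bin_width_deg=6.0))
    prop = eb.aligned_proportion(per_z, ref, tolerance=10.0)
    print(f"{label}: bridge fiber angle {ref:.1f} deg; Gaussian fit mean "
          f"{fit.mean:.1f} deg (goodness {fit.goodness:.2f}); "
          f"aligned proportion {prop.mean:.2f}")

print("\nTreated cells co-orient with the bridge: high aligned proportion "
      "and a sharp,\nwell-fitting orientation peak. Control orientations "
      "are broad and the aligned\nproportion drops towards the uniform "
      "expectation (20/180 = 0.11).")
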