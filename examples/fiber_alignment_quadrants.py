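"""Collagen alignment index via the four-corner quadrant protocol.

Generates fiber-field phantoms at three angular concentrations (kappa of
the axial von Mises law; 0 = isotropic) and runs the quadrant analysis:
corner ROIs in every Z-section, alignment index and aligned-fiber
intensity averaged per section and across the stack.
"""

import ecmbridge as eb

for kappa in (0.0, 5.0, 50.0):
    cfg = eb.SceneConfig(image_shape=(3, 300, 300), pixel_size_xy=2.5,
                         fiber_density=80.0, kappa=kappa,
                         bridge_axis_angle=68.8, seed=8)
    stack, truth = eb.generate_fiber_volume(cfg)
    res = eb.quadrant_analysis(stack, roi_px=120)
    print(f"kappa={kappa:>4g}: alignment index {res.alignment_index:.3f}, "
          f"dominant angle {res.dominant_angle:6.1f} deg, "
          f"aligned intensity {res.aligned_intensity:.1f}")

print("\nThe index (weighted mean resultant length of doubled angles) "
      "rises from ~0 (isotropic)\ntowards 1 as fibers concentrate around "
      "the planted 68.8 deg axis.")
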