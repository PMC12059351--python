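"""Hoechst/PI cytotoxicity scoring of a fibroblast cluster.

Generates a 200-um cluster of 500 nuclei imaged at 10-um Z-intervals with
a planted dead fraction, segments nuclei per section, classifies each as
PI-positive or -negative and averages the per-section proportions —
then compares against the planted truth.
"""

import ecmbridge as eb

for dead in (0.1, 0.4):
    cfg = eb.SceneConfig(image_shape=(21, 144, 144), pixel_size_xy=1.5,
                         z_step=10.0, cells_per_cluster=500,
                         dead_fraction=dead, seed=3)
    hoechst, pi, truth = eb.generate_cluster_nuclei(cfg)
    profile = eb.viability_profile(hoechst, pi)
    print(f"planted dead fraction {dead:.2f}: "
          f"{profile.n_nuclei.sum()} nuclei segmented over "
          f"{len(profile.n_nuclei)} sections, "
          f"measured PI-positive proportion {profile.cluster_proportion:.3f} "
          f"(truth {truth.dead_fraction:.3f})")

print("\nThe measured proportion tracks the planted dead fraction; the "
      "truth column is the\nexact planted value from the scene's "
      "ground-truth flags.")
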