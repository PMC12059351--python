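"""Simulated anti-fibrotic compound screen with efficacy-window calls.

Simulates a one-compound screen (6 concentrations, 1:3 dilutions, 2
replicates, shared CTR/TGFB controls), quantifies every well with the
imaging pipeline (reflection ROI density + PI-positive proportion),
normalizes to percent remodeling inhibition, classifies each dose, and
writes heatmap-ready CSV outputs.
"""

import tempfile

import ecmbridge as eb

design = eb.ScreenDesign(compounds=[eb.rocki_like()], n_replicates=2)
dataset = eb.generate_screen_dataset(design, seed=5)
table = eb.build_screen_table([eb.quantify_well(w) for w in dataset.wells])

ctr = table.control_mean("CTR")
tgfb = table.control_mean("TGFB")
print(f"controls: CTR {ctr:.1f}, TGFB {tgfb:.1f} (density units)\n")
print("conc  inhibition%  toxicity")
agg = table.aggregates
for _, row in agg[agg["conc_index"] > 0].iterrows():
    inh = eb.remodeling_inhibition(row["remodeling_mean"], ctr, tgfb)
    print(f"   {int(row['conc_index'])}      {inh:6.1f}     "
          f"{row['toxicity_mean']:.2f}")

window = eb.efficacy_window(table)["ROCKi-like"]
print(f"\nwindow calls: effective+nontoxic {sorted(window.effective_nontoxic)}, "
      f"effective but toxic {sorted(window.effective_toxic)}, "
      f"ineffective {sorted(window.ineffective)}")
oracle = eb.analytic_windows(design)["ROCKi-like"]
print(f"planted truth: effective+nontoxic {sorted(oracle['effective_nontoxic'])}")

with tempfile.TemporaryDirectory() as tmp:
    paths = eb.exports.write_screen_outputs(table, eb.efficacy_window(table),
                                            tmp)
    print(f"\nwrote {', '.join(p.name for p in paths.values())}")

print("\nThe compound suppresses remodeling at doses 1-4 but is cytotoxic "
      "at 1-3,\nleaving dose 4 as the usable efficacy window.")
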