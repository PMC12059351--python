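"""Tabular and on-disk outputs: CSV result tables, TIFF scenes, truth JSON.

Every analysis result can be serialized to a tidy table so downstream
statistics (ANOVA etc.) happen in external tools; the pipeline itself
stops at tables. Scene export writes one multi-page TIFF per channel plus
a JSON ground-truth sidecar, which is also the interchange format for
re-analyzing synthetic scenes from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentResult
from .directionality import AlignmentProportion
from .imaging import DensityResult, write_stack
from .scene import BridgeScene
from .screening import ScreenTable, EfficacyWindow, export_heatmap
from .viability import ClusterViabilityProfile

__all__ = [
    "density_table",
    "alignment_table",
    "viability_table",
    "proportion_table",
    "write_screen_outputs",
    "write_bridge_scene",
]


def density_table(result: DensityResult, stack_id: str) -> pd.DataFrame:
    """Per-section densities plus a summary row (z = -1 carries the mean)."""
    rows = [{"stack_id": stack_id, "z_index": z, "density": d}
            for z, d in enumerate(result.per_z)]
    rows.append({"stack_id": stack_id, "z_index": -1, "density": result.mean})
    return pd.DataFrame(rows)


def alignment_table(result: AlignmentResult, stack_id: str) -> pd.DataFrame:
    """Per (z, corner) alignment values plus per-z and stack summaries."""
    rows = []
    nz, nroi = result.per_roi_index.shape
    for z in range(nz):
        for k in range(nroi):
            rows.append({"stack_id": stack_id, "z": z, "roi_corner": k,
                         "alignment_index": result.per_roi_index[z, k],
                         "aligned_intensity": result.per_roi_intensity[z, k]})
        rows.append({"stack_id": stack_id, "z": z, "roi_corner": -1,
                     "alignment_index": result.per_z_index[z],
                     "aligned_intensity": result.per_z_intensity[z]})
    rows.append({"stack_id": stack_id, "z": -1, "roi_corner": -1,
                 "alignment_index": result.alignment_index,
                 "aligned_intensity": result.aligned_intensity})
    return pd.DataFrame(rows)


def viability_table(profile: ClusterViabilityProfile,
                    stack_id: str) -> pd.DataFrame:
    rows = [{"stack_id": stack_id, "z": z,
             "n_nuclei": int(profile.n_nuclei[z]),
             "n_pi_positive": int(profile.n_pi_positive[z]),
             "proportion": profile.proportion[z],
             "excluded": z in profile.empty_sections}
            for z in range(len(profile.n_nuclei))]
    rows.append({"stack_id": stack_id, "z": -1,
                 "n_nuclei": int(profile.n_nuclei.sum()),
                 "n_pi_positive": int(profile.n_pi_positive.sum()),
                 "proportion": profile.cluster_proportion,
                 "excluded": False})
    return pd.DataFrame(rows)


def proportion_table(prop: AlignmentProportion, scene_id: str) -> pd.DataFrame:
    rows = [{"scene_id": scene_id, "z": z, "proportion": p,
             "excluded": z in prop.empty_sections}
            for z, p in enumerate(prop.per_z)]
    rows.append({"scene_id": scene_id, "z": -1, "proportion": prop.mean,
                 "excluded": False})
    return pd.DataFrame(rows)


def write_screen_outputs(table: ScreenTable,
                         windows: dict[str, EfficacyWindow],
                         out_dir) -> dict[str, Path]:
    """Write screen_table.csv, windows.csv and heatmap_long.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["screen_table"] = out / "screen_table.csv"
    table.records.merge(table.aggregates, on=["compound", "conc_index"]) \
        .to_csv(paths["screen_table"], index=False)
    win_rows = []
    for name, w in sorted(windows.items()):
        for ci in sorted(w.effective_nontoxic | w.effective_toxic
                         | w.ineffective):
            call = ("effective_nontoxic" if ci in w.effective_nontoxic
                    else "effective_toxic" if ci in w.effective_toxic
                    else "ineffective")
            win_rows.append({"compound": name, "conc_index": ci, "call": call,
                             "efficacy_threshold_pct": w.efficacy_threshold_pct,
                             "toxicity_threshold": w.toxicity_threshold})
    paths["windows"] = out / "windows.csv"
    pd.DataFrame(win_rows).to_csv(paths["windows"], index=False)
    paths["heatmap_long"] = out / "heatmap_long.csv"
    export_heatmap(table).to_csv(paths["heatmap_long"], index=False)
    return paths


def write_bridge_scene(scene: BridgeScene, out_dir,
                       scene_id: str = "scene") -> dict[str, Path]:
    """One TIFF per channel plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("reflection", "factin", "hoechst", "pi"):
        paths[name] = out / f"{scene_id}_{name}.tif"
        write_stack(paths[name], getattr(scene, name))
    truth = scene.truth
    sidecar = {
        "fiber_segments": [[s.z, list(s.a), list(s.b), s.angle]
                           for s in truth.fiber_segments],
        "nuclei": [[n.z_um, n.y_um, n.x_um, n.radius_um, bool(n.is_dead)]
                   for n in truth.nuclei],
        "per_cell_orientation": list(truth.per_cell_orientation),
        "factin_angles_per_z": truth.factin_angles_per_z,
        "roi_suggestion": ([truth.roi_suggestion.x0, truth.roi_suggestion.y0,
                            truth.roi_suggestion.x1, truth.roi_suggestion.y1]
                           if truth.roi_suggestion else None),
        "artefact_spots": [list(s) for s in scene.config.artefact_spots],
    }
    paths["truth"] = out / f"{scene_id}_truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(sidecar, fh)
    return paths
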