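"""Dose-response assembly: per-well readouts to efficacy windows.

Each well contributes a remodeling score (mean reflection-signal density
in the inter-cluster ROI) and a toxicity fraction (PI-positive proportion
of cluster nuclei). Scores are normalized to percent remodeling
inhibition between the TGFB positive control (0 %) and the CTR negative
control (100 %), replicates are aggregated as mean +- SEM, and each
concentration index is classified into effective-nontoxic,
effective-toxic or ineffective. Window detection is per-concentration
classification rather than curve fitting, because dose responses in this
assay can be non-monotone (efficacy lost again at high dose); a Hill fit
is available separately for description, never for window calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .imaging import intensity_density
from .viability import viability_profile

__all__ = [
    "WellRecord",
    "ScreenTable",
    "EfficacyWindow",
    "remodeling_inhibition",
    "quantify_well",
    "build_screen_table",
    "efficacy_window",
    "export_heatmap",
    "fit_hill",
]


@dataclass(frozen=True)
class WellRecord:
    """Quantified readouts of one well.

    Exactly one of (compound + conc_index in 1..6) or control in
    {"CTR", "TGFB"} identifies the condition.
    """

    replicate: int
    remodeling_score: float
    toxicity_fraction: float
    compound: Optional[str] = None
    conc_index: Optional[int] = None
    control: Optional[str] = None

    def __post_init__(self):
        has_dose = self.compound is not None and self.conc_index is not None
        if has_dose == (self.control is not None):
            raise ValueError("set either compound+conc_index or control")
        if self.control is not None and self.control not in ("CTR", "TGFB"):
            raise ValueError('control must be "CTR" or "TGFB"')
        if not 0.0 <= self.toxicity_fraction <= 1.0:
            raise ValueError("toxicity_fraction must lie in [0, 1]")

    @property
    def condition(self) -> tuple[str, int]:
        if self.control is not None:
            return (self.control, 0)
        return (self.compound, self.conc_index)  # type: ignore[return-value]


@dataclass
class ScreenTable:
    """Long-format well records plus per-condition aggregates.

    ``records`` has one row per well; ``aggregates`` one row per
    (compound, conc_index) with mean, SEM and n for both readouts. SEM is
    NaN (flagged) for single-replicate conditions.
    """

    records: pd.DataFrame
    aggregates: pd.DataFrame

    @property
    def compounds(self) -> list[str]:
        mask = ~self.records["compound"].isin(["CTR", "TGFB"])
        return sorted(self.records.loc[mask, "compound"].unique())

    def control_mean(self, which: str) -> float:
        sel = self.aggregates
        row = sel[(sel["compound"] == which) & (sel["conc_index"] == 0)]
        return float(row["remodeling_mean"].iloc[0])


@dataclass
class EfficacyWindow:
    """Concentration indices split by efficacy and toxicity calls.

    The three sets partition the tested indices: effective_nontoxic is
    the usable window, effective_toxic suppresses remodeling only at
    cytotoxic doses, ineffective fails the efficacy threshold.
    """

    compound: str
    effective_nontoxic: set[int]
    effective_toxic: set[int]
    ineffective: set[int]
    efficacy_threshold_pct: float
    toxicity_threshold: float

    def __post_init__(self):
        sets = (self.effective_nontoxic, self.effective_toxic,
                self.ineffective)
        n_total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != n_total:
            raise ValueError("window sets must be disjoint")


def remodeling_inhibition(score: float, ctr_mean: float,
                          tgfb_mean: float) -> float:
    """Percent remodeling inhibition on the control scale.

    100 x (tgfb_mean - score) / (tgfb_mean - ctr_mean): 0 % means the
    well looks like the TGFB positive control, 100 % like the CTR
    negative control. Requires tgfb_mean > ctr_mean; invariant to adding
    a constant to all three inputs.
    """
    if not tgfb_mean > ctr_mean:
        raise ValueError("controls inverted or equal: need tgfb_mean > ctr_mean")
    return 100.0 * (tgfb_mean - score) / (tgfb_mean - ctr_mean)


def quantify_well(well) -> WellRecord:
    """Run the imaging pipeline on one simulated well.

    Remodeling = mean intensity density in the scene's suggested
    inter-cluster ROI of the reflection stack; toxicity = PI-positive
    cluster proportion from the viability stacks.
    """
    dens = intensity_density(well.bridge.reflection,
                             well.bridge.truth.roi_suggestion,
                             mask=well.bridge.truth.artefact_mask)
    profile = viability_profile(well.hoechst, well.pi)
    return WellRecord(replicate=well.replicate,
                      remodeling_score=dens.mean,
                      toxicity_fraction=profile.cluster_proportion,
                      compound=well.compound, conc_index=well.conc_index,
                      control=well.control)


def build_screen_table(records: Iterable[WellRecord]) -> ScreenTable:
    """Assemble well records into the long table with aggregates.

    Requires both CTR and TGFB control wells, rejects duplicate
    (condition, replicate) keys, and flags SEM as NaN where only one
    replicate exists.
    """
    records = list(records)
    if not records:
        raise ValueError("no well records")
    rows = []
    seen = set()
    for r in records:
        key = (*r.condition, r.replicate)
        if key in seen:
            raise ValueError(f"duplicate well key {key}")
        seen.add(key)
        comp, ci = r.condition
        rows.append({"compound": comp, "conc_index": ci,
                     "replicate": r.replicate,
                     "remodeling_score": r.remodeling_score,
                     "toxicity_fraction": r.toxicity_fraction})
    df = pd.DataFrame(rows)
    present = set(df["compound"].unique())
    missing = {"CTR", "TGFB"} - present
    if missing:
        raise ValueError(f"missing control wells: {sorted(missing)}")

    def _sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    agg = (df.groupby(["compound", "conc_index"])
           .agg(remodeling_mean=("remodeling_score", "mean"),
                remodeling_sem=("remodeling_score", _sem),
                toxicity_mean=("toxicity_fraction", "mean"),
                toxicity_sem=("toxicity_fraction", _sem),
                n=("replicate", "size"))
           .reset_index())
    return ScreenTable(records=df, aggregates=agg)


def efficacy_window(table: ScreenTable,
                    efficacy_threshold_pct: float = 50.0,
                    toxicity_threshold: float = 0.2
                    ) -> dict[str, EfficacyWindow]:
    """Classify every tested concentration of every compound.

    A concentration is effective when its replicate-mean remodeling
    inhibition reaches ``efficacy_threshold_pct`` and toxic when its mean
    toxicity fraction reaches ``toxicity_threshold``. The thresholds are
    pipeline defaults exposed for configuration, not assay constants.
    """
    if not 0.0 <= toxicity_threshold <= 1.0:
        raise ValueError("toxicity_threshold must lie in [0, 1]")
    ctr = table.control_mean("CTR")
    tgfb = table.control_mean("TGFB")
    windows: dict[str, EfficacyWindow] = {}
    agg = table.aggregates
    for comp in table.compounds:
        sub = agg[(agg["compound"] == comp) & (agg["conc_index"] > 0)]
        eff_ok, tox_ok, ineffective = set(), set(), set()
        for _, row in sub.iterrows():
            ci = int(row["conc_index"])
            inhibition = remodeling_inhibition(row["remodeling_mean"], ctr, tgfb)
            effective = inhibition >= efficacy_threshold_pct
            toxic = row["toxicity_mean"] >= toxicity_threshold
            if effective and not toxic:
                eff_ok.add(ci)
            elif effective:
                tox_ok.add(ci)
            else:
                ineffective.add(ci)
        windows[comp] = EfficacyWindow(
            compound=comp, effective_nontoxic=eff_ok,
            effective_toxic=tox_ok, ineffective=ineffective,
            efficacy_threshold_pct=efficacy_threshold_pct,
            toxicity_threshold=toxicity_threshold)
    return windows


def export_heatmap(table: ScreenTable, path: Optional[str] = None,
                   remodeling_scale: tuple[float, float] = (0.0, 150.0),
                   toxicity_scale: tuple[float, float] = (0.0, 1.0)
                   ) -> pd.DataFrame:
    """Heatmap-ready long table, optionally rendered to ``path``.

    One row per (replicate, compound, conc_index) with the raw remodeling
    score and the toxicity fraction clipped to [0, 1]. The rendering uses
    a blue map saturating at 150 density units for remodeling and a red
    map over [0, 1] for toxicity, higher = more remodeling / more
    cytotoxicity.
    """
    df = table.records
    long = df[~df["compound"].isin(["CTR", "TGFB"])].copy()
    long = long.sort_values(["compound", "replicate", "conc_index"])
    long["toxicity_fraction"] = long["toxicity_fraction"].clip(0.0, 1.0)
    long = long.reset_index(drop=True)
    if path is not None:
        _render_heatmap(long, path, remodeling_scale, toxicity_scale)
    return long


def _render_heatmap(long: pd.DataFrame, path: str,
                    remodeling_scale: tuple[float, float],
                    toxicity_scale: tuple[float, float]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    remod = long.pivot_table(index=["compound", "replicate"],
                             columns="conc_index",
                             values="remodeling_score")
    tox = long.pivot_table(index=["compound", "replicate"],
                          columns="conc_index",
                          values="toxicity_fraction")
    fig, axes = plt.subplots(1, 2, figsize=(9, 0.35 * len(remod) + 2))
    for ax, data, cmap, scale, title in (
            (axes[0], remod, "Blues", remodeling_scale, "ECM remodeling"),
            (axes[1], tox, "Reds", toxicity_scale, "Cytotoxicity")):
        im = ax.imshow(data.to_numpy(), cmap=cmap, aspect="auto",
                       vmin=scale[0], vmax=scale[1])
        ax.set_xticks(range(data.shape[1]),
                      [str(c) for c in data.columns])
        ax.set_yticks(range(data.shape[0]),
                      [f"{c} r{r}" for c, r in data.index])
        ax.set_xlabel("concentration index (1 = highest)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fit_hill(conc: np.ndarray, response: np.ndarray
             ) -> tuple[float, float, float]:
    """Descriptive Hill fit (emax, ec50, hill) of a monotone response.

    Provided for characterization only; window calls never rely on it,
    because assay dose responses can be non-monotone.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)

    def hill(c, emax, ec50, h):
        r = (c / ec50) ** h
        return emax * r / (1.0 + r)

    p0 = (max(response.max(), 1e-6), float(np.median(conc)), 1.5)
    popt, _ = curve_fit(hill, conc, response, p0=p0,
                        bounds=([0, 1e-9, 0.1], [np.inf, np.inf, 10.0]),
                        maxfev=20000)
    return tuple(float(v) for v in popt)  # type: ignore[return-value]
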