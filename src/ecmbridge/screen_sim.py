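"""Simulated compound screens with planted dose-response truth.

A screen is laid out like the assay plate: each compound is tested at six
concentrations (index 1 = highest, successive 1:3 dilutions), in
replicate wells, next to shared negative (CTR, unstimulated) and positive
(TGFB, stimulated) control wells. For every well the generator plants

* an efficacy fraction e(c) in [0, 1] from a Hill curve (optionally
  multiplied by a high-dose efficacy-loss Hill term, giving the
  bell-shaped dose response some kinase inhibitors show), which scales the
  bridge fiber density between the TGFB level (e = 0) and the CTR level
  (e = 1); and
* a dead fraction from a toxicity Hill curve on top of a baseline.

The planted values propagate analytically to expected remodeling
inhibition (100 x e) and toxicity, so detected efficacy windows can be
compared against ``analytic_windows`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .scene import BridgeScene, SceneConfig, SceneTruth, \
    generate_bridge_scene, generate_cluster_nuclei
from .imaging import VolumeImage

__all__ = [
    "HillCurve",
    "CompoundModel",
    "rocki_like",
    "tbri_like",
    "inert_compound",
    "ScreenDesign",
    "WellScene",
    "ScreenDataset",
    "generate_screen_dataset",
    "analytic_windows",
]


@dataclass(frozen=True)
class HillCurve:
    """emax * c^h / (c^h + ec50^h); monotone increasing in dose."""

    emax: float
    ec50: float
    hill: float = 2.0

    def __post_init__(self):
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")

    def __call__(self, conc: float) -> float:
        if conc <= 0:
            return 0.0
        r = (conc / self.ec50) ** self.hill
        return self.emax * r / (1.0 + r)


@dataclass(frozen=True)
class CompoundModel:
    """Planted pharmacology of one screened compound.

    ``efficacy`` gives the remodeling-suppression fraction in [0, 1];
    ``efficacy_loss`` (optional) multiplies it by (1 - loss(c)) to model
    efficacy lost again at high dose; ``toxicity`` adds to the baseline
    dead fraction.
    """

    name: str
    efficacy: HillCurve
    toxicity: HillCurve
    efficacy_loss: Optional[HillCurve] = None

    def efficacy_at(self, conc: float) -> float:
        e = self.efficacy(conc)
        if self.efficacy_loss is not None:
            e *= 1.0 - self.efficacy_loss(conc)
        return float(np.clip(e, 0.0, 1.0))

    def toxicity_at(self, conc: float) -> float:
        return float(self.toxicity(conc))


def rocki_like(name: str = "ROCKi-like") -> CompoundModel:
    """Potent remodeling suppressor that turns cytotoxic at the three
    highest concentrations, leaving a single effective non-toxic dose."""
    return CompoundModel(name,
                         efficacy=HillCurve(1.0, 5.0, 2.0),
                         toxicity=HillCurve(0.8, 20.0, 4.0))


def tbri_like(name: str = "TbRi-like") -> CompoundModel:
    """Non-monotone suppressor: ineffective at the top dose, effective in
    the mid range, inert at the lowest doses, without toxicity."""
    return CompoundModel(name,
                         efficacy=HillCurve(1.0, 15.0, 3.0),
                         toxicity=HillCurve(0.001, 1.0e6, 2.0),
                         efficacy_loss=HillCurve(1.0, 150.0, 4.0))


def inert_compound(name: str = "inert") -> CompoundModel:
    """Zero-potency compound: every well matches the TGFB control."""
    return CompoundModel(name,
                         efficacy=HillCurve(0.0, 1.0, 1.0),
                         toxicity=HillCurve(0.0, 1.0, 1.0))


def _default_bridge_config() -> SceneConfig:
    return SceneConfig(image_shape=(3, 160, 480), pixel_size_xy=2.5,
                       z_step=25.0, fiber_density=0.5,
                       artefact_spots=[(30, 70, 6), (130, 410, 6)])


def _default_viability_config() -> SceneConfig:
    return SceneConfig(image_shape=(9, 144, 144), pixel_size_xy=1.5,
                       z_step=10.0, cells_per_cluster=500)


@dataclass
class ScreenDesign:
    """Plate layout and planted pharmacology of a simulated screen.

    Concentrations are indexed 1..n_concentrations with index 1 = c_max
    and a ``dilution`` (default 1:3) ratio between neighbours, mirroring
    the assay's dose series. ``ctr_multiplier`` is the residual bridge
    density of the unstimulated control relative to the TGFB control.
    """

    compounds: list[CompoundModel]
    n_replicates: int = 3
    n_concentrations: int = 6
    c_max: float = 243.0
    dilution: float = 3.0
    ctr_multiplier: float = 0.1
    baseline_dead: float = 0.02
    max_dead: float = 0.95
    bridge_config: SceneConfig = field(default_factory=_default_bridge_config)
    viability_config: SceneConfig = field(default_factory=_default_viability_config)
    bridge_fiber_density: float = 12.0
    roi_size_um: tuple[float, float] = (300.0, 80.0)

    def __post_init__(self):
        if self.n_concentrations < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 concentration and replicate")
        if self.dilution <= 1:
            raise ValueError("dilution ratio must exceed 1")
        if not 0 <= self.ctr_multiplier < 1:
            raise ValueError("ctr_multiplier must lie in [0, 1)")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")

    def concentration(self, index: int) -> float:
        if not 1 <= index <= self.n_concentrations:
            raise ValueError("concentration index out of range")
        return self.c_max / self.dilution ** (index - 1)


@dataclass
class WellScene:
    """One simulated well: imagery plus its planted truth.

    Exactly one of (compound, conc_index) or control is set; control is
    "CTR" or "TGFB".
    """

    replicate: int
    bridge: BridgeScene
    hoechst: VolumeImage
    pi: VolumeImage
    viability_truth: SceneTruth
    planted_multiplier: float
    planted_efficacy: float
    planted_dead_fraction: float
    compound: Optional[str] = None
    conc_index: Optional[int] = None
    control: Optional[str] = None

    def __post_init__(self):
        has_dose = self.compound is not None and self.conc_index is not None
        if has_dose == (self.control is not None):
            raise ValueError("set either compound+conc_index or control")


@dataclass
class ScreenDataset:
    """All wells of a simulated screen plus the planted-truth table."""

    design: ScreenDesign
    wells: list[WellScene]
    planted: pd.DataFrame


def _well_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(seed), index])
               .generate_state(1)[0] % (2**31))


def _simulate_well(design: ScreenDesign, efficacy: float, dead: float,
                   seed: int) -> tuple[BridgeScene, VolumeImage, VolumeImage, SceneTruth]:
    mult = design.ctr_multiplier + (1.0 - design.ctr_multiplier) * (1.0 - efficacy)
    bcfg = replace(design.bridge_config, seed=seed)
    bridge = generate_bridge_scene(bcfg, treated=True,
                                   bridge_density_multiplier=mult,
                                   bridge_fiber_density=design.bridge_fiber_density,
                                   roi_size_um=design.roi_size_um,
                                   render_viability=False)
    vcfg = replace(design.viability_config, seed=seed, dead_fraction=dead)
    hoechst, pi, vtruth = generate_cluster_nuclei(vcfg)
    return bridge, hoechst, pi, vtruth


def generate_screen_dataset(design: ScreenDesign, seed: int = 0) -> ScreenDataset:
    """Simulate every well of the screen, deterministically from seed.

    Produces n_replicates wells per (compound, concentration) condition
    plus n_replicates shared CTR and TGFB control wells, and a planted
    table with the analytic efficacy fraction, expected inhibition
    percentage and dead fraction of every condition.
    """
    wells: list[WellScene] = []
    rows = []
    idx = 0
    for control, eff in (("CTR", 1.0), ("TGFB", 0.0)):
        for rep in range(1, design.n_replicates + 1):
            bridge, h, p, vt = _simulate_well(
                design, eff, design.baseline_dead, _well_seed(seed, idx))
            idx += 1
            mult = design.ctr_multiplier + (1 - design.ctr_multiplier) * (1 - eff)
            wells.append(WellScene(
                replicate=rep, bridge=bridge, hoechst=h, pi=p,
                viability_truth=vt, planted_multiplier=mult,
                planted_efficacy=eff,
                planted_dead_fraction=design.baseline_dead, control=control))
        rows.append({"compound": control, "conc_index": 0,
                     "efficacy_fraction": eff,
                     "inhibition_pct": 100.0 * eff,
                     "dead_fraction": design.baseline_dead})
    for comp in design.compounds:
        for ci in range(1, design.n_concentrations + 1):
            conc = design.concentration(ci)
            eff = comp.efficacy_at(conc)
            dead = float(np.clip(design.baseline_dead + comp.toxicity_at(conc),
                                 0.0, design.max_dead))
            rows.append({"compound": comp.name, "conc_index": ci,
                         "efficacy_fraction": eff,
                         "inhibition_pct": 100.0 * eff,
                         "dead_fraction": dead})
            for rep in range(1, design.n_replicates + 1):
                bridge, h, p, vt = _simulate_well(
                    design, eff, dead, _well_seed(seed, idx))
                idx += 1
                mult = design.ctr_multiplier + (1 - design.ctr_multiplier) * (1 - eff)
                wells.append(WellScene(
                    replicate=rep, bridge=bridge, hoechst=h, pi=p,
                    viability_truth=vt, planted_multiplier=mult,
                    planted_efficacy=eff, planted_dead_fraction=dead,
                    compound=comp.name, conc_index=ci))
    return ScreenDataset(design=design, wells=wells,
                         planted=pd.DataFrame(rows))


def analytic_windows(design: ScreenDesign,
                     efficacy_threshold_pct: float = 50.0,
                     toxicity_threshold: float = 0.2) -> dict[str, dict[str, set[int]]]:
    """Efficacy windows implied directly by the planted Hill parameters.

    The planted efficacy fraction maps one-to-one onto expected
    remodeling inhibition (100 x e), and the planted dead fraction is the
    expected toxicity, so the window of each compound follows by
    thresholding — the independent oracle for window detection.
    """
    out: dict[str, dict[str, set[int]]] = {}
    for comp in design.compounds:
        eff_ok, tox_ok, ineffective = set(), set(), set()
        for ci in range(1, design.n_concentrations + 1):
            conc = design.concentration(ci)
            effective = 100.0 * comp.efficacy_at(conc) >= efficacy_threshold_pct
            toxic = (design.baseline_dead + comp.toxicity_at(conc)
                     >= toxicity_threshold)
            if effective and not toxic:
                eff_ok.add(ci)
            elif effective:
                tox_ok.add(ci)
            else:
                ineffective.add(ci)
        out[comp.name] = {"effective_nontoxic": eff_ok,
                          "effective_toxic": tox_ok,
                          "ineffective": ineffective}
    return out
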