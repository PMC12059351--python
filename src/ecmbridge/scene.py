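"""Synthetic 3D multi-channel phantoms with ground truth.

The generator emulates the printed-fibroblast-cluster collagen assay: two
~200-um clusters of ~500 cells placed 900 um apart in a collagen fiber
field, imaged by confocal reflection microscopy (Z-sections every 25 um)
with an inter-cluster "bridge" of dense, aligned fibers; Hoechst/PI
viability stacks through a cluster (sections every 10 um) with a planted
dead fraction; F-actin rods for protruding cells; bright artefact discs
mimicking reflection from optical elements; Gaussian and optional Poisson
noise. Every scene returns a SceneTruth side-channel so downstream
measurements can be checked against planted values.

Fibers are rendered as per-section 2D anti-aliased segments, matching the
per-Z-section granularity of the analysis, and fiber orientations follow
an axial von Mises law (von Mises on doubled angles) with mean
``bridge_axis_angle`` and concentration ``kappa``; kappa = 0 is isotropic.
All randomness derives from one integer seed; per-channel sub-streams use
fixed offsets so each channel is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage.draw import disk, line_aa

from .circstats import sample_axial_vonmises
from .imaging import RectROI, VolumeImage, interspheroid_roi, um_to_px

__all__ = [
    "SceneConfig",
    "FiberSegment",
    "NucleusTruth",
    "SceneTruth",
    "BridgeScene",
    "generate_fiber_volume",
    "generate_cluster_nuclei",
    "generate_bridge_scene",
]

# fixed sub-stream offsets per channel (reproducibility contract)
_STREAM = {"reflection": 1, "hoechst": 2, "pi": 3, "factin": 4, "layout": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAM[stream]])


@dataclass
class SceneConfig:
    """Geometry, optics and noise parameters of one synthetic scene.

    Spatial fields are microns; ``image_shape`` is (z, y, x) voxels.
    ``fiber_density`` is fibers per 100 x 100 um per Z-section;
    ``bridge_axis_angle`` (degrees in [0, 180)) and ``kappa`` set the
    axial von Mises law of fiber orientations (kappa = 0 isotropic, on
    the doubled-angle scale). ``artefact_spots`` are (y_px, x_px,
    radius_px) bright discs. Defaults mirror the assay layout: 200-um
    clusters of 500 cells spaced 900 um apart, reflection sections every
    25 um, viability sections every 10 um, noise SD 2 % of the fiber peak.
    """

    image_shape: tuple[int, int, int] = (5, 300, 560)
    pixel_size_xy: float = 2.5
    z_step: float = 25.0
    cluster_centers_um: Optional[list[tuple[float, float, float]]] = None  # (z, y, x)
    cluster_diameter_um: float = 200.0
    cells_per_cluster: int = 500
    cluster_spacing_um: float = 900.0
    fiber_density: float = 2.0
    fiber_length_um: float = 40.0
    fiber_peak: float = 200.0
    bridge_axis_angle: float = 68.8
    kappa: float = 0.0
    dead_fraction: float = 0.0
    nucleus_radius_um: float = 5.0
    nucleus_peak: float = 200.0
    background: float = 5.0
    noise_gaussian_sd: float = 4.0
    poisson_noise: bool = False
    artefact_spots: list[tuple[int, int, int]] = field(default_factory=list)
    artefact_peak: float = 255.0
    seed: int = 0

    def __post_init__(self):
        z, y, x = self.image_shape
        if min(z, y, x) < 1:
            raise ValueError("image_shape must be positive")
        for name in ("pixel_size_xy", "z_step", "cluster_diameter_um",
                     "cluster_spacing_um", "fiber_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fiber_density < 0 or self.kappa < 0:
            raise ValueError("fiber_density and kappa must be >= 0")
        if not 0.0 <= self.bridge_axis_angle < 180.0:
            raise ValueError("bridge_axis_angle must lie in [0, 180)")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        if self.noise_gaussian_sd < 0:
            raise ValueError("noise_gaussian_sd must be >= 0")
        if self.cluster_centers_um is not None:
            centers = [tuple(c) for c in self.cluster_centers_um]
            if len(set(centers)) != len(centers):
                raise ValueError("cluster centers must be pairwise distinct")

    @property
    def section_shape(self) -> tuple[int, int]:
        return self.image_shape[1:]

    def default_two_cluster_centers(self) -> list[tuple[float, float, float]]:
        """Two clusters spaced ``cluster_spacing_um`` along x, centered."""
        z, y, x = self.image_shape
        cy = (y - 1) / 2.0 * self.pixel_size_xy
        cx = (x - 1) / 2.0 * self.pixel_size_xy
        cz = (z - 1) / 2.0 * self.z_step
        half = self.cluster_spacing_um / 2.0
        return [(cz, cy, cx - half), (cz, cy, cx + half)]


@dataclass(frozen=True)
class FiberSegment:
    """One planted fiber: section index, endpoints (y, x) px, axial angle."""

    z: int
    a: tuple[float, float]
    b: tuple[float, float]
    angle: float


@dataclass(frozen=True)
class NucleusTruth:
    """One planted nucleus: position (z, y, x) um, radius um, dead flag."""

    z_um: float
    y_um: float
    x_um: float
    radius_um: float
    is_dead: bool


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    fiber_segments: list[FiberSegment] = field(default_factory=list)
    nuclei: list[NucleusTruth] = field(default_factory=list)
    per_cell_orientation: list[float] = field(default_factory=list)
    factin_angles_per_z: list[list[float]] = field(default_factory=list)
    artefact_mask: Optional[np.ndarray] = None
    cluster_mask: Optional[np.ndarray] = None
    roi_suggestion: Optional[RectROI] = None

    @property
    def fiber_angles(self) -> np.ndarray:
        return np.array([s.angle for s in self.fiber_segments])

    @property
    def dead_fraction(self) -> float:
        if not self.nuclei:
            raise ValueError("truth holds no nuclei")
        return float(np.mean([n.is_dead for n in self.nuclei]))


def _artefact_mask(config: SceneConfig) -> np.ndarray:
    mask = np.zeros(config.section_shape, dtype=bool)
    for (y, x, r) in config.artefact_spots:
        rr, cc = disk((y, x), r, shape=config.section_shape)
        mask[rr, cc] = True
    return mask


def _stamp_artefacts(canvas: np.ndarray, config: SceneConfig) -> None:
    for (y, x, r) in config.artefact_spots:
        rr, cc = disk((y, x), r, shape=canvas.shape)
        canvas[rr, cc] = config.artefact_peak


def _apply_noise(volume: np.ndarray, config: SceneConfig,
                 rng: np.random.Generator) -> np.ndarray:
    out = volume + config.background
    if config.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, config.noise_gaussian_sd, size=out.shape)
    out = np.clip(out, 0.0, None)
    if config.poisson_noise:
        out = rng.poisson(out).astype(float)
    return out


def _draw_fibers(canvas: np.ndarray, n_fibers: int, mean_angle: float,
                 kappa: float, length_px: float, peak: float,
                 rng: np.random.Generator,
                 region: Optional[tuple[float, float, float, float]] = None,
                 z: int = 0) -> list[FiberSegment]:
    """Stamp anti-aliased segments onto one section; returns their truth.

    ``region`` restricts fiber centers to (y0, y1, x0, x1) px; default is
    the whole section. Overlapping fibers combine by maximum, so a fiber
    crossing another does not double its brightness.
    """
    h, w = canvas.shape
    y0, y1, x0, x1 = region if region is not None else (0.0, h, 0.0, w)
    angles = sample_axial_vonmises(mean_angle, kappa, n_fibers, rng)
    cy = rng.uniform(y0, y1, size=n_fibers)
    cx = rng.uniform(x0, x1, size=n_fibers)
    segments = []
    half = length_px / 2.0
    for ang, yy, xx in zip(angles, cy, cx):
        th = np.deg2rad(ang)
        dx, dy = np.cos(th) * half, -np.sin(th) * half  # y axis points down
        r0, c0 = int(round(yy - dy)), int(round(xx - dx))
        r1, c1 = int(round(yy + dy)), int(round(xx + dx))
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        if (r0, c0) == (r1, c1):
            continue
        rr, cc, val = line_aa(r0, c0, r1, c1)
        np.maximum.at(canvas, (rr, cc), val * peak)
        segments.append(FiberSegment(z=z, a=(float(r0), float(c0)),
                                     b=(float(r1), float(c1)),
                                     angle=float(ang)))
    return segments


def generate_fiber_volume(config: SceneConfig
                          ) -> tuple[VolumeImage, SceneTruth]:
    """Pure fiber-field reflection phantom (no clusters).

    Per section, the fiber count is Poisson with mean
    ``fiber_density x section area / (100 um)^2`` and orientations follow
    the axial von Mises law (mean ``bridge_axis_angle``, concentration
    ``kappa``). Artefact discs are stamped after the fibers and noise is
    applied last. Deterministic given the seed.
    """
    nz, h, w = config.image_shape
    area_units = (h * w * config.pixel_size_xy**2) / 1.0e4
    length_px = config.fiber_length_um / config.pixel_size_xy
    rng = _rng(config.seed, "reflection")
    truth = SceneTruth(artefact_mask=_artefact_mask(config))
    volume = np.zeros(config.image_shape, dtype=float)
    for z in range(nz):
        n_fibers = rng.poisson(config.fiber_density * area_units)
        truth.fiber_segments.extend(_draw_fibers(
            volume[z], n_fibers, config.bridge_axis_angle, config.kappa,
            length_px, config.fiber_peak, rng, z=z))
        _stamp_artefacts(volume[z], config)
    volume = _apply_noise(volume, config, rng)
    stack = VolumeImage(volume, config.pixel_size_xy, config.z_step,
                        "reflection")
    return stack, truth


def _place_nuclei(config: SceneConfig,
                  centers_um: Sequence[tuple[float, float, float]],
                  z_step: float, rng: np.random.Generator
                  ) -> list[NucleusTruth]:
    """Dart-throwing placement of nuclei inside spherical clusters.

    Rejects candidates closer than one nucleus diameter in 3D, and also
    candidates that would overlap laterally with a nucleus rendered in the
    same Z-section, so planted phantoms segment cleanly. Raises when the
    requested count cannot be placed.
    """
    r = config.nucleus_radius_um
    rmax = config.cluster_diameter_um / 2.0 - r
    if rmax <= 0:
        raise ValueError("cluster too small for the nucleus radius")
    placed: list[NucleusTruth] = []
    min_d2_3d = (2.0 * r) ** 2
    min_dxy = 2.0 * r + config.pixel_size_xy
    for (cz, cy, cx) in centers_um:
        accepted: list[tuple[float, float, float]] = []
        attempts = 0
        max_attempts = 2000 * config.cells_per_cluster
        while len(accepted) < config.cells_per_cluster:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "cannot place cells_per_cluster non-overlapping nuclei "
                    "at this cluster diameter; reduce cells_per_cluster")
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() > 1.0:
                continue
            z, y, x = cz + u[0] * rmax, cy + u[1] * rmax, cx + u[2] * rmax
            zbin = int(round(z / z_step))
            ok = True
            for (pz, py, px) in accepted:
                dz, dy, dx = z - pz, y - py, x - px
                if dz * dz + dy * dy + dx * dx < min_d2_3d:
                    ok = False
                    break
                if int(round(pz / z_step)) == zbin and \
                        np.hypot(dy, dx) < min_dxy:
                    ok = False
                    break
            if ok:
                accepted.append((z, y, x))
        placed.extend(NucleusTruth(z_um=z, y_um=y, x_um=x, radius_um=r,
                                   is_dead=False)
                      for (z, y, x) in accepted)
    # exactly round(f * n) dead overall, apportioned across Z-bins by
    # largest remainder so the planted dead fraction is homogeneous along
    # the axis (dead cells have no preferred depth); which nuclei within a
    # bin are dead is a seeded draw
    n_total = len(placed)
    n_dead = int(round(config.dead_fraction * n_total))
    bins: dict[int, list[int]] = {}
    for i, nu in enumerate(placed):
        bins.setdefault(int(round(nu.z_um / z_step)), []).append(i)
    quotas = {b: config.dead_fraction * len(ix) for b, ix in bins.items()}
    counts = {b: int(np.floor(q)) for b, q in quotas.items()}
    remainder = n_dead - sum(counts.values())
    by_frac = sorted(bins, key=lambda b: quotas[b] - counts[b], reverse=True)
    for b in by_frac[:remainder]:
        counts[b] += 1
    dead_idx: set[int] = set()
    for b, ix in bins.items():
        k = min(counts[b], len(ix))
        chosen = rng.permutation(len(ix))[:k]
        dead_idx.update(ix[j] for j in chosen)
    return [replace(nu, is_dead=(i in dead_idx))
            for i, nu in enumerate(placed)]


def _stamp_blob(canvas: np.ndarray, y_px: float, x_px: float,
                sigma_px: float, peak: float) -> None:
    h, w = canvas.shape
    ext = int(np.ceil(3.0 * sigma_px))
    yc, xc = int(round(y_px)), int(round(x_px))
    y0, y1 = max(0, yc - ext), min(h, yc + ext + 1)
    x0, x1 = max(0, xc - ext), min(w, xc + ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    blob = peak * np.exp(-((yy - y_px) ** 2 + (xx - x_px) ** 2)
                         / (2.0 * sigma_px**2))
    canvas[y0:y1, x0:x1] = np.maximum(canvas[y0:y1, x0:x1], blob)


def generate_cluster_nuclei(config: SceneConfig,
                            centers_um: Optional[Sequence[tuple[float, float, float]]] = None
                            ) -> tuple[VolumeImage, VolumeImage, SceneTruth]:
    """Hoechst and PI viability stacks for spherical nuclei clusters.

    Nuclei are placed without overlap inside each cluster sphere; every
    nucleus is bright in Hoechst and exactly round(dead_fraction x n) of
    them (chosen by a seeded permutation) are equally bright in PI. Each
    nucleus is rendered as a Gaussian blob in its nearest Z-section.
    Deterministic given the seed.
    """
    if centers_um is None:
        z, y, x = config.image_shape
        centers_um = [((z - 1) / 2.0 * config.z_step,
                       (y - 1) / 2.0 * config.pixel_size_xy,
                       (x - 1) / 2.0 * config.pixel_size_xy)]
    rng = _rng(config.seed, "layout")
    nuclei = _place_nuclei(config, centers_um, config.z_step, rng)
    truth = SceneTruth(nuclei=nuclei, artefact_mask=_artefact_mask(config))

    nz = config.image_shape[0]
    hoechst = np.zeros(config.image_shape, dtype=float)
    pi = np.zeros(config.image_shape, dtype=float)
    sigma_px = (config.nucleus_radius_um / 2.0) / config.pixel_size_xy
    for nu in nuclei:
        zbin = int(round(nu.z_um / config.z_step))
        if not 0 <= zbin < nz:
            continue
        y_px = nu.y_um / config.pixel_size_xy
        x_px = nu.x_um / config.pixel_size_xy
        _stamp_blob(hoechst[zbin], y_px, x_px, sigma_px, config.nucleus_peak)
        if nu.is_dead:
            _stamp_blob(pi[zbin], y_px, x_px, sigma_px, config.nucleus_peak)
    hoechst = _apply_noise(hoechst, config, _rng(config.seed, "hoechst"))
    pi = _apply_noise(pi, config, _rng(config.seed, "pi"))
    h_img = VolumeImage(hoechst, config.pixel_size_xy, config.z_step, "hoechst")
    p_img = VolumeImage(pi, config.pixel_size_xy, config.z_step, "pi")
    return h_img, p_img, truth


@dataclass
class BridgeScene:
    """Full two-cluster scene: channel stacks plus ground truth."""

    reflection: VolumeImage
    factin: VolumeImage
    hoechst: VolumeImage
    pi: VolumeImage
    truth: SceneTruth
    config: SceneConfig


def _corridor_region(config: SceneConfig,
                     centers_px: list[tuple[float, float]],
                     width_um: float) -> tuple[float, float, float, float]:
    """(y0, y1, x0, x1) px box between the two cluster rims (x-axis layout)."""
    (xa, ya), (xb, yb) = centers_px
    r_px = (config.cluster_diameter_um / 2.0) / config.pixel_size_xy
    half_w = (width_um / 2.0) / config.pixel_size_xy
    x0, x1 = min(xa, xb) + r_px, max(xa, xb) - r_px
    y0, y1 = ya - half_w, ya + half_w
    return (max(0.0, y0), min(config.section_shape[0], y1),
            max(0.0, x0), min(config.section_shape[1], x1))


def generate_bridge_scene(config: SceneConfig,
                          treated: bool = True,
                          bridge_density_multiplier: float = 1.0,
                          corridor_width_um: float = 120.0,
                          bridge_fiber_density: float = 8.0,
                          bridge_kappa: float = 8.0,
                          factin_kappa: float = 12.0,
                          cells_per_section: int = 12,
                          factin_rod_length_um: float = 30.0,
                          roi_size_um: tuple[float, float] = (100.0, 40.0),
                          render_viability: bool = True,
                          ) -> BridgeScene:
    """Two-cluster scene with an aligned ECM bridge and protruding cells.

    The reflection channel carries an isotropic background fiber field
    (density ``config.fiber_density``) outside a corridor joining the two
    clusters, and corridor fibers at density ``bridge_fiber_density x
    bridge_density_multiplier`` aligned (concentration ``bridge_kappa``)
    with the inter-cluster axis. The F-actin channel draws protruding-cell
    rods near the cluster rims whose orientations concentrate around the
    bridge axis when ``treated`` and are uniform otherwise. Hoechst/PI
    stacks render the cluster nuclei with the planted dead fraction.
    ``truth.roi_suggestion`` is a cell-free rectangle at the corridor
    midpoint avoiding artefact discs.

    The corridor runs along +x; place the two cluster centers on one
    horizontal line (the default layout does).
    """
    centers_um = config.cluster_centers_um or config.default_two_cluster_centers()
    if len(centers_um) != 2:
        raise ValueError("a bridge scene needs exactly two cluster centers")
    nz, h, w = config.image_shape
    px = config.pixel_size_xy
    centers_px = [(c[2] / px, c[1] / px) for c in centers_um]  # (x, y)
    region = _corridor_region(config, centers_px, corridor_width_um)
    roi_w_px = max(1, um_to_px(roi_size_um[0], px))
    if region[3] - region[2] < roi_w_px:
        raise ValueError("corridor narrower than the requested ROI")

    truth = SceneTruth(artefact_mask=_artefact_mask(config))
    length_px = config.fiber_length_um / px
    rod_px = factin_rod_length_um / px
    area_units = (h * w * px**2) / 1.0e4
    corr_area_units = ((region[1] - region[0]) * (region[3] - region[2])
                       * px**2) / 1.0e4
    axis_angle = 0.0  # corridor laid along +x

    rng_r = _rng(config.seed, "reflection")
    reflection = np.zeros(config.image_shape, dtype=float)
    corridor_mask = np.zeros(config.section_shape, dtype=bool)
    corridor_mask[int(region[0]):int(region[1]),
                  int(region[2]):int(region[3])] = True
    r_px = (config.cluster_diameter_um / 2.0) / px
    for z in range(nz):
        sec = reflection[z]
        # isotropic background field outside the corridor
        bg = np.zeros_like(sec)
        n_bg = rng_r.poisson(config.fiber_density * area_units)
        segs = _draw_fibers(bg, n_bg, 0.0, 0.0, length_px,
                            config.fiber_peak, rng_r, z=z)
        bg[corridor_mask] = 0.0
        # keep only background fibers that survive corridor clearing
        truth.fiber_segments.extend(
            s for s in segs
            if not corridor_mask[int((s.a[0] + s.b[0]) / 2),
                                 int((s.a[1] + s.b[1]) / 2)])
        # aligned corridor fibers
        n_corr = rng_r.poisson(bridge_fiber_density * bridge_density_multiplier
                               * corr_area_units)
        truth.fiber_segments.extend(_draw_fibers(
            sec, n_corr, axis_angle, bridge_kappa, length_px,
            config.fiber_peak, rng_r, region=region, z=z))
        np.maximum(sec, bg, out=sec)
        # cluster bodies scatter some reflection signal
        for (cx, cy) in centers_px:
            rr, cc = disk((cy, cx), r_px, shape=sec.shape)
            sec[rr, cc] = np.maximum(sec[rr, cc], 0.3 * config.fiber_peak)
        _stamp_artefacts(sec, config)
    reflection = _apply_noise(reflection, config, rng_r)

    # cluster bodies are F-actin bright; the truth mask marks them (with
    # a safety margin) for exclusion during protruding-cell analysis
    cluster_mask = np.zeros(config.section_shape, dtype=bool)
    for (cx, cy) in centers_px:
        rr, cc = disk((cy, cx), r_px + 2, shape=config.section_shape)
        cluster_mask[rr, cc] = True

    # protruding-cell rods on the corridor-facing rims
    rng_f = _rng(config.seed, "factin")
    factin = np.zeros(config.image_shape, dtype=float)
    for z in range(nz):
        for (cx, cy) in centers_px:
            rr, cc = disk((cy, cx), r_px, shape=config.section_shape)
            factin[z][rr, cc] = 0.6 * config.fiber_peak
        if treated:
            angles = sample_axial_vonmises(axis_angle, factin_kappa,
                                           cells_per_section, rng_f)
        else:
            angles = rng_f.uniform(0.0, 180.0, size=cells_per_section)
        z_angles = []
        for k, ang in enumerate(angles):
            cx, cy = centers_px[k % 2]
            toward = 1.0 if cx < (centers_px[0][0] + centers_px[1][0]) / 2 else -1.0
            bx = cx + toward * (r_px + rod_px * 0.8)
            by = cy + rng_f.uniform(-corridor_width_um / 2, corridor_width_um / 2) / px
            th = np.deg2rad(ang)
            dx, dy = np.cos(th) * rod_px / 2, -np.sin(th) * rod_px / 2
            r0, c0 = int(round(by - dy)), int(round(bx - dx))
            r1, c1 = int(round(by + dy)), int(round(bx + dx))
            r0, r1 = np.clip([r0, r1], 0, h - 1)
            c0, c1 = np.clip([c0, c1], 0, w - 1)
            if (r0, c0) == (r1, c1):
                continue
            rr, cc, val = line_aa(r0, c0, r1, c1)
            np.maximum.at(factin[z], (rr, cc), val * config.fiber_peak)
            z_angles.append(float(ang))
        truth.factin_angles_per_z.append(z_angles)
        truth.per_cell_orientation.extend(z_angles)
    factin = _apply_noise(factin, config, rng_f)

    # viability channels for the two clusters; skipping them leaves empty
    # background stacks (the screen images viability on dedicated stacks)
    if render_viability:
        h_img, p_img, via_truth = generate_cluster_nuclei(config, centers_um)
        truth.nuclei = via_truth.nuclei
    else:
        empty = _apply_noise(np.zeros(config.image_shape), config,
                             _rng(config.seed, "hoechst"))
        empty_pi = _apply_noise(np.zeros(config.image_shape), config,
                                _rng(config.seed, "pi"))
        h_img = VolumeImage(empty, px, config.z_step, "hoechst")
        p_img = VolumeImage(empty_pi, px, config.z_step, "pi")

    truth.cluster_mask = cluster_mask
    truth.roi_suggestion = interspheroid_roi(
        centers_px[0], centers_px[1], roi_size_um[0], roi_size_um[1],
        px, config.section_shape, exclusion=truth.artefact_mask)

    refl = VolumeImage(reflection, px, config.z_step, "reflection")
    fact = VolumeImage(factin, px, config.z_step, "factin")
    return BridgeScene(reflection=refl, factin=fact, hoechst=h_img,
                       pi=p_img, truth=truth, config=config)
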