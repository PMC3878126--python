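"""Synthetic LGE left-atrium phantom with known ground truth.

The phantom emulates the anatomy and intensity statistics a scar
segmentation method faces on late-gadolinium-enhancement CMR of the
left atrium: an ellipsoidal blood pool with two pulmonary-vein tubes, a
2.5 mm wall, enhancing scar/fibrosis patches whose mean intensity sits
a configurable number of blood-pool SDs above the blood-pool mean
(~2.1 SD for diffuse pre-ablation fibrosis, ~4.7 SD for focal
post-ablation scar), a bright navigator-beam band crossing the right PV
wall, and an enhancing aortic-wall tube separated from the atrium by a
background gap.  It also emits the "manual" auxiliary masks the
semi-automatic methods need (wall delineation, a healthy-wall region,
an enhanced region) and simulated observer segmentations for consensus
building, so the complete benchmark runs without patient data.

Everything is deterministic given the spec and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .imaging_io import BinaryMask, Volume3D
from .wall_model import dilate_mm

def _patch_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Anchor directions for the scar patches: an equatorial ring.

    Ablation injury typically forms contiguous lesion lines encircling
    the pulmonary-vein ostia, so the patch anchors are spread evenly in
    azimuth (with a little seeded jitter in azimuth and elevation) and
    neighbouring patches overlap into one connected lesion belt.
    """
    theta = 2.0 * np.pi * np.arange(n) / n + rng.uniform(-0.1, 0.1, n)
    elev = rng.uniform(-0.15, 0.15, n)
    return np.stack([np.cos(theta), np.sin(theta), elev], axis=1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity statistics and confounders of one phantom case.

    Intensity units are arbitrary; what matters is the scar enhancement
    level, expressed in blood-pool SDs above the blood-pool mean
    (``scar_level_sd``), and the contrast of wall and background.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)
    la_semi_axes_mm: tuple[float, float, float] = (34.0, 28.0, 22.0)
    pv_tube_radius_mm: float = 5.5
    pv_tube_reach_mm: float = 54.0
    pv_tube_offset_mm: tuple[float, float] = (6.0, 5.0)  # (y, z) of tube axes
    wall_thickness_mm: float = 2.5

    blood_mean: float = 100.0
    blood_sd: float = 15.0
    wall_mean: float = 70.0
    wall_sd: float = 17.0
    background_mean: float = 40.0
    background_sd: float = 10.0

    scar_level_sd: float = 4.7          # SDs above blood-pool mean
    scar_spread_sd: float = 0.5         # within-lesion spread, blood-SD units
    n_patches: int = 8
    patch_radius_mm: tuple[float, float] = (12.0, 15.0)

    navigator: bool = True
    navigator_level_sd: float = 4.0
    navigator_halfwidth_mm: float = 1.5
    aortic: bool = True
    aortic_level_sd: float = 3.0
    aortic_radius_mm: float = 8.5       # outer radius of the aortic wall
    aortic_wall_mm: float = 2.5
    aortic_gap_mm: float = 4.5          # background gap to the LA endocardium

    noise_model: str = "gaussian"       # or "rician"
    extra_noise_sd: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named study conditions: diffuse "pre" fibrosis or focal "post" scar.

    Enhancement means follow the reported per-centre enhancement
    quality: ~2.1 SD above blood pool pre-ablation, ~4.7 SD
    post-ablation.
    """
    if name == "pre":
        return PhantomSpec(scar_level_sd=2.1, seed=seed, **overrides)
    if name == "post":
        return PhantomSpec(scar_level_sd=4.7, seed=seed, **overrides)
    raise ValueError(f"unknown preset {name!r} (expected 'pre' or 'post')")


@dataclass(frozen=True)
class PhantomCase:
    """A generated phantom: the volume, truth masks and auxiliary masks."""

    spec: PhantomSpec
    volume: Volume3D
    endo: BinaryMask
    wall_gt: BinaryMask
    scar_gt: BinaryMask
    patches: tuple[BinaryMask, ...]
    region_masks: tuple[BinaryMask, ...]
    artefacts: dict
    healthy_region: BinaryMask
    enhanced_region: BinaryMask

    @property
    def wall_manual(self) -> BinaryMask:
        """Observer wall delineation: the true wall (artefact-free of the
        aorta by construction; the navigator beam does cross it, as it
        crosses the real PV wall)."""
        return self.wall_gt


def _grids(spec: PhantomSpec):
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing)
    origin = -(shape - 1) * spacing / 2.0  # centre the grid at 0
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return np.meshgrid(*axes, indexing="ij"), tuple(origin)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one phantom case (bitwise deterministic for a given spec)."""
    (X, Y, Z), origin = _grids(spec)
    spacing = spec.spacing
    rng = np.random.default_rng(spec.seed)

    a, b, c = spec.la_semi_axes_mm
    endo_data = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    yoff, zoff = spec.pv_tube_offset_mm
    r2 = spec.pv_tube_radius_mm ** 2
    tube = ((Y - yoff) ** 2 + (Z - zoff) ** 2 <= r2)
    endo_data |= tube & (X >= 0) & (X <= spec.pv_tube_reach_mm)
    endo_data |= (((Y + yoff) ** 2 + (Z - zoff) ** 2 <= r2)
                  & (X <= 0) & (X >= -spec.pv_tube_reach_mm))
    endo = BinaryMask(endo_data, spacing, origin, role="endocardium")

    wall = dilate_mm(endo, spec.wall_thickness_mm)
    wall_gt = wall.with_data(wall.data & ~endo_data, role="wall")

    # scar patches: balls around surface anchor points, clipped to the wall
    dirs = _patch_directions(spec.n_patches, rng)
    radii = rng.uniform(*spec.patch_radius_mm, size=spec.n_patches)
    patches = []
    for d, r in zip(dirs, radii):
        d = d / np.linalg.norm(d)
        scale = 1.0 / np.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2 + (d[2] / c) ** 2)
        cx, cy, cz = d * scale  # point on the ellipsoid surface
        ball = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r ** 2
        patch = ball & wall_gt.data
        if not patch.any():
            raise ValueError("scar patch does not intersect the wall")
        patches.append(BinaryMask(patch, spacing, origin, role="scar"))
    scar_data = np.logical_or.reduce([p.data for p in patches]) \
        if patches else np.zeros(spec.shape, dtype=bool)
    scar_gt = BinaryMask(scar_data, spacing, origin, role="scar")
    region_masks = tuple(dilate_mm(p, 2.0).with_data(
        dilate_mm(p, 2.0).data, role="region") for p in patches)

    # confounders
    artefacts = {}
    nav_data = np.zeros(spec.shape, dtype=bool)
    if spec.navigator:
        slab = (np.abs(Y - yoff) <= spec.navigator_halfwidth_mm) \
            & (X >= 25.0) & (X <= spec.pv_tube_reach_mm + 4.0)
        nav_data = slab & ~endo_data & ~scar_data
        artefacts["navigator"] = BinaryMask(nav_data, spacing, origin,
                                            role="artefact")
    ao_wall = np.zeros(spec.shape, dtype=bool)
    ao_blood = np.zeros(spec.shape, dtype=bool)
    if spec.aortic:
        axis_y = -(b + spec.aortic_radius_mm + spec.wall_thickness_mm
                   + spec.aortic_gap_mm)
        rr = np.sqrt(X ** 2 + (Y - axis_y) ** 2)
        ao_wall = (rr <= spec.aortic_radius_mm) \
            & (rr > spec.aortic_radius_mm - spec.aortic_wall_mm)
        ao_blood = rr <= spec.aortic_radius_mm - spec.aortic_wall_mm
        artefacts["aortic"] = BinaryMask(ao_wall, spacing, origin,
                                         role="artefact")

    # intensities: sample each tissue class around its mean
    data = rng.normal(spec.background_mean, spec.background_sd,
                      size=spec.shape)
    n_blood = int(endo_data.sum())
    data[endo_data] = rng.normal(spec.blood_mean, spec.blood_sd, size=n_blood)
    healthy_wall = wall_gt.data & ~scar_data
    data[healthy_wall] = rng.normal(spec.wall_mean, spec.wall_sd,
                                    size=int(healthy_wall.sum()))
    scar_mean = spec.blood_mean + spec.scar_level_sd * spec.blood_sd
    scar_sd = spec.scar_spread_sd * spec.blood_sd
    data[scar_data] = rng.normal(scar_mean, scar_sd, size=int(scar_data.sum()))
    if spec.aortic:
        data[ao_blood] = rng.normal(spec.blood_mean, spec.blood_sd,
                                    size=int(ao_blood.sum()))
        level = spec.blood_mean + spec.aortic_level_sd * spec.blood_sd
        data[ao_wall] = rng.normal(level, spec.background_sd,
                                   size=int(ao_wall.sum()))
    if spec.navigator:
        level = spec.blood_mean + spec.navigator_level_sd * spec.blood_sd
        data[nav_data] = rng.normal(level, spec.background_sd,
                                    size=int(nav_data.sum()))
    if spec.extra_noise_sd > 0:
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, spec.extra_noise_sd, size=spec.shape)
        elif spec.noise_model == "rician":
            data = np.sqrt(
                (data + rng.normal(0.0, spec.extra_noise_sd, size=spec.shape)) ** 2
                + rng.normal(0.0, spec.extra_noise_sd, size=spec.shape) ** 2)
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
    volume = Volume3D(data, spacing, origin)

    # auxiliary "manual" masks derived from truth
    exclusion = dilate_mm(scar_gt, 2.5).data.copy()
    if spec.navigator:
        exclusion |= dilate_mm(artefacts["navigator"], 2.5).data
    healthy_region = BinaryMask(wall_gt.data & ~exclusion, spacing, origin,
                                role="region")
    if patches:
        largest = max(patches, key=lambda p: p.count)
        enhanced_region = largest.with_data(largest.data, role="region")
    else:
        enhanced_region = scar_gt.with_data(scar_gt.data, role="region")

    return PhantomCase(spec, volume, endo, wall_gt, scar_gt, tuple(patches),
                       region_masks, artefacts, healthy_region,
                       enhanced_region)


def scar_prior_for(spec: PhantomSpec) -> tuple[float, float]:
    """The (mean, sd) scar/blood-ratio prior implied by a phantom spec.

    This plays the role of the training stage of the ratio-prior method:
    the prior is learned from cases with known scar, which for phantoms
    means directly from the generating statistics.
    """
    mean = (spec.blood_mean + spec.scar_level_sd * spec.blood_sd) / spec.blood_mean
    sd = spec.scar_spread_sd * spec.blood_sd / spec.blood_mean
    return mean, sd


def generate_raters(truth: BinaryMask, sens: float = 0.9, spec_: float = 0.95,
                    n_raters: int = 3, seed: int = 0) -> list[BinaryMask]:
    """Simulated observers: keep foreground w.p. ``sens``, background w.p.
    ``spec_``, independently per voxel and rater."""
    if not (0.5 < sens <= 1.0) or not (0.5 < spec_ <= 1.0):
        raise ValueError("sensitivity and specificity must lie in (0.5, 1]")
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(seed)
    out = []
    t = truth.data
    for _ in range(n_raters):
        u = rng.random(truth.shape)
        rater = np.where(t, u < sens, u >= spec_)
        out.append(truth.with_data(rater, role="scar"))
    return out
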