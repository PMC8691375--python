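"""Synthetic aneurysm phantoms and serial-scan cohorts with known truth.

Phantoms are tubes of varying radius swept along a straight or circular-arc
axis, voxelized by center inclusion, emulating the 40-90 mm infra-renal
aneurysms seen in surveillance: a Gaussian **bulge** models a focal
aneurysm sac, a sinusoidal **lobulation** models multi-lobed sacs (which
raise the undulation index), and a finite **bend radius** models aortic
tortuosity (which lowers the minimum centerline radius of curvature).
Every phantom carries its analytic truth (axis, diameter, and for
hull-tractable solids the exact volume terms of the undulation index).

Cohorts pair each synthetic patient's baseline geometry with a follow-up
interval (log-normal, median 2.0 years, floored at the 244-day serial-scan
rule) and an annual growth drawn from a known linear law of the three
geometric features plus Gaussian noise, so model recovery is exactly
measurable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.spatial import cKDTree

from .geometry_features import GeometricFeatures, extract_all_features
from .growth_analysis import (DAYS_PER_YEAR, MIN_INTERVAL_DAYS, GrowthRecord,
                              categorize_growth)
from .volume_io import VoxelVolume

log = logging.getLogger(__name__)

_INF = math.inf

#: Hard cap on grid side length; phantoms must fit or generation errors out.
MAX_GRID = 192


@dataclass(frozen=True)
class BulgeSpec:
    """Focal Gaussian widening of the tube radius."""

    offset_mm: float = 0.0     # center offset from the tube midpoint
    amplitude_mm: float = 0.0  # added radius at the bulge peak
    width_mm: float = 12.0     # Gaussian sigma along the axis


@dataclass(frozen=True)
class LobulationSpec:
    """Periodic sin^2 widening producing a multi-lobed sac."""

    amplitude_mm: float = 0.0
    n_lobes: int = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one tube phantom (all lengths in mm)."""

    base_radius_mm: float
    length_mm: float
    bend_radius_mm: float = _INF
    bulge: BulgeSpec = BulgeSpec()
    lobulation: LobulationSpec = LobulationSpec()
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.base_radius_mm > 0 or not self.length_mm > 0:
            raise ValueError("base radius and length must be positive")
        if math.isfinite(self.bend_radius_mm) and self.bend_radius_mm <= self.base_radius_mm:
            raise ValueError("bend radius must exceed the tube radius")
        if self.bulge.amplitude_mm < 0 or self.lobulation.amplitude_mm < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def is_straight(self) -> bool:
        return math.isinf(self.bend_radius_mm)

    def radius_profile(self, s: np.ndarray) -> np.ndarray:
        """Tube radius r(s) for arclength s in [0, length]."""
        s = np.asarray(s, dtype=float)
        r = np.full_like(s, self.base_radius_mm)
        if self.bulge.amplitude_mm > 0:
            c = self.length_mm / 2.0 + self.bulge.offset_mm
            r = r + self.bulge.amplitude_mm * np.exp(
                -0.5 * ((s - c) / self.bulge.width_mm) ** 2)
        if self.lobulation.amplitude_mm > 0 and self.lobulation.n_lobes > 0:
            r = r + self.lobulation.amplitude_mm * np.sin(
                math.pi * self.lobulation.n_lobes * s / self.length_mm) ** 2
        return r


@dataclass
class PhantomTruth:
    """Analytic ground truth carried alongside a generated phantom."""

    axis_mm: np.ndarray                 # true axis points, (M, 3) mm
    diameter_mm: float                  # 2 * max tube radius
    bend_radius_mm: float               # inf for straight phantoms
    volume_mm3: float | None = None     # analytic solid volume (straight only)
    hull_volume_mm3: float | None = None  # hull-tractable solids only
    ui: float | None = None             # analytic undulation index if known


def _axis_points(spec: PhantomSpec, n: int) -> np.ndarray:
    """n points along the phantom axis in untranslated (z, y, x) mm coords."""
    s = np.linspace(0.0, spec.length_mm, n)
    if spec.is_straight:
        return np.column_stack([s, np.zeros(n), np.zeros(n)])
    rb = spec.bend_radius_mm
    theta = spec.length_mm / rb
    phi = (s / spec.length_mm - 0.5) * theta
    z = rb * np.sin(phi)
    y = rb * (1.0 - np.cos(phi))
    return np.column_stack([z, y, np.zeros(n)])


def generate_phantom(spec: PhantomSpec, max_grid: int = MAX_GRID) -> tuple[VoxelVolume, PhantomTruth]:
    """Voxelize one tube phantom and return it with its analytic truth.

    Voxelization is by center inclusion: a voxel is foreground when its
    center lies inside the swept solid.  Straight phantoms are placed with
    their axis through exact voxel centers so that thinning recovers the
    axis without parity artifacts.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    n_axis = max(64, int(4 * spec.length_mm / spacing.min()))
    axis = _axis_points(spec, n_axis)
    s_axis = np.linspace(0.0, spec.length_mm, n_axis)
    r_axis = spec.radius_profile(s_axis)
    rmax = float(r_axis.max())

    lo = axis.min(axis=0) - rmax - 2 * spacing
    hi = axis.max(axis=0) + rmax + 2 * spacing
    # translate so the grid starts at voxel index 0, axis kept on voxel centers
    shift = np.ceil(-lo / spacing) * spacing
    axis_t = axis + shift
    shape = np.ceil((hi + shift) / spacing).astype(int) + 1
    if np.any(shape > max_grid):
        raise ValueError(
            f"solid exceeds grid: needs {tuple(shape)} voxels at spacing "
            f"{tuple(spacing)} (max {max_grid} per side)")

    zc = np.arange(shape[0]) * spacing[0]
    yc = np.arange(shape[1]) * spacing[1]
    xc = np.arange(shape[2]) * spacing[2]
    if spec.is_straight:
        # axis at (y0, x0), along z
        y0, x0 = axis_t[0, 1], axis_t[0, 2]
        z0 = axis_t[0, 0]
        zz = zc[:, None, None] - z0
        rr = np.sqrt((yc[None, :, None] - y0) ** 2 + (xc[None, None, :] - x0) ** 2)
        r_of_z = np.interp(zz[:, 0, 0], s_axis, r_axis, left=-1.0, right=-1.0)
        mask = (zz >= 0) & (zz <= spec.length_mm) & (rr <= r_of_z[:, None, None])
    else:
        centers = np.stack(np.meshgrid(zc, yc, xc, indexing="ij"), axis=-1).reshape(-1, 3)
        tree = cKDTree(axis_t)
        dist, idx = tree.query(centers, workers=-1)
        mask = (dist <= r_axis[idx]).reshape(tuple(shape))

    volume = VoxelVolume(mask, tuple(spacing))
    if not mask.any():
        raise ValueError("phantom produced an empty mask (grid/spacing mismatch)")

    truth = PhantomTruth(
        axis_mm=axis_t,
        diameter_mm=2.0 * rmax,
        bend_radius_mm=spec.bend_radius_mm,
    )
    if spec.is_straight:
        vol_analytic = float(math.pi * integrate.simpson(r_axis ** 2, x=s_axis))
        truth.volume_mm3 = vol_analytic
        if spec.bulge.amplitude_mm == 0 and spec.lobulation.amplitude_mm == 0:
            # a plain circular cylinder is convex: hull volume equals volume
            truth.hull_volume_mm3 = vol_analytic
            truth.ui = 0.0
    return volume, truth


# ---------------------------------------------------------------------------
# Dumbbell phantom (hull-tractable by solid geometry)
# ---------------------------------------------------------------------------

@dataclass
class DumbbellTruth:
    """Exact solid-geometry truth for a two-sphere dumbbell."""

    volume_mm3: float
    hull_volume_mm3: float
    ui: float


def dumbbell_truth(radius: float, separation: float, neck_radius: float) -> DumbbellTruth:
    """Analytic volume, hull volume and UI of the dumbbell solid.

    Two spheres of equal ``radius`` with centers ``separation`` apart,
    joined by a coaxial cylinder of ``neck_radius``.  The union volume adds,
    beyond the two spheres, the cylinder part outside both spheres
    (including the thin annular ring where the sphere narrows inside the
    cylinder).  The convex hull of two equal spheres is the capsule:
    cylinder of the sphere radius plus two hemispherical caps.
    """
    if neck_radius >= radius:
        raise ValueError("neck must be thinner than the spheres")
    if separation <= 2 * radius:
        raise ValueError("spheres must be disjoint")
    r, d, rn = radius, separation, neck_radius
    v_sphere = 4.0 / 3.0 * math.pi * r ** 3
    x0 = math.sqrt(r ** 2 - rn ** 2)  # where the cylinder exits a sphere
    v_free = math.pi * rn ** 2 * (d - 2 * x0)
    # annular cylinder-minus-sphere ring for x in (x0, r], per sphere:
    # integral of pi*(rn^2 - (r^2 - x^2)) dx
    v_ring = math.pi * ((rn ** 2 - r ** 2) * (r - x0) + (r ** 3 - x0 ** 3) / 3.0)
    volume = 2 * v_sphere + v_free + 2 * v_ring
    hull = math.pi * r ** 2 * d + v_sphere  # capsule: cylinder + 2 hemispheres
    return DumbbellTruth(volume_mm3=volume, hull_volume_mm3=hull,
                         ui=1.0 - volume / hull)


def generate_dumbbell(radius: float = 20.0, separation: float = 80.0,
                      neck_radius: float = 5.0,
                      spacing: float = 1.0) -> tuple[VoxelVolume, DumbbellTruth]:
    """Voxelized dumbbell (spheres joined by a thin cylinder) along axis 0."""
    truth = dumbbell_truth(radius, separation, neck_radius)
    sp = float(spacing)
    margin = radius + 2 * sp
    length = separation + 2 * margin
    nz = int(math.ceil(length / sp)) + 1
    nxy = int(math.ceil(2 * margin / sp)) + 1
    z = np.arange(nz) * sp
    y = np.arange(nxy) * sp
    x = np.arange(nxy) * sp
    # sphere centers on exact voxel centers
    c0 = sp * round(margin / sp)
    cyx = sp * round(margin / sp)
    z1, z2 = c0, c0 + separation
    zz = z[:, None, None]
    rr2 = (y[None, :, None] - cyx) ** 2 + (x[None, None, :] - cyx) ** 2
    in_s1 = (zz - z1) ** 2 + rr2 <= radius ** 2
    in_s2 = (zz - z2) ** 2 + rr2 <= radius ** 2
    in_neck = (zz >= z1) & (zz <= z2) & (rr2 <= neck_radius ** 2)
    return VoxelVolume(in_s1 | in_s2 | in_neck, (sp, sp, sp)), truth


def make_cuboid(shape: tuple[int, int, int] = (20, 30, 10),
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                pad: int = 2) -> VoxelVolume:
    """A filled rectangular cuboid mask (a convex solid, UI exactly 0)."""
    grid = tuple(s + 2 * pad for s in shape)
    mask = np.zeros(grid, dtype=bool)
    mask[pad:pad + shape[0], pad:pad + shape[1], pad:pad + shape[2]] = True
    return VoxelVolume(mask, spacing)


def make_sphere(radius_mm: float = 25.0, spacing: float = 1.0) -> VoxelVolume:
    """A voxelized ball (center-inclusion) centered on a voxel center."""
    sp = float(spacing)
    n = int(math.ceil(2 * (radius_mm + 2 * sp) / sp)) + 1
    c = sp * (n // 2)
    ax = np.arange(n) * sp
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_mm ** 2
    return VoxelVolume(mask, (sp, sp, sp))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Default growth law, chosen so that on the default phantom bank the
#: marginal feature-growth rank correlations reproduce the clinical pattern
#: (about +0.25 for diameter, +0.38 for UI, -0.5 for min RC) with the
#: growth distribution centered near 3.7 mm/yr at noise SD 1.5 mm/yr.
DEFAULT_COEFFICIENTS = {"intercept": 1.24, "apd": 0.033, "ui": 12.5, "min_rc": -0.028}


@dataclass
class CohortTruth:
    """Generating law of a synthetic serial-scan cohort."""

    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = 1.5               # mm/yr
    median_interval_yr: float = 2.0
    log_interval_sd: float = 0.97       # matches a 1.0-3.7 yr interquartile range
    min_interval_days: int = MIN_INTERVAL_DAYS
    n_patients: int = 192
    rc_cap_mm: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        missing = {"intercept", "apd", "ui", "min_rc"} - set(self.coefficients)
        if missing:
            raise ValueError(f"coefficients missing {sorted(missing)}")

    def expected_growth(self, f: GeometricFeatures) -> float:
        c = self.coefficients
        rc = min(f.min_rc, self.rc_cap_mm)
        return c["intercept"] + c["apd"] * f.apd + c["ui"] * f.ui + c["min_rc"] * rc


def default_phantom_bank(spacing: float = 1.5) -> list[PhantomSpec]:
    """A bank of bent, variably lobulated/bulged tubes spanning 40-90 mm.

    Tube radii cover the clinical aneurysm diameter range, bend radii span
    the clinical min-RC range (~30-90 mm), and lobulation/bulge amplitudes
    vary the undulation index, so the three predictors vary with limited
    collinearity across the bank.
    """
    sp = (spacing, spacing, spacing)
    bank: list[PhantomSpec] = []
    radii = (18.0, 24.0, 30.0, 36.0)
    bends = (60.0, 80.0, 105.0)
    # lobulation amplitude relative to the tube radius, assigned in a
    # Latin-square pattern over radius x bend so the three extracted
    # features are not confounded with one another across the bank; gentle
    # arc angles (length / bend radius < 1.2 rad) keep the bow-shaped hull
    # gap from dominating UI, which would otherwise tie UI to the bend
    lob_rel = (0.0, 0.15, 0.3)
    for i_r, radius in enumerate(radii):
        for i_b, bend in enumerate(bends):
            rel = lob_rel[(i_r + i_b) % 3]
            bank.append(PhantomSpec(
                base_radius_mm=radius, length_mm=70.0, bend_radius_mm=bend,
                lobulation=LobulationSpec(amplitude_mm=rel * radius, n_lobes=3),
                spacing=sp))
    # two focally bulged sacs round out the shape variety
    bank.append(PhantomSpec(base_radius_mm=20.0, length_mm=70.0, bend_radius_mm=60.0,
                            bulge=BulgeSpec(amplitude_mm=12.0, width_mm=14.0), spacing=sp))
    bank.append(PhantomSpec(base_radius_mm=28.0, length_mm=70.0, bend_radius_mm=105.0,
                            bulge=BulgeSpec(amplitude_mm=8.0, width_mm=10.0,
                                            offset_mm=10.0), spacing=sp))
    return bank


_FEATURE_CACHE: dict[PhantomSpec, GeometricFeatures] = {}


def bank_features(bank: Sequence[PhantomSpec]) -> list[GeometricFeatures]:
    """Extract (and memoize) geometric features for each phantom in a bank."""
    out = []
    for spec in bank:
        if spec not in _FEATURE_CACHE:
            volume, _ = generate_phantom(spec)
            _FEATURE_CACHE[spec] = extract_all_features(volume)
        out.append(_FEATURE_CACHE[spec])
    return out


def draw_interval_days(truth: CohortTruth, rng: np.random.Generator) -> int:
    """Follow-up interval: log-normal with the configured median, floored
    at the cohort's minimum serial-scan gap (redrawn until admissible)."""
    mu = math.log(truth.median_interval_yr)
    while True:
        years = float(rng.lognormal(mean=mu, sigma=truth.log_interval_sd))
        days = int(round(years * DAYS_PER_YEAR))
        if days >= truth.min_interval_days:
            return days


def generate_cohort(truth: CohortTruth, bank: Sequence[PhantomSpec],
                    features: Sequence[GeometricFeatures] | None = None) -> list[GrowthRecord]:
    """Simulate a serial-scan cohort from the generating law.

    Each patient draws a phantom from the bank (its extracted features are
    the baseline geometry), a follow-up interval, and an annual growth
    ``linear(features) + N(0, noise_sd)``; the follow-up APD is
    back-computed from the growth identity.  Fully determined by
    ``truth.seed``.
    """
    if len(bank) == 0:
        raise ValueError("phantom bank must be non-empty")
    if features is None:
        features = bank_features(bank)
    if len(features) != len(bank):
        raise ValueError("features must align with the phantom bank")
    rng = np.random.default_rng(truth.seed)
    records = []
    for i in range(truth.n_patients):
        f = features[int(rng.integers(len(bank)))]
        days = draw_interval_days(truth, rng)
        growth = truth.expected_growth(f) + float(rng.normal(0.0, truth.noise_sd))
        records.append(GrowthRecord(
            patient_id=f"synthetic-{i:04d}",
            baseline=f,
            apd_followup=f.apd + growth * (days / DAYS_PER_YEAR),
            days_between=days,
            annual_growth=growth,
            category=categorize_growth(growth),
        ))
    return records
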