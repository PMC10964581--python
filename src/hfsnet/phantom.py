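"""Synthetic three-phase CT phantom generator with exact ground truth.

Generates cases that emulate the statistical structure of a clinical HCC
cohort: a liver (ellipsoid compartment), 1-10 spheroidal lesions per case
spanning <2 cm to >5 cm with the cohort's size mixture, phase-dependent
lesion contrast (arterial hyperenhancement, portal-venous hypodensity),
partial-volume smoothing and additive acquisition noise.  Every lesion's
maximum in-plane diameter is controlled to within one voxel, so the
generator doubles as ground truth for the size-routing and evaluation
logic downstream.

Intensities are HU-like compartment means; the cohort's real intensity
statistics are unknown, so defaults are chosen for radiological
plausibility, not fidelity to any scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import max_pairwise_distance
from .imaging_io import DynamicCTVolume, LabelVolume, PHASE_NAMES

# cohort size mixture: fractions of lesions <2, 2-3, 3-5, >5 cm
DEFAULT_SIZE_MIXTURE = (93 / 595, 133 / 595, 178 / 595, 191 / 595)
SIZE_BIN_NAMES = ("<2cm", "2-3cm", "3-5cm", ">5cm")
# fraction of cases carrying a single tumor
P_SINGLE_TUMOR = 0.84

DEFAULT_PHASE_CONTRAST = {
    # HU-like compartment means per phase
    "background": {"non_contrast": 0.0, "arterial": 0.0, "portal_venous": 0.0},
    "liver": {"non_contrast": 55.0, "arterial": 70.0, "portal_venous": 110.0},
    "lesion": {"non_contrast": 45.0, "arterial": 110.0, "portal_venous": 70.0},
}


@dataclass
class PhantomSpec:
    """Recipe for one synthetic case."""

    grid_shape: tuple = (64, 256, 256)          # (slices, rows, cols)
    spacing_mm: tuple = (2.5, 1.4, 1.4)          # (z, y, x)
    liver_center_mm: tuple | None = None         # defaults to grid center
    liver_semiaxes_mm: tuple = (60.0, 90.0, 110.0)
    n_tumors: int = 1
    tumor_diameters_cm: tuple = (3.0,)           # target max in-plane diameters
    phase_contrast: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_PHASE_CONTRAST.items()})
    noise_sd: float = 10.0                       # additive Gaussian, HU
    smoothing_sigma: tuple = (0.3, 0.6, 0.6)     # partial volume, voxels
    surface_perturbation: float = 0.0            # optional radial jitter (frac)
    seed: int = 0
    case_id: str = "phantom"

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.liver_center_mm is None:
            self.liver_center_mm = tuple(
                (n - 1) * s / 2 for n, s in zip(self.grid_shape,
                                                self.spacing_mm))
        self.tumor_diameters_cm = tuple(float(d)
                                        for d in self.tumor_diameters_cm)
        if self.n_tumors < 0:
            raise ValueError("n_tumors must be >= 0")
        if self.n_tumors != len(self.tumor_diameters_cm):
            raise ValueError("n_tumors must equal len(tumor_diameters_cm)")
        if any(d <= 0 for d in self.tumor_diameters_cm):
            raise ValueError("tumor diameters must be positive")


# profile presets: a desk-scale "tiny" grid for CPU work, and the full grid
PROFILES = {
    "full": dict(grid_shape=(64, 256, 256), spacing_mm=(2.5, 1.4, 1.4),
                 liver_semiaxes_mm=(60.0, 90.0, 110.0), max_diameter_cm=7.0,
                 max_tumors=10),
    "tiny": dict(grid_shape=(32, 64, 64), spacing_mm=(2.5, 1.4, 1.4),
                 liver_semiaxes_mm=(32.0, 38.0, 40.0), max_diameter_cm=5.5,
                 max_tumors=3),
}


@dataclass
class PhantomCase:
    """A generated case: aligned 3-phase volume plus ground truth."""

    case_id: str
    volume: DynamicCTVolume
    liver_mask: np.ndarray          # boolean
    tumor_labels: LabelVolume       # instance ids 1..n_tumors
    manifest: pd.DataFrame          # one row per tumor
    spec: PhantomSpec


class PlacementError(RuntimeError):
    """A tumor could not be placed fully inside the liver."""


# -- case generation ---------------------------------------------------------

def _voxel_coords_mm(grid_shape, spacing_mm):
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(coords, center, semiaxes):
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semiaxes))
    return q <= 1.0


def _tumor_mask(coords, center, semiaxes_mm, angle, perturb, rng):
    """Voxelize a spheroid with optional in-plane rotation and low-amplitude
    radial perturbation (shrink-only, so the target diameter is an upper
    bound that the leading axis still attains)."""
    zc, yc, xc = coords
    dz = zc - center[0]
    dy = yc - center[1]
    dx = xc - center[2]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dy + sa * dx   # rotated in-plane axes
    v = -sa * dy + ca * dx
    q = (dz / semiaxes_mm[0]) ** 2 + (u / semiaxes_mm[1]) ** 2 \
        + (v / semiaxes_mm[2]) ** 2
    if perturb > 0:
        # smooth multiplicative field in [1-2*perturb, 1] shrinking the radius
        noise = rng.standard_normal(q.shape)
        noise = ndimage.gaussian_filter(noise, sigma=2.0)
        noise = (noise - noise.min()) / max(float(np.ptp(noise)), 1e-12)
        q = q / (1.0 - 2.0 * perturb * noise) ** 2
    return q <= 1.0


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Build one synthetic case; deterministic given ``spec`` (incl. seed).

    Lesions are spheroids whose longest axis lies in-plane with the
    requested maximum diameter (voxelization error at most one in-plane
    voxel); the z semi-axis is shorter so the 3D maximum diameter equals
    the in-plane one.  Raises :class:`PlacementError` when a lesion cannot
    be placed fully inside the liver without touching earlier lesions.
    """
    rng = np.random.default_rng(spec.seed)
    coords = _voxel_coords_mm(spec.grid_shape, spec.spacing_mm)
    liver = _ellipsoid_mask(coords, spec.liver_center_mm,
                            spec.liver_semiaxes_mm)
    if not liver.any():
        raise ValueError("liver geometry produces an empty mask")

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    rows = []
    c0 = np.asarray(spec.liver_center_mm)
    A = np.asarray(spec.liver_semiaxes_mm)
    for tid, d_cm in enumerate(spec.tumor_diameters_cm, start=1):
        # grow the major semi-axis by a quarter in-plane voxel to offset
        # voxel-center quantization at the lesion tips
        r = d_cm * 10.0 / 2.0 + 0.25 * spec.spacing_mm[2]  # mm
        ry = r * rng.uniform(0.85, 1.0)
        rz = min(r * rng.uniform(0.55, 0.8), A[0] * 0.85)
        angle = rng.uniform(0.0, np.pi)
        placed = False
        for _ in range(300):
            # candidate center uniform in the liver's inscribed box
            frac = rng.uniform(-0.8, 0.8, size=3)
            center = c0 + frac * A / np.sqrt(3.0)
            mask = _tumor_mask(coords, center, (rz, ry, r), angle,
                               spec.surface_perturbation, rng)
            if not mask.any():
                continue
            if np.any(mask & ~liver) or np.any(labels[mask] > 0):
                continue
            labels[mask] = tid
            centroid = [float(np.mean(ix))
                        for ix in np.nonzero(labels == tid)]
            rows.append({"tumor_id": tid, "diameter_cm": d_cm,
                         "centroid_z": centroid[0], "centroid_y": centroid[1],
                         "centroid_x": centroid[2]})
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {d_cm:.1f} cm tumor inside the liver "
                f"(grid {spec.grid_shape}, liver semi-axes "
                f"{spec.liver_semiaxes_mm} mm)")

    # intensities: piecewise-constant compartments + smoothing + noise
    pc = spec.phase_contrast
    phase_arrays = {}
    for phase in PHASE_NAMES:
        vol = np.full(spec.grid_shape, pc["background"][phase])
        vol[liver] = pc["liver"][phase]
        vol[labels > 0] = pc["lesion"][phase]
        if any(s > 0 for s in spec.smoothing_sigma):
            vol = ndimage.gaussian_filter(vol, sigma=spec.smoothing_sigma)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        phase_arrays[phase] = vol

    volume = DynamicCTVolume(phase_arrays["non_contrast"],
                             phase_arrays["arterial"],
                             phase_arrays["portal_venous"],
                             spec.spacing_mm, case_id=spec.case_id)
    manifest = pd.DataFrame(
        rows, columns=["tumor_id", "diameter_cm", "centroid_z",
                       "centroid_y", "centroid_x"])
    manifest.insert(0, "case_id", spec.case_id)
    return PhantomCase(spec.case_id, volume, liver,
                       LabelVolume(labels, "tumor", spec.spacing_mm),
                       manifest, spec)


# -- cohort generation -------------------------------------------------------

_BIN_RANGES_CM = ((1.0, 2.0), (2.0, 3.0), (3.0, 5.0), (5.0, None))


def size_bin_of(diameter_cm: float) -> int:
    """Bin index in the cohort's size strata (left-closed boundaries)."""
    if diameter_cm < 2.0:
        return 0
    if diameter_cm < 3.0:
        return 1
    if diameter_cm < 5.0:
        return 2
    return 3


def draw_cohort_plan(n_cases: int, size_mixture=None, seed: int = 0,
                     profile: str = "full",
                     p_single: float = P_SINGLE_TUMOR) -> pd.DataFrame:
    """Draw per-case tumor counts and diameters (no volumes).

    Tumor count is 1 with probability ``p_single``, otherwise 2 plus a
    geometric tail capped by the profile.  Each tumor's size bin is drawn
    from ``size_mixture`` and its diameter uniformly within the bin.
    Multi-tumor draws are rejection-sampled against a packing budget (total
    lesion sphere volume at most 40% of the liver ellipsoid volume) so
    every planned case is geometrically placeable; the budget only binds
    on small grids.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    mixture = np.asarray(DEFAULT_SIZE_MIXTURE if size_mixture is None
                         else size_mixture, dtype=np.float64)
    if mixture.shape != (4,) or not np.isclose(mixture.sum(), 1.0):
        raise ValueError("size_mixture must be 4 probabilities summing to 1")
    prof = PROFILES[profile]
    dmax = prof["max_diameter_cm"]
    semi_cm = np.asarray(prof["liver_semiaxes_mm"]) / 10.0
    budget_cm3 = 0.4 * 4.0 / 3.0 * np.pi * np.prod(semi_cm)
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(n_cases):
        if rng.uniform() < p_single:
            n_t = 1
        else:
            n_t = min(2 + rng.geometric(0.55) - 1, prof["max_tumors"])
        for _ in range(200):
            bins = rng.choice(4, size=n_t, p=mixture)
            diams = []
            for b in bins:
                lo, hi = _BIN_RANGES_CM[b]
                hi = dmax if hi is None else min(hi, dmax)
                diams.append(float(rng.uniform(lo, hi)))
            vol = sum(np.pi / 6.0 * d ** 3 for d in diams)
            if n_t == 1 or vol <= budget_cm3:
                break
        else:
            raise PlacementError(
                f"no feasible multi-tumor draw for case {i} under profile "
                f"{profile!r}")
        for tid, (b, d) in enumerate(zip(bins, diams), start=1):
            rows.append({"case_id": f"case_{i:04d}", "tumor_id": tid,
                         "diameter_cm": d, "size_bin": SIZE_BIN_NAMES[b],
                         "n_tumors": n_t})
    return pd.DataFrame(rows)


def generate_cohort(n_cases: int, size_mixture=None, seed: int = 0,
                    profile: str = "full",
                    p_single: float = P_SINGLE_TUMOR,
                    **spec_overrides) -> tuple[list, pd.DataFrame]:
    """Generate ``n_cases`` phantom cases plus a cohort manifest table."""
    plan = draw_cohort_plan(n_cases, size_mixture, seed, profile, p_single)
    prof = PROFILES[profile]
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in ss.spawn(n_cases)]
    cases = []
    manifests = []
    for i, (cid, grp) in enumerate(plan.groupby("case_id", sort=True)):
        case = None
        for retry in range(6):  # rare packing dead-ends: re-place, same sizes
            spec = PhantomSpec(
                grid_shape=prof["grid_shape"], spacing_mm=prof["spacing_mm"],
                liver_semiaxes_mm=prof["liver_semiaxes_mm"],
                n_tumors=len(grp),
                tumor_diameters_cm=tuple(grp["diameter_cm"]),
                seed=(case_seeds[i] + retry * 7919) % (2 ** 31),
                case_id=cid, **spec_overrides)
            try:
                case = generate_case(spec)
                break
            except PlacementError:
                if retry == 5:
                    raise
        m = case.manifest.merge(
            grp[["tumor_id", "size_bin", "n_tumors"]], on="tumor_id")
        case.manifest = m
        cases.append(case)
        manifests.append(m)
    return cases, pd.concat(manifests, ignore_index=True)


# -- self check --------------------------------------------------------------

def self_check_case(case: PhantomCase,
                    tol_px: float = 1.0) -> pd.DataFrame:
    """Re-measure every instance from its mask and compare to the manifest.

    Reports, per tumor: the longest in-plane axis (max over slices, in cm),
    the 3D maximum diameter (cm), voxels falling outside the liver, and
    violation flags (axis deviation beyond ``tol_px`` in-plane voxels, or
    any extrahepatic voxel).
    """
    labels = case.tumor_labels.labels
    sz, sy, sx = case.spec.spacing_mm
    px_cm = sy / 10.0
    rows = []
    for _, mrow in case.manifest.iterrows():
        tid = int(mrow["tumor_id"])
        where = labels == tid
        inplane_px = 0.0
        for z in np.unique(np.nonzero(where)[0]):
            yx = np.argwhere(where[z])
            inplane_px = max(inplane_px, max_pairwise_distance(yx))
        coords_mm = np.argwhere(where) * np.array([sz, sy, sx])
        d3_cm = max_pairwise_distance(coords_mm) / 10.0
        outside = int(np.count_nonzero(where & ~case.liver_mask))
        dev_px = abs(inplane_px * px_cm - mrow["diameter_cm"]) / px_cm
        rows.append({
            "tumor_id": tid,
            "requested_cm": mrow["diameter_cm"],
            "measured_inplane_cm": inplane_px * px_cm,
            "measured_3d_cm": d3_cm,
            "deviation_px": dev_px,
            "outside_liver_voxels": outside,
            "axis_violation": dev_px > tol_px,
            "containment_violation": outside > 0,
        })
    return pd.DataFrame(rows, columns=[
        "tumor_id", "requested_cm", "measured_inplane_cm", "measured_3d_cm",
        "deviation_px", "outside_liver_voxels", "axis_violation",
        "containment_violation"])
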