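"""Synthetic body-phantom cohort generator.

Builds labeled 3-D body volumes from stacked elliptical cross-sections so that
adipose-depot volumes (visceral ``VAT``, abdominal subcutaneous ``ASAT``,
gluteofemoral ``GFAT``) are analytically controllable, measures truth volumes
and anthropometrics from the voxel grid, and simulates prevalent / incident
cardiometabolic disease labels on top of the cohort table.

The population model is log-normal in a global girth factor (``size_factor``)
with an independent latent fat-distribution axis (``vat_asat_shape``) that
raises VAT while lowering ASAT at a fixed abdominal perimeter: the outer
waistline trades width against depth so a tape measure is blind to it while a
two-view silhouette is not. Marginal depot means/SDs per sex are matched to a
large population MRI reference (see :data:`POPULATION_REFERENCE`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage import measure as skmeasure

__all__ = [
    "LABELS",
    "DENSITY_KG_PER_L",
    "DEFAULT_SPACING",
    "POPULATION_REFERENCE",
    "PhantomParams",
    "BodyVolume",
    "PopulationConfig",
    "DiseaseEffects",
    "DEFAULT_DISEASE_EFFECTS",
    "generate_phantom",
    "measure_truth_depots",
    "measure_anthropometrics",
    "simulate_diseases",
    "sample_params",
    "analytic_cohort_table",
    "generate_cohort",
    "save_body_volume",
    "load_body_volume",
]

# ---------------------------------------------------------------------------
# constants

LABELS = {
    "background": 0,
    "lean": 1,
    "vat": 2,
    "asat": 3,
    "gfat": 4,
    "other_fat": 5,
}

#: tissue densities, kg per liter (standard literature constants)
DENSITY_KG_PER_L = {"lean": 1.06, "fat": 0.92}

#: (z, y, x) voxel pitch in mm of the target MRI resampling grid
DEFAULT_SPACING = (3.0, 2.232, 2.232)

#: per-sex marginal targets: heights/ages and depot volume means +- SD (liters)
POPULATION_REFERENCE = {
    "male": dict(
        height_mm=1763.0, height_sd_mm=66.0, age=65.2, age_sd=7.7,
        vat_l=5.0, vat_sd=2.3, asat_l=5.9, asat_sd=2.5, gfat_l=9.3, gfat_sd=2.6,
        weight_kg=83.8, bmi=27.1, waist_cm=94.6, hip_cm=100.9,
    ),
    "female": dict(
        height_mm=1628.0, height_sd_mm=63.5, age=63.8, age_sd=7.5,
        vat_l=2.6, vat_sd=1.5, asat_l=7.9, asat_sd=3.3, gfat_l=11.3, gfat_sd=3.2,
        weight_kg=68.9, bmi=26.1, waist_cm=82.8, hip_cm=100.9,
    ),
}

#: SD of ln(size_factor) in the sampled population (shared across sexes)
SIGMA_SIZE = 0.12

#: multiplier of vat_asat_shape on ln(width/depth aspect) of the abdominal wall
SHAPE_ASPECT_COEF = 0.15

# axial region boundaries as fractions of standing height (superior -> inferior)
_REGIONS = dict(
    head=(0.00, 0.12), neck=(0.12, 0.155), chest=(0.155, 0.32),
    abdomen=(0.32, 0.50), hip=(0.50, 0.58), thigh=(0.58, 0.78), shin=(0.78, 1.0),
)
_ARM_SPAN = (0.17, 0.42)  # arms end above the waist window so the waist contour is trunk-only
_VAT_WINDOW = (0.32, 0.54)
_ASAT_WINDOW = (0.28, 0.56)
_GFAT_HIP_WINDOW = (0.50, 0.58)
_GFAT_THIGH_WINDOW = (0.58, 0.78)
_GFAT_HIP_SHARE = 0.35  # buttock fraction of GFAT; the rest wraps the thighs

# lean-core cross-section area anchors: (height fraction, area / (H^2 * size_factor))
_CORE_AREA_ANCHORS = (
    (0.155, 0.0150), (0.22, 0.0165), (0.30, 0.0090), (0.34, 0.0073),
    (0.48, 0.0073), (0.52, 0.0115), (0.58, 0.0135),
)
_Q_ANCHORS = ((0.155, 0.58), (0.32, 0.55), (0.50, 0.53), (0.58, 0.48))  # depth/width

_WALL_MM = 8.0          # lean abdominal-wall ring thickness
_CHEST_FAT_FRACTION = 0.12  # other_fat ring area relative to chest core


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PhantomParams:
    """Latent parameters of one synthetic body."""

    sex: str
    height_mm: float
    size_factor: float = 1.0
    vat_asat_shape: float = 0.0
    gfat_factor: float = 1.0
    arm_prop: float = 1.0
    leg_prop: float = 1.0
    torso_prop: float = 1.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not 1300.0 <= self.height_mm <= 2100.0:
            raise ValueError("height_mm outside [1300, 2100]")
        if self.size_factor <= 0 or self.gfat_factor <= 0:
            raise ValueError("scale factors must be positive")
        if min(self.arm_prop, self.leg_prop, self.torso_prop) <= 0:
            raise ValueError("proportions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class BodyVolume:
    """A 3-D body image: axis order (z: superior->inferior, y: ant->post, x: left->right)."""

    voxels: np.ndarray
    spacing_mm: tuple
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing components must be positive")
        if self.labels is not None and self.labels.shape != self.voxels.shape:
            raise ValueError("labels shape mismatch")

    @property
    def voxel_volume_l(self) -> float:
        sz, sy, sx = self.spacing_mm
        return sz * sy * sx / 1e6


# ---------------------------------------------------------------------------
# closed-form population model


def _depot_model(sex: str) -> dict:
    """Per-sex log-normal dispersion/base constants derived from the reference marginals.

    Depot intents:  VAT = b_v * SF^2 * exp(+k_v s) * (H/H_ref)
                    ASAT = b_a * SF^2 * exp(-k_a s) * (H/H_ref)
                    GFAT = b_g * GF * SF^2 * (H/H_ref),  GF ~ LN(0, sigma_g)
    with SF ~ LN(0, SIGMA_SIZE), s ~ N(0, 1). The k's are solved so the total
    log-variance matches the reference CV; bases are mean-corrected so that the
    population expectation equals the reference mean.
    """
    ref = POPULATION_REFERENCE[sex]
    out = {"height_ref": ref["height_mm"]}
    four_s2 = 4.0 * SIGMA_SIZE**2
    for depot, mean_key, sd_key in (
        ("vat", "vat_l", "vat_sd"), ("asat", "asat_l", "asat_sd"), ("gfat", "gfat_l", "gfat_sd"),
    ):
        mean, sd = ref[mean_key], ref[sd_key]
        sln2 = np.log1p((sd / mean) ** 2)
        k = float(np.sqrt(max(sln2 - four_s2, 1e-6)))
        out[f"k_{depot}"] = k
        out[f"base_{depot}"] = mean / float(np.exp(2.0 * SIGMA_SIZE**2 + 0.5 * k * k))
    return out


def depot_intents(params: PhantomParams) -> tuple:
    """Intended (VAT_L, ASAT_L, GFAT_L) for a parameter set, before rasterization."""
    m = _depot_model(params.sex)
    hfac = params.height_mm / m["height_ref"]
    sf2 = params.size_factor**2
    s = params.vat_asat_shape
    vat = m["base_vat"] * sf2 * np.exp(m["k_vat"] * s) * hfac
    asat = m["base_asat"] * sf2 * np.exp(-m["k_asat"] * s) * hfac
    gfat = m["base_gfat"] * params.gfat_factor * sf2 * hfac
    return float(vat), float(asat), float(gfat)


# ---------------------------------------------------------------------------
# geometry helpers


def ellipse_perimeter_mm(a: float, b: float) -> float:
    """Ramanujan approximation of an ellipse perimeter (semi-axes in mm)."""
    a, b = float(a), float(b)
    h = ((a - b) / (a + b)) ** 2 if a + b > 0 else 0.0
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def _perimeter_slope(q):
    """g(q) with P(a, q*a) = a * g(q); linear in the major semi-axis."""
    q = np.asarray(q, dtype=float)
    h = ((1.0 - q) / (1.0 + q)) ** 2
    return np.pi * (1.0 + q) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def _interp_anchors(f, anchors):
    xs = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    return np.interp(f, xs, ys)


def _window(f, lo, hi, alpha: float = 0.5):
    """Tukey (tapered-cosine) window on [lo, hi): flat mid-section, cosine shoulders.

    A flat top keeps per-slice fat areas near volume/length so the waistline is
    not artificially peaked the way a pure Hann profile would make it.
    """
    f = np.asarray(f, dtype=float)
    t = (f - lo) / (hi - lo)
    w = np.zeros_like(f)
    inside = (t >= 0) & (t < 1)
    ti = t[inside]
    wi = np.ones_like(ti)
    lo_t = ti < alpha / 2
    hi_t = ti >= 1 - alpha / 2
    wi[lo_t] = 0.5 * (1.0 - np.cos(2.0 * np.pi * ti[lo_t] / alpha))
    wi[hi_t] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (1.0 - ti[hi_t]) / alpha))
    w[inside] = wi
    return w


def _normalized_window(f, dz_mm, lo, hi):
    """Window scaled so that sum(w * dz) == 1 on the realized slice grid."""
    w = _window(f, lo, hi)
    total = w.sum() * dz_mm
    if total <= 0:
        return w
    return w / total


# ---------------------------------------------------------------------------
# phantom construction


def _torso_profiles(params: PhantomParams, f, dz_mm):
    """Per-slice outer semi-axes and ring radii for the head/neck/torso column.

    Returns dict of arrays over the slice fractions ``f`` (NaN outside the column).
    """
    H = params.height_mm
    sf = params.size_factor
    vat_l, asat_l, gfat_l = depot_intents(params)
    vat_mm3, asat_mm3, gfat_mm3 = vat_l * 1e6, asat_l * 1e6, gfat_l * 1e6
    # outer wall is sized from the shape-neutral intents: the fat-distribution
    # axis moves only the interior VAT/ASAT boundary and the wall aspect, never
    # the wall perimeter (a tape measure cannot see it)
    vat0_l, asat0_l, _ = depot_intents(replace(params, vat_asat_shape=0.0))

    n = f.size
    a_out = np.full(n, np.nan)
    b_out = np.full(n, np.nan)
    area_v = np.zeros(n)
    area_s = np.zeros(n)
    area_g_hip = np.zeros(n)
    area_chest_fat = np.zeros(n)

    in_col = f < _REGIONS["hip"][1]  # head through hip form one centered column
    torso = (f >= _REGIONS["chest"][0]) & in_col

    # fat per-slice area targets from normalized windows
    wv = _normalized_window(f, dz_mm, *_VAT_WINDOW)
    wa = _normalized_window(f, dz_mm, *_ASAT_WINDOW)
    wg_hip = _normalized_window(f, dz_mm, *_GFAT_HIP_WINDOW)
    area_v = vat_mm3 * wv
    area_s = asat_mm3 * wa
    area_g_hip = _GFAT_HIP_SHARE * gfat_mm3 * wg_hip

    # lean core area profile (mm^2), scaled by girth factor and torso proportion
    core = _interp_anchors(f, _CORE_AREA_ANCHORS) * H * H * sf * params.torso_prop
    chest = (f >= _REGIONS["chest"][0]) & (f < _REGIONS["chest"][1])
    area_chest_fat[chest] = _CHEST_FAT_FRACTION * core[chest]

    # interior content determines the nominal outer ellipse; the shape axis then
    # re-aspects the abdominal wall at *fixed perimeter*
    content = core + vat0_l * 1e6 * wv + asat0_l * 1e6 * wa + area_g_hip + area_chest_fat
    content = content + 0.06 * core  # abdominal-wall/skin allowance
    q_nom = _interp_anchors(f, _Q_ANCHORS)
    shape_local = _window(f, *_VAT_WINDOW)  # shape axis acts on the belly only
    q_eff = np.clip(q_nom * np.exp(SHAPE_ASPECT_COEF * params.vat_asat_shape * shape_local),
                    0.32, 0.95)
    a_nom = np.sqrt(np.maximum(content, 1.0) / (np.pi * q_nom))
    perim = a_nom * _perimeter_slope(q_nom)
    a1 = perim / _perimeter_slope(q_eff)
    b1 = q_eff * a1
    a_out[torso] = a1[torso]
    b_out[torso] = b1[torso]

    # head: cosine dome; neck: narrow cylinder (both mildly girth-dependent)
    gir = sf**0.25
    head = f < _REGIONS["head"][1]
    dome = np.sqrt(np.clip(np.sin(np.pi * np.clip(f / (2 * _REGIONS["head"][1]), 0, 0.5)), 0, 1))
    a_out[head] = 0.048 * H * gir * np.maximum(dome[head], 0.15)
    b_out[head] = 0.058 * H * gir * np.maximum(dome[head], 0.15)
    neck = (f >= _REGIONS["neck"][0]) & (f < _REGIONS["neck"][1])
    a_out[neck] = 0.030 * H * gir
    b_out[neck] = 0.036 * H * gir

    # smooth the outer column so region boundaries blend (sigma ~ 9 mm)
    col = in_col
    sigma = max(9.0 / dz_mm, 0.5)
    a_out[col] = gaussian_filter1d(a_out[col], sigma, mode="nearest")
    b_out[col] = gaussian_filter1d(b_out[col], sigma, mode="nearest")

    return dict(a=a_out, b=b_out, area_v=area_v, area_s=area_s,
                area_g_hip=area_g_hip, area_chest_fat=area_chest_fat,
                gfat_mm3=gfat_mm3, in_col=in_col)


def _ring_radii(area_outer, *ring_areas, min_core=0.03):
    """Normalized radii of nested rings, outermost ring listed first.

    Given the outer ellipse area and ring areas (outer -> inner), returns for
    each ring its inner normalized radius; rings are clipped so a lean core of
    normalized radius >= sqrt(min_core) always survives.
    """
    radii = []
    r2 = np.ones_like(np.asarray(area_outer, dtype=float))
    for area in ring_areas:
        frac = np.clip(np.asarray(area, dtype=float) / np.maximum(area_outer, 1.0), 0.0, None)
        r2 = np.clip(r2 - frac, min_core, None)
        radii.append(np.sqrt(r2))
    return radii


def generate_phantom(params: PhantomParams, spacing=DEFAULT_SPACING, seed: int = 0) -> BodyVolume:
    """Rasterize a labeled body volume from latent parameters.

    The body is a stack of elliptical cross-sections: a head/neck/torso column
    with an interior VAT core and subcutaneous ASAT ring on abdominal slices, a
    GFAT shell over hips and thighs, two legs and two arms. Deterministic given
    ``(params, seed)``; the seed drives only the scalar-intensity noise.
    """
    sz, sy, sx = (float(v) for v in spacing)
    if min(sz, sy, sx) <= 0:
        raise ValueError("spacing must be positive")
    H = params.height_mm
    nz = int(round(H / sz))
    if nz < 8:
        raise ValueError("empty phantom")
    f = (np.arange(nz) + 0.5) * sz / H  # height fraction per slice

    prof = _torso_profiles(params, f, sz)
    a, b = prof["a"], prof["b"]

    # ring radii inside the torso column (outermost first): ASAT, lean wall, VAT
    area_outer = np.pi * np.nan_to_num(a) * np.nan_to_num(b)
    wall_area = _WALL_MM * ellipse_perimeter_mm(1.0, 1.0) * np.sqrt(
        np.maximum(area_outer, 1.0) / np.pi) / 2.0  # ~ perimeter * wall thickness
    hipg = prof["area_g_hip"]
    r_asat, r_gfat_hip, r_wall, r_vat = _ring_radii(
        np.maximum(area_outer, 1.0), prof["area_s"], hipg, wall_area, prof["area_v"])
    r_chest_fat = _ring_radii(np.maximum(area_outer, 1.0), prof["area_chest_fat"])[0]

    # limbs ------------------------------------------------------------------
    sfL = np.sqrt(params.size_factor)
    thigh_lo, thigh_hi = _REGIONS["thigh"]
    shin_lo = _REGIONS["shin"][0]
    r_thigh_core = np.where(
        (f >= thigh_lo) & (f < shin_lo),
        (0.048 - 0.014 * (f - thigh_lo) / (shin_lo - thigh_lo)) * H * sfL * params.leg_prop,
        0.0,
    )
    wg_thigh = _normalized_window(f, sz, *_GFAT_THIGH_WINDOW)
    gfat_thigh_area = (1.0 - _GFAT_HIP_SHARE) * prof["gfat_mm3"] * wg_thigh
    r_thigh_out = np.sqrt(r_thigh_core**2 + gfat_thigh_area / (2.0 * np.pi))
    r_shin = np.where(f >= shin_lo, 0.028 * H * sfL * params.leg_prop, 0.0)

    hip_sel = ~np.isnan(a) & (f >= _REGIONS["hip"][0])
    a_hip_bottom = a[hip_sel][-1] if hip_sel.any() else 0.1 * H
    x_leg = max(0.52 * a_hip_bottom, float(r_thigh_out.max()) + 1.0)

    arm_lo, arm_hi = _ARM_SPAN
    r_arm = np.where((f >= arm_lo) & (f < arm_hi), 0.030 * H * sfL * params.arm_prop, 0.0)

    # grid extents -----------------------------------------------------------
    a_max = np.nanmax(a)
    arm_reach = np.nanmax(np.where(r_arm > 0, np.nan_to_num(a) + 1.8 * r_arm, 0.0))
    half_x = max(a_max, arm_reach, x_leg + r_thigh_out.max(), x_leg + r_shin.max()) + 4 * sx
    half_y = np.nanmax(b) + 4 * sy
    nx = 2 * int(np.ceil(half_x / sx)) + 1
    ny = 2 * int(np.ceil(half_y / sy)) + 1
    xs = (np.arange(nx) - nx // 2) * sx
    ys = (np.arange(ny) - ny // 2) * sy
    X, Y = np.meshgrid(xs, ys)  # (ny, nx)

    lab = np.zeros((nz, ny, nx), dtype=np.uint8)
    L = LABELS
    chest_lo, chest_hi = _REGIONS["chest"]
    abd_lo = _ASAT_WINDOW[0]
    for k in range(nz):
        sl = lab[k]
        if not np.isnan(a[k]) and a[k] > 0:
            rho2 = (X / a[k]) ** 2 + (Y / b[k]) ** 2
            body = rho2 <= 1.0
            rho = np.sqrt(rho2, where=body, out=np.full_like(rho2, 2.0))
            sl[body] = L["lean"]
            if chest_lo <= f[k] < chest_hi:
                sl[body & (rho > r_chest_fat[k])] = L["other_fat"]
            if f[k] >= abd_lo:
                sl[body & (rho > r_vat[k]) & (rho <= r_wall[k])] = L["vat"]
                sl[body & (rho > r_gfat_hip[k]) & (rho <= r_asat[k])] = L["gfat"]
                sl[body & (rho > r_asat[k])] = L["asat"]
        if r_arm[k] > 0 and not np.isnan(a[k]):
            cx = a[k] + 0.8 * r_arm[k]
            for sign in (-1.0, 1.0):
                arm = (X - sign * cx) ** 2 + Y**2 <= r_arm[k] ** 2
                sl[arm & (sl == 0)] = L["lean"]
        if r_thigh_out[k] > 0:
            for sign in (-1.0, 1.0):
                d2 = (X - sign * x_leg) ** 2 + Y**2
                leg = d2 <= r_thigh_out[k] ** 2
                core = d2 <= r_thigh_core[k] ** 2
                sl[leg & (sl == 0)] = L["gfat"]
                sl[core] = L["lean"]
        if r_shin[k] > 0:
            for sign in (-1.0, 1.0):
                shin = (X - sign * x_leg) ** 2 + Y**2 <= r_shin[k] ** 2
                sl[shin & (sl == 0)] = L["lean"]

    if not lab.any():
        raise ValueError("empty phantom")

    # scalar intensities: MRI-fat-phase-like contrast plus Gaussian noise
    rng = np.random.default_rng(seed)
    vox = np.zeros(lab.shape, dtype=np.float32)
    vox[lab == L["lean"]] = 100.0
    fat_mask = (lab == L["vat"]) | (lab == L["asat"]) | (lab == L["gfat"]) | (lab == L["other_fat"])
    vox[fat_mask] = 160.0
    if params.noise_sd > 0:
        vox += params.noise_sd * rng.standard_normal(size=vox.shape, dtype=np.float32)
    return BodyVolume(voxels=vox, spacing_mm=(sz, sy, sx), labels=lab)


# ---------------------------------------------------------------------------
# measurements


def measure_truth_depots(vol: BodyVolume) -> tuple:
    """(VAT_L, ASAT_L, GFAT_L, VAT/ASAT) from the label grid; exact voxel counting."""
    if vol.labels is None:
        raise ValueError("labels required")
    vv = vol.voxel_volume_l
    counts = np.bincount(vol.labels.ravel(), minlength=6)
    vat = counts[LABELS["vat"]] * vv
    asat = counts[LABELS["asat"]] * vv
    gfat = counts[LABELS["gfat"]] * vv
    if counts[LABELS["asat"]] == 0:
        raise ValueError("ratio undefined")
    return float(vat), float(asat), float(gfat), float(vat / asat)


def label_volumes_l(vol: BodyVolume) -> dict:
    """Per-label volumes in liters (exact voxel counting)."""
    if vol.labels is None:
        raise ValueError("labels required")
    vv = vol.voxel_volume_l
    counts = np.bincount(vol.labels.ravel(), minlength=6)
    return {name: float(counts[idx] * vv) for name, idx in LABELS.items()}


def slice_perimeter_mm(mask2d: np.ndarray, spacing_mm: tuple) -> float:
    """Physical perimeter of the largest marching-squares contour of a binary slice.

    The mask is lightly Gaussian-smoothed before contouring so the subpixel
    level set tracks the underlying shape instead of the voxel staircase.
    """
    from scipy.ndimage import gaussian_filter

    sy, sx = spacing_mm
    padded = np.pad(mask2d.astype(float), 2)
    padded = gaussian_filter(padded, 1.0)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour in slice")
    best = 0.0
    for c in contours:
        d = np.diff(c, axis=0)
        length = float(np.sum(np.hypot(d[:, 0] * sy, d[:, 1] * sx)))
        best = max(best, length)
    return best


_IMPEDANCE_BASE = np.array([760.0, 680.0, 700.0, 820.0, 640.0])
_IMPEDANCE_SLOPE = np.array([18.0, 15.0, 16.0, 20.0, 12.0])
_IMPEDANCE_NOISE = 15.0

_WAIST_WINDOW = (0.42, 0.50)
_HIP_WINDOW = (0.50, 0.58)


def measure_anthropometrics(vol: BodyVolume, params: PhantomParams, seed: int = 0) -> dict:
    """Derived anthropometric fields from a labeled volume.

    Height from occupied slice extent, weight from per-label voxel volumes and
    tissue densities, waist/hip from marching-squares contour perimeters at the
    widest slice of the respective z-window, and 5 bioimpedance channels as
    noisy affine functions of lean volume / height^2.
    """
    if vol.labels is None:
        raise ValueError("labels required")
    sz, sy, sx = vol.spacing_mm
    body = vol.labels > 0
    occupied = np.flatnonzero(body.any(axis=(1, 2)))
    if occupied.size == 0:
        raise ValueError("empty volume")
    z0, z1 = occupied[0], occupied[-1]
    height_cm = (z1 - z0 + 1) * sz / 10.0

    vols = label_volumes_l(vol)
    lean_l = vols["lean"]
    fat_l = vols["vat"] + vols["asat"] + vols["gfat"] + vols["other_fat"]
    weight_kg = lean_l * DENSITY_KG_PER_L["lean"] + fat_l * DENSITY_KG_PER_L["fat"]

    extent = z1 - z0 + 1
    fz = (np.arange(extent) + 0.5) / extent
    areas = body[z0 : z1 + 1].sum(axis=(1, 2))

    def widest_perimeter(window):
        lo, hi = window
        idx = np.flatnonzero((fz >= lo) & (fz < hi))
        if idx.size == 0:
            raise ValueError("no abdominal slices")
        k = idx[np.argmax(areas[idx])]
        return slice_perimeter_mm(body[z0 + k], (sy, sx)) / 10.0  # cm

    waist_cm = widest_perimeter(_WAIST_WINDOW)
    hip_cm = widest_perimeter(_HIP_WINDOW)

    height_m = height_cm / 100.0
    bmi = weight_kg / height_m**2
    lbm_index = lean_l / height_m**2
    rng = np.random.default_rng(seed)
    impedance = _IMPEDANCE_BASE - _IMPEDANCE_SLOPE * lbm_index / 10.0 \
        + rng.normal(0.0, _IMPEDANCE_NOISE, size=5)
    out = dict(height_cm=float(height_cm), weight_kg=float(weight_kg), bmi=float(bmi),
               waist_cm=float(waist_cm), hip_cm=float(hip_cm),
               whr=float(waist_cm / hip_cm))
    for i, v in enumerate(impedance, start=1):
        out[f"impedance_{i}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# disease simulation


@dataclass(frozen=True)
class DiseaseEffects:
    """Generating coefficients for one disease (sex-specific where tuples)."""

    prevalence: tuple          # (male, female) baseline prevalence
    or_ratio: tuple            # OR per SD of VAT/ASAT ratio, (male, female)
    or_bmi: float
    or_age: float
    incident_rate: float       # baseline events / person-year
    hr_ratio: tuple
    hr_bmi: float
    hr_age: float


DEFAULT_DISEASE_EFFECTS = {
    "t2d": DiseaseEffects((0.065, 0.031), (1.78, 1.97), 1.9, 1.25, 0.0021, (1.33, 1.51), 1.6, 1.2),
    "cad": DiseaseEffects((0.079, 0.020), (1.27, 1.27), 1.25, 1.7, 0.0055, (1.19, 1.09), 1.2, 1.6),
    "htn": DiseaseEffects((0.370, 0.246), (1.31, 1.23), 1.6, 1.5, 0.012, (1.25, 1.20), 1.5, 1.4),
    "chol": DiseaseEffects((0.277, 0.154), (1.15, 1.15), 1.2, 1.35, 0.010, (1.15, 1.15), 1.2, 1.3),
}

_CENTER_INTERCEPTS = {0: 0.0, 1: 0.05, 2: -0.05}


def _zscore_by_sex(values: pd.Series, sex: pd.Series) -> pd.Series:
    out = values.astype(float).copy()
    for s, grp in values.groupby(sex):
        sd = grp.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero SD within stratum")
        out.loc[grp.index] = (grp - grp.mean()) / sd
    return out


def simulate_diseases(cohort: pd.DataFrame,
                      effects: dict | None = None,
                      follow_up_median_years: float = 2.8,
                      seed: int = 0) -> pd.DataFrame:
    """Attach prevalent/incident disease labels to a cohort table.

    Prevalent flags are Bernoulli draws from a logistic model in sex-standardized
    VAT/ASAT ratio, BMI and age; incident event times among the disease-free are
    exponential with proportional hazards in the same covariates, administratively
    censored at a uniform time whose median equals ``follow_up_median_years``.
    """
    effects = DEFAULT_DISEASE_EFFECTS if effects is None else effects
    for eff in effects.values():
        vals = [*eff.prevalence, *eff.or_ratio, eff.or_bmi, eff.or_age,
                eff.incident_rate, *eff.hr_ratio, eff.hr_bmi, eff.hr_age]
        if not np.all(np.isfinite(vals)):
            raise ValueError("nonfinite coefficients")
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    male = (df["sex"] == "male").to_numpy()
    z_ratio = _zscore_by_sex(df["ratio"], df["sex"]).to_numpy()
    z_bmi = _zscore_by_sex(df["bmi"], df["sex"]).to_numpy()
    z_age = _zscore_by_sex(df["age_years"], df["sex"]).to_numpy()
    center_shift = df.get("center", pd.Series(0, index=df.index)).map(
        lambda c: _CENTER_INTERCEPTS.get(int(c) % 3, 0.0)).to_numpy()

    n = len(df)
    censor = rng.uniform(0.0, 2.0 * follow_up_median_years, size=n)
    for name, eff in effects.items():
        b0 = np.where(male, _logit(eff.prevalence[0]), _logit(eff.prevalence[1]))
        b_ratio = np.where(male, np.log(eff.or_ratio[0]), np.log(eff.or_ratio[1]))
        lp = b0 + b_ratio * z_ratio + np.log(eff.or_bmi) * z_bmi \
            + np.log(eff.or_age) * z_age + center_shift
        prevalent = rng.uniform(size=n) < _expit(lp)

        g_ratio = np.where(male, np.log(eff.hr_ratio[0]), np.log(eff.hr_ratio[1]))
        lp_haz = g_ratio * z_ratio + np.log(eff.hr_bmi) * z_bmi \
            + np.log(eff.hr_age) * z_age + center_shift
        rate = eff.incident_rate * np.exp(lp_haz)
        with np.errstate(divide="ignore"):
            t_event = np.where(rate > 0, rng.exponential(1.0, size=n) / np.maximum(rate, 1e-300),
                               np.inf)
        incident = (~prevalent) & (t_event <= censor)
        follow_up = np.where(prevalent, 0.0, np.minimum(t_event, censor))
        df[f"{name}_prevalent"] = prevalent.astype(int)
        df[f"{name}_incident"] = incident.astype(int)
        df[f"{name}_follow_up_years"] = follow_up
        df[f"{name}_event_time_years"] = np.where(incident, t_event, np.nan)
    return df


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class PopulationConfig:
    """Stated-world population parameters (reference marginals by default)."""

    female_fraction: float = 0.51
    sigma_size: float = SIGMA_SIZE
    noise_sd: float = 5.0
    n_centers: int = 3
    follow_up_median_years: float = 2.8
    spacing_mm: tuple = DEFAULT_SPACING
    targets: dict = field(default_factory=lambda: POPULATION_REFERENCE)


def sample_params(n: int, config: PopulationConfig | None = None, seed: int = 0):
    """Draw latent parameters and demographics for ``n`` participants.

    Returns (list of PhantomParams, base DataFrame with id/sex/age/center).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    config = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.uniform(size=n) < config.female_fraction, "female", "male")
    params, rows = [], []
    for i in range(n):
        sex = str(sexes[i])
        ref = config.targets[sex]
        height = float(np.clip(rng.normal(ref["height_mm"], ref["height_sd_mm"]), 1310, 2090))
        p = PhantomParams(
            sex=sex,
            height_mm=height,
            size_factor=float(np.exp(rng.normal(0.0, config.sigma_size))),
            vat_asat_shape=float(rng.normal()),
            gfat_factor=float(np.exp(rng.normal(0.0, _gfat_sigma(sex)))),
            noise_sd=config.noise_sd,
        )
        params.append(p)
        rows.append(dict(id=f"P{i:06d}", sex=sex,
                         age_years=float(rng.normal(ref["age"], ref["age_sd"])),
                         center=int(rng.integers(config.n_centers))))
    return params, pd.DataFrame(rows)


def _gfat_sigma(sex: str) -> float:
    ref = POPULATION_REFERENCE[sex]
    sln2 = np.log1p((ref["gfat_sd"] / ref["gfat_l"]) ** 2)
    return float(np.sqrt(max(sln2 - 4.0 * SIGMA_SIZE**2, 1e-6)))


# approximate lean body volumes (L) at size_factor 1 for the analytic pathway
_LEAN_REF_L = {"male": 62.0, "female": 46.0}
_OTHER_FAT_REF_L = {"male": 2.6, "female": 2.2}


def analytic_cohort_table(n: int, config: PopulationConfig | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Closed-form cohort table (no voxel grids) for large-n statistical simulations.

    Depot volumes come from the same latent model as the rasterizer; waist and
    hip use the continuous ellipse formulas at the window peaks, plus ~0.8 cm
    of tape-measurement noise. Suitable for epidemiological recovery runs where
    building thousands of volumes would be wasteful.
    """
    config = config or PopulationConfig()
    params, base = sample_params(n, config, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for p in params:
        vat, asat, gfat = depot_intents(p)
        H, sf = p.height_mm, p.size_factor
        lean = _LEAN_REF_L[p.sex] * sf * (H / POPULATION_REFERENCE[p.sex]["height_mm"])
        other = _OTHER_FAT_REF_L[p.sex] * sf
        weight = lean * DENSITY_KG_PER_L["lean"] + (vat + asat + gfat + other) * DENSITY_KG_PER_L["fat"]
        height_cm = H / 10.0

        # waist: abdominal plateau cross-section content (Tukey flat-top ~ vol / (0.75 len)),
        # re-aspected at fixed perimeter exactly like the rasterizer
        vat0, asat0, _ = depot_intents(replace(p, vat_asat_shape=0.0))
        organ_area = 0.0073 * H * H * sf
        area = organ_area * 1.06 \
            + vat0 * 1e6 / (0.75 * (_VAT_WINDOW[1] - _VAT_WINDOW[0]) * H) \
            + asat0 * 1e6 / (0.75 * (_ASAT_WINDOW[1] - _ASAT_WINDOW[0]) * H)
        q0 = 0.55
        a0 = np.sqrt(area / (np.pi * q0))
        waist = ellipse_perimeter_mm(a0, q0 * a0) / 10.0 + rng.normal(0.0, 0.8)
        hip_area = 0.0125 * H * H * sf * 1.06 + _GFAT_HIP_SHARE * gfat * 1e6 / (
            0.75 * (_GFAT_HIP_WINDOW[1] - _GFAT_HIP_WINDOW[0]) * H)
        ah = np.sqrt(hip_area / (np.pi * 0.48))
        hip = ellipse_perimeter_mm(ah, 0.48 * ah) / 10.0 + rng.normal(0.0, 0.8)

        height_m = height_cm / 100.0
        imp = _IMPEDANCE_BASE - _IMPEDANCE_SLOPE * (lean / height_m**2) / 10.0 \
            + rng.normal(0.0, _IMPEDANCE_NOISE, size=5)
        row = dict(vat_l=vat, asat_l=asat, gfat_l=gfat, ratio=vat / asat,
                   weight_kg=weight, height_cm=height_cm, bmi=weight / height_m**2,
                   waist_cm=waist, hip_cm=hip, whr=waist / hip)
        row.update({f"impedance_{i}": float(v) for i, v in enumerate(imp, start=1)})
        rows.append(row)
    df = pd.concat([base.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    return simulate_diseases(df, follow_up_median_years=config.follow_up_median_years,
                             seed=seed + 2)


def generate_cohort(n: int, config: PopulationConfig | None = None, seed: int = 0,
                    out_dir=None, write_nifti: bool = False, volume_consumer=None):
    """Build a full synthetic cohort of labeled volumes plus its cohort table.

    Returns ``(volumes, cohort)`` where ``volumes`` is a list of
    :class:`BodyVolume` and ``cohort`` a DataFrame with truth depot volumes,
    anthropometrics and simulated disease labels. With ``out_dir`` the table is
    written as CSV (and volumes as NIfTI if ``write_nifti``).

    For large cohorts pass ``volume_consumer(index, participant_id, vol)``:
    each volume is handed to the consumer and *not* retained (the returned
    volume list is empty), keeping memory flat.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    config = config or PopulationConfig()
    params, base = sample_params(n, config, seed)
    volumes, rows = [], []
    for i, p in enumerate(params):
        vol = generate_phantom(p, spacing=config.spacing_mm, seed=seed + 7919 * (i + 1) % (2**31))
        vat, asat, gfat, ratio = measure_truth_depots(vol)
        anthro = measure_anthropometrics(vol, p, seed=seed + 104729 * (i + 1) % (2**31))
        row = dict(vat_l=vat, asat_l=asat, gfat_l=gfat, ratio=ratio,
                   size_factor=p.size_factor, vat_asat_shape=p.vat_asat_shape,
                   gfat_factor=p.gfat_factor, **anthro)
        rows.append(row)
        if volume_consumer is not None:
            volume_consumer(i, base["id"].iloc[i], vol)
        else:
            volumes.append(vol)
    cohort = pd.concat([base.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    cohort = simulate_diseases(cohort, follow_up_median_years=config.follow_up_median_years,
                               seed=seed + 3)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False)
        import yaml

        cfg = {"n": n, "seed": seed, "female_fraction": config.female_fraction,
               "sigma_size": config.sigma_size, "noise_sd": config.noise_sd,
               "n_centers": config.n_centers,
               "follow_up_median_years": config.follow_up_median_years,
               "spacing_mm": list(config.spacing_mm)}
        (out / "population.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
        if write_nifti:
            for pid, vol in zip(cohort["id"], volumes):
                save_body_volume(vol, out / f"{pid}.nii.gz")
    return volumes, cohort


def cohort_hash(cohort: pd.DataFrame) -> str:
    """Stable content hash of a cohort table (reproducibility checks)."""
    csv = cohort.to_csv(index=False, float_format="%.10g").encode()
    return hashlib.sha256(csv).hexdigest()


# ---------------------------------------------------------------------------
# NIfTI I/O (axis order on disk: x, y, z per NIfTI convention)


def save_body_volume(vol: BodyVolume, path) -> None:
    import nibabel as nib

    sz, sy, sx = vol.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels).transpose(2, 1, 0), affine)
    nib.save(img, str(path))
    if vol.labels is not None:
        limg = nib.Nifti1Image(vol.labels.transpose(2, 1, 0).astype(np.uint8), affine)
        p = str(path)
        suffix = ".nii.gz" if p.endswith(".nii.gz") else ".nii"
        nib.save(limg, p[: -len(suffix)] + "_labels" + suffix)


def load_body_volume(path, labels_path=None) -> BodyVolume:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    vox = np.asarray(img.dataobj).transpose(2, 1, 0)
    labels = None
    if labels_path is not None:
        limg = nib.as_closest_canonical(nib.load(str(labels_path)))
        labels = np.asarray(limg.dataobj).transpose(2, 1, 0).astype(np.uint8)
    return BodyVolume(voxels=vox, spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
                      labels=labels)
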