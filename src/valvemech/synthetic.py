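"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here with a
controllable, recoverable ground truth:

* confocal-like rasters of sinusoidally crimped fibers whose orientations
  follow a wrapped axial von-Mises-type law with concentration ``kappa``
  (``kappa = 0`` is isotropic), deformed by the affine stretch map
  ``(x, y) -> (lambda * x, lambda**-nu * y)``;
* labeled cell masks of ellipses whose circularity index has expectation
  ``base_ci + ci_slope * (lambda - 1)``, with labels stable across stretch;
* stress-stretch records drawn from the exponential Fung law plus additive
  Gaussian noise;
* a simulated two-post tensile test solving the force balance between the
  Fung tissue and two elastomeric cantilevers;
* stained-histology RGB slides with requested constituent area fractions
  inside a leaflet mask.

All generators are deterministic per seed: an identical spec and seed
reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import ellipe

from . import mechanics
from .errors import (
    DegenerateSceneError,
    EquilibriumFailureError,
    InvalidProtocolError,
    InvalidSpecError,
)
from .mechanics import PostGeometry, StressStrainCurve

#: Default transverse-contraction exponent of the affine stretch map;
#: 0.5 mimics the necking of an incompressible-ish planar strip.
DEFAULT_NU = 0.5

#: Protocol maximum stretch used to size cell layouts so that affinely
#: advected cells stay inside the frame over the whole loading ramp.
PROTOCOL_MAX_STRETCH = 1.6


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberFieldSpec:
    """Scene description for a crimped-fiber raster.

    ``orientation_concentration`` is the kappa of the wrapped axial
    distribution: fiber axis angles are drawn as half of a von Mises angle of
    concentration kappa, giving an isotropic axial law at kappa = 0 and
    alignment with the loading (+x) axis as kappa grows.
    """

    n_fibers: int = 150
    image_size: int = 256
    crimp_amplitude: float = 1.5
    crimp_wavelength: float = 64.0
    orientation_concentration: float = 2.0
    fiber_width: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise InvalidSpecError("n_fibers must be >= 1")
        if self.image_size < 64:
            raise InvalidSpecError("image_size must be >= 64")
        if not self.crimp_wavelength > 0:
            raise InvalidSpecError("crimp_wavelength must be positive")
        if self.crimp_amplitude < 0:
            raise InvalidSpecError("crimp_amplitude must be nonnegative")
        if self.orientation_concentration < 0:
            raise InvalidSpecError("orientation_concentration must be nonnegative")
        if not self.fiber_width > 0:
            raise InvalidSpecError("fiber_width must be positive")


@dataclass(frozen=True)
class CellFieldSpec:
    """Population of elliptical cells with a controllable circularity trend.

    The expected circularity index at stretch ``lam`` is
    ``base_ci + ci_slope * (lam - 1)``; per-cell, per-frame Gaussian noise of
    sd ``noise_sd`` is added on top.
    """

    n_cells: int = 50
    base_ci: float = 0.9
    ci_slope: float = -0.25
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidSpecError("n_cells must be >= 1")
        if not 0 < self.base_ci <= 1:
            raise InvalidSpecError("base_ci must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")

    def expected_ci(self, stretch: float) -> float:
        """Population-mean circularity index at a given stretch."""
        return self.base_ci + self.ci_slope * (stretch - 1.0)

    def validate_for_range(self, max_stretch: float) -> None:
        """Check that the expected CI stays in (0, 1] over [1, max_stretch]."""
        for lam in (1.0, max_stretch):
            ci = self.expected_ci(lam)
            if not 0 < ci <= 1:
                raise InvalidSpecError(
                    f"expected CI {ci:.3f} at stretch {lam:g} outside (0, 1]"
                )


@dataclass(frozen=True)
class TissueModel:
    """Fung-law tissue strip: sigma = alpha * (exp(beta * (lambda - 1)) - 1).

    ``width`` and ``thickness`` define the undeformed cross-section;
    ``rest_length`` is the grip-to-grip specimen length at lambda = 1.
    """

    alpha: float
    beta: float
    width: float = 1e-3
    thickness: float = 40e-6
    rest_length: float = 500e-6

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "width", "thickness", "rest_length"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be positive, got {getattr(self, name)!r}")

    def stress(self, stretch):
        """Nominal Fung stress at the given stretch ratio(s), Pa."""
        return mechanics.fung_stress(np.asarray(stretch, dtype=float) - 1.0, self.alpha, self.beta)

    def force(self, stretch):
        """Tensile force at the given stretch ratio(s), N (zero in compression)."""
        lam = np.asarray(stretch, dtype=float)
        return np.where(lam >= 1.0, self.stress(np.maximum(lam, 1.0)), 0.0) * (
            self.width * self.thickness
        )


def null_tissue(width: float = 1e-3, thickness: float = 40e-6, rest_length: float = 500e-6) -> TissueModel:
    """A tissue with negligible resistance (alpha at float tiny), for limit checks."""
    return TissueModel(alpha=np.finfo(float).tiny, beta=1.0, width=width, thickness=thickness, rest_length=rest_length)


# --------------------------------------------------------------------------
# fiber scenes
# --------------------------------------------------------------------------


def _sample_fiber_axes(spec: FiberFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Axial fiber angles in radians in (-pi/2, pi/2], wrapped axial law."""
    if spec.orientation_concentration == 0:
        return rng.uniform(-math.pi / 2, math.pi / 2, spec.n_fibers)
    phi = rng.vonmises(0.0, spec.orientation_concentration, spec.n_fibers)
    return phi / 2.0


def fiber_polylines(
    spec: FiberFieldSpec, stretch: float, nu: float = DEFAULT_NU, step: float = 0.35
) -> list[np.ndarray]:
    """Analytic fiber polylines (in x, y pixel coordinates) after the affine map.

    This is the ground truth behind :func:`gen_fiber_image`: the raster is a
    rendering of exactly these polylines.  Crimp is a sinusoidal perturbation
    perpendicular to each fiber axis; the affine map
    ``(x, y) -> (lam x, lam**-nu y)`` (about the image center) straightens it.
    """
    if stretch < 1.0:
        raise InvalidProtocolError(f"stretch must be >= 1, got {stretch!r}")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    centers = rng.uniform(0.0, size, (spec.n_fibers, 2))
    angles = _sample_fiber_axes(spec, rng)
    phases = rng.uniform(0.0, 2.0 * math.pi, spec.n_fibers)
    length = 0.7 * size
    t = np.arange(-length / 2.0, length / 2.0 + step, step)
    polylines = []
    c = size / 2.0
    sx, sy = stretch, stretch ** (-nu)
    for i in range(spec.n_fibers):
        ca, sa = math.cos(angles[i]), math.sin(angles[i])
        wave = spec.crimp_amplitude * np.sin(2.0 * math.pi * t / spec.crimp_wavelength + phases[i])
        x = centers[i, 0] + t * ca - wave * sa
        y = centers[i, 1] + t * sa + wave * ca
        x = c + sx * (x - c)
        y = c + sy * (y - c)
        polylines.append(np.column_stack([x, y]))
    return polylines


def gen_fiber_image(spec: FiberFieldSpec, stretch: float, nu: float = DEFAULT_NU) -> np.ndarray:
    """Render the crimped-fiber scene to a grayscale raster in [0, 1].

    Deterministic per (spec, stretch): the same arguments reproduce a
    bit-identical raster.

    Raises
    ------
    InvalidProtocolError
        If ``stretch < 1``.
    DegenerateSceneError
        If no fiber sample falls inside the frame.
    """
    polylines = fiber_polylines(spec, stretch, nu=nu)
    size = spec.image_size
    pts = np.concatenate(polylines, axis=0)
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < size - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < size - 1)
    )
    if not inside.any():
        raise DegenerateSceneError("all fibers fall outside the frame")
    pts = pts[inside]
    # bilinear splatting: nearest-pixel rounding would snap near-axis fibers
    # onto exact pixel rows/columns and bias the orientation spectrum
    c0 = np.floor(pts).astype(np.int64)
    frac = pts - c0
    canvas = np.zeros((size, size), dtype=float)
    for dy in (0, 1):
        for dx in (0, 1):
            w = (frac[:, 0] if dx else 1.0 - frac[:, 0]) * (
                frac[:, 1] if dy else 1.0 - frac[:, 1]
            )
            np.add.at(canvas, (c0[:, 1] + dy, c0[:, 0] + dx), w)
    canvas = gaussian_filter(canvas, sigma=spec.fiber_width / 2.0)
    peak = canvas.max()
    if peak > 0:
        canvas /= peak
    return canvas


def fiber_segment_angles(
    spec: FiberFieldSpec, stretch: float, nu: float = DEFAULT_NU
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment axial angles (degrees in [0, 180)) and lengths of the scene.

    Angles are measured from the +x (loading) axis toward +y, modulo 180.
    """
    angles, lengths = [], []
    for line in fiber_polylines(spec, stretch, nu=nu):
        d = np.diff(line, axis=0)
        seg_len = np.hypot(d[:, 0], d[:, 1])
        seg_ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
        angles.append(seg_ang)
        lengths.append(seg_len)
    return np.concatenate(angles), np.concatenate(lengths)


def analytic_fai(
    spec: FiberFieldSpec,
    stretch: float,
    nu: float = DEFAULT_NU,
    axis: float = 0.0,
    half_width: float = 10.0,
) -> float:
    """Ground-truth alignment index: length fraction of fiber segments whose
    axial angle lies within ``half_width`` degrees of ``axis``.

    Serves as the generator-side oracle for the image/FFT alignment index.
    """
    ang, seg_len = fiber_segment_angles(spec, stretch, nu=nu)
    dist = np.abs((ang - axis + 90.0) % 180.0 - 90.0)
    return float(seg_len[dist <= half_width].sum() / seg_len.sum())


# --------------------------------------------------------------------------
# cell scenes
# --------------------------------------------------------------------------


def _aspect_from_ci(ci: float) -> float:
    """Solve for the ellipse axis ratio q = b/a giving circularity ``ci``.

    For semi-axes a >= b with q = b/a, CI = pi^2 q / (4 E(1 - q^2)^2) with E
    the complete elliptic integral of the second kind; CI is monotone in q
    with CI(1) = 1.
    """
    if not 0 < ci <= 1:
        raise InvalidSpecError(f"circularity target {ci!r} outside (0, 1]")

    def f(q):
        return math.pi**2 * q / (4.0 * ellipe(1.0 - q * q) ** 2) - ci

    if ci >= 1.0 - 1e-12:
        return 1.0
    return brentq(f, 1e-6, 1.0, xtol=1e-12)


def gen_cell_masks(
    spec: CellFieldSpec,
    stretch: float,
    image_size: int = 768,
    nu: float = DEFAULT_NU,
    area_range: tuple[float, float] = (300.0, 600.0),
) -> np.ndarray:
    """Labeled uint16 mask of elliptical cells at one stretch level.

    Cell centroids sit on a jittered grid sized so the population stays in
    frame and disjoint up to the protocol maximum stretch; centroids are
    advected by the affine stretch map.  Labels (1..n_cells) are stable
    across stretch levels for a fixed seed.  Each cell's ellipse is shaped so
    its exact (continuous) circularity equals the spec's expected CI at this
    stretch plus the cell/frame noise draw.

    Raises
    ------
    InvalidProtocolError
        If ``stretch < 1``.
    InvalidSpecError
        If the expected CI falls outside (0, 1] at this stretch, or the
        requested population cannot be laid out disjointly.
    """
    if stretch < 1.0:
        raise InvalidProtocolError(f"stretch must be >= 1, got {stretch!r}")
    mean_ci = spec.expected_ci(stretch)
    if not 0 < mean_ci <= 1:
        raise InvalidSpecError(
            f"expected CI {mean_ci:.3f} at stretch {stretch:g} outside (0, 1]"
        )

    # stretch-independent draws: layout, per-cell size and orientation
    rng = np.random.default_rng(spec.seed)
    a_max = math.sqrt(area_range[1] / (math.pi * 0.25))  # conservative q >= 0.25
    d_min = 2.0 * a_max + 6.0
    margin = a_max + 6.0
    half = image_size / 2.0
    half_x = (half - margin) / PROTOCOL_MAX_STRETCH
    half_y = half - margin
    spacing_x = d_min
    spacing_y = d_min * PROTOCOL_MAX_STRETCH**nu  # survives transverse contraction
    nx = max(int(2 * half_x // spacing_x), 1)
    ny = max(int(2 * half_y // spacing_y), 1)
    if nx * ny < spec.n_cells:
        raise InvalidSpecError(
            f"cannot place {spec.n_cells} disjoint cells on a {nx}x{ny} grid; "
            "increase image_size or reduce n_cells"
        )
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    base = np.column_stack(
        [
            (gx.ravel() + 0.5) / nx * 2 * half_x - half_x,
            (gy.ravel() + 0.5) / ny * 2 * half_y - half_y,
        ]
    )
    order = rng.permutation(nx * ny)[: spec.n_cells]
    jitter_x = (2 * half_x / nx - d_min) / 2.0
    jitter_y = (2 * half_y / ny - spacing_y) / 2.0
    jit = rng.uniform(-1.0, 1.0, (spec.n_cells, 2)) * np.array(
        [max(jitter_x, 0.0), max(jitter_y, 0.0)]
    )
    centers = base[order] + jit
    areas = rng.uniform(*area_range, spec.n_cells)
    orientations = rng.uniform(0.0, math.pi, spec.n_cells)

    # stretch-dependent CI noise: independent across frames, reproducible
    noise_rng = np.random.default_rng([spec.seed, int(round(stretch * 1e6))])
    ci_noise = noise_rng.normal(0.0, spec.noise_sd, spec.n_cells) if spec.noise_sd > 0 else np.zeros(spec.n_cells)

    from skimage.draw import ellipse as draw_ellipse

    mask = np.zeros((image_size, image_size), dtype=np.uint16)
    c = image_size / 2.0
    sx, sy = stretch, stretch ** (-nu)
    for i in range(spec.n_cells):
        ci = float(np.clip(mean_ci + ci_noise[i], 0.02, 1.0))
        q = _aspect_from_ci(ci)
        a = math.sqrt(areas[i] / (math.pi * q))
        b = a * q
        cx = c + sx * centers[i, 0]
        cy = c + sy * centers[i, 1]
        rr, cc = draw_ellipse(
            cy, cx, b, a, shape=mask.shape, rotation=orientations[i]
        )
        mask[rr, cc] = i + 1
    return mask


# --------------------------------------------------------------------------
# stress-strain records and the two-post experiment
# --------------------------------------------------------------------------


def gen_stress_strain(
    model: TissueModel,
    n_points: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_stretch: float = PROTOCOL_MAX_STRETCH,
) -> StressStrainCurve:
    """Stress-stretch record from the Fung law with additive Gaussian noise.

    Stretch levels are evenly spaced on [1, max_stretch]; noise of sd
    ``noise_sd`` (Pa) is added independently per point.
    """
    if n_points < 3:
        raise InvalidSpecError("n_points must be >= 3")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be nonnegative")
    lam = np.linspace(1.0, max_stretch, n_points)
    sigma = np.asarray(model.stress(lam), dtype=float)
    if noise_sd > 0:
        sigma = sigma + np.random.default_rng(seed).normal(0.0, noise_sd, n_points)
    return StressStrainCurve(lam, sigma, model.width, model.thickness)


def simulate_two_post_test(
    geometry: PostGeometry,
    model: TissueModel,
    grip_displacements: Sequence[float],
) -> pd.DataFrame:
    """Quasi-static two-post tensile test of a Fung tissue strip.

    At each grip displacement ``d`` (each post carried outward by ``d``), the
    posts deflect inward by ``v`` until the tissue tension balances the
    elastic restoring force of both cantilevers:

        k * v = F_tissue(lambda),   lambda = (s0 + 2 d - 2 v) / rest_length.

    The residual is monotone in ``v`` on the physical bracket [0, d], so the
    root is unique; it is solved by bracketed root-finding and polished by
    Newton steps to drive the force residual below 1e-9 N.

    Returns a record table with columns ``step, displacement_m, deflection_m,
    separation_m, stretch, force_N``.
    """
    d_arr = np.asarray(grip_displacements, dtype=float)
    if np.any(d_arr < 0):
        raise InvalidSpecError("grip displacements must be nonnegative")
    if np.any(np.diff(d_arr) < 0):
        raise InvalidSpecError("grip displacements must be nondecreasing")
    k = mechanics.post_bending_stiffness(geometry)
    s0 = geometry.base_separation
    rows = []
    for step, d in enumerate(d_arr):
        def residual(v):
            lam = (s0 + 2.0 * d - 2.0 * v) / model.rest_length
            return k * v - float(model.force(lam))

        if d == 0.0:
            v = 0.0
        else:
            lo, hi = residual(0.0), residual(d)
            if lo > 0 or hi < 0:
                raise EquilibriumFailureError(
                    f"no equilibrium in v ∈ [0, {d:g}] at step {step}: "
                    f"residual({0.0}) = {lo:g}, residual({d:g}) = {hi:g}"
                )
            v = brentq(residual, 0.0, d, xtol=1e-15, rtol=8.9e-16)
            # Newton polish: residual slope k + 2 F'(lambda) / rest_length
            for _ in range(3):
                lam = (s0 + 2.0 * d - 2.0 * v) / model.rest_length
                if lam >= 1.0:
                    dF = (
                        model.alpha
                        * model.beta
                        * math.exp(model.beta * (lam - 1.0))
                        * model.width
                        * model.thickness
                    )
                else:
                    dF = 0.0
                slope = k + 2.0 * dF / model.rest_length
                v = min(max(v - residual(v) / slope, 0.0), d)
        s = s0 + 2.0 * d - 2.0 * v
        rows.append(
            {
                "step": step,
                "displacement_m": d,
                "deflection_m": v,
                "separation_m": s,
                "stretch": s / model.rest_length,
                "force_N": k * v,
            }
        )
    return pd.DataFrame(rows, columns=mechanics.RECORD_COLUMNS)


# --------------------------------------------------------------------------
# histology slides
# --------------------------------------------------------------------------


def gen_histology_slide(
    fractions: Mapping[str, float],
    image_size: int = 512,
    seed: int = 0,
    stain: str = "movat",
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stained-slide RGB raster plus its leaflet mask.

    Constituents are painted in the stain's canonical colors inside an
    elliptical leaflet region; pixel assignment follows the level sets of a
    smooth random field, giving blob-like compartments whose realized pixel
    fractions match the request to within one pixel each.  The in-leaflet
    remainder is pale background tissue; outside the leaflet is white.

    Returns ``(rgb_uint8, leaflet_mask_bool)``.
    """
    from .histology import stain_paint_colors

    total = 0.0
    for name, f in fractions.items():
        if f < 0:
            raise InvalidSpecError(f"fraction for {name!r} is negative")
        total += f
    if total > 1.0 + 1e-12:
        raise InvalidSpecError(f"fractions sum to {total:.3f} > 1")
    colors = stain_paint_colors(stain)
    unknown = set(fractions) - set(colors)
    if unknown:
        raise InvalidSpecError(f"constituents {sorted(unknown)} not painted by stain {stain!r}")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    cy, cx = image_size * 0.52, image_size * 0.5
    leaflet = ((xx - cx) / (0.40 * image_size)) ** 2 + ((yy - cy) / (0.30 * image_size)) ** 2 <= 1.0

    rgb = np.full((image_size, image_size, 3), 255, dtype=float)
    rgb[leaflet] = colors["__background__"]

    field = gaussian_filter(rng.standard_normal((image_size, image_size)), sigma=image_size / 24.0)
    flat_idx = np.flatnonzero(leaflet.ravel())
    ranked = flat_idx[np.argsort(field.ravel()[flat_idx], kind="stable")]
    n_leaflet = len(ranked)
    start = 0
    rgb_flat = rgb.reshape(-1, 3)
    for name in sorted(fractions):
        n_px = int(round(fractions[name] * n_leaflet))
        sel = ranked[start : start + n_px]
        rgb_flat[sel] = colors[name]
        start += n_px
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd * 255.0, rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8), leaflet


# --------------------------------------------------------------------------
# scene writers (External interfaces: TIFF + YAML sidecars + CSV records)
# --------------------------------------------------------------------------


def write_fiber_scenes(
    spec: FiberFieldSpec,
    stretches: Sequence[float],
    out_dir: str | Path,
    nu: float = DEFAULT_NU,
) -> pd.DataFrame:
    """Write one fiber TIFF per stretch level plus ground-truth YAML sidecars.

    Returns the manifest table (``filename, stretch``) also written to
    ``manifest.csv`` in the output directory.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for lam in stretches:
        img = gen_fiber_image(spec, lam, nu=nu)
        name = f"scene_l{lam:.2f}.tif"
        tifffile.imwrite(out / name, img.astype(np.float32))
        truth = {
            "spec": asdict(spec),
            "stretch": float(lam),
            "nu": float(nu),
            "analytic_fai": analytic_fai(spec, lam, nu=nu),
        }
        (out / f"scene_l{lam:.2f}.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
        rows.append({"filename": name, "stretch": float(lam)})
    manifest = pd.DataFrame(rows, columns=["filename", "stretch"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def write_cell_scenes(
    spec: CellFieldSpec,
    stretches: Sequence[float],
    out_dir: str | Path,
    image_size: int = 768,
    nu: float = DEFAULT_NU,
) -> pd.DataFrame:
    """Write one labeled 16-bit cell-mask TIFF per stretch level plus sidecars."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for lam in stretches:
        mask = gen_cell_masks(spec, lam, image_size=image_size, nu=nu)
        name = f"cells_l{lam:.2f}.tif"
        tifffile.imwrite(out / name, mask)
        truth = {
            "spec": asdict(spec),
            "stretch": float(lam),
            "nu": float(nu),
            "expected_mean_ci": float(spec.expected_ci(float(lam))),
        }
        (out / f"cells_l{lam:.2f}.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
        rows.append({"filename": name, "stretch": float(lam)})
    manifest = pd.DataFrame(rows, columns=["filename", "stretch"])
    manifest.to_csv(out / "cells_manifest.csv", index=False)
    return manifest


def write_mechanics_record(record: pd.DataFrame, path: str | Path) -> None:
    """Write a two-post record to CSV with the documented header."""
    record.to_csv(path, index=False, columns=mechanics.RECORD_COLUMNS)
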