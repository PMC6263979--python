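"""Digital phantoms: the resolution and depth-coding targets used to
exercise the imaging chain, plus synthetic vascular / oxygenation scenes.

The physical counterparts are thin absorbing cylinders (hairs, threads,
pencil lead) suspended in 1% Lipofundin.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np

from .optical_transport import CartesianGrid, LIPOFUNDIN_1PCT, OpticalMedium
from .spectral_unmixing import ExtinctionTable, absorption_from_concentrations

__all__ = [
    "AbsorberPrimitive",
    "PhantomSpec",
    "make_two_hair_phantom",
    "make_multi_target_phantom",
    "make_vessel_scene",
    "make_oxygenation_scene",
    "rasterize_phantom",
    "phantom_scatterers",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class AbsorberPrimitive:
    """One absorbing primitive.

    shape: "cylinder" (straight, along ``axis``), "sphere", or
    "curved_tube" (circular-arc centerline via ``path`` samples).
    center: (x, y, z) mm; axis: unit direction for cylinders;
    diameter_um; rel_mu_a: relative absorption; length_mm for cylinders.
    """

    shape: str
    center: tuple[float, float, float]
    diameter_um: float
    rel_mu_a: float = 1.0
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    length_mm: float = 40.0
    path: tuple[tuple[float, float, float], ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise GeometryError("diameter must be > 0")
        if self.rel_mu_a < 0:
            raise GeometryError("rel_mu_a must be >= 0")
        if self.shape not in ("cylinder", "sphere", "curved_tube"):
            raise GeometryError(f"unknown shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """A list of absorbers in a background medium on a grid."""

    primitives: tuple[AbsorberPrimitive, ...]
    background: OpticalMedium = dataclass_field(default=LIPOFUNDIN_1PCT)
    grid: CartesianGrid = dataclass_field(
        default_factory=lambda: CartesianGrid(extents=(16.0, 40.0, 16.0),
                                              spacing=0.05))
    meta: dict = dataclass_field(default_factory=dict)


def make_two_hair_phantom(gap_um: float = 180.0, diameter_um: float = 150.0,
                          depth_mm: float = 10.2,
                          gap_convention: str = "edge") -> PhantomSpec:
    """Two parallel hairs (150 um diameter) separated laterally by a 180 um
    edge-to-edge gap at 10.2 mm depth in 1% Lipofundin.

    With the "edge" convention the center separation is gap + diameter;
    "center" reads the gap as center-to-center instead.
    """
    if gap_convention == "edge":
        center_sep_mm = (gap_um + diameter_um) / 1000.0
    elif gap_convention == "center":
        center_sep_mm = gap_um / 1000.0
    else:
        raise GeometryError("gap_convention must be 'edge' or 'center'")
    prims = tuple(
        AbsorberPrimitive(shape="cylinder",
                          center=(sign * center_sep_mm / 2, 0.0, depth_mm),
                          diameter_um=diameter_um, rel_mu_a=1.0,
                          axis=(0.0, 1.0, 0.0), length_mm=30.0,
                          name=f"hair_{'L' if sign < 0 else 'R'}")
        for sign in (-1.0, +1.0))
    return PhantomSpec(primitives=prims,
                       meta={"gap_um": gap_um,
                             "gap_convention": gap_convention,
                             "depth_mm": depth_mm})


def make_multi_target_phantom(scan_length_mm: float = 35.0) -> PhantomSpec:
    """Depth-coding phantom: one 500 um pencil lead, two ~250 um black
    threads and one ~150 um curved black hair, crossing within the scan
    length, all between 8.5 and 11 mm depth."""
    half = scan_length_mm / 2.0
    lead = AbsorberPrimitive(
        shape="cylinder", center=(0.0, 0.0, 9.0), diameter_um=500.0,
        rel_mu_a=1.0, axis=(0.25, 0.97, 0.0), length_mm=scan_length_mm,
        name="pencil_lead")
    thread1 = AbsorberPrimitive(
        shape="cylinder", center=(-2.0, 0.0, 9.8), diameter_um=250.0,
        rel_mu_a=0.6, axis=(-0.2, 0.98, 0.03), length_mm=scan_length_mm,
        name="thread_1")
    thread2 = AbsorberPrimitive(
        shape="cylinder", center=(2.5, 0.0, 10.5), diameter_um=250.0,
        rel_mu_a=0.6, axis=(0.1, 0.99, -0.02), length_mm=scan_length_mm,
        name="thread_2")
    # gentle circular arc spanning the scan, bowing in x and z
    t = np.linspace(-1.0, 1.0, 41)
    path = tuple((float(-1.0 + 2.0 * math.sin(1.2 * ti)),
                  float(ti * half),
                  float(9.9 + 0.9 * math.cos(1.1 * ti)))
                 for ti in t)
    hair = AbsorberPrimitive(
        shape="curved_tube", center=(0.0, 0.0, 10.0), diameter_um=150.0,
        rel_mu_a=0.4, path=path, name="curved_hair")
    grid = CartesianGrid(extents=(12.0, 36.0, 14.0), spacing=0.05)
    return PhantomSpec(primitives=(lead, thread1, thread2, hair), grid=grid,
                       meta={"scan_length_mm": scan_length_mm,
                             "depth_window_mm": (8.5, 11.0)})


def make_vessel_scene(occluded: bool = False, occlusion_factor: float = 0.8,
                      seed: int = 0) -> tuple[PhantomSpec, np.ndarray]:
    """Branching surface-vessel scene and the ground-truth occlusion mask.

    A main vessel with two branches near the surface; when ``occluded``,
    one branch's relative mu_a is reduced by ``occlusion_factor``
    (default 80% reduction).  The returned mask marks, on the rasterized
    TopView grid, where the non-occluded and occluded scenes differ.
    """
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 0.05, size=3)
    depth = 1.2
    main = AbsorberPrimitive(
        shape="cylinder", center=(0.0, 0.0, depth), diameter_um=400.0,
        rel_mu_a=1.0, axis=(0.1 + jitter[0] * 0.1, 0.99, 0.0),
        length_mm=18.0, name="main_vessel")
    branch_a = AbsorberPrimitive(
        shape="cylinder", center=(1.5, 3.0, depth), diameter_um=250.0,
        rel_mu_a=1.0, axis=(0.6, 0.8, 0.0), length_mm=8.0, name="branch_a")
    mu_b = 1.0 * (1.0 - occlusion_factor) if occluded else 1.0
    branch_b = AbsorberPrimitive(
        shape="cylinder", center=(-1.5, -3.0, depth), diameter_um=250.0,
        rel_mu_a=mu_b, axis=(-0.6, 0.8, 0.0), length_mm=8.0,
        name="branch_b")
    grid = CartesianGrid(extents=(10.0, 20.0, 4.0), spacing=0.1)
    spec = PhantomSpec(primitives=(main, branch_a, branch_b), grid=grid,
                       meta={"occluded": occluded,
                             "occlusion_factor": occlusion_factor,
                             "seed": seed})
    base = rasterize_phantom(
        PhantomSpec(primitives=(branch_b,), grid=grid))
    mask = base.max(axis=2) > 0  # TopView footprint of the occludable branch
    return spec, mask


def make_oxygenation_scene(table: ExtinctionTable, seed: int = 0,
                           shape: tuple[int, int] = (100, 100),
                           tumor_so2: tuple[float, float] = (0.3, 0.6),
                           background_so2: tuple[float, float] = (0.9, 0.98),
                           noise: float = 0.0) -> dict:
    """Synthetic oxygenation map: a hypoxic disc "tumor" in well-oxygenated
    background, with per-wavelength mu_a maps built from the extinction
    table at 750/850 nm.

    Returns a dict with so2_true, hbt_true, tumor_mask, mu_a_750, mu_a_850
    (optionally corrupted by multiplicative Gaussian noise of relative
    sigma ``noise``).
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = ny / 2.0, nx / 2.0
    radius = min(ny, nx) / 5.0
    tumor = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    so2 = rng.uniform(*background_so2, size=shape)
    so2[tumor] = rng.uniform(*tumor_so2, size=int(tumor.sum()))
    hbt = np.full(shape, 150e-6)  # mol/L, physiological total hemoglobin
    hbt *= rng.uniform(0.8, 1.2, size=shape)
    hbo2 = so2 * hbt
    hb = hbt - hbo2
    mu750 = absorption_from_concentrations(750.0, hbo2, hb, table)
    mu850 = absorption_from_concentrations(850.0, hbo2, hb, table)
    if noise > 0:
        mu750 = mu750 * (1.0 + noise * rng.standard_normal(shape))
        mu850 = mu850 * (1.0 + noise * rng.standard_normal(shape))
    return {"so2_true": so2, "hbt_true": hbt, "tumor_mask": tumor,
            "mu_a_750": mu750, "mu_a_850": mu850, "seed": seed}


def _dist_point_segment(pts: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> np.ndarray:
    """Distance from points (N, 3) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def rasterize_phantom(spec: PhantomSpec,
                      grid: CartesianGrid | None = None) -> np.ndarray:
    """Voxelized relative-mu_a map (nx, ny, nz); overlapping primitives
    take the maximum."""
    grid = grid or spec.grid
    xs, ys, zs = grid.axis(0), grid.axis(1), grid.axis(2)
    vol = np.zeros(grid.shape)
    for prim in spec.primitives:
        r_mm = prim.diameter_um / 2000.0
        c = np.asarray(prim.center)
        if prim.shape == "sphere":
            bbox = _bbox_mask(xs, ys, zs, c - r_mm, c + r_mm)
            if bbox is None:
                raise GeometryError(f"{prim.name or prim.shape} outside grid")
            (ix, iy, iz), pts = bbox
            d = np.linalg.norm(pts - c, axis=1)
            _accumulate(vol, ix, iy, iz, d <= r_mm, prim.rel_mu_a)
        elif prim.shape == "cylinder":
            ax = np.asarray(prim.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            a = c - ax * prim.length_mm / 2.0
            b = c + ax * prim.length_mm / 2.0
            lo = np.minimum(a, b) - r_mm
            hi = np.maximum(a, b) + r_mm
            bbox = _bbox_mask(xs, ys, zs, lo, hi)
            if bbox is None:
                raise GeometryError(f"{prim.name or prim.shape} outside grid")
            (ix, iy, iz), pts = bbox
            d = _dist_point_segment(pts, a, b)
            _accumulate(vol, ix, iy, iz, d <= r_mm, prim.rel_mu_a)
        else:  # curved_tube
            path = np.asarray(prim.path, dtype=float)
            lo = path.min(axis=0) - r_mm
            hi = path.max(axis=0) + r_mm
            bbox = _bbox_mask(xs, ys, zs, lo, hi)
            if bbox is None:
                raise GeometryError(f"{prim.name or prim.shape} outside grid")
            (ix, iy, iz), pts = bbox
            d = np.full(pts.shape[0], np.inf)
            for a, b in zip(path[:-1], path[1:]):
                d = np.minimum(d, _dist_point_segment(pts, a, b))
            _accumulate(vol, ix, iy, iz, d <= r_mm, prim.rel_mu_a)
    return vol


def _bbox_mask(xs, ys, zs, lo, hi):
    ix = np.nonzero((xs >= lo[0]) & (xs <= hi[0]))[0]
    iy = np.nonzero((ys >= lo[1]) & (ys <= hi[1]))[0]
    iz = np.nonzero((zs >= lo[2]) & (zs <= hi[2]))[0]
    if ix.size == 0 or iy.size == 0 or iz.size == 0:
        return None
    pts = np.stack(np.meshgrid(xs[ix], ys[iy], zs[iz], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    return (ix, iy, iz), pts


def _accumulate(vol, ix, iy, iz, inside_flat, value):
    sub = vol[np.ix_(ix, iy, iz)]
    shape = sub.shape
    sub = np.maximum(sub, inside_flat.reshape(shape) * value)
    vol[np.ix_(ix, iy, iz)] = sub


def phantom_scatterers(spec: PhantomSpec, y_mm: float = 0.0,
                       tol_mm: float = 0.1) -> list[tuple[float, float, float]]:
    """Point-scatterer list for the array simulator: centerline samples of
    every primitive intersecting the X-Z plane at ``y_mm``.

    Reflectivity is the primitive's relative mu_a scaled by its diameter
    (thicker absorbers return more signal)."""
    out: list[tuple[float, float, float]] = []
    for prim in spec.primitives:
        refl = prim.rel_mu_a * prim.diameter_um / 500.0
        if prim.shape == "sphere":
            if abs(prim.center[1] - y_mm) <= tol_mm:
                out.append((prim.center[0], prim.center[2], refl))
        elif prim.shape == "cylinder":
            ax = np.asarray(prim.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            if abs(ax[1]) < 1e-9:
                if abs(prim.center[1] - y_mm) <= tol_mm:
                    out.append((prim.center[0], prim.center[2], refl))
                continue
            t = (y_mm - prim.center[1]) / ax[1]
            if abs(t) <= prim.length_mm / 2.0:
                p = np.asarray(prim.center) + t * ax
                out.append((float(p[0]), float(p[2]), refl))
        else:
            path = np.asarray(prim.path, dtype=float)
            for a, b in zip(path[:-1], path[1:]):
                ya, yb = a[1], b[1]
                if (ya - y_mm) * (yb - y_mm) <= 0 and ya != yb:
                    t = (y_mm - ya) / (yb - ya)
                    p = a + t * (b - a)
                    out.append((float(p[0]), float(p[2]), refl))
    return out
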