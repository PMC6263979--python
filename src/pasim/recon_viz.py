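"""Volume assembly and projection: B-scan stacks, MIP, C-scan slices,
depth-coded composites and PA/US overlays.

A B-scan stack is an ordered sequence of X-Z envelope images collected at
a uniform Y step; the maximum-intensity projection keeps, for each column
along the chosen axis, the pixel with maximum intensity (Z projection =
TopView, X projection = SideView).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from matplotlib import colormaps

__all__ = [
    "BScanStack",
    "MipImage",
    "CScanSlices",
    "DepthCodedImage",
    "OverlayImage",
    "stack_bscans",
    "mip_project",
    "extract_cscan_slices",
    "depth_color_code",
    "coregister_overlay",
]


class InputError(ValueError):
    pass


class RangeError(ValueError):
    pass


@dataclass
class BScanStack:
    """3-D volume indexed (y, x, z) with axis metadata in mm."""

    volume: np.ndarray          # (ny, nx, nz)
    y_step_mm: float
    x_mm: np.ndarray
    z_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.y_step_mm <= 0:
            raise InputError("y step must be > 0")
        if self.volume.ndim != 3:
            raise InputError("stack volume must be 3-D")

    @property
    def y_mm(self) -> np.ndarray:
        return np.arange(self.volume.shape[0]) * self.y_step_mm


@dataclass
class MipImage:
    image: np.ndarray
    axes: tuple[str, str]
    view: str


@dataclass
class CScanSlices:
    slices: np.ndarray          # (n_depths, ny, nx)
    depths_mm: np.ndarray
    slab_mm: float


@dataclass
class DepthCodedImage:
    brightness: np.ndarray      # windowed TopView MIP
    depth_mm: np.ndarray        # depth of each pixel's maximum
    z_window_mm: tuple[float, float]

    def to_rgb(self, cmap: str = "hsv_r") -> np.ndarray:
        """Hue encodes depth inside the window, value encodes brightness."""
        z0, z1 = self.z_window_mm
        frac = np.clip((self.depth_mm - z0) / max(z1 - z0, 1e-12), 0, 1)
        rgb = colormaps[cmap](frac)[..., :3]
        b = self.brightness / max(self.brightness.max(), 1e-300)
        return rgb * b[..., None]


@dataclass
class OverlayImage:
    rgb: np.ndarray
    threshold_db: float
    pa_mask: np.ndarray
    meta: dict = dataclass_field(default_factory=dict)


def stack_bscans(slices: Sequence[np.ndarray], y_step_mm: float = 0.05,
                 x_mm: np.ndarray | None = None,
                 z_mm: np.ndarray | None = None) -> BScanStack:
    """Assemble ordered X-Z B-scan images into a (y, x, z) volume."""
    slices = [np.asarray(s, dtype=float) for s in slices]
    if not slices:
        raise InputError("no slices given")
    shape = slices[0].shape
    if any(s.shape != shape for s in slices):
        raise InputError("all B-scan slices must share one shape")
    vol = np.stack(slices, axis=0)
    nx, nz = shape
    x = np.arange(nx, dtype=float) if x_mm is None else np.asarray(x_mm)
    z = np.arange(nz, dtype=float) if z_mm is None else np.asarray(z_mm)
    return BScanStack(volume=vol, y_step_mm=y_step_mm, x_mm=x, z_mm=z)


def mip_project(stack: BScanStack, axis: str = "Z") -> MipImage:
    """Per-column maximum along X, Y or Z of the stack volume."""
    axis = axis.upper()
    if axis == "Z":       # TopView: X-Y image
        img = stack.volume.max(axis=2)
        return MipImage(image=img, axes=("y", "x"), view="TopView")
    if axis == "X":       # SideView: Y-Z image
        img = stack.volume.max(axis=1)
        return MipImage(image=img, axes=("y", "z"), view="SideView")
    if axis == "Y":       # through-scan projection: X-Z image
        img = stack.volume.max(axis=0)
        return MipImage(image=img, axes=("x", "z"), view="FrontView")
    raise InputError("axis must be one of X, Y, Z")


def extract_cscan_slices(stack: BScanStack, depths_mm: Sequence[float],
                         slab_mm: float = 0.0) -> CScanSlices:
    """X-Y planes at the nearest grid depths, or thin-slab maxima of the
    stated thickness centered on each depth."""
    z = stack.z_mm
    out = []
    for d in depths_mm:
        if not (z.min() - 1e-9 <= d <= z.max() + 1e-9):
            raise RangeError(f"depth {d} mm outside stack range")
        if slab_mm <= 0:
            iz = int(np.argmin(np.abs(z - d)))
            out.append(stack.volume[:, :, iz])
        else:
            sel = np.abs(z - d) <= slab_mm / 2.0
            if not sel.any():
                raise RangeError(f"slab at {d} mm contains no samples")
            out.append(stack.volume[:, :, sel].max(axis=2))
    return CScanSlices(slices=np.stack(out),
                       depths_mm=np.asarray(depths_mm, dtype=float),
                       slab_mm=slab_mm)


def depth_color_code(stack: BScanStack,
                     z_window_mm: tuple[float, float] = (8.5, 11.0)
                     ) -> DepthCodedImage:
    """TopView restricted to the depth window; each pixel carries the depth
    of its maximum (color) and the maximum value (brightness)."""
    z0, z1 = z_window_mm
    sel = (stack.z_mm >= z0) & (stack.z_mm <= z1)
    if not sel.any():
        raise RangeError("empty depth window")
    sub = stack.volume[:, :, sel]
    zs = stack.z_mm[sel]
    brightness = sub.max(axis=2)
    depth = zs[np.argmax(sub, axis=2)]
    return DepthCodedImage(brightness=brightness, depth_mm=depth,
                           z_window_mm=(float(z0), float(z1)))


def coregister_overlay(us_img: np.ndarray, pa_img: np.ndarray,
                       threshold_db: float = -20.0,
                       pa_cmap: str = "hot") -> OverlayImage:
    """Grayscale US base with PA pixels above ``threshold_db`` (relative to
    the PA maximum) rendered in a color scale on top."""
    us_img = np.asarray(us_img, dtype=float)
    pa_img = np.asarray(pa_img, dtype=float)
    if us_img.shape != pa_img.shape:
        raise InputError("US and PA images must share geometry")
    us_n = us_img / max(us_img.max(), 1e-300)
    rgb = np.repeat(us_n[..., None], 3, axis=-1)
    pa_max = pa_img.max()
    if pa_max > 0:
        with np.errstate(divide="ignore"):
            pa_db = 20 * np.log10(np.maximum(pa_img, 1e-300) / pa_max)
        mask = pa_db >= threshold_db
        frac = np.zeros_like(pa_img)
        if threshold_db < 0:
            frac[mask] = 1.0 - pa_db[mask] / threshold_db
        else:
            frac[mask] = 1.0
        colors = colormaps[pa_cmap](frac)[..., :3]
        rgb[mask] = colors[mask]
    else:
        mask = np.zeros(pa_img.shape, dtype=bool)
    return OverlayImage(rgb=rgb, threshold_db=threshold_db, pa_mask=mask)
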