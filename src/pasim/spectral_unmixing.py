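"""Two-wavelength hemoglobin unmixing and cerebral-blood-volume proxies.

Per-pixel inversion of Beer's law for two chromophores:

    mu_a(lambda) = eps_HbO2(lambda) [HbO2] + eps_Hb(lambda) [Hb]
    HbT = [HbO2] + [Hb],   SO2 = [HbO2] / HbT

Pixel intensities are treated as relative mu_a (the images the instrument
produces are normalized; no fluence-depth compensation is applied by
default).  An 800 nm image, close to the hemoglobin isosbestic point,
serves as a total-blood-volume (CBV) proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from importlib import resources

import numpy as np

from .optical_transport import (
    CartesianGrid,
    IlluminationGeometry,
    OpticalMedium,
    PulseProfile,
    fluence_at_depth,
    solve_fluence,
)

__all__ = [
    "ExtinctionTable",
    "ChromophoreMap",
    "load_extinction_table",
    "absorption_from_concentrations",
    "unmix_two_wavelength",
    "cbv_proxy",
    "wavelength_intensity_balance",
]


class WavelengthRangeError(ValueError):
    pass


class UnmixingConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and Hb vs wavelength.

    Units: cm^-1 / (mol/L).  Wavelengths strictly increasing.
    """

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.eps_hbo2 <= 0) or np.any(self.eps_hb <= 0):
            raise ValueError("extinction coefficients must be > 0")

    def at(self, wavelength_nm: float) -> tuple[float, float]:
        """(eps_HbO2, eps_Hb) linearly interpolated at ``wavelength_nm``."""
        wl = self.wavelength_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise WavelengthRangeError(
                f"{wavelength_nm} nm outside table range "
                f"[{wl[0]}, {wl[-1]}] nm")
        return (float(np.interp(wavelength_nm, wl, self.eps_hbo2)),
                float(np.interp(wavelength_nm, wl, self.eps_hb)))


def load_extinction_table(path: str | None = None) -> ExtinctionTable:
    """Load a whitespace-delimited table (nm, eps_HbO2, eps_Hb); '#'
    comments.  With no path, the bundled default table is used."""
    if path is None:
        ref = resources.files("pasim") / "data" / "hb_extinction.tsv"
        with resources.as_file(ref) as p:
            raw = np.loadtxt(p)
    else:
        raw = np.loadtxt(path)
    return ExtinctionTable(wavelength_nm=raw[:, 0], eps_hbo2=raw[:, 1],
                           eps_hb=raw[:, 2])


@dataclass
class ChromophoreMap:
    """Co-registered [HbO2], [Hb], HbT, SO2 maps with a validity mask."""

    hbo2: np.ndarray
    hb: np.ndarray
    hbt: np.ndarray
    so2: np.ndarray
    mask: np.ndarray
    meta: dict = dataclass_field(default_factory=dict)


def absorption_from_concentrations(wavelength_nm: float,
                                   c_hbo2: float | np.ndarray,
                                   c_hb: float | np.ndarray,
                                   table: ExtinctionTable
                                   ) -> float | np.ndarray:
    """mu_a(lambda) = eps_HbO2 [HbO2] + eps_Hb [Hb], 1/cm."""
    e_o, e_h = table.at(wavelength_nm)
    out = e_o * np.asarray(c_hbo2, dtype=float) + \
        e_h * np.asarray(c_hb, dtype=float)
    return out if out.ndim else float(out)


def unmix_two_wavelength(img_l1: np.ndarray, img_l2: np.ndarray,
                         wavelength1_nm: float, wavelength2_nm: float,
                         table: ExtinctionTable,
                         so2_slack: float = 0.05) -> ChromophoreMap:
    """Per-pixel 2x2 inversion of the extinction system.

    Pixels with non-positive HbT or SO2 outside [-so2_slack, 1 + so2_slack]
    are masked invalid; in-range SO2 is clipped to [0, 1].
    """
    img_l1 = np.asarray(img_l1, dtype=float)
    img_l2 = np.asarray(img_l2, dtype=float)
    if img_l1.shape != img_l2.shape:
        raise UnmixingConfigurationError("images must be co-registered "
                                         "(same shape)")
    e = np.array([table.at(wavelength1_nm), table.at(wavelength2_nm)])
    det = e[0, 0] * e[1, 1] - e[0, 1] * e[1, 0]
    scale = np.abs(e).max() ** 2
    if abs(det) < 1e-12 * scale:
        raise UnmixingConfigurationError(
            "extinction matrix is singular at the chosen wavelength pair")
    inv = np.array([[e[1, 1], -e[0, 1]], [-e[1, 0], e[0, 0]]]) / det
    hbo2 = inv[0, 0] * img_l1 + inv[0, 1] * img_l2
    hb = inv[1, 0] * img_l1 + inv[1, 1] * img_l2
    hbt = hbo2 + hb
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(hbt != 0, hbo2 / hbt, np.nan)
    mask = (hbt > 0) & np.isfinite(so2) & \
        (so2 >= -so2_slack) & (so2 <= 1.0 + so2_slack)
    so2 = np.clip(so2, 0.0, 1.0)
    return ChromophoreMap(hbo2=hbo2, hb=hb, hbt=hbt, so2=so2, mask=mask,
                          meta={"wavelengths_nm": (wavelength1_nm,
                                                   wavelength2_nm)})


def cbv_proxy(img_800nm: np.ndarray,
              reference_mask: np.ndarray | None = None) -> np.ndarray:
    """Relative CBV map: the isosbestic-wavelength image normalized to the
    mean over a reference region (whole image by default)."""
    img = np.asarray(img_800nm, dtype=float)
    if reference_mask is None:
        reference_mask = np.ones(img.shape, dtype=bool)
    if not np.any(reference_mask):
        raise UnmixingConfigurationError("empty reference region")
    ref = img[reference_mask].mean()
    if ref == 0:
        raise UnmixingConfigurationError("reference region has zero mean")
    return img / ref


def wavelength_intensity_balance(medium_l1: OpticalMedium,
                                 medium_l2: OpticalMedium,
                                 depth_mm: float = 10.0,
                                 geom: IlluminationGeometry | None = None,
                                 pulse: PulseProfile | None = None,
                                 grid: CartesianGrid | None = None) -> float:
    """Incident-energy multiplier for wavelength 1 equalizing the midline
    fluence of the two wavelengths at ``depth_mm``.

    Returns fluence(lambda2) / fluence(lambda1) at the observation point;
    scaling the lambda-1 pulse energy by this factor balances the pair.
    """
    geom = geom or IlluminationGeometry()
    pulse = pulse or PulseProfile()
    grid = grid or CartesianGrid(spacing=1.0)
    f1 = fluence_at_depth(
        solve_fluence(medium_l1, pulse, geom, grid, mode="steady"), depth_mm)
    f2 = fluence_at_depth(
        solve_fluence(medium_l2, pulse, geom, grid, mode="steady"), depth_mm)
    return f2 / f1
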