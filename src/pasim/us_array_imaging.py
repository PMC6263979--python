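"""Linear-array point-scatterer simulation and delay-and-sum imaging.

Models the 128-element, 0.10 mm pitch, 18.5 MHz (67% -6 dB fractional
bandwidth) linear array: per-element RF from ideal point scatterers
(plane-wave transmit for pulse-echo, or one-way reception as in
photoacoustics), delay-and-sum beamforming with a dynamic receive aperture
and optional Hann apodization, envelope detection via the analytic signal,
and PSF/resolution measurements (FWHM maps, two-point resolvability).

Coordinates: x = 0 at the array center, z = 0 at the element surface,
z increasing into the medium; lengths in mm, times in us.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, hilbert

__all__ = [
    "LinearArray",
    "PointScene",
    "RFDataFrame",
    "BeamformedImage",
    "PsfMeasurement",
    "transducer_impulse_response",
    "simulate_point_scatterer_rf",
    "das_beamform",
    "measure_fwhm",
    "psf_map_sweep",
    "two_point_resolvability",
    "min_resolvable_separation",
    "psf_at",
]


class GeometryError(ValueError):
    pass


class MeasurementError(RuntimeError):
    pass


@dataclass(frozen=True)
class LinearArray:
    """Linear transducer array geometry and band shape."""

    n_elements: int = 128
    pitch_mm: float = 0.10
    center_frequency_mhz: float = 18.5
    fractional_bandwidth_pct: float = 67.0
    element_width_mm: float | None = None
    sound_speed_m_s: float = 1540.0
    sample_rate_mhz: float = 62.5

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be > 0")
        if not (0 < self.fractional_bandwidth_pct < 200):
            raise ValueError("fractional bandwidth out of range")
        if self.sample_rate_mhz <= 2 * self.center_frequency_mhz * (
                1 + self.fractional_bandwidth_pct / 200.0):
            raise ValueError("sample rate below Nyquist for the pulse band")
        if self.element_width_mm is None:
            object.__setattr__(self, "element_width_mm", 0.9 * self.pitch_mm)

    @property
    def element_x_mm(self) -> np.ndarray:
        """Element center positions (mm), symmetric about x = 0."""
        idx = np.arange(self.n_elements)
        return (idx - (self.n_elements - 1) / 2.0) * self.pitch_mm

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / 1000.0 / self.center_frequency_mhz

    @property
    def aperture_mm(self) -> float:
        return (self.n_elements - 1) * self.pitch_mm


#: Imaging region of the 12.8 mm array: lateral +-6.4 mm, depth 0..20 mm.
LATERAL_LIMIT_MM = 6.4
DEPTH_LIMIT_MM = 20.0


@dataclass(frozen=True)
class PointScene:
    """Ideal point scatterers: (x_mm, z_mm, reflectivity)."""

    points: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for x, z, refl in self.points:
            if z <= 0:
                raise GeometryError("scatterer depth must be > 0")
            if refl < 0:
                raise GeometryError("reflectivity must be >= 0")

    @staticmethod
    def single(x_mm: float, z_mm: float, reflectivity: float = 1.0
               ) -> "PointScene":
        return PointScene(points=((x_mm, z_mm, reflectivity),))


@dataclass
class RFDataFrame:
    """Per-element RF signals (elements x samples)."""

    data: np.ndarray
    sample_rate_mhz: float
    start_time_us: float
    mode: str  # "pulse_echo" | "one_way"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RF contains non-finite values")

    @property
    def time_axis_us(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.start_time_us + np.arange(n) / self.sample_rate_mhz


@dataclass
class BeamformedImage:
    """Envelope-detected image with physical axes (linear scale)."""

    envelope: np.ndarray  # (nx, nz)
    x_mm: np.ndarray
    z_mm: np.ndarray
    dynamic_range_db: float = 40.0
    meta: dict = dataclass_field(default_factory=dict)

    def db(self) -> np.ndarray:
        """Log-compressed image, 0 dB at peak (display only)."""
        peak = self.envelope.max()
        if peak <= 0:
            return np.full_like(self.envelope, -self.dynamic_range_db)
        return np.clip(20 * np.log10(np.maximum(self.envelope, 1e-300) / peak),
                       -self.dynamic_range_db, 0.0)


@dataclass
class PsfMeasurement:
    axial_fwhm_um: float
    lateral_fwhm_um: float
    peak_x_mm: float
    peak_z_mm: float


def transducer_impulse_response(array: LinearArray, t_us: np.ndarray
                                ) -> np.ndarray:
    """Gaussian-enveloped sinusoid at f_c whose -6 dB two-sided spectral
    width equals the fractional bandwidth times f_c; unit peak, centered on
    the middle of ``t_us``."""
    fc = array.center_frequency_mhz
    span = t_us[-1] - t_us[0]
    if span < 6.0 / fc:
        raise ValueError("time axis must span at least 6 carrier periods")
    bw_hz = array.fractional_bandwidth_pct / 100.0 * fc  # MHz
    sigma_f = bw_hz / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_t = 1.0 / (2.0 * math.pi * sigma_f)  # us
    t0 = 0.5 * (t_us[0] + t_us[-1])
    env = np.exp(-((t_us - t0) ** 2) / (2.0 * sigma_t**2))
    return env * np.cos(2.0 * math.pi * fc * (t_us - t0))


def simulate_point_scatterer_rf(array: LinearArray, scene: PointScene,
                                mode: str = "pulse_echo") -> RFDataFrame:
    """Per-element RF as a sum over scatterers of the delayed impulse
    response, weighted by reflectivity, hard-baffle element directivity
    sinc(pi w sin(theta) / lambda) and spherical spreading 1/d.

    pulse_echo uses plane-wave transmit (d_tx = z); one_way uses the
    element-to-point distance only (the photoacoustic reception case).
    """
    if mode not in ("pulse_echo", "one_way"):
        raise ValueError("mode must be pulse_echo or one_way")
    for x, z, _ in scene.points:
        if abs(x) > LATERAL_LIMIT_MM or z > DEPTH_LIMIT_MM:
            raise GeometryError(f"scatterer ({x}, {z}) outside imaging region")
    c = array.sound_speed_m_s / 1000.0  # mm/us
    ex = array.element_x_mm
    kern_center = 4.0 * _pulse_sigma_t(array)
    fs = array.sample_rate_mhz
    max_d = max(math.hypot(x - e, z)
                for x, z, _ in scene.points for e in (ex[0], ex[-1]))
    max_t = (max_d + max(z for _, z, _ in scene.points)) / c if mode == \
        "pulse_echo" else max_d / c
    n_samples = int(math.ceil((max_t + 5 * kern_center) * fs))
    data = np.zeros((array.n_elements, n_samples))
    t_axis = np.arange(n_samples) / fs
    lam = array.wavelength_mm
    w = array.element_width_mm
    for x, z, refl in scene.points:
        if refl == 0:
            continue
        d_rx = np.hypot(x - ex, z)
        sin_th = (x - ex) / d_rx
        arg = math.pi * w / lam * sin_th
        directivity = np.sinc(arg / math.pi)  # np.sinc(x)=sin(pi x)/(pi x)
        delay = (z + d_rx) / c if mode == "pulse_echo" else d_rx / c
        amp = refl * directivity / d_rx
        # the Gaussian-cosine kernel is analytic: evaluate it exactly at
        # t - delay rather than interpolating a pre-sampled waveform
        sigma_t = _pulse_sigma_t(array)
        t_rel = t_axis[None, :] - delay[:, None]
        mask = np.abs(t_rel) <= 4.0 * sigma_t
        vals = np.zeros_like(t_rel)
        tr = t_rel[mask]
        vals[mask] = np.exp(-tr**2 / (2 * sigma_t**2)) * np.cos(
            2 * math.pi * array.center_frequency_mhz * tr)
        data += amp[:, None] * vals
    return RFDataFrame(data=data, sample_rate_mhz=fs, start_time_us=0.0,
                       mode=mode)


def _pulse_sigma_t(array: LinearArray) -> float:
    """Gaussian envelope sigma (us) from the -6 dB fractional bandwidth."""
    sigma_f = (array.fractional_bandwidth_pct / 100.0
               * array.center_frequency_mhz) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return 1.0 / (2.0 * math.pi * sigma_f)


def das_beamform(rf: RFDataFrame, array: LinearArray,
                 x_mm: np.ndarray, z_mm: np.ndarray,
                 f_number: float = 1.0, apodization: str = "hann"
                 ) -> BeamformedImage:
    """Delay-and-sum with dynamic receive aperture (f-number limited) and
    optional Hann apodization; envelope via the analytic signal along z."""
    x_mm = np.asarray(x_mm, dtype=float)
    z_mm = np.asarray(z_mm, dtype=float)
    if z_mm.min() <= 0:
        raise GeometryError("imaging grid must be below the array (z > 0)")
    c = array.sound_speed_m_s / 1000.0
    t = rf.time_axis_us
    max_t = t[-1]
    # reject only grids entirely beyond the recorded window
    min_need = 2 * z_mm.min() / c if rf.mode == "pulse_echo" else z_mm.min() / c
    if min_need > max_t + 1e-9:
        raise GeometryError("grid outside RF data support")
    xx = x_mm[:, None]
    zz = z_mm[None, :]
    acc = np.zeros((x_mm.size, z_mm.size))
    half_ap = zz / (2.0 * f_number)
    for i, ex in enumerate(array.element_x_mm):
        d_rx = np.hypot(xx - ex, zz)
        tau = (zz + d_rx) / c if rf.mode == "pulse_echo" else d_rx / c
        sig = np.interp(tau, t, rf.data[i], left=0.0, right=0.0)
        dist = np.abs(xx - ex)
        inside = dist <= half_ap
        if apodization == "hann":
            wgt = np.where(inside,
                           0.5 * (1 + np.cos(math.pi * np.minimum(
                               dist / np.maximum(half_ap, 1e-12), 1.0))), 0.0)
        elif apodization in (None, "none", "rect"):
            wgt = inside.astype(float)
        else:
            raise ValueError(f"unknown apodization {apodization!r}")
        acc += wgt * sig
    env = np.abs(hilbert(acc, axis=1))
    return BeamformedImage(envelope=env, x_mm=x_mm, z_mm=z_mm,
                           meta={"f_number": f_number,
                                 "apodization": apodization,
                                 "mode": rf.mode})


def _fwhm_1d(axis_mm: np.ndarray, profile: np.ndarray, i_peak: int) -> float:
    """FWHM around profile[i_peak] with linear interpolation at crossings."""
    half = profile[i_peak] / 2.0
    lo = None
    for i in range(i_peak, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i - 1])
            lo = axis_mm[i] - frac * (axis_mm[i] - axis_mm[i - 1])
            break
    hi = None
    for i in range(i_peak, profile.size - 1):
        if profile[i + 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            hi = axis_mm[i] + frac * (axis_mm[i + 1] - axis_mm[i])
            break
    if lo is None or hi is None:
        raise MeasurementError("no half-maximum crossing inside image")
    return hi - lo


def measure_fwhm(img: BeamformedImage) -> PsfMeasurement:
    """Axial and lateral FWHM along the lines through the image peak."""
    env = img.envelope
    ix, iz = np.unravel_index(int(np.argmax(env)), env.shape)
    lateral = _fwhm_1d(img.x_mm, env[:, iz], ix)
    axial = _fwhm_1d(img.z_mm, env[ix, :], iz)
    return PsfMeasurement(axial_fwhm_um=axial * 1000.0,
                          lateral_fwhm_um=lateral * 1000.0,
                          peak_x_mm=float(img.x_mm[ix]),
                          peak_z_mm=float(img.z_mm[iz]))


def psf_at(array: LinearArray, x_mm: float, z_mm: float,
           mode: str = "pulse_echo", f_number: float = 1.0,
           apodization: str = "hann",
           pixel_um: tuple[float, float] = (8.0, 4.0)) -> PsfMeasurement:
    """Simulate -> beamform -> measure for one scatterer position.

    The beamforming ROI is a small window around the true position;
    pixel_um = (lateral, axial) pixel size.
    """
    scene = PointScene.single(x_mm, z_mm)
    rf = simulate_point_scatterer_rf(array, scene, mode=mode)
    half_x, half_z = 0.9, 0.6  # mm window half-sizes
    xs = np.arange(x_mm - half_x, x_mm + half_x, pixel_um[0] / 1000.0)
    zs = np.arange(max(z_mm - half_z, 0.2), z_mm + half_z,
                   pixel_um[1] / 1000.0)
    img = das_beamform(rf, array, xs, zs, f_number=f_number,
                       apodization=apodization)
    return measure_fwhm(img)


@dataclass
class ResolutionMap:
    x_mm: np.ndarray
    z_mm: np.ndarray
    axial_fwhm_um: np.ndarray   # (nx, nz)
    lateral_fwhm_um: np.ndarray


def psf_map_sweep(array: LinearArray,
                  x_range_mm: Sequence[float] = (-6.0, 6.0),
                  z_range_mm: Sequence[float] = (3.0, 15.0),
                  step_mm: float = 1.0, mode: str = "pulse_echo",
                  f_number: float = 1.0, apodization: str = "hann"
                  ) -> ResolutionMap:
    """One simulate/beamform/measure cycle per grid position."""
    xs = np.arange(x_range_mm[0], x_range_mm[1] + step_mm / 2, step_mm)
    zs = np.arange(z_range_mm[0], z_range_mm[1] + step_mm / 2, step_mm)
    ax = np.empty((xs.size, zs.size))
    lat = np.empty((xs.size, zs.size))
    for i, x in enumerate(xs):
        for j, z in enumerate(zs):
            m = psf_at(array, x, z, mode=mode, f_number=f_number,
                       apodization=apodization)
            ax[i, j] = m.axial_fwhm_um
            lat[i, j] = m.lateral_fwhm_um
    return ResolutionMap(x_mm=xs, z_mm=zs, axial_fwhm_um=ax,
                         lateral_fwhm_um=lat)


def two_point_resolvability(array: LinearArray, depth_mm: float,
                            separation_um: float, mode: str = "pulse_echo",
                            dip_db: float = 3.0, f_number: float = 1.0,
                            apodization: str = "hann") -> tuple[bool, float]:
    """Two equal scatterers laterally separated at ``depth_mm``.

    Returns (resolvable, dip) where dip is the depth in dB of the valley
    below the lower of the two peaks in the lateral envelope profile
    (0 when no two-peak structure exists).  Resolvable iff dip >= dip_db.
    """
    if separation_um <= 0:
        raise ValueError("separation must be > 0")
    s_mm = separation_um / 1000.0
    scene = PointScene(points=((-s_mm / 2, depth_mm, 1.0),
                               (+s_mm / 2, depth_mm, 1.0)))
    rf = simulate_point_scatterer_rf(array, scene, mode=mode)
    xs = np.arange(-s_mm / 2 - 0.8, s_mm / 2 + 0.8, 0.005)
    zs = np.arange(depth_mm - 0.5, depth_mm + 0.5, 0.008)
    img = das_beamform(rf, array, xs, zs, f_number=f_number,
                       apodization=apodization)
    # lateral profile: max over the axial window kills axial misalignment
    profile = img.envelope.max(axis=1)
    peaks, _ = find_peaks(profile)
    # the relevant peak pair: the highest local maximum on each side of the
    # midline (ripple sidelobes elsewhere do not count as "two scatterers")
    left = peaks[img.x_mm[peaks] < 0]
    right = peaks[img.x_mm[peaks] >= 0]
    if left.size == 0 or right.size == 0:
        return False, 0.0
    p1 = left[np.argmax(profile[left])]
    p2 = right[np.argmax(profile[right])]
    if p2 <= p1 + 1:
        return False, 0.0
    valley = profile[p1:p2 + 1].min()
    lower_peak = min(profile[p1], profile[p2])
    # equal scatterers must yield comparable peaks: a faint sidelobe
    # opposite the merged mainlobe is not a resolved second target
    if lower_peak < 0.5 * max(profile[p1], profile[p2]):
        return False, 0.0
    if valley <= 0:
        return True, math.inf
    dip = 20.0 * math.log10(lower_peak / valley)
    return dip >= dip_db, dip


def min_resolvable_separation(array: LinearArray, depth_mm: float,
                              separations_um: Sequence[float] | None = None,
                              mode: str = "pulse_echo", dip_db: float = 3.0,
                              f_number: float = 1.0,
                              apodization: str = "hann") -> float | None:
    """Smallest separation classified resolvable; None if none in range.

    Default sweep: 100 to 400 um in 10 um steps, ascending; the first
    separation crossing the criterion is reported.
    """
    if separations_um is None:
        separations_um = np.arange(100.0, 401.0, 10.0)
    for s in separations_um:
        ok, _ = two_point_resolvability(array, depth_mm, s, mode=mode,
                                        dip_db=dip_db, f_number=f_number,
                                        apodization=apodization)
        if ok:
            return float(s)
    return None
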