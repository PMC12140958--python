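"""Synthetic speckle-cine generator with analytic ground truth.

Emulates transverse B-mode imaging of a pulsatile thick-walled vessel
phantom: the imaging plane cuts the spherical sac at its maximal diameter,
which the mechanical model treats as a plane-strain thick-walled cylinder
(inner radius ``a``, outer radius ``b``) of compliant silicone.  Wall motion
under the lumen pressure waveform follows the closed-form Lamé solution, so
every generated cine carries exact per-frame displacement fields and the
true mean circumferential Green–Lagrange strain, cycle maximum, and
pulse-pressure-normalized strain.

Embolization-plug packing is represented by a damping factor ``δ ∈ [0, 1]``
applied to the pulsatile component of the distending pressure: fully packed
plugs acting in aggregate as a strain dampener correspond to δ → 1, an empty
sac to δ = 0.  The mean (diastolic) pressure is not damped, mirroring the
benchtop observation that sac pressure stays near lumen pressure while
pulsatile strain falls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .cine import CineLoop
from .hemodynamics import MMHG_TO_KPA, PressureTrace, pulse_pressure, synth_waveform

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "lame_displacement",
    "compliance",
    "calibrate_modulus",
    "effective_pressure",
    "annulus_area",
    "scatter_field",
    "render_frame",
    "generate_cine",
    "generate_rigid_cine",
]

logger = logging.getLogger(__name__)

#: Speed of sound in water/tissue used for the round-trip carrier phase, mm/µs.
SOUND_SPEED_MM_US = 1.540


def annulus_area(a: float, b: float) -> float:
    """Area of the wall annulus in mm²."""
    return math.pi * (b**2 - a**2)


def lame_displacement(
    r: np.ndarray | float,
    p_mmhg: float,
    a: float,
    b: float,
    young_kpa: float,
    poisson: float,
) -> np.ndarray | float:
    """Radial displacement (mm) of a pressurized thick-walled cylinder.

    Plane-strain Lamé solution for internal pressure ``p`` on ``a <= r <= b``::

        u(r) = (1 + ν) p a² / (Y (b² − a²)) · ((1 − 2ν) r + b² / r)

    ``p`` in mm Hg (converted to kPa internally), ``Y`` in kPa.  The ν = 0.5
    incompressible limit is the same expression with the (1 − 2ν) term zero.
    """
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    if young_kpa <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 <= poisson <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    r_arr = np.asarray(r, dtype=float)
    tol = 1e-9 * b
    if np.any(r_arr < a - tol) or np.any(r_arr > b + tol):
        raise ValueError("radius outside the wall [a, b]")
    r_arr = np.clip(r_arr, a, b)
    p_kpa = p_mmhg * MMHG_TO_KPA
    coeff = (1.0 + poisson) * p_kpa * a**2 / (young_kpa * (b**2 - a**2))
    u = coeff * ((1.0 - 2.0 * poisson) * r_arr + b**2 / r_arr)
    return u if np.ndim(r) else float(u)


def compliance(young_kpa: float, a: float, b: float, poisson: float) -> float:
    """Diameter compliance in %/100 mm Hg: 100 · Δd/d at 100 mm Hg."""
    return float(lame_displacement(a, 100.0, a, b, young_kpa, poisson)) / a * 100.0


def calibrate_modulus(
    target_compliance: float, a: float = 25.0, b: float = 27.5, poisson: float = 0.495
) -> float:
    """Young's modulus (kPa) giving the target diameter compliance.

    ``target_compliance`` in %/100 mm Hg (the phantom was validated at
    5–7%/100 mm Hg).  Inverts the Lamé expression; compliance is linear in
    1/Y so the inversion is exact, and a round trip through
    :func:`compliance` is enforced.
    """
    if not 0 < target_compliance < 50:
        raise ValueError("target compliance must lie in (0, 50) %/100 mm Hg")
    p_kpa = 100.0 * MMHG_TO_KPA
    y = (
        (1.0 + poisson)
        * p_kpa
        * a
        * ((1.0 - 2.0 * poisson) * a + b**2 / a)
        / ((target_compliance / 100.0) * (b**2 - a**2))
    )
    achieved = compliance(y, a, b, poisson)
    if abs(achieved - target_compliance) > 1e-6:
        raise AssertionError("compliance calibration round trip failed")
    return float(y)


def effective_pressure(
    p: np.ndarray | float, damping: float, p_dia: float
) -> np.ndarray | float:
    """Distending pressure felt by the wall under plug damping.

    Only the pulsatile component above diastolic is attenuated::

        p_eff = p_dia + (p − p_dia) (1 − δ)

    δ = 0 leaves the drive unchanged; δ = 1 freezes the wall at diastole.
    """
    if not 0.0 <= damping <= 1.0:
        raise ValueError("damping must lie in [0, 1]")
    out = p_dia + (np.asarray(p, dtype=float) - p_dia) * (1.0 - damping)
    return out if np.ndim(p) else float(out)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, material, drive, damping, and imaging parameters.

    Defaults describe the benchtop setup: a 50-mm sac (inner radius 25 mm)
    with a 2.5-mm wall of 6%/100 mm Hg-compliant silicone (Poisson ratio
    0.495, nearly incompressible), driven at 70 bpm by a skewed waveform
    whose pulse pressure equals the circuit's 83.4 mm Hg mean lumen value,
    imaged at 5 MHz over a 64-mm field of view at 256×256 px.
    """

    inner_radius: float = 25.0  # mm
    outer_radius: float = 27.5  # mm
    young_kpa: float | None = None  # calibrated from target_compliance when None
    poisson: float = 0.495
    target_compliance: float = 6.0  # %/100 mm Hg, used when young_kpa is None
    damping: float = 0.0
    heart_rate: float = 70.0  # bpm
    p_sys: float = 130.4  # mm Hg
    p_dia: float = 47.0  # mm Hg
    waveform_shape: str = "skewed"
    n_cycles: int = 1
    frames_per_cycle: int = 64
    pixel_spacing: float = 0.25  # mm/px
    image_size: int = 256  # px
    scatterer_density: float = 30.0  # per mm²
    psf_sigma_axial: float = 0.3  # mm
    psf_sigma_lateral: float = 0.6  # mm
    psf_frequency: float = 5.0  # MHz
    log_dynamic_range_db: float = 40.0
    noise_sigma: float = 0.05  # intensity units on the [0, 1] image
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if not 0.0 <= self.damping <= 1.0:
            raise ValueError("damping must lie in [0, 1]")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.frames_per_cycle < 8:
            raise ValueError("need at least 8 frames per cycle")
        if self.young_kpa is None:
            y = calibrate_modulus(
                self.target_compliance, self.inner_radius, self.outer_radius, self.poisson
            )
            object.__setattr__(self, "young_kpa", y)
        elif self.young_kpa <= 0:
            raise ValueError("Young's modulus must be positive")

    @property
    def center(self) -> tuple[float, float]:
        """Annulus center in image mm coordinates (x, y)."""
        c = (self.image_size - 1) / 2.0 * self.pixel_spacing
        return (c, c)

    @property
    def frame_rate(self) -> float:
        return self.frames_per_cycle * self.heart_rate / 60.0

    def with_(self, **changes) -> "PhantomConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth accompanying a generated cine.

    Per-frame lumen and effective pressures, incremental pressure relative
    to the end-diastolic reference frame, the true area-weighted mean
    circumferential Green–Lagrange strain per frame, its cycle maximum,
    the (undamped, lumen) pulse pressure, and the normalized strain.
    """

    config: PhantomConfig
    times: np.ndarray  # s
    lumen_pressure: np.ndarray  # mm Hg
    effective_pressure: np.ndarray  # mm Hg
    delta_p: np.ndarray  # mm Hg, wall load relative to frame 0
    mean_strain: np.ndarray  # ε̄ρ(t)
    eps_max: float  # ε̄ρ+
    eps_max_frame: int
    pp: float  # mm Hg
    eps_norm: float  # ε̄ρ+/PP, per mm Hg

    def radial_displacement(self, r: np.ndarray | float, frame: int) -> np.ndarray | float:
        """True radial displacement u(r) at a frame, mm."""
        cfg = self.config
        return lame_displacement(
            r, float(self.delta_p[frame]), cfg.inner_radius, cfg.outer_radius,
            cfg.young_kpa, cfg.poisson,
        )

    def displacement_at(self, points_mm: np.ndarray, frame: int) -> np.ndarray:
        """True 2-D displacement vectors at image-coordinate points (mm).

        ``points_mm`` has shape (N, 2) as (x, y) in the cine's coordinate
        frame.  Points must lie within the wall annulus.
        """
        cx, cy = self.config.center
        rel = np.asarray(points_mm, dtype=float) - [cx, cy]
        r = np.hypot(rel[:, 0], rel[:, 1])
        u = self.radial_displacement(r, frame)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = rel / r[:, None]
        return u[:, None] * unit

    def summary(self) -> dict[str, float]:
        return {
            "eps_max": self.eps_max,
            "eps_max_frame": self.eps_max_frame,
            "pp_mmhg": self.pp,
            "eps_norm_per_mmhg": self.eps_norm,
        }


def _true_mean_strain(delta_p: float, cfg: PhantomConfig, n_quad: int = 2001) -> float:
    """Area-weighted mean circumferential Green–Lagrange strain over the wall.

    For a radial displacement field the circumferential Green–Lagrange
    strain at radius r is u/r + u²/(2r²); the area weight in polar
    coordinates is r dr.
    """
    a, b = cfg.inner_radius, cfg.outer_radius
    r = np.linspace(a, b, n_quad)
    u = lame_displacement(r, delta_p, a, b, cfg.young_kpa, cfg.poisson)
    eps = u / r + u**2 / (2.0 * r**2)
    return float(np.trapezoid(eps * r, r) / np.trapezoid(r, r))


def scatter_field(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random acoustic scatterers filling the wall annulus.

    Returns ``(radii, angles, amplitudes)``: positions uniform over the
    annulus area (count Poisson-distributed at ``scatterer_density``),
    amplitudes standard normal.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    a, b = config.inner_radius, config.outer_radius
    n = int(rng.poisson(config.scatterer_density * annulus_area(a, b)))
    if n < 50:
        logger.warning("scatterer density yields only %d scatterers", n)
    radii = np.sqrt(rng.uniform(a**2, b**2, n))
    angles = rng.uniform(0.0, 2.0 * np.pi, n)
    amplitudes = rng.standard_normal(n)
    return radii, angles, amplitudes


def render_frame(
    positions_mm: np.ndarray,
    amplitudes: np.ndarray,
    config: PhantomConfig,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one B-mode-like frame from scatterer positions.

    ``positions_mm`` is (N, 2) as (x, y) in image mm coordinates, already
    displaced for this frame.  Each scatterer carries a round-trip carrier
    phase exp(i·4π·y/λ) at ``psf_frequency`` so axial motion produces the
    phase roll that real speckle exhibits; the complex field is splatted
    bilinearly, convolved with the anisotropic Gaussian PSF envelope,
    envelope-detected (magnitude), log-compressed over
    ``log_dynamic_range_db``, degraded with additive Gaussian noise, and
    clipped to [0, 1].  Scatterers displaced outside the image are dropped
    (count logged).
    """
    n_px = config.image_size
    ps = config.pixel_spacing
    x_px = positions_mm[:, 0] / ps
    y_px = positions_mm[:, 1] / ps
    inside = (x_px >= 0) & (x_px <= n_px - 1) & (y_px >= 0) & (y_px <= n_px - 1)
    n_dropped = int(np.size(inside) - np.count_nonzero(inside))
    if n_dropped:
        logger.info("render_frame: dropped %d scatterers outside the image", n_dropped)
    x_px, y_px = x_px[inside], y_px[inside]
    wavelength = SOUND_SPEED_MM_US / config.psf_frequency  # mm
    phase = np.exp(1j * 4.0 * np.pi * positions_mm[inside, 1] / wavelength)
    weights = amplitudes[inside] * phase

    field_c = np.zeros((n_px, n_px), dtype=np.complex128)
    ix = np.floor(x_px).astype(int)
    iy = np.floor(y_px).astype(int)
    fx = x_px - ix
    fy = y_px - iy
    ix1 = np.minimum(ix + 1, n_px - 1)
    iy1 = np.minimum(iy + 1, n_px - 1)
    np.add.at(field_c, (iy, ix), weights * (1 - fx) * (1 - fy))
    np.add.at(field_c, (iy, ix1), weights * fx * (1 - fy))
    np.add.at(field_c, (iy1, ix), weights * (1 - fx) * fy)
    np.add.at(field_c, (iy1, ix1), weights * fx * fy)

    sig = (config.psf_sigma_axial / ps, config.psf_sigma_lateral / ps)
    rf = gaussian_filter(field_c.real, sig) + 1j * gaussian_filter(field_c.imag, sig)
    env = np.abs(rf)
    peak = env.max()
    if peak <= 0:
        return np.zeros((n_px, n_px), dtype=np.float32)
    floor = 10.0 ** (-config.log_dynamic_range_db / 20.0)
    db = 20.0 * np.log10(np.maximum(env / peak, floor))
    img = (db + config.log_dynamic_range_db) / config.log_dynamic_range_db
    if noise_rng is not None and config.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, config.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _drive_trace(config: PhantomConfig) -> PressureTrace:
    return synth_waveform(
        config.heart_rate,
        config.p_sys,
        config.p_dia,
        n_cycles=config.n_cycles,
        samples_per_cycle=config.frames_per_cycle,
        shape=config.waveform_shape,
    )


def generate_cine(config: PhantomConfig) -> tuple[CineLoop, GroundTruth]:
    """Generate a pulsating-phantom cine and its analytic ground truth.

    Frame 0 is the undeformed end-diastolic reference; each later frame
    displaces every scatterer radially by the Lamé solution at the damped
    incremental pressure.  The ground-truth normalized strain divides the
    true strain maximum by the *undamped* lumen pulse pressure — the
    circuit's pulse pressure — which is what makes ε̄ρ+/PP fall as the plug
    damping δ rises.
    """
    radii, angles, amplitudes = scatter_field(config)
    trace = _drive_trace(config)
    p_eff = np.asarray(
        effective_pressure(trace.pressure, config.damping, config.p_dia), dtype=float
    )
    delta_p = p_eff - p_eff[0]
    cx, cy = config.center
    cos_t, sin_t = np.cos(angles), np.sin(angles)

    frames = np.empty((len(trace), config.image_size, config.image_size), dtype=np.float32)
    for t in range(len(trace)):
        u = lame_displacement(
            radii, float(delta_p[t]), config.inner_radius, config.outer_radius,
            config.young_kpa, config.poisson,
        )
        r_def = radii + u
        pos = np.column_stack((cx + r_def * cos_t, cy + r_def * sin_t))
        noise_rng = np.random.default_rng([config.seed, 1, t])
        frames[t] = render_frame(pos, amplitudes, config, noise_rng)

    mean_strain = np.array([_true_mean_strain(dp, config) for dp in delta_p])
    eps_max_frame = int(np.argmax(mean_strain))
    eps_max = float(mean_strain[eps_max_frame])
    pp = pulse_pressure(trace)
    truth = GroundTruth(
        config=config,
        times=trace.time.copy(),
        lumen_pressure=trace.pressure.copy(),
        effective_pressure=p_eff,
        delta_p=delta_p,
        mean_strain=mean_strain,
        eps_max=eps_max,
        eps_max_frame=eps_max_frame,
        pp=pp,
        eps_norm=eps_max / pp,
    )
    cine = CineLoop(frames=frames, pixel_spacing=config.pixel_spacing,
                    frame_rate=config.frame_rate)
    return cine, truth


def generate_rigid_cine(
    config: PhantomConfig,
    translation_mm: tuple[float, float] = (0.6, 0.4),
    rotation_deg: float = 1.0,
) -> tuple[CineLoop, dict]:
    """Generate a cine of the *undeformed* annulus moving rigidly.

    The whole scatterer field translates by ``translation_mm`` and rotates
    by ``rotation_deg`` about the annulus center, modulated by a
    raised-cosine cycle profile.  A strain pipeline applied to this loop
    should report (near) zero strain — the rigid-motion control.
    Returns the cine and the per-frame motion truth.
    """
    radii, angles, amplitudes = scatter_field(config)
    cx, cy = config.center
    n = config.n_cycles * config.frames_per_cycle
    profile = (1.0 - np.cos(2.0 * np.pi * np.arange(n) / config.frames_per_cycle)) / 2.0
    theta = np.deg2rad(rotation_deg) * profile
    tx = translation_mm[0] * profile
    ty = translation_mm[1] * profile

    frames = np.empty((n, config.image_size, config.image_size), dtype=np.float32)
    for t in range(n):
        ang = angles + theta[t]
        pos = np.column_stack(
            (cx + radii * np.cos(ang) + tx[t], cy + radii * np.sin(ang) + ty[t])
        )
        noise_rng = np.random.default_rng([config.seed, 1, t])
        frames[t] = render_frame(pos, amplitudes, config, noise_rng)
    cine = CineLoop(frames=frames, pixel_spacing=config.pixel_spacing,
                    frame_rate=config.frame_rate)
    motion = {"rotation_rad": theta, "translation_x_mm": tx, "translation_y_mm": ty}
    return cine, motion
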