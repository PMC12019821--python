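"""Analytic dynamic cardiac/torso phantom.

A beating left ventricle (LV) is modelled as a pair of concentric ellipsoids
(endocardium = blood pool, epicardium = outer myocardial shell) embedded in a
static torso ellipsoid.  Contraction scales the endocardial semi-axes with a
smooth periodic curve so the cavity volume has a closed form at every cardiac
phase; respiration translates the whole heart along the superior-inferior (SI,
+z) axis.  The phantom provides the ground-truth physiology (trigger times,
respiratory displacement, cavity volume) that the self-gating and volumetry
stages are later asked to recover.

World coordinates are in millimetres with the origin at the volume centre.
Cardiac phase is in [0, 1) with phase 0 = end-diastole (ED).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AnatomyConfig",
    "PhysioConfig",
    "PhysioTrace",
    "DynamicPhantom",
    "anatomy_for_volumes",
    "contraction_scale",
    "default_phantom",
    "generate_physio",
    "make_coil_maps",
    "render_volume",
    "true_cavity_volume",
]

MIN_RR_MS = 300.0


@dataclass
class AnatomyConfig:
    """Geometry and tissue contrast of the synthetic heart and torso."""

    lv_center: np.ndarray = field(default_factory=lambda: np.array([10.0, 20.0, 0.0]))
    lv_long_axis: np.ndarray = field(
        default_factory=lambda: np.array([np.sin(np.deg2rad(15.0)), 0.0, np.cos(np.deg2rad(15.0))])
    )
    endo_semi_axes_ed: tuple[float, float, float] = (30.9, 30.9, 40.2)
    epi_wall_thickness: float = 10.0
    contraction_fraction: float = 0.317
    es_phase: float = 0.38
    tissue_intensities: tuple[float, float, float] = (1.0, 0.35, 0.15)  # blood, myo, bg
    torso_semi_axes: tuple[float, float, float] = (100.0, 85.0, 105.0)

    def __post_init__(self) -> None:
        self.lv_center = np.asarray(self.lv_center, dtype=float)
        axis = np.asarray(self.lv_long_axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("lv_long_axis must be a nonzero direction")
        self.lv_long_axis = axis / n
        if not all(a > 0 for a in self.endo_semi_axes_ed):
            raise ValueError("endo semi-axes must be positive")
        if not 0.0 <= self.contraction_fraction < 1.0:
            raise ValueError("contraction_fraction must lie in [0, 1)")
        if not 0.0 < self.es_phase < 1.0:
            raise ValueError("es_phase must lie in (0, 1)")
        blood, myo, _ = self.tissue_intensities
        if blood <= myo:
            raise ValueError("bright-blood contrast requires blood > myocardium intensity")

    def heart_basis(self) -> np.ndarray:
        """Orthonormal basis (columns: short axis a, short axis b, long axis)."""
        w = self.lv_long_axis
        helper = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(helper, w)) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        u = np.cross(helper, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return np.stack([u, v, w], axis=1)


@dataclass
class PhysioConfig:
    """Heart-rate and breathing parameters of one synthetic subject."""

    heart_rate_mean: float = 70.0  # bpm
    rr_jitter_sd: float = 25.0  # ms
    resp_rate: float = 14.0  # breaths/min
    resp_amplitude: float = 14.0  # mm SI translation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 <= self.heart_rate_mean <= 200.0:
            raise ValueError("heart_rate_mean outside [30, 200] bpm")
        if not 4.0 <= self.resp_rate <= 40.0:
            raise ValueError("resp_rate outside [4, 40] breaths/min")
        if self.resp_amplitude < 0:
            raise ValueError("resp_amplitude must be >= 0")


@dataclass
class PhysioTrace:
    """Sampled ground-truth physiology over one acquisition.

    ``times`` holds one sample per repetition interval (TR); ``cardiac_phase``
    resets to zero exactly at each true trigger; ``resp_displacement`` is the
    SI translation of the heart in mm.
    """

    times: np.ndarray
    cardiac_phase: np.ndarray
    resp_displacement: np.ndarray
    true_trigger_times: np.ndarray
    rr_intervals: np.ndarray  # ms, one per beat starting at each trigger
    resp_amplitude: float

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        # interpolate the monotone cumulative phase (beat index + phase) so the
        # sawtooth wrap at each trigger does not produce spurious mid-phases
        beat = np.searchsorted(self.true_trigger_times, self.times, side="right") - 1
        cumulative = np.clip(beat, 0, None) + self.cardiac_phase
        return np.interp(t, self.times, cumulative) % 1.0

    def displacement_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.resp_displacement)


def generate_physio(config: PhysioConfig, duration: float, tr: float) -> PhysioTrace:
    """Simulate beat-to-beat RR intervals and a breathing waveform.

    Parameters
    ----------
    config : PhysioConfig
    duration : float
        Acquisition duration in seconds.
    tr : float
        Repetition time in milliseconds (one physio sample per TR).

    RR intervals are ``60000 / heart_rate_mean`` plus zero-mean Gaussian
    jitter (sd ``rr_jitter_sd`` ms); any draw at or below 300 ms is resampled
    so no unphysiological beat is ever emitted.  Respiratory displacement is
    ``resp_amplitude * sin**4(pi * t / T_resp)``, which dwells near zero
    (end-expiration) much longer than at peak inspiration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if tr <= 0:
        raise ValueError("tr must be positive")
    rng = np.random.default_rng(config.seed)
    mean_rr = 60000.0 / config.heart_rate_mean

    triggers = [0.0]
    rrs = []
    # cover slightly past the acquisition so every time has a following beat
    if config.rr_jitter_sd == 0 and mean_rr <= MIN_RR_MS:
        raise ValueError("mean RR interval must exceed 300 ms")
    while triggers[-1] < duration + 2 * mean_rr / 1000.0:
        rr = mean_rr + (rng.normal(0.0, config.rr_jitter_sd) if config.rr_jitter_sd > 0 else 0.0)
        while rr <= MIN_RR_MS:
            rr = mean_rr + rng.normal(0.0, config.rr_jitter_sd)
        rrs.append(rr)
        triggers.append(triggers[-1] + rr / 1000.0)
    triggers = np.asarray(triggers)
    rrs = np.asarray(rrs)

    times = np.arange(0.0, duration, tr / 1000.0)
    beat = np.searchsorted(triggers, times, side="right") - 1
    phase = (times - triggers[beat]) / (rrs[beat] / 1000.0)
    phase = np.clip(phase, 0.0, np.nextafter(1.0, 0.0))

    t_resp = 60.0 / config.resp_rate
    disp = config.resp_amplitude * np.sin(np.pi * times / t_resp) ** 4

    in_window = triggers < duration
    return PhysioTrace(
        times=times,
        cardiac_phase=phase,
        resp_displacement=disp,
        true_trigger_times=triggers[in_window],
        rr_intervals=rrs[in_window[:-1]] if in_window[:-1].size else rrs[:0],
        resp_amplitude=config.resp_amplitude,
    )


def contraction_scale(phase, contraction_fraction: float, es_phase: float):
    """Smooth periodic short-axis scale s(phase): 1 at ED, 1-cf at ES.

    Piecewise sin^2 in phase, C1-continuous at both ES and the wrap point.
    """
    phase = np.asarray(phase, dtype=float)
    s = np.empty_like(phase)
    systole = phase <= es_phase
    s[systole] = 1.0 - contraction_fraction * np.sin(np.pi * phase[systole] / (2.0 * es_phase)) ** 2
    d = ~systole
    s[d] = 1.0 - contraction_fraction * np.sin(
        np.pi * (1.0 - phase[d]) / (2.0 * (1.0 - es_phase))
    ) ** 2
    return s if s.shape else float(s)


def _semi_axes_at(anatomy: AnatomyConfig, phase: float) -> np.ndarray:
    a, b, c = anatomy.endo_semi_axes_ed
    s = contraction_scale(phase, anatomy.contraction_fraction, anatomy.es_phase)
    s_long = contraction_scale(phase, anatomy.contraction_fraction / 2.0, anatomy.es_phase)
    return np.array([a * s, b * s, c * s_long])


def make_coil_maps(
    grid_shape: tuple[int, int, int],
    fov: float,
    n_coils: int = 8,
    torso_semi_axes: tuple[float, float, float] = (100.0, 85.0, 105.0),
) -> np.ndarray:
    """Smooth complex receive sensitivities: Gaussian magnitude lobes placed
    around the torso perimeter with a gentle linear phase per channel.

    Returns an array of shape ``(n_coils, *grid_shape)`` (complex64).
    """
    coords = _voxel_coords(grid_shape, fov)
    ax, ay, _ = torso_semi_axes
    sigma = 0.65 * fov
    maps = np.empty((n_coils,) + tuple(grid_shape), dtype=np.complex64)
    for k in range(n_coils):
        ang = 2.0 * np.pi * k / n_coils
        center = np.array([1.15 * ax * np.cos(ang), 1.15 * ay * np.sin(ang), 0.0])
        # alternate coil rings above/below the axial mid-plane
        center[2] = 40.0 if k % 2 else -40.0
        d2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
        mag = np.exp(-d2 / (2.0 * sigma**2))
        grad = np.array([np.cos(ang + 0.7), np.sin(ang + 0.7), 0.3 * (-1) ** k]) / fov
        phs = 2.0 * np.pi * 0.35 * sum(coords[i] * grad[i] for i in range(3)) + ang
        maps[k] = (mag * np.exp(1j * phs)).astype(np.complex64)
    return maps


@dataclass
class DynamicPhantom:
    """Discretised view of the analytic anatomy plus coil sensitivities."""

    anatomy: AnatomyConfig
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    fov: float = 220.0
    coil_maps: np.ndarray | None = None

    def __post_init__(self) -> None:
        gs = np.atleast_1d(np.asarray(self.grid_shape, dtype=int))
        if gs.size == 1:
            gs = np.repeat(gs, 3)
        if gs.size != 3:
            raise ValueError("grid_shape must have three axes")
        self.grid_shape = tuple(int(x) for x in gs)
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 per axis")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.coil_maps is None:
            self.coil_maps = make_coil_maps(
                self.grid_shape, self.fov, torso_semi_axes=self.anatomy.torso_semi_axes
            )
        if not np.any(np.abs(self.coil_maps) > 0):
            raise ValueError("coil maps vanish everywhere")

    @property
    def voxel_size(self) -> float:
        return self.fov / self.grid_shape[0]

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]


def _voxel_coords(grid_shape, fov):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * (fov / n)
        for n in grid_shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(points, center, basis, semi_axes):
    """points: tuple of coordinate arrays; returns boolean membership."""
    rel = [points[i] - center[i] for i in range(3)]
    q = 0.0
    for j in range(3):
        proj = rel[0] * basis[0, j] + rel[1] * basis[1, j] + rel[2] * basis[2, j]
        q = q + (proj / semi_axes[j]) ** 2
    return q <= 1.0


def _render_points(phantom, points, cardiac_phase, resp_displacement, labels=False):
    an = phantom.anatomy
    basis = an.heart_basis()
    blood_i, myo_i, bg_i = an.tissue_intensities
    shift = np.array([0.0, 0.0, resp_displacement])
    heart_center = an.lv_center + shift

    endo_axes = _semi_axes_at(an, cardiac_phase)
    epi_axes = np.asarray(an.endo_semi_axes_ed) + an.epi_wall_thickness

    torso = _ellipsoid_mask(points, np.zeros(3), np.eye(3), np.asarray(an.torso_semi_axes))
    epi = _ellipsoid_mask(points, heart_center, basis, epi_axes)
    endo = _ellipsoid_mask(points, heart_center, basis, endo_axes)

    if labels:
        lab = np.zeros(points[0].shape, dtype=np.int8)
        lab[torso] = 1
        lab[epi] = 2
        lab[endo] = 3
        return lab
    vol = np.zeros(points[0].shape, dtype=np.float32)
    vol[torso] = bg_i
    vol[epi] = myo_i
    vol[endo] = blood_i
    return vol


def render_volume(
    phantom: DynamicPhantom,
    cardiac_phase: float,
    resp_displacement: float,
    labels: bool = False,
) -> np.ndarray:
    """Voxelise the phantom at one motion state (binary occupancy, no partial
    volume).  ``labels=True`` returns the tissue label map (0 bg outside torso,
    1 torso, 2 myocardium, 3 blood) instead of intensities."""
    if not 0.0 <= cardiac_phase < 1.0:
        raise ValueError("cardiac_phase must lie in [0, 1)")
    an = phantom.anatomy
    epi_extent = max(np.asarray(an.endo_semi_axes_ed) + an.epi_wall_thickness)
    z_reach = abs(an.lv_center[2] + resp_displacement) + epi_extent
    if z_reach > phantom.fov / 2.0:
        raise ValueError(
            f"respiratory displacement {resp_displacement} mm pushes the heart outside the FOV"
        )
    points = _voxel_coords(phantom.grid_shape, phantom.fov)
    return _render_points(phantom, points, cardiac_phase, resp_displacement, labels=labels)


def render_plane(
    phantom: DynamicPhantom,
    cardiac_phase: float,
    resp_displacement: float,
    center: np.ndarray,
    in_plane_axes: np.ndarray,
    extent: float,
    n_pixels: int,
    labels: bool = False,
) -> np.ndarray:
    """Analytically render one oblique plane (used by the 2D cine reference
    and by ground-truth masks).  ``in_plane_axes`` is a (2, 3) array of
    orthonormal in-plane directions; ``extent`` is the in-plane FOV in mm."""
    u = np.asarray(in_plane_axes[0], float)
    v = np.asarray(in_plane_axes[1], float)
    px = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * (extent / n_pixels)
    uu, vv = np.meshgrid(px, px, indexing="ij")
    points = tuple(center[i] + uu * u[i] + vv * v[i] for i in range(3))
    return _render_points(phantom, points, cardiac_phase, resp_displacement, labels=labels)


def true_cavity_volume(phantom: DynamicPhantom, cardiac_phase) -> float:
    """Closed-form LV blood-pool volume in mL at the given cardiac phase."""
    phase = np.asarray(cardiac_phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("cardiac_phase must lie in [0, 1)")
    an = phantom.anatomy
    a, b, c = an.endo_semi_axes_ed
    s = contraction_scale(phase, an.contraction_fraction, an.es_phase)
    s_long = contraction_scale(phase, an.contraction_fraction / 2.0, an.es_phase)
    vol = np.asarray((4.0 / 3.0) * np.pi * (a * s) * (b * s) * (c * s_long) / 1000.0)
    return float(vol) if vol.ndim == 0 else vol


def true_ef(anatomy: AnatomyConfig) -> float:
    """Analytic ejection fraction (%) implied by the contraction curve."""
    cf = anatomy.contraction_fraction
    return 100.0 * (1.0 - (1.0 - cf) ** 2 * (1.0 - cf / 2.0))


def anatomy_for_volumes(edv_ml: float, ef_pct: float, **kwargs) -> AnatomyConfig:
    """Build an anatomy whose analytic EDV and EF match the requested values.

    Semi-axes keep the default prolate shape (c = 1.3 a); the contraction
    fraction is solved from EF = 100 * (1 - (1-cf)^2 (1-cf/2)).
    """
    if not 0 < ef_pct < 100:
        raise ValueError("ef_pct must lie in (0, 100)")
    a = (edv_ml * 1000.0 * 3.0 / (4.0 * np.pi * 1.3)) ** (1.0 / 3.0)
    target = 1.0 - ef_pct / 100.0

    def f(cf):
        return (1.0 - cf) ** 2 * (1.0 - cf / 2.0) - target

    cf = brentq(f, 1e-6, 0.95)
    return AnatomyConfig(endo_semi_axes_ed=(a, a, 1.3 * a), contraction_fraction=cf, **kwargs)


def default_phantom(grid: int = 48, edv_ml: float = 160.0, ef_pct: float = 61.0, **kwargs) -> DynamicPhantom:
    """Convenience constructor for the standard desk-scale phantom."""
    return DynamicPhantom(anatomy=anatomy_for_volumes(edv_ml, ef_pct), grid_shape=(grid,) * 3, **kwargs)
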