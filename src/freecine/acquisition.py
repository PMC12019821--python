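"""Free-running 3D radial acquisition and breath-held 2D cine reference.

The free-running sequence samples k-space along full-diameter radial readouts
whose endpoints follow the spiral phyllotaxis rule on the upper hemisphere
(golden-angle azimuthal increments of 137.51 deg, polar angle proportional to
sqrt of the point index).  Each interleave comprises ``readouts_per_interleave``
TRs, the first of which is a superior-inferior (SI) self-gating readout, so
the SG cadence is ``readouts_per_interleave * tr`` (77.66 ms at the defaults,
i.e. one SG sample every ~80 ms).

Simulation renders the analytic phantom at each readout's motion state and
evaluates the coil-weighted volume along the readout's radial line with the
gridding NUFFT.  Cardiac phase and respiratory displacement are quantised
(1/64 cycle, 1/4 voxel) so repeated motion states share one rendered volume
and one FFT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nufft import GriddingPlan, NufftOperator3D
from .phantom import DynamicPhantom, PhysioTrace, render_plane

logger = logging.getLogger(__name__)

__all__ = [
    "RadialTrajectory",
    "KSpaceData",
    "CineStackReference",
    "phyllotaxis_trajectory",
    "duration_of",
    "preset_interleaves",
    "interleaves_for_duration",
    "acquisition_efficiency",
    "simulate_kspace",
    "simulate_2d_cine_reference",
]

GOLDEN_ANGLE_DEG = 137.51
#: spiral interleave counts used for the 1..6 minute acquisitions
PRESET_INTERLEAVES = {1: 762, 2: 1516, 3: 2322, 4: 3058, 5: 3833, 6: 4621}
DEFAULT_TR_MS = 3.53
DEFAULT_READOUTS_PER_INTERLEAVE = 22


@dataclass
class RadialTrajectory:
    """Readout geometry and timing of one free-running acquisition."""

    directions: np.ndarray  # (n_readouts, 3) unit vectors
    sample_radii: np.ndarray  # (n_samples,) normalized radius in [-0.5, 0.5)
    interleave_index: np.ndarray  # (n_readouts,)
    readout_index_in_interleave: np.ndarray  # (n_readouts,)
    timestamps: np.ndarray  # (n_readouts,) seconds
    is_sg: np.ndarray  # (n_readouts,) bool
    tr: float  # ms
    readouts_per_interleave: int

    @property
    def n_readouts(self) -> int:
        return self.directions.shape[0]

    @property
    def n_interleaves(self) -> int:
        return int(self.interleave_index.max()) + 1

    @property
    def sg_interval_ms(self) -> float:
        return self.readouts_per_interleave * self.tr

    def kpoints(self, readout_mask=None) -> np.ndarray:
        """Sample coordinates (n_sel * n_samples, 3) in cycles/voxel."""
        d = self.directions if readout_mask is None else self.directions[readout_mask]
        return (d[:, None, :] * self.sample_radii[None, :, None]).reshape(-1, 3)

    def duration(self) -> float:
        return self.n_readouts * self.tr / 1000.0


@dataclass
class KSpaceData:
    """Complex multi-coil samples bound to their trajectory and ground truth."""

    samples: np.ndarray  # (n_readouts, n_samples, n_coils) complex
    trajectory: RadialTrajectory
    noise_sd: float
    physio: PhysioTrace | None = None
    seed: int | None = None
    fov: float = 220.0  # mm, isotropic

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]


@dataclass
class CineStackReference:
    """Simulated breath-held short-axis 2D cine stack (end-expiratory)."""

    images: np.ndarray  # (n_slices, n_phases, rows, cols)
    slice_centers: np.ndarray  # (n_slices, 3) world mm
    slice_normal: np.ndarray
    in_plane_axes: np.ndarray  # (2, 3)
    pixel_mm: float
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    n_phases: int = 25

    @property
    def slice_spacing(self) -> float:
        return self.slice_thickness + self.slice_gap

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]


def phyllotaxis_trajectory(
    n_interleaves: int,
    readouts_per_interleave: int = DEFAULT_READOUTS_PER_INTERLEAVE,
    tr: float = DEFAULT_TR_MS,
    n_samples: int = 48,
) -> RadialTrajectory:
    """Spiral phyllotaxis trajectory with one SI self-gating readout per interleave.

    Imaging endpoint ``m`` (0-based, ``m < N = n_interleaves * (rpi - 1)``) has
    polar angle ``(pi/2) * sqrt(m / N)`` and azimuth ``m * 137.51 deg``;
    imaging readout ``j`` (1..rpi-1) of interleave ``i`` uses endpoint
    ``m = (j - 1) * n_interleaves + i``, so each interleave traces one smooth
    spiral arm from pole to equator.  Readout 0 of each interleave points
    along +SI (the self-gating readout).  Every readout samples a full
    diameter with ``n_samples`` points, radii ``(arange(n) - n//2) / n``.
    """
    if n_interleaves < 1:
        raise ValueError("n_interleaves must be >= 1")
    if readouts_per_interleave < 2:
        raise ValueError("readouts_per_interleave must be >= 2")
    rpi = int(readouts_per_interleave)
    n_img = n_interleaves * (rpi - 1)

    m = np.arange(n_img, dtype=np.float64)
    theta = (np.pi / 2.0) * np.sqrt(m / n_img)
    psi = m * np.deg2rad(GOLDEN_ANGLE_DEG)
    endpoints = np.stack(
        [np.sin(theta) * np.cos(psi), np.sin(theta) * np.sin(psi), np.cos(theta)], axis=1
    )

    n_total = n_interleaves * rpi
    directions = np.zeros((n_total, 3))
    interleave = np.repeat(np.arange(n_interleaves), rpi)
    within = np.tile(np.arange(rpi), n_interleaves)
    sg = within == 0
    directions[sg] = [0.0, 0.0, 1.0]
    j = within[~sg]  # 1..rpi-1
    i = interleave[~sg]
    directions[~sg] = endpoints[(j - 1) * n_interleaves + i]

    radii = (np.arange(n_samples) - n_samples // 2) / n_samples
    timestamps = np.arange(n_total) * tr / 1000.0
    return RadialTrajectory(
        directions=directions,
        sample_radii=radii,
        interleave_index=interleave,
        readout_index_in_interleave=within,
        timestamps=timestamps,
        is_sg=sg,
        tr=tr,
        readouts_per_interleave=rpi,
    )


def duration_of(
    n_interleaves: int,
    tr: float = DEFAULT_TR_MS,
    readouts_per_interleave: int = DEFAULT_READOUTS_PER_INTERLEAVE,
) -> float:
    """Acquisition duration in seconds of ``n_interleaves`` spiral interleaves."""
    if n_interleaves <= 0 or tr <= 0 or readouts_per_interleave <= 0:
        raise ValueError("arguments must be positive")
    return n_interleaves * readouts_per_interleave * tr / 1000.0


def preset_interleaves(duration_label: int) -> int:
    """Interleave count of the 1..6 minute preset acquisitions."""
    try:
        return PRESET_INTERLEAVES[int(duration_label)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"duration label must be one of 1..6 min, got {duration_label!r}") from exc


def interleaves_for_duration(
    seconds: float,
    tr: float = DEFAULT_TR_MS,
    readouts_per_interleave: int = DEFAULT_READOUTS_PER_INTERLEAVE,
) -> int:
    """Interleave count for an arbitrary duration (floor of whole interleaves)."""
    if seconds <= 0:
        raise ValueError("duration must be positive")
    return int(np.floor(seconds * 1000.0 / (readouts_per_interleave * tr)))


def acquisition_efficiency(sampling_time: float, total_time: float) -> float:
    """Percent of total scanner time spent sampling data."""
    if not 0 < sampling_time <= total_time:
        raise ValueError("need 0 < sampling_time <= total_time")
    return 100.0 * sampling_time / total_time


def simulate_kspace(
    phantom: DynamicPhantom,
    traj: RadialTrajectory,
    physio: PhysioTrace,
    noise_sd: float = 0.0,
    seed: int | None = None,
    osf: float = 1.5,
    width: int = 3,
) -> KSpaceData:
    """Multi-coil radial k-space of the moving phantom.

    Each readout is attributed the motion state at its timestamp (looked up on
    a 10 ms grid), the phantom is rendered at that state, multiplied by each
    coil map and evaluated along the readout's radial line by the gridding
    NUFFT.  i.i.d. complex Gaussian noise of standard deviation ``noise_sd``
    is added to every sample.
    """
    from .phantom import render_volume

    t_end = traj.timestamps[-1]
    if physio.times[-1] + 1e-9 < t_end:
        raise ValueError(
            f"physio trace ({physio.times[-1]:.2f} s) does not cover the trajectory ({t_end:.2f} s)"
        )
    plan = GriddingPlan(phantom.grid_shape, osf=osf, width=width)

    t_q = np.floor(traj.timestamps / 0.01) * 0.01
    phase = physio.phase_at(t_q)
    disp = physio.displacement_at(t_q)
    # quantize motion states so repeated states share one render + FFT
    phase_q = np.round(phase * 64.0) / 64.0 % 1.0
    disp_step = phantom.voxel_size / 4.0
    disp_q = np.round(disp / disp_step) * disp_step

    n_coils = phantom.n_coils
    n_samp = traj.sample_radii.size
    samples = np.empty((traj.n_readouts, n_samp, n_coils), dtype=np.complex64)

    keys = np.stack([phase_q, disp_q], axis=1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    boundaries = np.flatnonzero(np.diff(inverse[order])) + 1
    groups = np.split(order, boundaries)

    maps = phantom.coil_maps.astype(np.complex64)
    for grp in groups:
        ph, dz = phase_q[grp[0]], disp_q[grp[0]]
        vol = render_volume(phantom, float(ph), float(dz))
        coil_vols = maps * vol[None]
        op = NufftOperator3D(plan, traj.kpoints(grp))
        vals = op.forward(coil_vols)  # (len(grp)*n_samp, n_coils)
        samples[grp] = vals.reshape(len(grp), n_samp, n_coils)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, samples.shape) + 1j * rng.normal(
            0.0, noise_sd, samples.shape
        )
        samples = (samples + noise.astype(np.complex64)).astype(np.complex64)

    return KSpaceData(
        samples=samples, trajectory=traj, noise_sd=noise_sd, physio=physio, seed=seed,
        fov=phantom.fov,
    )


def simulate_2d_cine_reference(
    phantom: DynamicPhantom,
    n_slices: int,
    n_phases: int = 25,
    slice_thickness: float = 8.0,
    slice_gap: float = 2.0,
    pixel_mm: float = 1.7,
    in_plane_fov: float = 220.0,
    n_subslices: int = 5,
) -> CineStackReference:
    """Breath-held short-axis cine stack, rendered analytically at end-expiration.

    Slices are perpendicular to the LV long axis with 10 mm centre spacing
    (8 mm slab + 2 mm gap), each slab averaged over ``n_subslices`` analytic
    sub-planes, 25 uniformly spaced cardiac phases, no noise.
    """
    an = phantom.anatomy
    basis = an.heart_basis()
    normal = basis[:, 2]
    axes = basis[:, :2].T  # (2, 3) in-plane directions
    spacing = slice_thickness + slice_gap

    offsets = (np.arange(n_slices) - (n_slices - 1) / 2.0) * spacing
    centers = an.lv_center[None, :] + offsets[:, None] * normal[None, :]

    lv_half_length = an.endo_semi_axes_ed[2] + an.epi_wall_thickness
    if offsets[0] > -lv_half_length or offsets[-1] < lv_half_length:
        logger.warning(
            "2D cine stack (%d slices, spacing %.0f mm) may not cover the LV (half-length %.0f mm)",
            n_slices, spacing, lv_half_length,
        )

    n_px = int(round(in_plane_fov / pixel_mm))
    sub = np.linspace(-slice_thickness / 2.0, slice_thickness / 2.0, n_subslices)
    images = np.zeros((n_slices, n_phases, n_px, n_px), dtype=np.float32)
    for p in range(n_phases):
        phase = p / n_phases
        for s in range(n_slices):
            acc = np.zeros((n_px, n_px), dtype=np.float64)
            for dz in sub:
                c = centers[s] + dz * normal
                acc += render_plane(phantom, phase, 0.0, c, axes, in_plane_fov, n_px)
            images[s, p] = acc / n_subslices

    return CineStackReference(
        images=images,
        slice_centers=centers,
        slice_normal=normal,
        in_plane_axes=axes,
        pixel_mm=in_plane_fov / n_px,
        slice_thickness=slice_thickness,
        slice_gap=slice_gap,
        n_phases=n_phases,
    )
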