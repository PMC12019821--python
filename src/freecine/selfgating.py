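"""Cardiac/respiratory motion extraction from the self-gating readouts.

The SI self-gating spokes are turned into per-coil projection profiles, the
profile matrix is whitened by PCA and unmixed by second-order blind
identification (SOBI): approximate joint diagonalisation of time-lagged
covariance matrices by Jacobi (Givens) rotations.  Physiological sources are
then selected by their in-band periodogram power, cardiac triggers by peak
picking on the band-passed cardiac source, and four equally populated
respiratory amplitude states by rank quartiles with the end-expiratory state
identified by its dwell time (breathing plateaus near end-expiration, so the
blind polarity of the source can be fixed without a sign convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy import signal

from .acquisition import KSpaceData

logger = logging.getLogger(__name__)

__all__ = [
    "SGSeries",
    "MotionSignals",
    "TriggerList",
    "build_sg_series",
    "sobi_unmix",
    "select_physio_sources",
    "detect_triggers",
    "respiratory_states",
]

RESP_BAND = (0.08, 0.5)  # Hz
CARDIAC_BAND = (0.5, 3.0)  # Hz
MIN_INBAND_FRACTION = 0.4
MIN_TRIGGER_SEPARATION_S = 0.3


@dataclass
class SGSeries:
    """Detrended per-coil SI projection magnitudes, one row per interleave."""

    matrix: np.ndarray  # (n_sg, n_features)
    sg_interval: float  # ms
    timestamps: np.ndarray  # (n_sg,) seconds


@dataclass
class MotionSignals:
    """Selected unit-variance cardiac and respiratory sources."""

    cardiac: np.ndarray
    respiratory: np.ndarray
    f_cardiac: float  # Hz
    f_respiratory: float  # Hz
    timestamps: np.ndarray
    sg_interval: float  # ms
    mixing_diagnostics: dict


@dataclass
class TriggerList:
    """Strictly increasing cardiac trigger times in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("trigger times must be strictly increasing")
        self.times = t

    def median_rr_ms(self) -> float:
        return float(np.median(np.diff(self.times)) * 1000.0)


def build_sg_series(kdata: KSpaceData) -> SGSeries:
    """SI projections of the self-gating spokes, magnitude, linearly detrended.

    Each SG readout is a radial spoke along +SI; its 1D inverse Fourier
    transform is the projection of the coil-weighted volume onto the SI axis.
    Features are the per-coil projection magnitudes concatenated along the
    sample axis; each column is detrended to remove slow scanner drift and the
    static anatomy baseline.
    """
    traj = kdata.trajectory
    sg_mask = traj.is_sg
    n_sg = int(sg_mask.sum())
    if n_sg < 8:
        raise ValueError(f"need at least 8 SG readouts, found {n_sg}")
    spokes = kdata.samples[sg_mask]  # (n_sg, n_samples, n_coils)
    proj = sfft.fftshift(
        sfft.ifft(sfft.ifftshift(spokes, axes=1), axis=1, norm="ortho"), axes=1
    )
    feats = np.abs(proj).reshape(n_sg, -1).astype(np.float64)
    feats = signal.detrend(feats, axis=0, type="linear")
    return SGSeries(
        matrix=feats,
        sg_interval=traj.sg_interval_ms,
        timestamps=traj.timestamps[sg_mask],
    )


def _joint_diagonalize(mats: np.ndarray, threshold: float = 1e-8, max_sweeps: int = 100):
    """Jacobi approximate joint diagonalisation of symmetric matrices.

    ``mats``: (n_mats, r, r).  Returns the orthogonal rotation ``V`` such that
    ``V.T @ C @ V`` is as diagonal as possible for all C (Cardoso-Souloumiac
    Givens-rotation scheme).
    """
    c = np.array(mats, dtype=np.float64, copy=True)
    r = c.shape[1]
    v = np.eye(r)
    for _ in range(max_sweeps):
        rotated = False
        for p in range(r - 1):
            for q in range(p + 1, r):
                h1 = c[:, p, p] - c[:, q, q]
                h2 = c[:, p, q] + c[:, q, p]
                g11 = np.dot(h1, h1)
                g12 = np.dot(h1, h2)
                g22 = np.dot(h2, h2)
                ton = g11 - g22
                toff = 2.0 * g12
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                cs, sn = np.cos(theta), np.sin(theta)
                if abs(sn) <= threshold:
                    continue
                rotated = True
                rot = np.array([[cs, -sn], [sn, cs]])
                idx = [p, q]
                c[:, idx, :] = np.einsum("ij,njk->nik", rot.T, c[:, idx, :])
                c[:, :, idx] = np.einsum("nij,jk->nik", c[:, :, idx], rot)
                v[:, idx] = v[:, idx] @ rot
        if not rotated:
            break
    return v, c


@dataclass
class SobiResult:
    sources: np.ndarray  # (n_times, n_sources), unit variance
    rotation: np.ndarray
    whitener: np.ndarray  # maps features -> whitened components
    explained_variance: np.ndarray


def sobi_unmix(series: SGSeries, n_components: int = 8, lags=range(1, 26)) -> SobiResult:
    """PCA-whiten the SG matrix and jointly diagonalise its lagged covariances.

    Lags 1..25 at the ~78 ms SG cadence span ~0.08-1.9 s, covering both the
    cardiac and respiratory correlation times.  If the matrix rank is lower
    than ``n_components`` the decomposition proceeds at the available rank
    with a logged warning.
    """
    x = series.matrix - series.matrix.mean(axis=0)
    t = x.shape[0]
    if t < 4 * n_components:
        raise ValueError("need at least 4*n_components SG time points")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    r = min(n_components, rank)
    if r < n_components:
        logger.warning("SG matrix rank %d < requested %d components", rank, n_components)
    z = u[:, :r] * np.sqrt(t)  # whitened, unit variance components

    lags = [int(l) for l in lags if l < t]
    covs = np.empty((len(lags), r, r))
    for i, lag in enumerate(lags):
        c = z[:-lag].T @ z[lag:] / (t - lag)
        covs[i] = 0.5 * (c + c.T)
    rot, _ = _joint_diagonalize(covs)
    sources = z @ rot
    sources /= sources.std(axis=0, ddof=0)
    whitener = None  # feature-space unmixing not needed downstream
    return SobiResult(
        sources=sources,
        rotation=rot,
        whitener=whitener,
        explained_variance=(s[:r] ** 2) / (s**2).sum(),
    )


def _band_fraction(source: np.ndarray, fs: float, band: tuple[float, float]):
    freqs, power = signal.periodogram(source, fs=fs, detrend="constant")
    keep = freqs > 0
    freqs, power = freqs[keep], power[keep]
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    total = power.sum()
    if total == 0 or not in_band.any():
        return 0.0, np.nan
    frac = power[in_band].sum() / total
    f_peak = freqs[in_band][np.argmax(power[in_band])]
    return float(frac), float(f_peak)


def select_physio_sources(
    sobi: SobiResult,
    sg_interval: float,
    timestamps: np.ndarray,
    resp_band: tuple[float, float] = RESP_BAND,
    cardiac_band: tuple[float, float] = CARDIAC_BAND,
) -> MotionSignals:
    """Pick the respiratory and cardiac sources by in-band periodogram power.

    For each band the source maximising the in-band power fraction wins; the
    selection fails (raises) if the best fraction is below 0.4 or if both
    bands select the same source with no runner-up.  The cardiac frequency
    must lie below the SG Nyquist limit ``1000 / (2 * sg_interval)``.
    """
    sources = sobi.sources
    if sources.shape[1] < 2:
        raise ValueError("need at least 2 sources")
    duration = timestamps[-1] - timestamps[0]
    if duration < 10.0:
        raise ValueError("record too short for physiological selection (< 10 s)")
    fs = 1000.0 / sg_interval
    nyq = fs / 2.0

    fracs = {}
    for name, band in (("respiratory", resp_band), ("cardiac", cardiac_band)):
        if band[0] >= nyq:
            raise ValueError(f"{name} band {band} not representable at Nyquist {nyq:.2f} Hz")
        per_source = [_band_fraction(sources[:, j], fs, band) for j in range(sources.shape[1])]
        fracs[name] = per_source

    def best(name, exclude=None):
        cand = [
            (frac, j, fpk)
            for j, (frac, fpk) in enumerate(fracs[name])
            if j != exclude
        ]
        frac, j, fpk = max(cand)
        if frac < MIN_INBAND_FRACTION:
            raise ValueError(
                f"no physiological component found in the {name} band "
                f"(best in-band fraction {frac:.2f} < {MIN_INBAND_FRACTION})"
            )
        return frac, j, fpk

    frac_r, j_r, f_r = best("respiratory")
    frac_c, j_c, f_c = best("cardiac")
    if j_r == j_c:
        # same source tops both bands: keep it for the stronger band
        if frac_c >= frac_r:
            frac_r, j_r, f_r = best("respiratory", exclude=j_c)
        else:
            frac_c, j_c, f_c = best("cardiac", exclude=j_r)
    if f_c >= nyq:
        raise ValueError(f"cardiac frequency {f_c:.2f} Hz exceeds SG Nyquist {nyq:.2f} Hz")
    if not f_r < f_c:
        raise ValueError("respiratory frequency must be below cardiac frequency")

    return MotionSignals(
        cardiac=sources[:, j_c],
        respiratory=sources[:, j_r],
        f_cardiac=f_c,
        f_respiratory=f_r,
        timestamps=np.asarray(timestamps),
        sg_interval=sg_interval,
        mixing_diagnostics={
            "cardiac_inband_fraction": frac_c,
            "respiratory_inband_fraction": frac_r,
            "cardiac_source": j_c,
            "respiratory_source": j_r,
        },
    )


def detect_triggers(motion: MotionSignals, timestamps: np.ndarray | None = None) -> TriggerList:
    """Cardiac triggers = refined peaks of the band-passed cardiac source.

    The source is band-passed around the detected cardiac frequency (+-50%),
    the polarity maximising mean peak prominence is kept, and peak times are
    refined by quadratic interpolation.  The trigger fiducial is arbitrary but
    constant, which the 50 ms binning downstream tolerates.
    """
    t = motion.timestamps if timestamps is None else np.asarray(timestamps)
    if np.ptp(motion.cardiac) == 0:
        raise ValueError("cardiac source is constant; no triggers found")
    dt = motion.sg_interval / 1000.0
    fs = 1.0 / dt
    f = motion.f_cardiac
    lo, hi = 0.5 * f, min(1.5 * f, 0.95 * fs / 2.0)
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, motion.cardiac)
    if np.ptp(x) == 0:
        raise ValueError("cardiac source is constant; no triggers found")

    min_dist = max(1, int(round(0.5 / f / dt)))
    best = None
    for sgn in (1.0, -1.0):
        peaks, props = signal.find_peaks(sgn * x, distance=min_dist, prominence=0.0)
        if peaks.size == 0:
            continue
        score = props["prominences"].mean()
        if best is None or score > best[0]:
            best = (score, sgn, peaks)
    if best is None or best[2].size < 3:
        raise ValueError("fewer than 3 cardiac triggers detected")
    _, sgn, peaks = best
    y = sgn * x

    times = t[peaks].astype(float)
    interior = (peaks > 0) & (peaks < len(y) - 1)
    p = peaks[interior]
    denom = y[p - 1] - 2.0 * y[p] + y[p + 1]
    ok = denom != 0
    offset = np.zeros(p.shape)
    offset[ok] = 0.5 * (y[p - 1] - y[p + 1])[ok] / denom[ok]
    offset = np.clip(offset, -0.5, 0.5)
    times[interior] = t[p] + offset * dt

    keep = np.concatenate([[True], np.diff(times) > MIN_TRIGGER_SEPARATION_S])
    return TriggerList(times=times[keep])


def respiratory_states(
    motion: MotionSignals,
    readout_timestamps: np.ndarray,
    n_states: int = 4,
) -> np.ndarray:
    """Equally populated respiratory amplitude states per imaging readout.

    The respiratory source is interpolated to every imaging-readout timestamp
    and split at its rank quartiles (populations equal within +-1).  State 0
    is end-expiration, identified by dwell: natural breathing plateaus at
    end-expiration, so the signal's probability mass concentrates at the
    expiratory end of its range.  The sample skewness locates that dense end
    robustly (positive skew = long dwell at the low end), which fixes the
    arbitrary blind-source polarity without any sign convention.
    """
    if n_states != 4:
        logger.info("using %d respiratory states (4 is the standard choice)", n_states)
    t = np.asarray(readout_timestamps)
    if t.min() < motion.timestamps[0] - motion.sg_interval / 1000.0 or t.max() > motion.timestamps[-1] + motion.sg_interval / 1000.0:
        raise ValueError("respiratory signal does not span the readout time range")
    resp = np.interp(t, motion.timestamps, motion.respiratory)
    n = resp.size
    ranks = np.argsort(np.argsort(resp, kind="stable"), kind="stable")
    states = (ranks * n_states) // n

    centred = resp - resp.mean()
    sd = centred.std()
    skew = float((centred**3).mean() / sd**3) if sd > 0 else 0.0
    if skew < 0:  # dense (plateau) end is at high amplitudes: flip
        states = (n_states - 1) - states
    return states.astype(np.int64)
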