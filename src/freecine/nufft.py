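"""Kaiser-Bessel gridding non-uniform FFT (type 2) with an exact-transpose adjoint.

The forward operator approximates the centred DFT sum

    s(k) = (1 / sqrt(prod(os_shape))) * sum_u x(u) exp(-2*pi*i * k . u)

for k in cycles/voxel (|k_j| <= 0.5) and centred voxel indices u, via
deapodisation, zero-padding to an oversampled grid, an orthonormal FFT and
Kaiser-Bessel interpolation (kernel width 3, oversampling 1.5 by default,
relative accuracy ~2e-2 against the exact DFT).  The adjoint is the exact
algebraic transpose of each linear step, so the inner-product test holds to
machine precision by construction.

Interpolation is a numba gather/scatter over precomputed per-axis kernel
weights; batch (e.g. coil) dimensions are carried through as extra columns.
"""

from __future__ import annotations

import numba
import numpy as np
import scipy.fft as sfft
from numpy import i0 as bessel_i0

__all__ = ["GriddingPlan", "NufftOperator3D", "kb_beta"]


def kb_beta(width: int, osf: float) -> float:
    """Beatty et al. optimal Kaiser-Bessel shape parameter."""
    arg = (width / osf) ** 2 * (osf - 0.5) ** 2 - 0.8
    return float(np.pi * np.sqrt(max(arg, 0.0)))


def _kb_kernel(tau: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel at grid-unit offsets tau (zero outside support)."""
    inside = np.abs(tau) <= width / 2.0
    out = np.zeros_like(tau, dtype=np.float64)
    t = tau[inside]
    out[inside] = bessel_i0(beta * np.sqrt(1.0 - (2.0 * t / width) ** 2))
    return out


def _kb_transform(xi: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the kernel at frequency xi (1/grid unit)."""
    arg = beta**2 - (np.pi * width * xi) ** 2
    out = np.empty_like(xi, dtype=np.float64)
    pos = arg > 0
    r = np.sqrt(arg[pos])
    out[pos] = np.sinh(r) / r
    r = np.sqrt(-arg[~pos])
    out[~pos] = np.sinc(r / np.pi)
    return width * out


@numba.njit(fastmath=True)
def _interp_forward(spec, base, wts, no_y, no_z, no_x, out):  # pragma: no cover
    m, b = out.shape
    w = wts.shape[2]
    for i in range(m):
        for a in range(w):
            ix = (base[i, 0] + a) % no_x
            wx = wts[i, 0, a]
            for bb in range(w):
                iy = (base[i, 1] + bb) % no_y
                wxy = wx * wts[i, 1, bb]
                for c in range(w):
                    iz = (base[i, 2] + c) % no_z
                    wxyz = wxy * wts[i, 2, c]
                    idx = (ix * no_y + iy) * no_z + iz
                    for col in range(b):
                        out[i, col] += wxyz * spec[idx, col]


@numba.njit(fastmath=True)
def _interp_adjoint(y, base, wts, no_y, no_z, no_x, spec):  # pragma: no cover
    m, b = y.shape
    w = wts.shape[2]
    for i in range(m):
        for a in range(w):
            ix = (base[i, 0] + a) % no_x
            wx = wts[i, 0, a]
            for bb in range(w):
                iy = (base[i, 1] + bb) % no_y
                wxy = wx * wts[i, 1, bb]
                for c in range(w):
                    iz = (base[i, 2] + c) % no_z
                    wxyz = wxy * wts[i, 2, c]
                    idx = (ix * no_y + iy) * no_z + iz
                    for col in range(b):
                        spec[idx, col] += wxyz * y[i, col]


class GriddingPlan:
    """Fixed-grid part of the NUFFT: oversampled orthonormal FFT + deapodisation."""

    def __init__(self, grid_shape, osf: float = 1.5, width: int = 3, dtype=np.complex64):
        self.grid_shape = tuple(int(n) for n in grid_shape)
        self.osf = float(osf)
        self.width = int(width)
        if self.width % 2 == 0:
            raise ValueError("kernel width must be odd (nearest-point centring)")
        self.dtype = np.dtype(dtype)
        self._real = np.float32 if self.dtype == np.complex64 else np.float64
        self.beta = kb_beta(self.width, self.osf)
        self.os_shape = tuple(int(np.ceil(n * osf / 2.0) * 2) for n in self.grid_shape)
        self._deapod = []
        for n, no in zip(self.grid_shape, self.os_shape):
            u = np.arange(n) - n // 2
            self._deapod.append(
                (1.0 / _kb_transform(u / no, self.width, self.beta)).astype(self._real)
            )

    def _apodize(self, img: np.ndarray) -> np.ndarray:
        d = self._deapod
        return img * d[0][:, None, None] * d[1][None, :, None] * d[2][None, None, :]

    def _crop_slices(self):
        sl = []
        for n, no in zip(self.grid_shape, self.os_shape):
            lo = no // 2 - n // 2
            sl.append(slice(lo, lo + n))
        return tuple(sl)

    def to_spectrum(self, img: np.ndarray) -> np.ndarray:
        """Image(s) (..., Nx, Ny, Nz) -> oversampled spectrum in natural FFT order.

        The image is placed centred in the padded grid without an ifftshift;
        the resulting per-frequency sign (-1)**(fx+fy+fz) is folded into the
        interpolation weights by :meth:`sample_weights`.
        """
        x = self._apodize(np.asarray(img).astype(self.dtype, copy=False))
        out = np.zeros(x.shape[:-3] + self.os_shape, dtype=self.dtype)
        out[(Ellipsis,) + self._crop_slices()] = x
        return sfft.fftn(out, axes=(-3, -2, -1), norm="ortho", overwrite_x=True)

    def from_spectrum(self, spec: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`to_spectrum` (may overwrite its input)."""
        x = sfft.ifftn(spec, axes=(-3, -2, -1), norm="ortho", overwrite_x=True)
        x = np.ascontiguousarray(x[(Ellipsis,) + self._crop_slices()])
        return self._apodize(x)

    def sample_weights(self, kpoints: np.ndarray):
        """Per-axis base indices and kernel weights for a set of k points.

        Weights absorb the (-1)**f sign of the natural-order spectrum, so the
        interpolation evaluates the centred DFT directly.
        """
        k = np.asarray(kpoints, dtype=np.float64).reshape(-1, 3)
        w = self.width
        offs = np.arange(w) - w // 2
        base = np.empty((k.shape[0], 3), dtype=np.int64)
        wts = np.empty((k.shape[0], 3, w), dtype=self._real)
        for ax in range(3):
            no = self.os_shape[ax]
            g = k[:, ax] * no  # frequency index (natural order, signed)
            nearest = np.round(g).astype(np.int64)
            taps = nearest[:, None] + offs[None, :]
            sign = 1.0 - 2.0 * np.mod(taps, 2)
            wts[:, ax, :] = _kb_kernel(g[:, None] - taps, w, self.beta) * sign
            base[:, ax] = nearest - w // 2
        return base, wts


class NufftOperator3D:
    """NUFFT bound to a fixed set of sample points (forward and exact adjoint)."""

    def __init__(self, plan: GriddingPlan, kpoints: np.ndarray):
        self.plan = plan
        self.base, self.wts = plan.sample_weights(kpoints)
        self.n_samples = self.base.shape[0]

    def interp(self, spec: np.ndarray) -> np.ndarray:
        """Interpolate an oversampled spectrum (B, *os_shape) to samples (M, B)."""
        b = spec.shape[0]
        flat = np.ascontiguousarray(spec.reshape(b, -1).T)
        out = np.zeros((self.n_samples, b), dtype=self.plan.dtype)
        nx, ny, nz = self.plan.os_shape
        _interp_forward(flat, self.base, self.wts, ny, nz, nx, out)
        return out

    def spread(self, samples: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`interp`: samples (M, B) -> (B, *os_shape)."""
        y = np.ascontiguousarray(samples.astype(self.plan.dtype, copy=False))
        b = y.shape[1]
        nx, ny, nz = self.plan.os_shape
        flat = np.zeros((nx * ny * nz, b), dtype=self.plan.dtype)
        _interp_adjoint(y, self.base, self.wts, ny, nz, nx, flat)
        return np.ascontiguousarray(flat.T).reshape((b, nx, ny, nz))

    def forward(self, img: np.ndarray) -> np.ndarray:
        """img: (Nx, Ny, Nz) or (B, Nx, Ny, Nz) -> samples (M,) or (M, B)."""
        single = img.ndim == 3
        spec = self.plan.to_spectrum(img if not single else img[None])
        out = self.interp(spec)
        return out[:, 0] if single else out

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """samples: (M,) or (M, B) -> image (Nx, Ny, Nz) or (B, Nx, Ny, Nz)."""
        single = samples.ndim == 1
        y = samples[:, None] if single else samples
        b = y.shape[1]
        nx, ny, nz = self.plan.os_shape
        flat = np.zeros((nx * ny * nz, b), dtype=self.plan.dtype)
        _interp_adjoint(
            np.ascontiguousarray(y.astype(self.plan.dtype, copy=False)),
            self.base, self.wts, ny, nz, nx, flat,
        )
        spec = np.ascontiguousarray(flat.T).reshape((b, nx, ny, nz))
        img = self.plan.from_spectrum(spec)
        return img[0] if single else img
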