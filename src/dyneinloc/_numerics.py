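"""Differentiation and antidifferentiation on uniform grids.

Two routes, chosen by the caller:

* spectral (FFT) derivatives for periodic grids — exact for band-limited
  fields, which the analytic traveling-wave fixtures are;
* Fornberg finite-difference stencils of arbitrary derivative order and
  accuracy for non-periodic grids, with one-sided closures at boundaries.

Grids exclude the periodic endpoint: a periodic grid of n points with
spacing h covers a domain of length n·h.
"""

from __future__ import annotations

import numpy as np

from .core import GridError

__all__ = [
    "check_uniform",
    "spectral_derivative",
    "spectral_antiderivative",
    "fornberg_weights",
    "fd_derivative",
]


def check_uniform(grid: np.ndarray, name: str = "grid") -> float:
    """Validate a strictly increasing uniform grid; return its spacing."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise GridError(f"{name} must be 1-D with at least 2 points")
    d = np.diff(grid)
    if np.any(d <= 0):
        raise GridError(f"{name} must be strictly increasing")
    h = d[0]
    if not np.allclose(d, h, rtol=1e-6, atol=1e-12 * abs(h)):
        raise GridError(f"{name} must be uniformly spaced")
    return float(h)


def spectral_derivative(y: np.ndarray, period: float, order: int, axis: int = -1) -> np.ndarray:
    """Order-``order`` derivative along ``axis`` of a periodic sampled field."""
    y = np.asarray(y, dtype=float)
    n = y.shape[axis]
    k = 2j * np.pi * np.fft.rfftfreq(n, d=period / n)
    Y = np.fft.rfft(y, axis=axis)
    shape = [1] * y.ndim
    shape[axis] = k.size
    Y = Y * (k.reshape(shape) ** order)
    if order % 2 == 1 and n % 2 == 0:
        # The Nyquist mode has no well-defined odd derivative on a real grid.
        idx = [slice(None)] * y.ndim
        idx[axis] = -1
        Y[tuple(idx)] = 0.0
    return np.fft.irfft(Y, n=n, axis=axis)


def spectral_antiderivative(y: np.ndarray, period: float, axis: int = -1) -> np.ndarray:
    """Zero-mean antiderivative along ``axis`` of a periodic sampled field.

    The DC (mean) mode of the input is discarded — the antiderivative of a
    periodic field is only defined up to the mean of the input being zero —
    and the output is normalized to zero spatial mean.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[axis]
    k = 2j * np.pi * np.fft.rfftfreq(n, d=period / n)
    Y = np.fft.rfft(y, axis=axis)
    shape = [1] * y.ndim
    shape[axis] = k.size
    k = k.reshape(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        Y = np.where(k == 0, 0.0, Y / np.where(k == 0, 1.0, k))
    return np.fft.irfft(Y, n=n, axis=axis)


def fornberg_weights(offsets: np.ndarray, order: int) -> np.ndarray:
    """Finite-difference weights at node offsets for the ``order``-th derivative.

    Classic recursive algorithm for weights on arbitrarily spaced nodes
    (here offsets relative to the evaluation point, in grid units or
    physical units — the caller scales).
    """
    xs = np.asarray(offsets, dtype=float)
    n = xs.size
    if n < order + 1:
        raise ValueError("need at least order+1 nodes")
    c = np.zeros((n, order + 1))
    c1 = 1.0
    c4 = xs[0]
    c[0, 0] = 1.0
    for i in range(1, n):
        mn = min(i, order)
        c2 = 1.0
        c5 = c4
        c4 = xs[i]
        for j in range(i):
            c3 = xs[i] - xs[j]
            c2 *= c3
            if j == i - 1:
                for m in range(mn, 0, -1):
                    c[i, m] = c1 * (m * c[i - 1, m - 1] - c5 * c[i - 1, m]) / c2
                c[i, 0] = -c1 * c5 * c[i - 1, 0] / c2
            for m in range(mn, 0, -1):
                c[j, m] = (c4 * c[j, m] - m * c[j, m - 1]) / c3
            c[j, 0] = c4 * c[j, 0] / c3
        c1 = c2
    return c[:, order]


def fd_derivative(
    y: np.ndarray, h: float, order: int, axis: int = -1, accuracy: int = 4
) -> np.ndarray:
    """Finite-difference derivative on a uniform non-periodic grid.

    Centered stencils of the requested accuracy in the interior, shifted
    (one-sided) stencils of the same width near the boundaries.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[axis]
    s = order + accuracy
    if s % 2 == 0:
        s += 1
    if n < s:
        raise GridError(
            f"need at least {s} samples along the differentiated axis for "
            f"derivative order {order} at accuracy {accuracy}; got {n}"
        )
    y2 = np.moveaxis(y, axis, -1)
    flat = y2.reshape(-1, n)
    out = np.empty_like(flat)
    half = s // 2
    cache: dict[int, np.ndarray] = {}
    for i in range(n):
        start = min(max(i - half, 0), n - s)
        shift = start - i
        w = cache.get(shift)
        if w is None:
            offsets = (np.arange(s) + shift) * h
            w = fornberg_weights(offsets, order)
            cache[shift] = w
        out[:, i] = flat[:, start : start + s] @ w
    return np.moveaxis(out.reshape(y2.shape), -1, axis)
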