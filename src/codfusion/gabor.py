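"""2D Gabor filter bank for EEM texture-feature extraction.

A Gabor kernel is a Gaussian envelope times a complex sinusoid,

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * exp(i (2 pi x'/lambda + psi))
    x' =  x cos(theta) + y sin(theta)
    y' = -x sin(theta) + y cos(theta)

with wavelength lambda (px), orientation theta, phase psi, bandwidth sigma
(default 2*pi) and aspect ratio gamma (default 0.5).  The kernel's square
spatial extent follows the 3-sigma rule applied to the envelope ellipse
(long axis 3*sigma/gamma):

    Xmax = max(3 sigma cos(theta), (3 sigma / gamma) sin(theta))
    Ymax = max(3 sigma sin(theta), (3 sigma / gamma) cos(theta))
    K    = ceil(max(Xmax, Ymax)), rounded up to odd

The default bank is 35 kernels — lambda in {3, 6, 9, 12, 15} (wavelength-
major order) crossed with theta in {0, pi/12, pi/8, pi/6, pi/4, pi/3,
3 pi/8}.  Applying the bank to an upsampled EEM gives, per kernel, the
complex-response magnitude with reflect border handling, min–max scaled to
the 0–255 gray range and bilinearly resized to the feature grid (default
554 x 554, so a flattened response has 306,916 rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from skimage.transform import resize

from .synth import EEM

DEFAULT_SIGMA = 2.0 * math.pi
DEFAULT_GAMMA = 0.5
DEFAULT_LAMS = (3.0, 6.0, 9.0, 12.0, 15.0)
DEFAULT_THETAS = (0.0, math.pi / 12, math.pi / 8, math.pi / 6,
                  math.pi / 4, math.pi / 3, 3 * math.pi / 8)
FEATURE_SIDE = 554


@dataclass(frozen=True)
class GaborParams:
    lam: float
    theta: float
    psi: float = 0.0
    sigma: float = DEFAULT_SIGMA
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not (0.0 <= self.theta < math.pi / 2):
            raise ValueError("theta must lie in [0, pi/2)")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if not (-math.pi <= self.psi <= math.pi):
            raise ValueError("psi must lie in [-pi, pi]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class GaborKernel:
    real: np.ndarray
    imag: np.ndarray
    params: GaborParams
    K: int

    @property
    def complex(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.complex)


@dataclass(frozen=True)
class GaborBank:
    kernels: tuple[GaborKernel, ...]

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass(frozen=True)
class ResponseStack:
    """Per-kernel grayscale responses on the feature grid, values in [0, 255]."""

    responses: np.ndarray       # (n_kernels, H, W)

    def __post_init__(self) -> None:
        if self.responses.ndim != 3:
            raise ValueError("responses must be a (n_kernels, H, W) stack")


def kernel_extent(params: GaborParams) -> int:
    """Odd square side length (px) of the kernel's spatial support."""
    long_axis = 3.0 * params.sigma / params.gamma
    short_axis = 3.0 * params.sigma
    x_max = max(short_axis * math.cos(params.theta), long_axis * math.sin(params.theta))
    y_max = max(short_axis * math.sin(params.theta), long_axis * math.cos(params.theta))
    k = math.ceil(max(x_max, y_max))
    return k if k % 2 == 1 else k + 1


def make_kernel(params: GaborParams) -> GaborKernel:
    """Evaluate the closed-form kernel on the integer grid centered at 0."""
    k = kernel_extent(params)
    half = k // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xp = x * math.cos(params.theta) + y * math.sin(params.theta)
    yp = -x * math.sin(params.theta) + y * math.cos(params.theta)
    envelope = np.exp(-(xp**2 + (params.gamma * yp)**2) / (2.0 * params.sigma**2))
    phase = 2.0 * math.pi * xp / params.lam + params.psi
    return GaborKernel(real=envelope * np.cos(phase),
                       imag=envelope * np.sin(phase),
                       params=params, K=k)


def build_bank(
    lams: tuple[float, ...] = DEFAULT_LAMS,
    thetas: tuple[float, ...] = DEFAULT_THETAS,
    psi: float = 0.0,
    sigma: float = DEFAULT_SIGMA,
    gamma: float = DEFAULT_GAMMA,
) -> GaborBank:
    """Wavelength-major bank: kernel index = lam_index * len(thetas) + theta_index."""
    if not lams or not thetas:
        raise ValueError("parameter grids must be non-empty")
    pairs = [(l, t) for l in lams for t in thetas]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (lam, theta) pairs in bank")
    kernels = tuple(
        make_kernel(GaborParams(lam=l, theta=t, psi=psi, sigma=sigma, gamma=gamma))
        for l, t in pairs
    )
    return GaborBank(kernels)


def convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size 2D convolution with reflect padding (direct definition).

    y[i, j] = sum_{u,v} image_padded[i - u + c, j - v + c] * kernel[u + c, v + c]

    Computed via FFT; used both standalone and inside :func:`apply_bank`.
    """
    k = kernel.shape[0]
    if k > min(image.shape):
        raise ValueError("kernel larger than image")
    pad = k // 2
    padded = np.pad(image, pad, mode="reflect")
    s0 = scipy.fft.next_fast_len(padded.shape[0] + k - 1)
    s1 = scipy.fft.next_fast_len(padded.shape[1] + k - 1)
    f = scipy.fft.fft2(padded, (s0, s1)) * scipy.fft.fft2(kernel, (s0, s1))
    full = scipy.fft.ifft2(f)
    # center crop of the 'full' convolution back to the image frame
    r0 = pad + (k - 1) // 2
    r1 = pad + (k - 1) // 2
    out = full[r0:r0 + image.shape[0], r1:r1 + image.shape[1]]
    return out if np.iscomplexobj(kernel) else out.real


def _bank_responses_raw(image: np.ndarray, bank: GaborBank) -> list[np.ndarray]:
    """Complex-magnitude responses of all kernels, sharing one padded-image FFT."""
    kmax = max(k.K for k in bank.kernels)
    if kmax > min(image.shape):
        raise ValueError("kernel larger than image")
    pad = kmax // 2
    padded = np.pad(image, pad, mode="reflect")
    s0 = scipy.fft.next_fast_len(padded.shape[0] + kmax - 1)
    s1 = scipy.fft.next_fast_len(padded.shape[1] + kmax - 1)
    fimg = scipy.fft.fft2(padded, (s0, s1))
    out = []
    for kern in bank.kernels:
        fk = scipy.fft.fft2(kern.complex, (s0, s1))
        full = scipy.fft.ifft2(fimg * fk)
        r = pad + (kern.K - 1) // 2
        out.append(np.abs(full[r:r + image.shape[0], r:r + image.shape[1]]))
    return out


def grayscale(response: np.ndarray) -> np.ndarray:
    """Min–max scale a response to the [0, 255] gray range (flat -> zeros)."""
    lo, hi = response.min(), response.max()
    if hi - lo <= 0:
        return np.zeros_like(response)
    return 255.0 * (response - lo) / (hi - lo)


def apply_bank(
    eem: EEM, bank: GaborBank, feature_side: int = FEATURE_SIDE
) -> ResponseStack:
    """Filter an upsampled EEM with every kernel of the bank.

    Per kernel: complex convolution with reflect padding, magnitude, min–max
    scaling to [0, 255], bilinear resize to the feature grid.
    """
    raw = _bank_responses_raw(eem.intensity.astype(float), bank)
    stack = np.empty((len(bank), feature_side, feature_side), dtype=np.float32)
    for i, resp in enumerate(raw):
        g = grayscale(resp)
        if g.shape != (feature_side, feature_side):
            g = resize(g, (feature_side, feature_side), order=1,
                       anti_aliasing=False, preserve_range=True)
        stack[i] = np.clip(g, 0.0, 255.0)
    return ResponseStack(stack)


def flatten_features(stack: ResponseStack, order: str = "ex-major") -> np.ndarray:
    """Flatten responses to a (pixels x kernels) feature matrix.

    Responses are stored (emission row, excitation column); "ex-major" makes
    the excitation index vary slowest along the rows (row = ex_idx * H +
    em_idx), "em-major" the reverse (row = em_idx * W + ex_idx).
    """
    r = stack.responses
    if order == "ex-major":
        cols = [img.T.reshape(-1) for img in r]
    elif order == "em-major":
        cols = [img.reshape(-1) for img in r]
    else:
        raise ValueError(f"unknown flatten order {order!r}")
    return np.stack(cols, axis=1)
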